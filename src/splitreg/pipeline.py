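"""End-to-end orchestration: simulate/load -> normalize -> test -> decompose.

A run is fully described by a :class:`PipelineConfig`; the echoed config
plus the master seed reproduce the artifact directory bit-for-bit.
Outputs are written atomically: everything goes to a temporary sibling
directory that replaces the target only on success, so a failed run
leaves no partial outputs behind.
"""

from __future__ import annotations

import logging
import shutil
import tempfile
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .decompose import AutoregulationDecomposer
from .densitometry import LoadingConfig, free_poly_ratio, quantify_relative
from .nanostring import CountMatrix, NanoStringNormalizer
from .proteomics import DigestionRule, PeptideRollup, concordance
from .stats import GroupComparator, log2fc_vs_ctrl
from .simulate import StudyBundle, scenario_suite

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable description of a full run."""

    scenario: str | None = None       # named synthetic scenario ...
    input_dir: str | None = None      # ... or an existing bundle directory
    seed: int = 0
    control: str = "Ctrl"
    family_size: int = 2
    cutoff: float = 0.025
    pseudocount: float = 0.5
    reference: str = "geometric"
    combine: str = "mean-of-logs"
    effect: float = 2.0
    with_proteomics: bool = False
    max_missed_cleavages: int = 2
    enzyme: str = "trypsin"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_bundle(cfg: PipelineConfig) -> StudyBundle:
    if (cfg.scenario is None) == (cfg.input_dir is None):
        raise ValueError("exactly one of scenario or input_dir must be given")
    if cfg.scenario is not None:
        return scenario_suite(cfg.scenario, seed=cfg.seed, effect=cfg.effect,
                              with_proteomics=cfg.with_proteomics)
    path = Path(cfg.input_dir)
    for required in ("counts.csv", "probes.csv", "samples.csv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"input bundle is missing {required} (looked in {path})")
    return StudyBundle.read(path)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full analysis described by ``config`` and write the artifact
    directory (normalized.csv, factors.csv, comparisons.csv, calls.csv,
    scatter.csv, optional proteomics/densitometry tables, run.log,
    config_echo.yaml).  Raises on any validation failure, removing
    partial outputs."""
    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".splitreg-run-", dir=out_dir.parent))
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        log(f"splitreg {__version__}; seed={config.seed}")
        bundle = _load_bundle(config)
        cm: CountMatrix = bundle.counts
        log(f"input: {cm.counts.shape[0]} probes x {cm.counts.shape[1]} samples "
            f"({'scenario ' + repr(bundle.scenario) if config.scenario else config.input_dir})")

        norm_est = NanoStringNormalizer().fit(cm)
        norm = norm_est.transform(cm)
        norm.values.to_csv(tmp / "normalized.csv")
        pd.DataFrame({"pos_factor": norm.pos_factors, "hk_factor": norm.hk_factors}).to_csv(
            tmp / "factors.csv")
        (tmp / "exclusions.log").write_text(
            "\n".join([f"background_threshold {norm.background_threshold:.4f}"]
                      + norm.excluded_controls) + "\n")
        log(f"normalized; background threshold {norm.background_threshold:.3f}, "
            f"{len(norm.excluded_controls)} control exclusion(s)")

        endo = norm.probes.index[norm.probes["class"] == "endogenous"]
        comp = GroupComparator(control=config.control, family_size=config.family_size,
                               pseudocount=config.pseudocount).fit(
            norm.values.loc[endo], samples=norm.samples)
        comp.results_.to_csv(tmp / "comparisons.csv", index=False)

        dec = AutoregulationDecomposer(
            control=config.control, family_size=config.family_size, cutoff=config.cutoff,
            pseudocount=config.pseudocount, reference=config.reference,
            combine=config.combine).fit(norm)
        dec.calls_.to_csv(tmp / "calls.csv", index=False)
        dec.scatter_.to_csv(tmp / "scatter.csv", index=False)
        mode_counts = dec.calls_["mode"].value_counts().to_dict()
        log(f"decomposition: {len(dec.calls_)} calls, modes {mode_counts}")

        if bundle.peptides is not None and bundle.proteome is not None:
            rule = DigestionRule(enzyme=config.enzyme,
                                 max_missed_cleavages=config.max_missed_cleavages)
            roll = PeptideRollup(bundle.proteome, rule)
            ab = roll.transform(bundle.peptides)
            ab.to_csv(tmp / "abundances.csv")
            log(f"proteomics: {ab.shape[0]} quantifiable isoforms; "
                f"not quantifiable: {roll.not_quantifiable_}")
            groups = norm.samples["group"]
            ctrl_cols = [s for s in ab.columns if groups.get(s) == config.control]
            trt_cols = [s for s in ab.columns if groups.get(s) != config.control]
            if len(ctrl_cols) >= 2 and len(trt_cols) >= 2:
                prot_lfc = pd.Series({
                    iso: float(log2fc_vs_ctrl(ab.loc[iso, trt_cols],
                                              ab.loc[iso, ctrl_cols], 0.0).mean())
                    for iso in ab.index})
                mrna = dec.calls_.groupby("isoform")["dE"].mean()
                res = concordance(mrna, prot_lfc)
                pd.DataFrame([{"slope": res.slope, "intercept": res.intercept,
                               "r2": res.r2, "p": res.p, "n": res.n}]).to_csv(
                    tmp / "concordance.csv", index=False)
                log(f"concordance: slope {res.slope:.3f}, R2 {res.r2:.3f}, p {res.p:.2e}")

        if bundle.densitometry is not None:
            rel = quantify_relative(bundle.densitometry, norm.samples, target="alpha-tub",
                                    normalizer="GAPDH", control=config.control)
            ratio = free_poly_ratio(bundle.densitometry, LoadingConfig())
            pd.DataFrame({"alpha_tub_vs_GAPDH": rel, "free_poly_ratio": ratio}).to_csv(
                tmp / "relquant.csv")
            log("densitometry: wrote relquant.csv")

        if config.scenario is not None:
            bundle.truth.to_csv(tmp / "truth.csv", index=False)
        (tmp / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        (tmp / "run.log").write_text("\n".join(log_lines) + "\n")

        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
        return out_dir
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
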