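"""Mechanistic synthetic-data generator with known ground truth.

Generates study-shaped data for every stage of the pipeline — panel
count tables with control probes, western-blot densitometry and peptide
intensity tables — by running the autoregulation model of
:mod:`splitreg.kinetics` under a named experimental scenario and layering
the platform's noise structure on top:

* replicate-level biological variation (lognormal CV on transcription
  rates),
* per-lane technical scaling (lognormal lane factors),
* counting noise (negative binomial with dispersion phi; Poisson at
  phi = 0), plus additive background on every probe.

Each bundle carries per-isoform ground-truth regulation modes derived
from which kinetic parameters actually differ between groups, so
recovery of the truth by the analysis modules is a measurable quantity.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .densitometry import LoadingConfig
from .kinetics import (
    CellState,
    IsoformKinetics,
    PerturbationSpec,
    PoolKinetics,
    simulate_trajectory,
    steady_state,
)
from .nanostring import CountMatrix
from .proteomics import DigestionRule, digest

__all__ = [
    "StudyDesign",
    "GroupModel",
    "StudyBundle",
    "default_isoform_kinetics",
    "default_probe_annotation",
    "generate_count_matrix",
    "generate_densitometry",
    "generate_peptide_table",
    "toy_isoform_proteome",
    "truth_labels",
    "scenario_suite",
    "SCENARIOS",
    "simulate_study",
]

DEFAULT_ISOFORMS = ("Tuba1a", "Tuba1b", "Tuba4a", "Tuba8", "Tubb2a", "Tubb2b", "Tubb5", "Tubb6")
# per-isoform transcription rates: spread over ~2.3x, as real panels are
_DEFAULT_KTX = (140.0, 110.0, 80.0, 60.0, 120.0, 90.0, 130.0, 100.0)
HOUSEKEEPING_LEVELS = {"Gapdh": 8000.0, "Rpl4": 3000.0, "Tbp": 600.0}
# six-point geometric ladder, ratio 4, lowest point "F"
POSITIVE_LADDER = {"POS_A": 128.0, "POS_B": 32.0, "POS_C": 8.0,
                   "POS_D": 2.0, "POS_E": 0.5, "POS_F": 0.125}


@dataclass(frozen=True)
class StudyDesign:
    """Replication and noise structure of a synthetic study.

    groups maps group label -> replicate count (>= 2 each); horizon_h is
    the readout time after perturbation onset; biological_cv is the
    lognormal CV applied to each replicate's transcription rates;
    lane_sigma the lognormal sigma of per-lane scaling; dispersion the
    negative-binomial overdispersion phi (variance = mu + phi mu^2;
    Poisson at 0); background_mean the mean additive background count;
    w_pre the weight with which exonic probes also see pre-mRNA.
    """

    groups: Mapping[str, int] = field(default_factory=lambda: {"Ctrl": 6, "Treated": 6})
    control: str = "Ctrl"
    horizon_h: float = 6.0
    biological_cv: float = 0.10
    lane_sigma: float = 0.10
    dispersion: float = 0.005
    background_mean: float = 4.0
    w_pre: float = 1.0

    def __post_init__(self) -> None:
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not in groups")
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("each group needs >= 2 replicates")
        if self.horizon_h <= 0:
            raise ValueError("horizon_h must be > 0")
        for name in ("biological_cv", "lane_sigma", "dispersion", "background_mean", "w_pre"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroupModel:
    """The kinetic model one group's cells obey."""

    kins: tuple[IsoformKinetics, ...]
    pool: PoolKinetics
    perturbation: PerturbationSpec = PerturbationSpec()


def default_isoform_kinetics(isoforms: Sequence[str] = DEFAULT_ISOFORMS,
                             alpha: float = 5.0, **overrides) -> list[IsoformKinetics]:
    """Panel of isoform kinetics with realistic heterogeneous expression."""
    k_tx = overrides.pop("k_tx", None)
    out = []
    for i, iso in enumerate(isoforms):
        ktx = k_tx if k_tx is not None else _DEFAULT_KTX[i % len(_DEFAULT_KTX)]
        out.append(IsoformKinetics(isoform_id=iso, k_tx=ktx, alpha=alpha, **overrides))
    return out


def default_probe_annotation(isoforms: Sequence[str] = DEFAULT_ISOFORMS,
                             exon_efficiency: float = 6.0,
                             intron_efficiency: float = 20.0,
                             positive_efficiency: float = 150.0,
                             n_negatives: int = 8) -> pd.DataFrame:
    """Panel annotation: exon+intron probe per isoform, 6 positives, negatives, 3 HK."""
    rows = {}
    for iso in isoforms:
        rows[f"{iso}_exon"] = dict(gene=iso, region="exon", class_="endogenous",
                                   expected_conc=np.nan, efficiency=exon_efficiency, level=np.nan)
        rows[f"{iso}_intron"] = dict(gene=iso, region="intron", class_="endogenous",
                                     expected_conc=np.nan, efficiency=intron_efficiency, level=np.nan)
    for name, conc in POSITIVE_LADDER.items():
        rows[name] = dict(gene=name, region=np.nan, class_="positive",
                          expected_conc=conc, efficiency=positive_efficiency, level=np.nan)
    for i in range(n_negatives):
        rows[f"NEG_{i + 1}"] = dict(gene=f"NEG_{i + 1}", region=np.nan, class_="negative",
                                    expected_conc=np.nan, efficiency=np.nan, level=np.nan)
    for name, level in HOUSEKEEPING_LEVELS.items():
        rows[name] = dict(gene=name, region=np.nan, class_="housekeeping",
                          expected_conc=np.nan, efficiency=np.nan, level=level)
    probes = pd.DataFrame.from_dict(rows, orient="index")
    probes = probes.rename(columns={"class_": "class"})
    probes.index.name = "probe_id"
    return probes


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with variance mu + phi*mu^2 (Poisson at phi = 0)."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(mu).all():
        raise ValueError("non-finite probe means (invalid cell state?)")
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + np.where(mu > 0, mu, 1.0))
    out = rng.negative_binomial(r, p)
    return np.where(mu > 0, out, 0)


def generate_count_matrix(
    states: Mapping[str, CellState],
    probes: pd.DataFrame,
    design: StudyDesign,
    sample_groups: Mapping[str, str],
    rng: np.random.Generator,
    lane_factors: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Draw a probe x sample integer count matrix from per-sample cell states.

    Probe means: exon -> lane * eff * (M + w_pre * P); intron -> lane * eff * P;
    positive -> lane * eff * expected_conc; housekeeping -> lane * level;
    negatives carry background only.  Additive background (mean
    ``background_mean``) applies to every probe; counts are negative
    binomial with dispersion phi (Poisson when phi = 0).
    """
    classes = set(probes["class"])
    if not {"positive", "negative", "housekeeping"} <= classes:
        raise ValueError("probe annotation must include positive, negative and housekeeping probes")
    sample_ids = list(states)
    if lane_factors is None:
        # lane factors are lognormal with sigma = lane_sigma (not CV-parameterized)
        lane_factors = {
            s: float(np.exp(rng.normal(0.0, design.lane_sigma))) if design.lane_sigma > 0 else 1.0
            for s in sample_ids
        }
    means = np.zeros((len(probes), len(sample_ids)))
    for j, s in enumerate(sample_ids):
        st = states[s]
        lane = lane_factors[s]
        idx = {iso: i for i, iso in enumerate(st.isoform_ids)}
        for i, (pid, row) in enumerate(probes.iterrows()):
            cls = row["class"]
            if cls == "endogenous":
                if row["gene"] not in idx:
                    raise ValueError(f"probe {pid!r} targets isoform {row['gene']!r} absent from the model")
                k = idx[row["gene"]]
                signal = (st.M[k] + design.w_pre * st.P[k]) if row["region"] == "exon" else st.P[k]
                means[i, j] = lane * row["efficiency"] * signal
            elif cls == "positive":
                means[i, j] = lane * row["efficiency"] * row["expected_conc"]
            elif cls == "housekeeping":
                means[i, j] = lane * row["level"]
            # negatives: background only
    means += design.background_mean
    counts = _nb_draw(rng, means, design.dispersion).astype(int)
    counts_df = pd.DataFrame(counts, index=probes.index, columns=sample_ids)
    samples = pd.DataFrame({
        "group": [sample_groups[s] for s in sample_ids],
        "lane": range(1, len(sample_ids) + 1),
        "lane_factor": [lane_factors[s] for s in sample_ids],
    }, index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(counts_df, probes.copy(), samples)


def simulate_study(
    models: Mapping[str, GroupModel],
    design: StudyDesign,
    probes: pd.DataFrame | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[CountMatrix, dict[str, CellState]]:
    """Simulate every replicate of every group and draw the count matrix.

    Each replicate gets its own biological parameter draw (lognormal CV
    on every isoform's k_tx), its own baseline steady state, and — for
    perturbed groups — a finite-horizon trajectory readout at
    ``design.horizon_h`` after drug onset.
    """
    rng = np.random.default_rng(rng)
    if probes is None:
        probes = default_probe_annotation([k.isoform_id for k in models[design.control].kins])
    states: dict[str, CellState] = {}
    sample_groups: dict[str, str] = {}
    for group, n in design.groups.items():
        model = models[group]
        for r in range(n):
            sid = f"{group}_{r + 1}"
            bio = _lognormal_factor(rng, design.biological_cv, size=len(model.kins))
            kins_r = [replace(k, k_tx=k.k_tx * b) for k, b in zip(model.kins, bio)]
            if model.perturbation.kind == "none":
                st = steady_state(kins_r, model.pool)
            else:
                st = simulate_trajectory(
                    kins_r, model.pool, model.perturbation,
                    horizon_h=design.horizon_h, n_steps=13,
                ).final
            states[sid] = st
            sample_groups[sid] = group
    return generate_count_matrix(states, probes, design, sample_groups, rng), states


def truth_labels(models: Mapping[str, GroupModel], control: str) -> pd.DataFrame:
    """Ground-truth regulation mode per isoform per contrast.

    Derived from which effective parameters differ between each treated
    group's model (after applying its perturbation) and the control's:
    a transcription-rate change is transcriptional regulation; a polymer
    exchange change engages autoregulation for isoforms with alpha > 0
    (k_off up -> autoinhibition, down -> autoactivation); both -> mixed.
    """
    from .kinetics import apply_perturbation

    ctrl = models[control]
    ctrl_kins, ctrl_pool = apply_perturbation(ctrl.kins, ctrl.pool, ctrl.perturbation)
    ctrl_ktx = {k.isoform_id: k.k_tx for k in ctrl_kins}
    rows = []
    for group, model in models.items():
        if group == control:
            continue
        kins_p, pool_p = apply_perturbation(model.kins, model.pool, model.perturbation)
        for k in kins_p:
            trans = not np.isclose(k.k_tx, ctrl_ktx[k.isoform_id])
            auto = (not np.isclose(pool_p.k_off, ctrl_pool.k_off)) and k.alpha > 0
            if trans and auto:
                mode = "mixed"
            elif trans:
                mode = "transcriptional-up" if k.k_tx > ctrl_ktx[k.isoform_id] else "transcriptional-down"
            elif auto:
                mode = "autoinhibition" if pool_p.k_off > ctrl_pool.k_off else "autoactivation"
            else:
                mode = "unchanged"
            rows.append({"isoform": k.isoform_id, "contrast": f"{group}_vs_{control}", "mode": mode})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# densitometry + proteomics generators
# ---------------------------------------------------------------------------

def generate_densitometry(
    states: Mapping[str, CellState],
    samples: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    blots: Mapping[str, Sequence[str]] | None = None,
    gains: Mapping[str, float] | None = None,
    noise_sigma: float = 0.05,
    loading: LoadingConfig | None = None,
    gapdh_amount: float = 100.0,
    control: str = "Ctrl",
) -> pd.DataFrame:
    """Blot/lane intensity records from per-sample protein pool states.

    Each sample is run in technical duplicate; alpha-tubulin band amounts
    come from the model pools (free -> F, poly -> G, total -> F + G) and
    GAPDH is a constant per-sample loading control.  Intensity =
    blot_gain x amount x loading-equivalents x lognormal noise.
    """
    rng = np.random.default_rng(rng)
    loading = loading or LoadingConfig()
    sample_ids = list(states)
    if blots is None:
        blots = {"B1": sample_ids}
    gains = gains or {b: 1.0 for b in blots}
    groups = samples["group"]
    for blot, members in blots.items():
        if not any(groups.get(s) == control for s in members):
            raise ValueError(f"blot {blot!r} contains no {control!r} sample; "
                             "blot-matched normalization would be impossible")
    equiv = {"total": loading.poly_equivalents, "free": loading.free_equivalents,
             "poly": loading.poly_equivalents}
    rows = []
    for blot, members in blots.items():
        gain = gains[blot]
        lane = 0
        for s in members:
            st = states[s]
            amounts = {"free": float(st.F), "poly": float(st.G), "total": float(st.F + st.G)}
            for rep in (1, 2):
                lane += 1
                for fraction, amount in amounts.items():
                    for target, amt in (("alpha-tub", amount), ("GAPDH", gapdh_amount)):
                        noise = _lognormal_factor(rng, noise_sigma)
                        rows.append({
                            "blot_id": blot, "lane": lane, "sample_id": s,
                            "target": target, "fraction": fraction, "replicate": rep,
                            "intensity": gain * amt * equiv[fraction] * noise,
                        })
    return pd.DataFrame(rows)


def toy_isoform_proteome(n_isoforms: int = 4, length: int = 90, n_variant_sites: int = 6,
                         rng: np.random.Generator | int | None = None) -> dict[str, str]:
    """Synthetic homologous isoform family (shared backbone, few substitutions).

    Mimics the tubulin situation: isoforms share most tryptic peptides
    and differ at a handful of residues, so only peptides covering a
    variant site are unique.
    """
    rng = np.random.default_rng(rng)
    aa = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R placed separately to control sites
    backbone = rng.choice(aa, size=length)
    for pos in range(8, length - 1, 9):  # tryptic sites every ~9 residues
        backbone[pos] = rng.choice(["K", "R"])
    seqs = {}
    for i in range(n_isoforms):
        seq = backbone.copy()
        sites = rng.choice(np.arange(length), size=n_variant_sites, replace=False)
        for pos in sites:
            if seq[pos] in "KR":
                continue
            seq[pos] = rng.choice(aa)
        seqs[f"ISO{i + 1}"] = "".join(seq)
    return seqs


def generate_peptide_table(
    sequences: Mapping[str, str],
    abundances: pd.DataFrame,
    rule: DigestionRule | None = None,
    missing_rate: float = 0.1,
    noise_sigma: float = 0.1,
    ionization_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Peptide intensity table from isoform abundances.

    A peptide's intensity is the sum of its parent isoforms' abundances
    (shared peptides add contributions), times an optional fixed
    per-peptide ionization efficiency (lognormal, sigma =
    ``ionization_sigma``), times per-measurement lognormal noise; values
    are missing completely at random at ``missing_rate`` (NaN).
    """
    rng = np.random.default_rng(rng)
    rule = rule or DigestionRule()
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    parents: dict[str, set[str]] = {}
    for iso, seq in sequences.items():
        peps = set(digest(seq, rule))
        if not peps:
            warnings.warn(f"isoform {iso!r}: empty digestion result; no peptides emitted", stacklevel=2)
        for p in peps:
            parents.setdefault(p, set()).add(iso)
    missing_iso = set(abundances.index) - set(sequences)
    if missing_iso:
        raise ValueError(f"abundances given for unknown isoforms: {sorted(missing_iso)}")
    peptide_list = sorted(parents)
    ioniz = {p: (_lognormal_factor(rng, 0.0) if ionization_sigma == 0
                 else float(rng.lognormal(-ionization_sigma ** 2 / 2, ionization_sigma)))
             for p in peptide_list}
    rows = []
    for pep in peptide_list:
        par = parents[pep] & set(abundances.index)
        for sample in abundances.columns:
            base = float(sum(abundances.loc[iso, sample] for iso in par))
            noise = _lognormal_factor(rng, noise_sigma) if noise_sigma > 0 else 1.0
            value = base * ioniz[pep] * noise
            if missing_rate > 0 and rng.random() < missing_rate:
                value = np.nan
            rows.append({"peptide": pep, "sample_id": sample, "intensity": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario catalogue
# ---------------------------------------------------------------------------

SCENARIOS = ("null", "colchicine-6h", "taxol-6h", "pe-transcriptional",
             "transcriptional-down", "pe-4day")


@dataclass
class StudyBundle:
    """A complete synthetic study: counts, annotations, truth and extras."""

    scenario: str
    counts: CountMatrix
    truth: pd.DataFrame
    config: dict
    densitometry: pd.DataFrame | None = None
    peptides: pd.DataFrame | None = None
    proteome: dict[str, str] | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts.counts.astype(int).to_csv(path / "counts.csv")
        self.counts.probes.to_csv(path / "probes.csv")
        self.counts.samples.to_csv(path / "samples.csv")
        self.truth.to_csv(path / "truth.csv", index=False)
        (path / "config.yaml").write_text(yaml.safe_dump(self.config, sort_keys=True))
        if self.densitometry is not None:
            self.densitometry.to_csv(path / "densitometry.csv", index=False)
        if self.peptides is not None:
            self.peptides.to_csv(path / "peptides.csv", index=False)
        if self.proteome is not None:
            with open(path / "proteome.fasta", "w") as fh:
                for iso, seq in self.proteome.items():
                    fh.write(f">{iso}\n{seq}\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "StudyBundle":
        path = Path(path)
        counts = pd.read_csv(path / "counts.csv", index_col=0)
        probes = pd.read_csv(path / "probes.csv", index_col=0)
        samples = pd.read_csv(path / "samples.csv", index_col=0)
        truth = pd.read_csv(path / "truth.csv")
        config = yaml.safe_load((path / "config.yaml").read_text())
        dens = pd.read_csv(path / "densitometry.csv") if (path / "densitometry.csv").exists() else None
        peps = pd.read_csv(path / "peptides.csv") if (path / "peptides.csv").exists() else None
        proteome = None
        if (path / "proteome.fasta").exists():
            from .proteomics import read_fasta
            proteome = read_fasta(path / "proteome.fasta")
        return cls(scenario=config.get("scenario", "unknown"),
                   counts=CountMatrix(counts, probes, samples),
                   truth=truth, config=config, densitometry=dens,
                   peptides=peps, proteome=proteome)


def _scenario_models(name: str, effect: float, drug_magnitude: float | None,
                     isoforms: Sequence[str]) -> tuple[dict[str, GroupModel], str, float]:
    """Group models, treated-group label and horizon for a named scenario."""
    pool = PoolKinetics()
    if name == "null":
        kins = tuple(default_isoform_kinetics(isoforms))
        return ({"Ctrl": GroupModel(kins, pool), "Treated": GroupModel(kins, pool)},
                "Treated", 6.0)
    if name == "colchicine-6h":
        kins = tuple(default_isoform_kinetics(isoforms))
        pert = PerturbationSpec("colchicine", magnitude=drug_magnitude or 10.0)
        return ({"Ctrl": GroupModel(kins, pool), "Colch": GroupModel(kins, pool, pert)},
                "Colch", 6.0)
    if name == "taxol-6h":
        kins = tuple(default_isoform_kinetics(isoforms))
        pert = PerturbationSpec("taxol", magnitude=drug_magnitude or 0.1)
        return ({"Ctrl": GroupModel(kins, pool), "Tax": GroupModel(kins, pool, pert)},
                "Tax", 6.0)
    if name in ("pe-transcriptional", "transcriptional-down"):
        # feedback off: a pure transcriptional regime
        kins = tuple(default_isoform_kinetics(isoforms, alpha=0.0))
        factor = effect if name == "pe-transcriptional" else 1.0 / effect
        pert = PerturbationSpec("adrenergic", magnitude=max(factor, 1.0 / factor),
                                targets={iso: factor for iso in isoforms})
        return ({"Ctrl": GroupModel(kins, pool), "PE": GroupModel(kins, pool, pert)},
                "PE", 24.0)
    if name == "pe-4day":
        # established hypertrophy: microtubule stabilization (taxol-like)
        # plus isoform-specific transcriptional induction
        kins = tuple(default_isoform_kinetics(isoforms))
        stab = PerturbationSpec("taxol", magnitude=drug_magnitude or 0.2)
        targets = {iso: 1.0 for iso in isoforms}
        if "Tubb6" in targets:
            targets["Tubb6"] = 4.0  # strongest induced isoform
        if "Tubb2a" in targets:
            targets["Tubb2a"] = 2.0
        kins_pe = tuple(apply_adrenergic(kins, targets))
        return ({"Ctrl": GroupModel(kins, pool), "PE": GroupModel(kins_pe, pool, stab)},
                "PE", 96.0)
    raise ValueError(f"unknown scenario {name!r}; catalogue: {list(SCENARIOS)}")


def apply_adrenergic(kins: Sequence[IsoformKinetics], targets: Mapping[str, float]):
    return [replace(k, k_tx=k.k_tx * targets.get(k.isoform_id, 1.0)) for k in kins]


def scenario_suite(
    name: str,
    design: StudyDesign | None = None,
    seed: int | None = 0,
    effect: float = 2.0,
    drug_magnitude: float | None = None,
    isoforms: Sequence[str] = DEFAULT_ISOFORMS,
    n_per_group: int = 6,
    biological_cv: float = 0.10,
    with_densitometry: bool | None = None,
    with_proteomics: bool = False,
) -> StudyBundle:
    """Generate a complete named synthetic study.

    Scenarios: ``null`` (no effect), ``colchicine-6h`` (depolymerizer ->
    autoinhibition of every isoform with alpha > 0), ``taxol-6h``
    (stabilizer -> autoactivation), ``pe-transcriptional`` /
    ``transcriptional-down`` (pure transcriptional regimes, feedback
    off), ``pe-4day`` (stabilization plus isoform-specific induction;
    includes densitometry by default).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; catalogue: {list(SCENARIOS)}")
    rng = np.random.default_rng(seed)
    models, treated, horizon = _scenario_models(name, effect, drug_magnitude, isoforms)
    if design is None:
        design = StudyDesign(groups={g: n_per_group for g in models}, control="Ctrl",
                             horizon_h=horizon, biological_cv=biological_cv)
    else:
        design = dataclasses.replace(
            design,
            groups={g: design.groups.get(g, next(iter(design.groups.values()))) for g in models},
        )
    counts, states = simulate_study(models, design, rng=rng)
    truth = truth_labels(models, design.control)

    if with_densitometry is None:
        with_densitometry = name == "pe-4day"
    dens = None
    if with_densitometry:
        dens = generate_densitometry(states, counts.samples, rng=rng, control=design.control)

    peptides = proteome = None
    if with_proteomics:
        proteome = toy_isoform_proteome(n_isoforms=len(isoforms), rng=rng)
        proteome = dict(zip(isoforms, proteome.values()))
        # per-isoform protein proxy: translation flux k_tl * M_i
        ctrl_kins = models[design.control].kins
        ktl = {k.isoform_id: k.k_tl for k in ctrl_kins}
        ab = pd.DataFrame({s: {iso: ktl[iso] * st.M[list(st.isoform_ids).index(iso)]
                               for iso in isoforms} for s, st in states.items()})
        peptides = generate_peptide_table(proteome, ab, rng=rng)

    config = {
        "scenario": name,
        "seed": seed,
        "effect": effect,
        "drug_magnitude": drug_magnitude,
        "design": {
            "groups": dict(design.groups), "control": design.control,
            "horizon_h": design.horizon_h, "biological_cv": design.biological_cv,
            "lane_sigma": design.lane_sigma, "dispersion": design.dispersion,
            "background_mean": design.background_mean, "w_pre": design.w_pre,
        },
    }
    return StudyBundle(name, counts, truth, config, dens, peptides, proteome)
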