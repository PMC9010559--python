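"""Intron/exon decomposition of mRNA changes.

Intronic probes see only unspliced pre-mRNA, whose level tracks
transcription; exonic probes see the mature transcript, which is
additionally subject to autoregulated decay.  Plotting each isoform's
intron log2 fold-change (x) against its exon log2 fold-change (y),
transcriptional regulation moves points along the diagonal y = x while
autoregulation shifts them vertically off it.  The **autoregulation
index** is that signed vertical deviation,

    A_j = dE_j - dI_j            (per sample j),

and an isoform is classified from two adjusted hypothesis tests:
whether its intron level changed (transcription) and whether A changed
(autoregulation):

    p_I < cutoff, p_A >= cutoff  ->  transcriptional-up / -down  (sign of dI)
    p_I >= cutoff, p_A < cutoff  ->  autoactivation (A > 0) / autoinhibition (A < 0)
    both < cutoff                ->  mixed
    neither                      ->  unchanged

Because intron and exon probes of a sample hybridize in the same lane,
any multiplicative per-sample (lane) effect multiplies both counts and
cancels exactly in A_j — the index is valid even on unnormalized counts.
This exact cancellation relies on the default *geometric* control-mean
reference for the fold-changes (an arithmetic control mean, the western
blot convention, is available as ``reference="arithmetic"`` but cancels
lane effects only approximately).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .nanostring import NormalizedMatrix
from .stats import adaptive_test, bonferroni_adjust

__all__ = [
    "autoregulation_index",
    "classify_isoform",
    "decompose_panel",
    "AutoregulationDecomposer",
    "MODES",
]

logger = logging.getLogger(__name__)

MODES = (
    "transcriptional-up",
    "transcriptional-down",
    "autoactivation",
    "autoinhibition",
    "mixed",
    "unchanged",
)


def autoregulation_index(dE, dI) -> np.ndarray:
    """Per-sample autoregulation index A_j = dE_j - dI_j.

    Inputs must be paired (same samples, same order); pandas inputs are
    checked for index agreement.
    """
    if isinstance(dE, pd.Series) and isinstance(dI, pd.Series):
        if not dE.index.equals(dI.index):
            raise ValueError("intron and exon fold-changes are not paired (index mismatch)")
    dE_a = np.asarray(dE, dtype=float)
    dI_a = np.asarray(dI, dtype=float)
    if dE_a.shape != dI_a.shape:
        raise ValueError("intron and exon fold-changes are not paired (shape mismatch)")
    return dE_a - dI_a


def classify_isoform(p_I: float, p_A: float, dI: float, A: float, cutoff: float = 0.025) -> str:
    """Mode label from the significance pattern of intron change and A."""
    for name, v in (("p_I", p_I), ("p_A", p_A)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"{name} is missing")
    sig_I, sig_A = p_I < cutoff, p_A < cutoff
    if sig_I and not sig_A:
        return "transcriptional-up" if dI > 0 else "transcriptional-down"
    if sig_A and not sig_I:
        return "autoactivation" if A > 0 else "autoinhibition"
    if sig_I and sig_A:
        return "mixed"
    return "unchanged"


def _region_log_signal(values: pd.DataFrame, probe_ids, pseudocount: float, combine: str) -> pd.Series:
    """Per-sample log2 signal of one isoform region, combining its probes."""
    sub = values.loc[probe_ids]
    if combine == "mean-of-logs":
        return np.log2(sub + pseudocount).mean(axis=0)
    if combine == "log-of-sums":
        return np.log2(sub.sum(axis=0) + pseudocount)
    raise ValueError(f"unknown combine rule {combine!r}")


class AutoregulationDecomposer(BaseEstimator):
    """Decompose per-isoform mRNA changes into transcription vs autoregulation.

    Parameters
    ----------
    control : str
        Control group label.
    family_size : int
        Bonferroni family size applied to every reported p-value.
    cutoff : float
        Adjusted-p significance cut-off for the decision table (0.025 =
        family level 0.05 over two treatment contrasts).
    pseudocount : float
        Added inside every log2; use 0 for exactly lane-invariant A on
        strictly positive counts.
    reference : {"geometric", "arithmetic"}
        Control-mean convention for fold-changes (see module docstring).
    combine : {"mean-of-logs", "log-of-sums"}
        How multiple probes of one region are merged per sample.

    Fitted attributes
    -----------------
    calls_ : DataFrame — one row per isoform per contrast (dI, dE, A, SEMs,
        adjusted p_I/p_E/p_A, mode).
    scatter_ : DataFrame — per-isoform means +/- SEM for the intron (x) vs
        exon (y) scatter.
    per_sample_ : DataFrame — retained per-sample dI_j, dE_j, A_j.
    excluded_ : list of isoforms skipped for missing a probe region.
    """

    def __init__(self, control: str = "Ctrl", family_size: int = 2, cutoff: float = 0.025,
                 pseudocount: float = 0.5, reference: str = "geometric",
                 combine: str = "mean-of-logs", normality_alpha: float = 0.05):
        self.control = control
        self.family_size = family_size
        self.cutoff = cutoff
        self.pseudocount = pseudocount
        self.reference = reference
        self.combine = combine
        self.normality_alpha = normality_alpha

    # -- helpers ---------------------------------------------------------
    def _lfc(self, log_signal: pd.Series, raw_signal: pd.Series, ctrl_cols) -> pd.Series:
        if self.reference == "geometric":
            return log_signal - log_signal[ctrl_cols].mean()
        if self.reference == "arithmetic":
            return log_signal - np.log2(raw_signal[ctrl_cols].mean() + self.pseudocount)
        raise ValueError(f"unknown reference {self.reference!r}")

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y: None = None, *, probes: pd.DataFrame | None = None,
            samples: pd.DataFrame | None = None) -> "AutoregulationDecomposer":
        if isinstance(X, NormalizedMatrix):
            values, probes, samples = X.values, X.probes, X.samples
        else:
            values = X
            if probes is None or samples is None:
                raise ValueError("probes= and samples= are required with a plain values table")
        if self.reference not in ("geometric", "arithmetic"):
            raise ValueError(f"unknown reference {self.reference!r}")

        groups = samples.loc[values.columns, "group"]
        if self.control not in set(groups):
            raise ValueError(f"control group {self.control!r} not present")
        ctrl_cols = values.columns[groups == self.control]
        treated_groups = [g for g in pd.unique(groups) if g != self.control]
        if not treated_groups:
            raise ValueError("no treated groups")

        endo = probes[probes["class"] == "endogenous"]
        isoforms = pd.unique(endo["gene"])

        calls, scatter, per_sample = [], [], []
        excluded: list[str] = []
        for iso in isoforms:
            iso_probes = endo[endo["gene"] == iso]
            ex_ids = iso_probes.index[iso_probes["region"] == "exon"]
            in_ids = iso_probes.index[iso_probes["region"] == "intron"]
            if len(ex_ids) == 0 or len(in_ids) == 0:
                excluded.append(iso)
                logger.warning("isoform %s lacks an %s probe; excluded from decomposition",
                               iso, "exon" if len(ex_ids) == 0 else "intron")
                continue
            logE = _region_log_signal(values, ex_ids, self.pseudocount, self.combine)
            logI = _region_log_signal(values, in_ids, self.pseudocount, self.combine)
            rawE, rawI = 2.0 ** logE, 2.0 ** logI  # combined raw-scale region signals

            dE = self._lfc(logE, rawE, ctrl_cols)
            dI = self._lfc(logI, rawI, ctrl_cols)
            A = pd.Series(autoregulation_index(dE, dI), index=dE.index)

            for treated in treated_groups:
                t_cols = values.columns[groups == treated]
                contrast = f"{treated}_vs_{self.control}"
                res_I = adaptive_test(rawI[t_cols], rawI[ctrl_cols], self.normality_alpha)
                res_E = adaptive_test(rawE[t_cols], rawE[ctrl_cols], self.normality_alpha)
                res_A = adaptive_test(A[t_cols], A[ctrl_cols], self.normality_alpha)
                p_I = bonferroni_adjust(res_I.p, self.family_size)
                p_E = bonferroni_adjust(res_E.p, self.family_size)
                p_A = bonferroni_adjust(res_A.p, self.family_size)

                dI_m, dE_m = float(dI[t_cols].mean()), float(dE[t_cols].mean())
                A_m = dE_m - dI_m  # exact additivity of the means
                sem = lambda s: float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else np.nan
                mode = classify_isoform(p_I, p_A, dI_m, A_m, self.cutoff)
                calls.append({
                    "isoform": iso, "contrast": contrast,
                    "dI": dI_m, "dE": dE_m, "A": A_m,
                    "sem_dI": sem(dI[t_cols]), "sem_dE": sem(dE[t_cols]), "sem_A": sem(A[t_cols]),
                    "p_I": p_I, "p_E": p_E, "p_A": p_A,
                    "test_I": res_I.test_used, "test_A": res_A.test_used,
                    "m": self.family_size, "mode": mode,
                    "concordance_ratio": dE_m / dI_m if dI_m != 0 else np.nan,
                })
                scatter.append({
                    "isoform": iso, "contrast": contrast,
                    "x_intron": dI_m, "sem_x": sem(dI[t_cols]),
                    "y_exon": dE_m, "sem_y": sem(dE[t_cols]),
                })
            for col in values.columns:
                per_sample.append({
                    "isoform": iso, "sample_id": col, "group": groups[col],
                    "dI_j": float(dI[col]), "dE_j": float(dE[col]), "A_j": float(A[col]),
                })

        self.calls_ = pd.DataFrame(calls)
        self.scatter_ = pd.DataFrame(scatter)
        self.per_sample_ = pd.DataFrame(per_sample)
        self.excluded_ = excluded
        return self


def decompose_panel(X, probes: pd.DataFrame | None = None, samples: pd.DataFrame | None = None,
                    **params) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper: returns ``(calls, scatter)`` tables."""
    dec = AutoregulationDecomposer(**params).fit(X, probes=probes, samples=samples)
    return dec.calls_, dec.scatter_
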