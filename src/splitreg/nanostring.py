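"""NanoString nCounter-style count normalization.

The chain mirrors the platform's standard workflow for a panel with
negative controls, a positive-control concentration ladder and
housekeeping genes:

1. **Background thresholding** — geometric mean of the negative-control
   counts after discarding outlying negatives (any value more than three
   times the geometric mean of the remaining ones, removed one at a time
   from the largest down).  The threshold is *reported*, not subtracted,
   and endogenous counts are never floored or removed.
2. **Positive-control (lane) normalization** — per-sample factors that
   equalize the geometric mean of the positive-control probes across
   lanes, after dropping the lowest ladder point ("F") panel-wide when it
   sits too close to background.
3. **Housekeeping (content) normalization** — the same geometric-mean
   factor construction on the housekeeping genes, computed on the
   lane-normalized values.

Factors compose multiplicatively, so the whole chain is idempotent and
invariant to arbitrary per-lane rescalings of the raw counts.

Zeros are replaced by 1 (the smallest observable count) before any
geometric mean — never log-of-zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "NanoStringNormalizer",
    "geometric_mean",
    "background_threshold",
    "lane_factors",
    "normalize",
    "read_rcc_lite",
]

PROBE_CLASSES = frozenset({"endogenous", "positive", "negative", "housekeeping"})


@dataclass
class CountMatrix:
    """Probe-by-sample count table with probe and sample annotations.

    ``counts`` is a probes x samples DataFrame of non-negative numbers;
    ``probes`` is indexed by probe_id with at least columns ``gene``,
    ``region`` (exon/intron, NaN for controls) and ``class`` (one of
    endogenous / positive / negative / housekeeping); ``samples`` is
    indexed by sample_id with at least a ``group`` column.
    """

    counts: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not np.isfinite(self.counts.to_numpy()).all():
            raise ValueError("non-finite counts")
        missing = set(self.counts.index) - set(self.probes.index)
        if missing:
            raise ValueError(f"probes without annotation: {sorted(missing)[:5]}")
        if "class" not in self.probes.columns:
            raise ValueError("probe annotation must have a 'class' column")
        bad = set(self.probes.loc[self.counts.index, "class"]) - PROBE_CLASSES
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        missing_s = set(self.counts.columns) - set(self.samples.index)
        if missing_s:
            raise ValueError(f"samples without metadata: {sorted(missing_s)[:5]}")

    def of_class(self, cls: str) -> pd.DataFrame:
        ids = self.probes.index[self.probes["class"] == cls]
        return self.counts.loc[self.counts.index.intersection(ids)]


@dataclass
class NormalizedMatrix:
    """Output of the normalization chain.

    ``values`` are probe x sample non-negative reals; the per-sample
    ``pos_factors`` / ``hk_factors`` and the reported ``background_threshold``
    document the chain; ``excluded_controls`` lists dropped control probes
    or negative values with reasons.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame
    background_threshold: float
    pos_factors: pd.Series
    hk_factors: pd.Series
    excluded_controls: list[str] = field(default_factory=list)


def geometric_mean(x: Iterable[float]) -> float:
    """Geometric mean with zeros replaced by 1 beforehand."""
    a = np.asarray(list(x), dtype=float)
    if a.size == 0:
        raise ValueError("geometric mean of empty set")
    if (a < 0).any():
        raise ValueError("negative values")
    a = np.where(a == 0, 1.0, a)
    return float(np.exp(np.mean(np.log(a))))


def background_threshold(negative_counts: Iterable[float]) -> tuple[float, list[float]]:
    """Background level from negative-control counts.

    Discards, one value at a time from the largest down, any negative
    count greater than three times the geometric mean of the remaining
    ones, then returns the geometric mean of what is retained together
    with the list of excluded values.
    """
    vals = sorted(np.asarray(list(negative_counts), dtype=float), reverse=True)
    if len(vals) < 2:
        raise ValueError("need at least 2 negative-control values")
    retained = list(vals)
    excluded: list[float] = []
    for v in vals:
        rest = list(retained)
        rest.remove(v)
        if not rest:
            break
        if v > 3.0 * geometric_mean(rest):
            retained.remove(v)
            excluded.append(v)
    if not retained:
        raise ValueError("all negative controls excluded by the 3x rule (pathological input)")
    return geometric_mean(retained), excluded


def lane_factors(class_counts: pd.DataFrame) -> pd.Series:
    """Per-sample normalization factors from one control class.

    factor_j = mean_over_samples(per-sample geometric mean) / geomean_j,
    so multiplying lane j's raw counts by k divides its factor by k and
    the normalized class geomeans become identical across lanes.
    """
    if class_counts.shape[0] < 1:
        raise ValueError("no probes of the requested class")
    geo = class_counts.apply(geometric_mean, axis=0)
    zero_lanes = class_counts.columns[(class_counts == 0).all(axis=0)]
    if len(zero_lanes):
        raise ValueError(f"all-zero control counts in sample(s): {list(zero_lanes)}")
    return geo.mean() / geo


class NanoStringNormalizer(BaseEstimator, TransformerMixin):
    """Background thresholding + positive-control and housekeeping normalization.

    Parameters
    ----------
    drop_f_multiplier : float, default 2.0
        The lowest positive-control ladder point (named ``*_F`` or with the
        smallest expected concentration) is dropped panel-wide when its
        mean count is below ``drop_f_multiplier x background_threshold``.
    pooled_negatives : bool, default True
        Pool negative controls across lanes for thresholding (the default
        reading); if False, a threshold is computed per lane and the
        maximum is reported.

    Fitted attributes
    -----------------
    background_threshold_ : float
    pos_factors_, hk_factors_ : pandas.Series (per sample)
    excluded_controls_ : list of str
    """

    def __init__(self, drop_f_multiplier: float = 2.0, pooled_negatives: bool = True):
        self.drop_f_multiplier = drop_f_multiplier
        self.pooled_negatives = pooled_negatives

    def fit(self, X: CountMatrix, y: None = None) -> "NanoStringNormalizer":
        neg = X.of_class("negative")
        if neg.shape[0] < 2:
            raise ValueError("need >= 2 negative-control probes")
        pos = X.of_class("positive")
        if pos.shape[0] < 2:
            raise ValueError("need >= 2 positive-control probes")
        hk = X.of_class("housekeeping")
        if hk.shape[0] < 1:
            raise ValueError("need >= 1 housekeeping probe")

        excluded: list[str] = []
        if self.pooled_negatives:
            thr, excl_vals = background_threshold(neg.to_numpy().ravel())
        else:
            per_lane = [background_threshold(neg[c].to_numpy()) for c in neg.columns]
            thr = max(t for t, _ in per_lane)
            excl_vals = [v for _, ex in per_lane for v in ex]
        excluded += [f"negative value {v:g} excluded by 3x rule" for v in excl_vals]

        # drop the lowest ladder point panel-wide if it hugs the background
        pos_use = pos
        low_probe = self._lowest_positive(X, pos)
        if low_probe is not None and pos.loc[low_probe].mean() < self.drop_f_multiplier * thr:
            pos_use = pos.drop(index=low_probe)
            excluded.append(
                f"positive control {low_probe!r} dropped: mean count "
                f"{pos.loc[low_probe].mean():.2f} < {self.drop_f_multiplier:g} x background {thr:.2f}"
            )
        if pos_use.shape[0] < 2:
            raise ValueError("fewer than 2 positive controls remain after exclusion")

        pos_f = lane_factors(pos_use)
        hk_f = lane_factors(hk.mul(pos_f, axis=1))

        self.background_threshold_ = float(thr)
        self.pos_factors_ = pos_f
        self.hk_factors_ = hk_f
        self.excluded_controls_ = excluded
        return self

    @staticmethod
    def _lowest_positive(X: CountMatrix, pos: pd.DataFrame) -> str | None:
        ann = X.probes.loc[pos.index]
        if "expected_conc" in ann.columns and ann["expected_conc"].notna().all():
            return ann["expected_conc"].astype(float).idxmin()
        f_named = [p for p in pos.index if str(p).endswith("F")]
        return f_named[0] if len(f_named) == 1 else None

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        if list(X.counts.columns) != list(self.pos_factors_.index):
            if set(X.counts.columns) != set(self.pos_factors_.index):
                raise ValueError("transform requires the samples the normalizer was fitted on")
        # lane factors apply to every probe; content (housekeeping) factors
        # only to biological content (endogenous + housekeeping probes).
        # Control probes therefore stay equalized across lanes and the
        # whole chain is an exact projection (idempotent).
        values = X.counts.mul(self.pos_factors_.reindex(X.counts.columns), axis=1)
        content = X.probes.loc[X.counts.index, "class"].isin(["endogenous", "housekeeping"])
        values.loc[content] = values.loc[content].mul(
            self.hk_factors_.reindex(X.counts.columns), axis=1)
        return NormalizedMatrix(
            values=values,
            probes=X.probes,
            samples=X.samples,
            background_threshold=self.background_threshold_,
            pos_factors=self.pos_factors_.copy(),
            hk_factors=self.hk_factors_.copy(),
            excluded_controls=list(self.excluded_controls_),
        )


def normalize(X: CountMatrix, **params) -> NormalizedMatrix:
    """One-shot normalization (fit + transform on the same matrix)."""
    return NanoStringNormalizer(**params).fit(X).transform(X)


def read_rcc_lite(paths: Sequence[str | Path], samples: pd.DataFrame | None = None) -> CountMatrix:
    """Read simplified per-lane RCC files into a CountMatrix.

    Each file holds ``CodeClass,Name,Accession,Count`` records (one lane);
    the file stem becomes the sample id.  CodeClass values Endogenous /
    Positive / Negative / Housekeeping map onto the probe classes.
    """
    lanes: dict[str, pd.Series] = {}
    probe_rows: dict[str, dict] = {}
    cls_map = {"endogenous": "endogenous", "positive": "positive",
               "negative": "negative", "housekeeping": "housekeeping"}
    for p in paths:
        p = Path(p)
        df = pd.read_csv(io.StringIO(p.read_text()))
        need = {"CodeClass", "Name", "Count"}
        if not need.issubset(df.columns):
            raise ValueError(f"{p}: RCC-lite file must have columns {sorted(need)}")
        df["CodeClass"] = df["CodeClass"].str.lower()
        bad = set(df["CodeClass"]) - set(cls_map)
        if bad:
            raise ValueError(f"{p}: unknown CodeClass values {sorted(bad)}")
        lanes[p.stem] = pd.Series(df["Count"].to_numpy(float), index=df["Name"])
        for _, row in df.iterrows():
            region = "intron" if str(row["Name"]).endswith("_intron") else (
                "exon" if str(row["Name"]).endswith("_exon") else None)
            probe_rows[row["Name"]] = {
                "gene": str(row["Name"]).rsplit("_", 1)[0],
                "region": region,
                "class": cls_map[row["CodeClass"]],
            }
    counts = pd.DataFrame(lanes)
    probes = pd.DataFrame.from_dict(probe_rows, orient="index")
    probes.index.name = "probe_id"
    if samples is None:
        samples = pd.DataFrame(index=counts.columns)
        samples["group"] = "unknown"
    return CountMatrix(counts, probes, samples)
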