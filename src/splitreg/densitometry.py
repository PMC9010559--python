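"""Western-blot-style densitometry quantification.

Inputs are already-integrated band intensities (no image processing).
Two normalizations are implemented:

* **Relative quantification** — each lane's target intensity is divided
  by the loading-control intensity of the same lane (GAPDH, or
  alpha-tubulin for modification-vs-total ratios), technical duplicates
  are averaged *after* ratio formation, and the result is divided by the
  mean over control-group samples **run on the same blot**.  Per-blot
  gain therefore cancels exactly and values are comparable across blots.

* **Free:polymerized ratio** — free and polymerized tubulin fractions
  are prepared and loaded with different volumes and dilutions; the
  ratio corrects intensities back to equal mg-tissue equivalents.  The
  default loading scheme (5 uL polymer fraction, 10 uL free fraction
  diluted 2x more) makes the corrections cancel, so the default ratio is
  simply I_free / I_poly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LoadingConfig", "quantify_relative", "free_poly_ratio", "validate_table"]

REQUIRED_COLUMNS = {"blot_id", "lane", "sample_id", "target", "fraction", "intensity", "replicate"}


@dataclass(frozen=True)
class LoadingConfig:
    """Gel-loading bookkeeping for the free/polymer fractions.

    With the defaults the mg-equivalents loaded are equal:
    free 10 uL at an extra 2x dilution == poly 5 uL.
    """

    poly_load_volume: float = 5.0
    free_load_volume: float = 10.0
    free_extra_dilution: float = 2.0

    def __post_init__(self) -> None:
        if min(self.poly_load_volume, self.free_load_volume, self.free_extra_dilution) <= 0:
            raise ValueError("all loading parameters must be > 0")

    @property
    def free_equivalents(self) -> float:
        return self.free_load_volume / self.free_extra_dilution

    @property
    def poly_equivalents(self) -> float:
        return self.poly_load_volume


def validate_table(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise ValueError("negative intensities")


def quantify_relative(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    target: str,
    normalizer: str = "GAPDH",
    control: str = "Ctrl",
    fraction: str = "total",
    ceiling: float | None = None,
) -> pd.Series:
    """Loading-control and blot-matched relative quantification.

    Returns per-sample fold-changes of ``target`` (within ``fraction``)
    normalized lane-wise by ``normalizer`` and blot-wise by the mean of
    the control-group samples on the same blot.  ``ceiling``, if given,
    drops saturated bands (intensity > ceiling) before averaging.
    """
    validate_table(table)
    if "group" not in samples.columns:
        raise ValueError("sample metadata needs a 'group' column")
    sub = table[table["fraction"] == fraction]
    tgt = sub[sub["target"] == target]
    nrm = sub[sub["target"] == normalizer]
    if tgt.empty:
        raise ValueError(f"no rows for target {target!r} in fraction {fraction!r}")
    if nrm.empty:
        raise ValueError(f"no rows for normalizer {normalizer!r} in fraction {fraction!r}")
    if ceiling is not None:
        tgt = tgt[tgt["intensity"] <= ceiling]

    key = ["blot_id", "sample_id", "replicate"]
    merged = tgt.merge(nrm[key + ["intensity"]], on=key, suffixes=("", "_norm"))
    if merged.empty:
        raise ValueError("target and normalizer never measured on the same lane")
    if (merged["intensity_norm"] <= 0).any():
        raise ValueError("zero or negative normalizer intensity")
    merged["ratio"] = merged["intensity"] / merged["intensity_norm"]

    # average technical duplicates after ratio formation
    per_sample = merged.groupby(["blot_id", "sample_id"])["ratio"].mean().reset_index()
    per_sample["group"] = samples.loc[per_sample["sample_id"], "group"].to_numpy()

    out = {}
    for blot, blot_df in per_sample.groupby("blot_id"):
        ctrl = blot_df[blot_df["group"] == control]
        if ctrl.empty:
            raise ValueError(f"blot {blot!r} has no {control!r} sample: blot-matched normalization impossible")
        ref = ctrl["ratio"].mean()
        for _, row in blot_df.iterrows():
            out[row["sample_id"]] = row["ratio"] / ref
    return pd.Series(out, name=f"{target}_vs_{normalizer}").sort_index()


def free_poly_ratio(table: pd.DataFrame, config: LoadingConfig | None = None,
                    target: str = "alpha-tub") -> pd.Series:
    """Per-sample free:polymerized tubulin ratio, corrected for loading.

    ratio = (I_free / free_equivalents) / (I_poly / poly_equivalents);
    with the default loading scheme the equivalents are equal and the
    corrections cancel.
    """
    validate_table(table)
    config = config or LoadingConfig()
    sub = table[table["target"] == target]
    free = sub[sub["fraction"] == "free"].groupby("sample_id")["intensity"].mean()
    poly = sub[sub["fraction"] == "poly"].groupby("sample_id")["intensity"].mean()
    missing = set(free.index).symmetric_difference(poly.index)
    if missing:
        raise ValueError(f"samples missing a fraction: {sorted(missing)}")
    if free.empty:
        raise ValueError(f"no free/poly measurements for target {target!r}")
    if (poly <= 0).any():
        raise ValueError("zero polymer-fraction intensity")
    per_mg_free = free / config.free_equivalents
    per_mg_poly = poly / config.poly_equivalents
    return (per_mg_free / per_mg_poly).rename("free_poly_ratio").sort_index()
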