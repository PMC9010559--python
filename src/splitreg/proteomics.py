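"""Isoform-resolved protein quantification from peptide intensities.

Tubulin isoforms are highly homologous, so most proteolytic peptides are
shared between several isoforms and carry no isoform-level information.
The workflow here is the standard one for such families: digest each
isoform sequence in silico (enzyme-specific cleavage with missed
cleavages), keep only peptides whose sequence occurs in exactly one
isoform ("unique peptides"), and summarize isoform abundance as the mean
intensity of its unique peptides after half-minimum imputation of
missing values and per-sample median scaling.  mRNA-protein concordance
is an ordinary least-squares regression of protein log2 fold-changes on
mRNA log2 fold-changes across matched isoforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DigestionRule",
    "PeptideMap",
    "digest",
    "read_fasta",
    "build_uniqueness_map",
    "rollup_abundance",
    "PeptideRollup",
    "concordance",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# cleavage specificity: residues cut after; proline suppression on the C-side
_ENZYMES = {
    "trypsin": (frozenset("KR"), True),
    "chymotrypsin": (frozenset("FWY"), True),
    "glu-c": (frozenset("E"), False),
}


@dataclass(frozen=True)
class DigestionRule:
    """Enzyme specificity and peptide filters for in-silico digestion.

    Defaults follow common search settings: up to 2 missed cleavages; no
    length bounds unless given (``min_length``/``max_length``).
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 1
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.enzyme not in _ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}; known: {sorted(_ENZYMES)}")
        if self.max_missed_cleavages < 0 or self.min_length < 1:
            raise ValueError("max_missed_cleavages >= 0 and min_length >= 1 required")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length < min_length")


def _cleavage_sites(seq: str, rule: DigestionRule) -> list[int]:
    """Positions i such that the bond after residue i-1 (0-based: between
    seq[i-1] and seq[i]) is cleaved."""
    residues, no_pro = _ENZYMES[rule.enzyme]
    sites = []
    for i in range(1, len(seq)):
        if seq[i - 1] in residues and not (no_pro and seq[i] == "P"):
            sites.append(i)
    return sites


def digest(sequence: str, rule: DigestionRule | None = None) -> list[str]:
    """All peptides of a sequence with up to ``max_missed_cleavages``.

    Builds the fully-cleaved fragments and joins runs of up to
    ``max_missed_cleavages + 1`` adjacent fragments; the result is
    ordered by position and duplicate-free per (start, end) span.
    """
    rule = rule or DigestionRule()
    seq = str(sequence).upper().strip("*")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"illegal residue characters: {sorted(bad)}")
    if not seq:
        return []
    bounds = [0] + _cleavage_sites(seq, rule) + [len(seq)]
    frags = [seq[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: list[str] = []
    for i in range(len(frags)):
        for k in range(rule.max_missed_cleavages + 1):
            if i + k >= len(frags):
                break
            pep = "".join(frags[i: i + k + 1])
            if len(pep) < rule.min_length:
                continue
            if rule.max_length is not None and len(pep) > rule.max_length:
                break
            peptides.append(pep)
    return peptides


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> {id: sequence}; duplicate ids are an error."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate isoform ids in FASTA")
    return {r.id: str(r.seq) for r in records}


@dataclass
class PeptideMap:
    """Peptide -> parent-isoform mapping with uniqueness bookkeeping."""

    parents: dict[str, frozenset[str]]
    rule: DigestionRule
    isoforms: tuple[str, ...]

    def is_unique(self, peptide: str) -> bool:
        return len(self.parents[peptide]) == 1

    @property
    def unique_peptides(self) -> dict[str, set[str]]:
        """Per-isoform set of unique peptides."""
        out: dict[str, set[str]] = {iso: set() for iso in self.isoforms}
        for pep, par in self.parents.items():
            if len(par) == 1:
                out[next(iter(par))].add(pep)
        return out

    def unique_counts(self) -> pd.Series:
        return pd.Series({iso: len(peps) for iso, peps in self.unique_peptides.items()})


def build_uniqueness_map(sequences: Mapping[str, str] | str | Path,
                         rule: DigestionRule | None = None) -> PeptideMap:
    """Digest every isoform and assign each peptide its set of parents.

    A peptide's parents are all isoforms whose digest contains that exact
    peptide string (I/L are distinct residues by default).  A peptide is
    *unique* iff it has exactly one parent.
    """
    rule = rule or DigestionRule()
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    if len(sequences) == 0:
        raise ValueError("no sequences")
    parents: dict[str, set[str]] = {}
    for iso, seq in sequences.items():
        peps = set(digest(seq, rule))
        if not peps:
            warnings.warn(f"isoform {iso!r}: empty digestion result under {rule}", stacklevel=2)
        for pep in peps:
            parents.setdefault(pep, set()).add(iso)
    return PeptideMap({p: frozenset(s) for p, s in parents.items()}, rule, tuple(sequences))


def rollup_abundance(
    peptides: pd.DataFrame,
    pmap: PeptideMap,
    impute: bool = True,
    median_scale: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Unique-peptide roll-up to per-isoform, per-sample abundances.

    ``peptides`` is a long table with columns ``peptide``, ``sample_id``,
    ``intensity`` (NaN = missing).  Missing values are imputed per
    peptide as half its minimum observed intensity across samples;
    samples are then median-scaled (each sample divided by its median
    peptide intensity, re-centred on the global median); finally each
    isoform's abundance is the mean of its unique peptides.  Returns the
    isoform x sample abundance table and the list of isoforms that are
    not quantifiable (zero unique peptides, or none observed).
    """
    need = {"peptide", "sample_id", "intensity"}
    if not need.issubset(peptides.columns):
        raise ValueError(f"peptide table must have columns {sorted(need)}")
    if len(peptides) == 0:
        raise ValueError("empty peptide intensity table")
    wide = peptides.pivot_table(index="peptide", columns="sample_id", values="intensity",
                                aggfunc="mean", dropna=False)
    if impute:
        half_min = wide.min(axis=1, skipna=True) / 2.0
        all_missing = wide.isna().all(axis=1)
        if all_missing.any():
            warnings.warn(f"{int(all_missing.sum())} peptide(s) missing in every sample; dropped",
                          stacklevel=2)
            wide = wide[~all_missing]
            half_min = half_min[~all_missing]
        wide = wide.apply(lambda row: row.fillna(half_min[row.name]), axis=1)
    if median_scale:
        med = wide.median(axis=0, skipna=True)
        if (med <= 0).any() or med.isna().any():
            raise ValueError("non-positive or undefined sample median; cannot median-scale")
        wide = wide.div(med, axis=1) * float(np.median(med))

    uniq = pmap.unique_peptides
    abundances = {}
    not_quant: list[str] = []
    for iso in pmap.isoforms:
        peps = [p for p in uniq[iso] if p in wide.index]
        if not peps:
            not_quant.append(iso)
            continue
        abundances[iso] = wide.loc[peps].mean(axis=0)
    ab = pd.DataFrame(abundances).T
    ab.index.name = "isoform"
    return ab, not_quant


class PeptideRollup:
    """Transformer-style wrapper: digest + uniqueness at construction,
    roll-up on ``transform``."""

    def __init__(self, sequences: Mapping[str, str] | str | Path,
                 rule: DigestionRule | None = None,
                 impute: bool = True, median_scale: bool = True):
        self.rule = rule or DigestionRule()
        self.map_ = build_uniqueness_map(sequences, self.rule)
        self.impute = impute
        self.median_scale = median_scale

    def transform(self, peptides: pd.DataFrame) -> pd.DataFrame:
        ab, self.not_quantifiable_ = rollup_abundance(
            peptides, self.map_, impute=self.impute, median_scale=self.median_scale)
        return ab


@dataclass(frozen=True)
class ConcordanceResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def concordance(mrna_lfc: pd.Series | Sequence[float],
                protein_lfc: pd.Series | Sequence[float]) -> ConcordanceResult:
    """OLS of protein log2FC (y) on mRNA log2FC (x) across matched isoforms.

    When both inputs are pandas Series they are aligned on their
    (isoform) index first.  Returns slope, intercept, R^2 and the
    two-sided p-value of the slope.
    """
    if isinstance(mrna_lfc, pd.Series) and isinstance(protein_lfc, pd.Series):
        common = mrna_lfc.index.intersection(protein_lfc.index)
        x = mrna_lfc.loc[common].to_numpy(float)
        y = protein_lfc.loc[common].to_numpy(float)
    else:
        x = np.asarray(mrna_lfc, float)
        y = np.asarray(protein_lfc, float)
    if x.size != y.size:
        raise ValueError("unmatched isoform sets")
    if x.size < 3:
        raise ValueError("need >= 3 matched isoforms")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mRNA fold-changes")
    res = sps.linregress(x, y)
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rvalue ** 2)  # constant y: no explained variance
    return ConcordanceResult(float(res.slope), float(res.intercept),
                             r2, float(res.pvalue), int(x.size))
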