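"""Monte-Carlo experiments that quantify the pipeline's operating characteristics.

These are the package's own benchmarks: type-I-error calibration of the
adaptive test, ground-truth recovery of the intron/exon decomposition
across the canonical regulation regimes, slope recovery of the
mRNA-protein concordance regression, and equivalence of the in-silico
digestion against a brute-force enumerator.  Each function is
deterministic given its seed and returns plain numbers/tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import AutoregulationDecomposer
from .nanostring import normalize
from .proteomics import DigestionRule, build_uniqueness_map, concordance, digest
from .simulate import scenario_suite
from .stats import adaptive_test

__all__ = [
    "null_calibration",
    "mode_recovery",
    "concordance_recovery",
    "bruteforce_digest",
    "digestion_oracle_check",
]


def null_calibration(n_sim: int = 10_000, n_per_group: int = 6, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Null rejection rate of the adaptive two-sample test.

    Both groups standard normal; returns the fraction of simulations
    with p < alpha (nominally alpha).
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        if adaptive_test(a, b).p < alpha:
            rejections += 1
    return rejections / n_sim


@dataclass
class RecoveryResult:
    accuracy: float
    n_calls: int
    by_regime: pd.DataFrame  # scenario, n_calls, n_correct, accuracy
    confusion: pd.DataFrame  # truth mode x called mode counts


_RECOVERY_SCENARIOS = ("pe-transcriptional", "transcriptional-down",
                       "taxol-6h", "colchicine-6h", "null")


def mode_recovery(n_studies: int = 200, n_per_group: int = 6, biological_cv: float = 0.10,
                  effect_range: tuple[float, float] = (1.5, 2.0), seed: int = 0,
                  family_size: int = 2, cutoff: float = 0.025) -> RecoveryResult:
    """Ground-truth recovery of the decomposition's mode labels.

    Simulates ``n_studies`` seeded studies cycling through the five
    regimes (transcriptional up/down with effects drawn uniformly from
    ``effect_range``, drug-driven autoactivation/autoinhibition, and a
    null), runs normalization + decomposition on each, and scores every
    per-isoform call against the generator's truth.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_studies):
        scen = _RECOVERY_SCENARIOS[i % len(_RECOVERY_SCENARIOS)]
        effect = float(rng.uniform(*effect_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        bundle = scenario_suite(scen, seed=sub_seed, effect=effect,
                                n_per_group=n_per_group, biological_cv=biological_cv)
        norm = normalize(bundle.counts)
        dec = AutoregulationDecomposer(control="Ctrl", family_size=family_size,
                                       cutoff=cutoff).fit(norm)
        truth = bundle.truth.set_index(["isoform", "contrast"])["mode"]
        for _, row in dec.calls_.iterrows():
            t = truth.loc[(row["isoform"], row["contrast"])]
            records.append({"scenario": scen, "isoform": row["isoform"],
                            "truth": t, "called": row["mode"], "correct": t == row["mode"]})
    df = pd.DataFrame(records)
    by_regime = (df.groupby("scenario")["correct"]
                 .agg(n_calls="size", n_correct="sum", accuracy="mean").reset_index())
    confusion = pd.crosstab(df["truth"], df["called"])
    return RecoveryResult(float(df["correct"].mean()), len(df), by_regime, confusion)


def concordance_recovery(n_seeds: int = 500, n_isoforms: int = 20, true_slope: float = 0.2,
                         sigma: float = 0.3, x_sd: float = 1.2, seed: int = 0) -> dict:
    """Mean recovered OLS slope when protein LFC = slope * mRNA LFC + noise."""
    rng = np.random.default_rng(seed)
    slopes, r2s, ps = [], [], []
    for _ in range(n_seeds):
        x = rng.normal(0.0, x_sd, size=n_isoforms)
        y = true_slope * x + rng.normal(0.0, sigma, size=n_isoforms)
        res = concordance(x, y)
        slopes.append(res.slope)
        r2s.append(res.r2)
        ps.append(res.p)
    return {"mean_slope": float(np.mean(slopes)), "mean_r2": float(np.mean(r2s)),
            "median_p": float(np.median(ps)), "true_slope": true_slope, "n_seeds": n_seeds}


def bruteforce_digest(sequence: str, rule: DigestionRule) -> set[str]:
    """Independent digestion oracle: enumerate every substring span and keep
    those whose ends are termini or cleavage sites and which contain at
    most ``max_missed_cleavages`` internal sites.

    Deliberately O(n^2); used only to cross-check :func:`splitreg.proteomics.digest`.
    """
    from .proteomics import _ENZYMES  # same specificity table, different algorithm

    seq = str(sequence).upper().strip("*")
    residues, no_pro = _ENZYMES[rule.enzyme]
    cut = [False] * (len(seq) + 1)
    cut[0] = cut[len(seq)] = True
    internal = set()
    for i in range(1, len(seq)):
        if seq[i - 1] in residues and not (no_pro and seq[i] == "P"):
            cut[i] = True
            internal.add(i)
    out = set()
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if not (cut[i] and cut[j]):
                continue
            n_missed = sum(1 for k in internal if i < k < j)
            if n_missed > rule.max_missed_cleavages:
                continue
            pep = seq[i:j]
            if len(pep) < rule.min_length:
                continue
            if rule.max_length is not None and len(pep) > rule.max_length:
                continue
            out.add(pep)
    return out


def digestion_oracle_check(n_proteomes: int = 100, seed: int = 0) -> dict:
    """Exact set-equality of digest + uniqueness against the brute-force oracle.

    Random toy proteomes (<= 5 sequences of <= 60 residues, random
    enzyme/missed-cleavage settings); returns the fraction of proteomes
    in exact agreement for both the digest sets and the unique-peptide
    assignment.
    """
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    enzymes = ["trypsin", "chymotrypsin", "glu-c"]
    n_ok = 0
    for _ in range(n_proteomes):
        rule = DigestionRule(enzyme=str(rng.choice(enzymes)),
                             max_missed_cleavages=int(rng.integers(0, 3)),
                             min_length=int(rng.integers(1, 3)))
        n_seq = int(rng.integers(1, 6))
        seqs = {}
        base = "".join(rng.choice(aa, size=int(rng.integers(10, 61))))
        for s in range(n_seq):
            # homologous family: mutate the base a little
            chars = list(base)
            for _ in range(int(rng.integers(0, 5))):
                chars[int(rng.integers(0, len(chars)))] = str(rng.choice(aa))
            seqs[f"S{s}"] = "".join(chars)
        ok = all(set(digest(seq, rule)) == bruteforce_digest(seq, rule) for seq in seqs.values())
        if ok:
            pmap = build_uniqueness_map(seqs, rule)
            oracle_digests = {iso: bruteforce_digest(seq, rule) for iso, seq in seqs.items()}
            all_peps = set().union(*oracle_digests.values()) if oracle_digests else set()
            oracle_parents = {p: frozenset(i for i, d in oracle_digests.items() if p in d)
                              for p in all_peps}
            ok = pmap.parents == oracle_parents
        n_ok += bool(ok)
    return {"agreement": n_ok / n_proteomes, "n_proteomes": n_proteomes}
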