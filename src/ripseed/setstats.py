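"""Gene-set overlap and phenotype-penetrance statistics.

Covers the three small statistical tools the analysis leans on: an
upper-tail hypergeometric test for the overlap of two gene sets drawn from
a common universe, Fisher's exact test on 2x2 arrest/non-arrest tables,
the standard error of a proportion, and an enhancer-screen wrapper that
applies them across a phenotype table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapTest",
    "hypergeometric_overlap",
    "fisher_exact",
    "proportion_se",
    "enhancer_screen",
]


@dataclass(frozen=True)
class OverlapTest:
    """Result of an upper-tail hypergeometric gene-set overlap test."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    expected_overlap: float
    fold_enrichment: float
    p_value: float


def hypergeometric_overlap(N: int, a: int, b: int, k: int) -> OverlapTest:
    """P(X >= k) for the overlap of sets of sizes a and b in a universe of N.

    X ~ Hypergeometric(N, a, b).  ``fold_enrichment`` is the observed
    overlap over its expectation ``a*b/N``.
    """
    if N <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= a <= N and 0 <= b <= N):
        raise ValueError("set sizes must lie in [0, N]")
    if not 0 <= k <= min(a, b):
        raise ValueError("overlap must lie in [0, min(a, b)]")
    if k < a + b - N:
        raise ValueError("overlap below the minimum forced by the margins")
    p = float(stats.hypergeom.sf(k - 1, N, a, b))
    p = min(max(p, 0.0), 1.0)
    expected = a * b / N
    fold = k / expected if expected > 0 else math.nan
    return OverlapTest(N, a, b, k, expected, fold, p)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers.

    Two-sidedness by the minimum-likelihood rule: sum of hypergeometric
    probabilities of all tables (with the observed margins) no more probable
    than the observed one.  Degenerate margins give p = 1; an all-zero table
    is an error.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise ValueError("cells must be nonnegative integers")
        t = np.round(t).astype(int)
    if t.sum() == 0:
        raise ValueError("empty table: all margins are zero")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def proportion_se(k: int, n: int) -> float:
    """SE of a binomial proportion, sqrt(p(1-p)/n) with p = k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    return math.sqrt(p * (1 - p) / n)


def enhancer_screen(
    table: pd.DataFrame,
    reference_labels: Iterable[str],
    alpha: float = 0.001,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Arrest proportion, SE and Fisher tests of each genotype vs references.

    ``table`` has columns (genotype, n_scored, n_arrested).  A non-reference
    genotype is flagged as an *enhancer* when its arrest proportion exceeds
    every reference's and its Fisher two-sided p is below ``alpha`` against
    every reference.  With ``bh_correct`` the p-values of each vs-reference
    column are Benjamini-Hochberg adjusted before thresholding (off by
    default: the screen convention is a fixed raw-significance cutoff).
    """
    refs = list(reference_labels)
    if not refs:
        raise ValueError("at least one reference label required")
    idx = table.set_index("genotype")
    if idx.index.duplicated().any():
        raise ValueError("duplicate genotype labels")
    for r in refs:
        if r not in idx.index:
            raise ValueError(f"reference genotype {r!r} not in table")
    bad = table[
        (table["n_arrested"] < 0) | (table["n_arrested"] > table["n_scored"])
    ]
    if len(bad):
        raise ValueError(f"inconsistent counts for {bad['genotype'].iloc[0]!r}")

    rows = []
    for geno, rec in idx.iterrows():
        n, k = int(rec["n_scored"]), int(rec["n_arrested"])
        row: dict = {
            "genotype": geno,
            "n_scored": n,
            "n_arrested": k,
            "proportion": k / n,
            "se": proportion_se(k, n),
        }
        for r in refs:
            rn, rk = int(idx.loc[r, "n_scored"]), int(idx.loc[r, "n_arrested"])
            row[f"p_vs_{r}"] = fisher_exact([[k, n - k], [rk, rn - rk]])
        rows.append(row)
    out = pd.DataFrame(rows)

    pcols = [f"p_vs_{r}" for r in refs]
    sig = out[pcols].copy()
    if bh_correct:
        from .enrichment import bh_adjust

        for c in pcols:
            sig[c] = bh_adjust(sig[c].to_numpy())
    ref_props = {r: float(idx.loc[r, "n_arrested"] / idx.loc[r, "n_scored"]) for r in refs}
    is_ref = out["genotype"].isin(refs)
    exceeds = out["proportion"].gt(max(ref_props.values()))
    out["is_enhancer"] = (~is_ref) & exceeds & (sig[pcols] < alpha).all(axis=1)
    return out
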