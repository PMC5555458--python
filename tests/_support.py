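"""Independent test oracles: brute-force implementations kept deliberately
separate from the package's code paths."""

from itertools import combinations
from math import comb

import numpy as np

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_force_sites(utr: str, seed7: str) -> set[tuple[int, int, str]]:
    """Window-by-window scan against explicitly constructed pattern strings.

    Patterns: 8mer = rc(seed 2-8) + A; 7mer-m8 = rc(seed 2-8);
    7mer-A1 = rc(seed 2-7) + A.  A 7mer-m8 window is suppressed by an 8mer
    at the same start, a 7mer-A1 window by an 8mer one base upstream (both
    are extensions of the same seed-core occurrence).
    """
    utr = utr.upper().replace("T", "U")
    pat8 = _rc(seed7) + "A"
    pat7m8 = _rc(seed7)
    pat7a1 = _rc(seed7[:6]) + "A"
    n = len(utr)
    out: set[tuple[int, int, str]] = set()
    starts8 = {s for s in range(n - 7) if utr[s : s + 8] == pat8}
    for s in starts8:
        out.add((s, s + 8, "8mer"))
    for s in range(n - 6):
        w = utr[s : s + 7]
        if w == pat7m8 and s not in starts8:
            out.add((s, s + 7, "7mer-m8"))
        if w == pat7a1 and (s - 1) not in starts8:
            out.add((s, s + 7, "7mer-A1"))
    return out


def hypergeom_upper_tail_enum(N: int, a: int, b: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, a) subsets."""
    b_set = set(range(b))
    total = 0
    hits = 0
    for a_tuple in combinations(range(N), a):
        total += 1
        if len(b_set.intersection(a_tuple)) >= k:
            hits += 1
    return hits / total


def fisher_two_sided_enum(table) -> float:
    """Minimum-likelihood two-sided Fisher p by enumerating all tables with
    the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def null_count_matrix(n_transcripts: int, seed: int, dispersion: float = 0.05):
    """A 3 IP / 2 CTRL / 2 TOTAL count matrix with no enrichment anywhere."""
    from ripseed.simulate import GroundTruth, SimConfig, generate_counts

    cfg = SimConfig(
        n_genes=n_transcripts,
        n_bound=0,
        ip_effect=1.0,
        nb_dispersion=dispersion,
        isoforms_per_gene=(1, 1),
        rng_seed=seed,
    )
    isoforms = {f"g{i + 1:04d}.1": [] for i in range(n_transcripts)}
    effects = {f"g{i + 1:04d}": 1.0 for i in range(n_transcripts)}
    truth = GroundTruth(set(), isoforms, effects, [], [])
    return generate_counts(cfg, truth)


def random_utr(rng: np.random.Generator, max_len: int = 200) -> str:
    bases = np.array(list("ACGU"))
    n = int(rng.integers(1, max_len + 1))
    return "".join(bases[rng.integers(0, 4, size=n)])


def random_seed7(rng: np.random.Generator) -> str:
    bases = np.array(list("ACGU"))
    return "".join(bases[rng.integers(0, 4, size=7)])
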