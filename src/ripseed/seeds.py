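"""miRNA seed-site detection in 3'UTR sequences and site-density statistics.

A miRNA *seed* is nucleotides 2-8 of the mature miRNA.  Canonical conserved
site classes on the mRNA sense strand (5'->3') are:

* ``8mer``    -- perfect Watson-Crick match to seed positions 2-8 followed by
  an ``A`` opposite miRNA position 1 (8 nt).
* ``7mer-m8`` -- perfect match to positions 2-8 (7 nt).
* ``7mer-A1`` -- perfect match to positions 2-7 followed by an ``A`` (7 nt).

Every site is anchored on an occurrence of the 6-nt seed core (reverse
complement of miRNA positions 2-7); each core occurrence yields exactly one
site, classified by the strongest pattern it supports (8mer > 7mer-m8 >
7mer-A1).  Bare 6mers are not reported.  Distinct core occurrences are
counted as distinct sites even when their windows overlap; sites of
different families are counted independently.

Conservation is *not* computed here: the caller restricts the family list to
the conserved families of interest, and every exact seed match for those
families is reported.  This differs from pipelines that consume pre-computed
cross-species conserved-site tables; the family list is the conservation
filter.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "MirnaFamily",
    "SeedSite",
    "GeneUtrSummary",
    "DensityComparison",
    "derive_seed",
    "find_seed_sites",
    "count_sites",
    "gene_summary",
    "density_comparison",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
# Ambiguity codes are accepted on input but never match a seed pattern.
_IUPAC_RNA = frozenset("ACGURYSWKMBDHVN")


def normalize_rna(sequence: str, *, what: str = "sequence") -> str:
    """Uppercase, convert T->U and validate IUPAC nucleotide characters.

    Raises ``ValueError`` naming the first offending position.
    """
    seq = sequence.upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in _IUPAC_RNA:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i} in {what}"
            )
    return seq


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def derive_seed(mature_sequence: str) -> str:
    """Return the 7-nt seed (positions 2-8, 1-based) of a mature miRNA.

    The mature sequence is given 5'->3'; T is normalised to U.
    """
    seq = normalize_rna(mature_sequence, what="mature miRNA sequence")
    if len(seq) < 8:
        raise ValueError(
            f"mature sequence must be >= 8 nt to derive a seed, got {len(seq)}"
        )
    return seq[1:8]


@dataclass(frozen=True)
class MirnaFamily:
    """A miRNA family: members sharing one seed sequence.

    ``mature_sequences`` holds one mature 5'->3' RNA sequence per member.
    All members must share positions 2-8; this is checked on construction.
    """

    name: str
    members: tuple[str, ...]
    mature_sequences: tuple[str, ...]
    seed7: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.mature_sequences):
            raise ValueError(
                f"family {self.name}: {len(self.members)} members but "
                f"{len(self.mature_sequences)} mature sequences"
            )
        if not self.mature_sequences:
            raise ValueError(f"family {self.name}: no members")
        seeds = {derive_seed(m) for m in self.mature_sequences}
        if len(seeds) != 1:
            raise ValueError(
                f"family {self.name}: members do not share one seed: {sorted(seeds)}"
            )
        object.__setattr__(self, "seed7", seeds.pop())

    def site_patterns(self) -> dict[str, str]:
        """The three site-pattern strings on the UTR sense strand (RNA)."""
        core6 = reverse_complement_rna(self.seed7[:6])  # positions 2-7
        m8_complement = self.seed7[6].translate(_RNA_COMPLEMENT)
        pat_7m8 = m8_complement + core6
        return {
            "8mer": pat_7m8 + "A",
            "7mer-m8": pat_7m8,
            "7mer-A1": core6 + "A",
        }


@dataclass(frozen=True, order=True)
class SeedSite:
    """One seed-match site, 0-based half-open on the UTR sense strand."""

    isoform_id: str
    start: int
    end: int
    family: str
    site_type: str


class GeneUtrSummary(NamedTuple):
    gene_id: str
    median_sites: float
    median_length: float
    density_per_kb: float


class DensityComparison(NamedTuple):
    mean_density_targets: float
    mean_density_background: float
    fold_change: float


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (overlapping) start positions of ``needle`` in ``haystack``."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_seed_sites(
    utr_sequence: str, family: MirnaFamily, *, isoform_id: str = ""
) -> list[SeedSite]:
    """Scan a 3'UTR for >=7mer seed-match sites of one family.

    Returns sites sorted by position.  One site per seed-core occurrence:
    an 8mer suppresses the 7mer-m8 sharing its start and the 7mer-A1 one
    base downstream, since all three extend the same core occurrence.
    """
    seq = normalize_rna(utr_sequence, what=f"UTR {isoform_id or '(unnamed)'}")
    core6 = reverse_complement_rna(family.seed7[:6])
    m8c = family.seed7[6].translate(_RNA_COMPLEMENT)
    n = len(seq)

    sites: list[SeedSite] = []
    for p in _occurrences(seq, core6):
        has_m8 = p > 0 and seq[p - 1] == m8c
        has_a1 = p + 6 < n and seq[p + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(isoform_id, p - 1, p + 7, family.name, "8mer"))
        elif has_m8:
            sites.append(SeedSite(isoform_id, p - 1, p + 6, family.name, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(isoform_id, p, p + 7, family.name, "7mer-A1"))
        # bare 6mer core: below the >=7mer threshold, not reported
    return sorted(sites)


def count_sites(
    utr_sequence: str,
    families: Iterable[MirnaFamily],
    *,
    isoform_id: str = "",
) -> dict[str, int]:
    """Per-family site counts in one UTR (deduplicated by span within family)."""
    return {
        fam.name: len(find_seed_sites(utr_sequence, fam, isoform_id=isoform_id))
        for fam in families
    }


def scan_utrs(
    utrs: Mapping[str, str], families: Iterable[MirnaFamily]
) -> list[SeedSite]:
    """All sites of all families across a set of UTRs, sorted."""
    fams = list(families)
    sites: list[SeedSite] = []
    for isoform_id, seq in utrs.items():
        for fam in fams:
            sites.extend(find_seed_sites(seq, fam, isoform_id=isoform_id))
    return sorted(sites)


def gene_summary(
    gene_id: str,
    isoform_site_counts: Sequence[float],
    isoform_lengths: Sequence[float],
) -> GeneUtrSummary:
    """Median-over-isoforms site count, UTR length and sites per 1000 nt.

    For genes with several annotated 3'UTR isoforms the median site count
    and the median length are taken *independently* and the density pairs
    the two medians: ``(median_sites / median_length) * 1000``.  With an
    even number of isoforms the median is the mean of the two middle
    values, so ``median_sites`` may be half-integer.
    """
    if len(isoform_site_counts) != len(isoform_lengths):
        raise ValueError("site-count and length lists differ in length")
    if not isoform_site_counts:
        raise ValueError(f"gene {gene_id}: no isoforms")
    if any(l <= 0 for l in isoform_lengths):
        raise ValueError(f"gene {gene_id}: nonpositive UTR length")
    med_sites = float(statistics.median(isoform_site_counts))
    med_len = float(statistics.median(isoform_lengths))
    if med_len <= 0:
        raise ValueError(f"gene {gene_id}: zero median UTR length")
    return GeneUtrSummary(gene_id, med_sites, med_len, med_sites / med_len * 1000.0)


def density_comparison(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    summaries: Mapping[str, GeneUtrSummary],
    expressed_set: Iterable[str],
) -> DensityComparison:
    """Mean seed-site density of targets vs background after expression filtering.

    Both gene sets are intersected with ``expressed_set`` (and with the genes
    that have a UTR summary) before averaging ``density_per_kb``; the fold
    change is targets over background.  An empty filtered set is an error.
    """
    expressed = set(expressed_set)

    def _densities(genes: Iterable[str], label: str) -> list[float]:
        vals = [
            summaries[g].density_per_kb
            for g in set(genes)
            if g in expressed and g in summaries
        ]
        if not vals:
            raise ValueError(f"{label} set is empty after expression filtering")
        return vals

    t = _densities(target_genes, "target")
    b = _densities(background_genes, "background")
    mean_t = float(sum(t) / len(t))
    mean_b = float(sum(b) / len(b))
    fold = mean_t / mean_b if mean_b > 0 else float("nan")
    return DensityComparison(mean_t, mean_b, fold)
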