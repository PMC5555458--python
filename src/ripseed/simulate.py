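"""Synthetic RIP-Seq study generator.

Emulates the statistical structure the downstream analysis assumes: three
IP, two control-IP and two total-RNA libraries drawn from negative-binomial
count distributions with a planted set of bound genes enriched in the IP
libraries; 3'UTR annotations in which bound genes carry a planted excess of
miRNA seed sites for a designated subset of "interacting" families; an
expressed-gene list; and phenotype-penetrance tables for enhancer-screen
statistics.

Ground truth is exact by construction: after planting, every UTR is
re-scanned and background bases are adjusted until the scan reproduces the
planted record precisely (no spurious matches, no class upgrades).  All
randomness flows from a single ``numpy`` Generator seeded by
``SimConfig.rng_seed``, so identical configurations give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import CountMatrix
from .seeds import SITE_TYPES, MirnaFamily, SeedSite, find_seed_sites

__all__ = [
    "SimConfig",
    "GroundTruth",
    "UtrRecord",
    "SyntheticDataset",
    "SimulationError",
    "generate_families",
    "generate_annotation",
    "generate_counts",
    "generate_phenotypes",
    "simulate_dataset",
]

_BASES = np.array(list("ACGU"))


class SimulationError(ValueError):
    pass


def _default_library_sizes() -> dict[str, float]:
    # Depth is not pinned by the experimental design; 1e6 reads per library
    # is a realistic desk-scale default and is fully configurable.
    sizes = {f"IP:{i}": 1_000_000.0 for i in (1, 2, 3)}
    sizes.update({f"CTRL:{i}": 1_000_000.0 for i in (1, 2)})
    sizes.update({f"TOTAL:{i}": 1_000_000.0 for i in (1, 2)})
    return sizes


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the experimental design the analysis is built for:
    3 IP / 2 CTRL / 2 TOTAL libraries, 500 genes of which 50 are bound with
    4-fold IP enrichment, NB dispersion 0.05, and bound genes carrying a
    ~3x planted excess of seed sites concentrated in the designated
    interacting families.
    """

    n_genes: int = 500
    isoforms_per_gene: tuple[int, int] = (1, 3)  # inclusive range
    utr_length: tuple[float, float, int] = (200.0, 60.0, 60)  # mean, sd, min
    n_bound: int = 50
    ip_effect: float = 4.0
    nb_dispersion: float = 0.05
    library_sizes: Mapping[str, float] = field(default_factory=_default_library_sizes)
    n_families: int = 10
    n_interacting: int = 5
    interacting_weight: float = 3.0
    planted_sites_bound: float = 3.0
    planted_sites_unbound: float = 1.0
    site_count_mode: str = "poisson"  # or "fixed": plant exactly the mean
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    expressed_fraction: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be positive")
        if not 0 <= self.n_bound <= self.n_genes:
            raise SimulationError("n_bound must lie in [0, n_genes]")
        lo, hi = self.isoforms_per_gene
        if not 1 <= lo <= hi:
            raise SimulationError("isoforms_per_gene must be 1 <= min <= max")
        mean, sd, min_len = self.utr_length
        if min_len < 8 or mean <= 0 or sd < 0:
            raise SimulationError("utr_length must have mean>0, sd>=0, min>=8")
        if self.ip_effect <= 0:
            raise SimulationError("ip_effect must be positive")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0 (0 = Poisson)")
        if any(s <= 0 for s in self.library_sizes.values()):
            raise SimulationError("library sizes must be positive")
        if not 0 < self.n_families or not 0 <= self.n_interacting <= self.n_families:
            raise SimulationError("need 0 < n_families and 0 <= n_interacting <= n_families")
        if self.planted_sites_bound < 0 or self.planted_sites_unbound < 0:
            raise SimulationError("planted site means must be nonnegative")
        if self.site_count_mode not in ("poisson", "fixed"):
            raise SimulationError("site_count_mode must be 'poisson' or 'fixed'")
        if not 0 < self.expressed_fraction <= 1:
            raise SimulationError("expressed_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class UtrRecord:
    isoform_id: str
    gene_id: str
    sequence: str  # RNA alphabet internally; written as DNA in FASTA


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery benchmarking."""

    bound_genes: set[str]
    planted_sites: dict[str, list[SeedSite]]  # isoform -> sites
    true_ip_effect: dict[str, float]  # gene -> fold enrichment in IP
    families: list[MirnaFamily]
    interacting_families: list[str]


@dataclass
class SyntheticDataset:
    config: SimConfig
    utrs: list[UtrRecord]
    gene_map: dict[str, str]  # isoform -> gene
    truth: GroundTruth
    counts: CountMatrix
    expressed_genes: set[str]

    @property
    def utr_sequences(self) -> dict[str, str]:
        return {r.isoform_id: r.sequence for r in self.utrs}


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def generate_families(
    rng: np.random.Generator, n_families: int, members_per_family: int = 2
) -> list[MirnaFamily]:
    """Random miRNA families with mutually non-confusable seed patterns.

    Seeds are redrawn until no site pattern of one family is a substring of
    (or equal to) a pattern of another, so a planted site of one family can
    never wholly contain a match for a different family.  Members of a
    family share their first 8 nt (the seed region) and differ in the tail.
    """
    families: list[MirnaFamily] = []
    patterns: list[str] = []
    attempts = 0
    while len(families) < n_families:
        attempts += 1
        if attempts > 1000 * n_families:
            raise SimulationError("could not draw non-confusable family seeds")
        mature = "".join(_random_seq(rng, 22))
        try:
            fam = MirnaFamily(
                name=f"fam-{len(families) + 1:02d}",
                members=tuple(
                    f"mir-s{len(families) + 1:02d}-{chr(ord('a') + j)}"
                    for j in range(members_per_family)
                ),
                mature_sequences=tuple(
                    mature[:8] + "".join(_random_seq(rng, 14))
                    for _ in range(members_per_family)
                ),
            )
        except ValueError:
            continue
        new = list(fam.site_patterns().values())
        # same-family containment (7mers inside the 8mer) is handled by the
        # scanner's class priority, so only cross-family containment matters
        if any(a in b or b in a for a in new for b in patterns):
            continue
        families.append(fam)
        patterns.extend(new)
    return families


def _family_weights(cfg: SimConfig, truth_interacting: Sequence[str], families: Sequence[MirnaFamily], bound: bool) -> np.ndarray:
    w = np.ones(len(families))
    if bound:
        for i, fam in enumerate(families):
            if fam.name in truth_interacting:
                w[i] = cfg.interacting_weight
    return w / w.sum()


def _plant_isoform(
    rng: np.random.Generator,
    gene_id: str,
    isoform_id: str,
    length: int,
    n_sites: int,
    families: Sequence[MirnaFamily],
    family_probs: np.ndarray,
) -> tuple[str, list[SeedSite]]:
    """One UTR with exactly ``n_sites`` planted, ground truth exact.

    Sites are placed non-overlapping with >= 1 nt spacing; after planting,
    the sequence is rescanned and free (non-planted) bases inside any
    discrepant window are mutated until the scan equals the planted record.
    """
    if n_sites == 0 and not families:
        return "".join(_random_seq(rng, length)), []

    fam_idx = rng.choice(len(families), size=n_sites, p=family_probs)
    types = [SITE_TYPES[t] for t in rng.integers(0, len(SITE_TYPES), size=n_sites)]
    site_seqs = [
        families[f].site_patterns()[t] for f, t in zip(fam_idx, types)
    ]
    total_len = sum(len(s) for s in site_seqs)
    need = total_len + max(0, n_sites - 1)  # >=1 nt gap between sites
    if need > length:
        raise SimulationError(
            f"gene {gene_id}: cannot fit {n_sites} planted sites "
            f"({need} nt needed) in a UTR of {length} nt"
        )

    for _regen in range(50):
        seq = _random_seq(rng, length)
        # place sites left-to-right with random slack distributed in the gaps
        slack = length - need
        cuts = np.sort(rng.integers(0, slack + 1, size=n_sites)) if n_sites else []
        planted: list[SeedSite] = []
        pos = 0
        prev_cut = 0
        for i, s in enumerate(site_seqs):
            pos += int(cuts[i]) - prev_cut
            prev_cut = int(cuts[i])
            start = pos
            seq[start : start + len(s)] = list(s)
            planted.append(
                SeedSite(isoform_id, start, start + len(s), families[fam_idx[i]].name, types[i])
            )
            pos = start + len(s) + 1  # 1 nt mandatory gap
        planted_spans = [(p.start, p.end) for p in planted]
        covered = np.zeros(length, dtype=bool)
        for a, b in planted_spans:
            covered[a:b] = True
        want = {(p.family, p.start, p.end, p.site_type) for p in planted}

        ok = False
        for _fix in range(300):
            got_sites = [
                s
                for fam in families
                for s in find_seed_sites("".join(seq), fam, isoform_id=isoform_id)
            ]
            got = {(s.family, s.start, s.end, s.site_type) for s in got_sites}
            if got == want:
                ok = True
                break
            bad = got - want | want - got
            free_positions: list[int] = []
            for (_f, a, b, _t) in bad:
                free_positions.extend(i for i in range(a, b) if not covered[i])
            free_positions = sorted(set(free_positions))
            if not free_positions:
                break  # regenerate background
            i = int(rng.choice(free_positions))
            alternatives = [b for b in "ACGU" if b != seq[i]]
            seq[i] = alternatives[int(rng.integers(0, 3))]
        if ok:
            return "".join(seq), planted
    raise SimulationError(
        f"gene {gene_id}: could not realise an exact planted-site UTR "
        f"(length {length}, {n_sites} sites)"
    )


def generate_annotation(
    cfg: SimConfig,
) -> tuple[list[UtrRecord], dict[str, str], GroundTruth]:
    """UTR records, isoform->gene map and exact ground truth for one study."""
    rng = np.random.default_rng(cfg.rng_seed)
    families = generate_families(rng, cfg.n_families)
    interacting = [f.name for f in families[: cfg.n_interacting]]

    genes = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    bound = set(
        np.sort(rng.choice(cfg.n_genes, size=cfg.n_bound, replace=False))
    )
    bound_genes = {genes[i] for i in bound}

    mean_len, sd_len, min_len = cfg.utr_length
    lo_iso, hi_iso = cfg.isoforms_per_gene
    w_bound = _family_weights(cfg, interacting, families, bound=True)
    w_unbound = _family_weights(cfg, interacting, families, bound=False)

    utrs: list[UtrRecord] = []
    gene_map: dict[str, str] = {}
    planted: dict[str, list[SeedSite]] = {}
    for gi, gene in enumerate(genes):
        is_bound = gi in bound
        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        mean_sites = cfg.planted_sites_bound if is_bound else cfg.planted_sites_unbound
        for j in range(n_iso):
            isoform = f"{gene}.{j + 1}"
            length = max(min_len, int(round(rng.normal(mean_len, sd_len))))
            if cfg.site_count_mode == "fixed":
                n_sites = int(round(mean_sites))
            else:
                n_sites = int(rng.poisson(mean_sites))
            seq, sites = _plant_isoform(
                rng,
                gene,
                isoform,
                length,
                n_sites,
                families,
                w_bound if is_bound else w_unbound,
            )
            utrs.append(UtrRecord(isoform, gene, seq))
            gene_map[isoform] = gene
            planted[isoform] = sites

    truth = GroundTruth(
        bound_genes=bound_genes,
        planted_sites=planted,
        true_ip_effect={
            g: (cfg.ip_effect if g in bound_genes else 1.0) for g in genes
        },
        families=families,
        interacting_families=interacting,
    )
    return utrs, gene_map, truth


def generate_counts(cfg: SimConfig, truth: GroundTruth) -> CountMatrix:
    """NB count table for 3 IP / 2 CTRL / 2 TOTAL libraries (per config).

    Per-transcript baseline abundances are log-normal; bound transcripts are
    multiplied by ``ip_effect`` in IP libraries only.  Expected proportions
    are renormalised to each configured library depth (fixed sequencing
    depth), and counts are NB with variance ``m + alpha * m**2``
    (``alpha = 0`` falls back to Poisson).
    """
    if cfg.nb_dispersion < 0:
        raise SimulationError("nb_dispersion must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    isoforms = sorted(truth.planted_sites)
    gene_of = {iso: iso.rsplit(".", 1)[0] for iso in isoforms}
    n = len(isoforms)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    baseline /= baseline.sum()
    effect = np.array(
        [truth.true_ip_effect.get(gene_of[iso], 1.0) for iso in isoforms]
    )

    cols: dict[str, np.ndarray] = {}
    for sample, size in cfg.library_sizes.items():
        cls = str(sample).split(":", 1)[0]
        prop = baseline * (effect if cls == "IP" else 1.0)
        prop = prop / prop.sum()
        mean = prop * float(size)
        if cfg.nb_dispersion == 0:
            cols[sample] = rng.poisson(mean)
        else:
            a = cfg.nb_dispersion
            cols[sample] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mean))
    frame = pd.DataFrame(cols, index=pd.Index(isoforms, name="transcript_id"))
    return CountMatrix(frame)


def generate_phenotypes(
    genotypes: Sequence[tuple[str, int, float]], rng_seed: int
) -> pd.DataFrame:
    """Binomial phenotype table: (genotype, n_scored, n_arrested) rows."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for label, n, p in genotypes:
        if not 0 <= p <= 1:
            raise SimulationError(f"{label}: arrest probability {p} outside [0, 1]")
        if n <= 0:
            raise SimulationError(f"{label}: n must be positive")
        rows.append((label, int(n), int(rng.binomial(n, p))))
    return pd.DataFrame(rows, columns=["genotype", "n_scored", "n_arrested"])


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Full study bundle: annotation, ground truth, counts, expressed genes."""
    utrs, gene_map, truth = generate_annotation(cfg)
    counts = generate_counts(cfg, truth)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 2]))
    genes = sorted(set(gene_map.values()))
    n_expr = max(1, int(round(cfg.expressed_fraction * len(genes))))
    # bound genes are always expressed (they were immunoprecipitated)
    others = [g for g in genes if g not in truth.bound_genes]
    n_extra = max(0, n_expr - len(truth.bound_genes))
    extra = (
        set(np.array(others)[rng.choice(len(others), size=min(n_extra, len(others)), replace=False)])
        if others and n_extra
        else set()
    )
    expressed = set(truth.bound_genes) | extra
    return SyntheticDataset(cfg, utrs, gene_map, truth, counts, expressed)


def with_seed(cfg: SimConfig, rng_seed: int) -> SimConfig:
    return replace(cfg, rng_seed=rng_seed)
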