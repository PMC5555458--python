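"""End-to-end orchestration: simulate -> enrich -> seed scan -> overlap/screen.

The pipeline ties target calling to seed-site density: it simulates a study
(or the stages can be run individually from files via the CLI), fits the
RIP enrichment model, calls targets, scans 3'UTRs for seed sites of every
family and of the designated "interacting" subset, compares site densities
of targets vs the expressed background, tests the overlap of targets with
subset-site-carrying genes, and runs the enhancer-screen statistics.

The report is a pure function of (config, seed): rerunning with the same
configuration yields a byte-identical ``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io
from .enrichment import RIPEnrichment
from .seeds import MirnaFamily, count_sites, density_comparison, gene_summary
from .setstats import enhancer_screen, hypergeometric_overlap
from .simulate import SimConfig, SyntheticDataset, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("ripseed")

_DEFAULT_SCREEN = (
    ("WT", 300, 0.01),
    ("vgln-1(lf)", 300, 0.2),
    ("vgln-1(lf);mir-x(lf)", 300, 0.97),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    q_threshold: float = 0.1
    alpha: float = 0.001
    use_enrichment_filter: bool = False
    screen_genotypes: tuple = _DEFAULT_SCREEN
    screen_references: tuple = ("WT", "vgln-1(lf)")

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def rng_seed(self) -> int:
        return self.sim.rng_seed

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, sim=replace(self.sim, rng_seed=seed))


def _param_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def gene_utr_summaries(
    utr_sequences: Mapping[str, str],
    gene_map: Mapping[str, str],
    families: Sequence[MirnaFamily],
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene median site counts, lengths and densities (all + subset).

    Returns a frame indexed by gene with ``median_sites``, ``median_length``,
    ``density_per_kb`` for all supplied families and, when ``subset`` names
    are given, ``median_sites_subset`` / ``density_subset`` restricted to
    those families.
    """
    subset_set = set(subset or ())
    per_gene: dict[str, dict[str, list]] = {}
    for isoform, seq in utr_sequences.items():
        gene = gene_map.get(isoform, isoform)
        counts = count_sites(seq, families, isoform_id=isoform)
        rec = per_gene.setdefault(gene, {"all": [], "sub": [], "len": []})
        rec["all"].append(sum(counts.values()))
        rec["sub"].append(sum(v for f, v in counts.items() if f in subset_set))
        rec["len"].append(len(seq))

    rows = []
    for gene in sorted(per_gene):
        rec = per_gene[gene]
        s_all = gene_summary(gene, rec["all"], rec["len"])
        row = {
            "gene_id": gene,
            "median_sites": s_all.median_sites,
            "median_length": s_all.median_length,
            "density_per_kb": s_all.density_per_kb,
        }
        if subset_set:
            s_sub = gene_summary(gene, rec["sub"], rec["len"])
            row["median_sites_subset"] = s_sub.median_sites
            row["density_subset"] = s_sub.density_per_kb
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def _density_report(
    summary_frame: pd.DataFrame,
    density_col: str,
    sites_col: str,
    targets: set[str],
    background: set[str],
    expressed: set[str],
) -> dict:
    from .seeds import GeneUtrSummary

    summaries = {
        g: GeneUtrSummary(
            g,
            float(summary_frame.loc[g, sites_col]),
            float(summary_frame.loc[g, "median_length"]),
            float(summary_frame.loc[g, density_col]),
        )
        for g in summary_frame.index
    }
    cmp = density_comparison(targets, background, summaries, expressed)
    return {
        "mean_density_targets": cmp.mean_density_targets,
        "mean_density_background": cmp.mean_density_background,
        "fold_change": cmp.fold_change,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a synthetic study and write all stage outputs.

    Returns the report dict (also written to ``out_dir/report.json``).
    Any stage failure is re-raised tagged with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.rng_seed,
        "parameters": {
            "q_threshold": config.q_threshold,
            "alpha": config.alpha,
            "n_genes": config.sim.n_genes,
            "n_bound": config.sim.n_bound,
            "ip_effect": config.sim.ip_effect,
            "nb_dispersion": config.sim.nb_dispersion,
        },
    }

    stage = "simulate"
    try:
        logger.info("[simulate] seed=%d n_genes=%d", config.rng_seed, config.sim.n_genes)
        data: SyntheticDataset = simulate_dataset(config.sim)
        io.write_utr_fasta(out / "utrs.fa", data.utrs)
        io.write_gene_map(out / "gene_map.tsv", data.gene_map)
        io.write_counts(out / "counts.tsv", data.counts)
        io.write_families(out / "families.tsv", data.truth.families)
        io.write_gene_list(out / "expressed_genes.txt", data.expressed_genes)
        io.write_gene_list(out / "bound_genes.txt", data.truth.bound_genes)
        io.write_sites_bed(
            out / "planted_sites.tsv",
            [s for sites in data.truth.planted_sites.values() for s in sites],
        )

        stage = "enrich"
        logger.info("[enrich] %d transcripts", len(data.counts.frame))
        model = RIPEnrichment(data.counts, data.gene_map)
        results = model.fit(
            q_threshold=config.q_threshold,
            use_enrichment_filter=config.use_enrichment_filter,
        )
        results.to_tsv(out / "enrichment_results.tsv")
        targets = results.target_genes()
        io.write_gene_list(out / "target_genes.txt", targets)
        fc = results.fold_change_summary()
        bound = data.truth.bound_genes
        tp = len(targets & bound)
        report["targets"] = {
            "n_target_genes": len(targets),
            "n_bound_genes_true": len(bound),
            "sensitivity": tp / len(bound) if bound else None,
            "gene_fdr": (len(targets) - tp) / len(targets) if targets else None,
            "median_fc_targets": fc.median_fc_targets,
            "mean_fc_targets": fc.mean_fc_targets,
            "median_fc_all": fc.median_fc_all,
            "mean_fc_all": fc.mean_fc_all,
        }

        stage = "seedscan"
        families = data.truth.families
        subset = data.truth.interacting_families
        logger.info("[seedscan] %d isoforms x %d families", len(data.utrs), len(families))
        summaries = gene_utr_summaries(
            data.utr_sequences, data.gene_map, families, subset
        )
        summaries.to_csv(out / "gene_utr_summary.tsv", sep="\t")
        genes = set(summaries.index)
        background = genes
        if targets & data.expressed_genes:
            density_all = _density_report(
                summaries, "density_per_kb", "median_sites", targets, background,
                data.expressed_genes,
            )
            density_sub = _density_report(
                summaries, "density_subset", "median_sites_subset", targets,
                background, data.expressed_genes,
            )
        else:  # no expressed targets (e.g. a null study): densities undefined
            empty = {
                "mean_density_targets": None,
                "mean_density_background": None,
                "fold_change": None,
            }
            density_all = dict(empty)
            density_sub = dict(empty)
        report["seed_density"] = {
            "all_families": density_all,
            "interacting_families": density_sub,
            "interacting_family_names": list(subset),
        }

        stage = "overlap"
        expressed = data.expressed_genes & genes
        with_subset_sites = {
            g for g in expressed if summaries.loc[g, "median_sites_subset"] > 0
        }
        t_expr = targets & expressed
        k = len(t_expr & with_subset_sites)
        ov = hypergeometric_overlap(
            len(expressed), len(t_expr), len(with_subset_sites), k
        )
        report["overlap"] = {
            "universe": ov.universe_size,
            "targets": ov.set_a_size,
            "genes_with_interacting_sites": ov.set_b_size,
            "overlap": ov.overlap,
            "expected_overlap": ov.expected_overlap,
            "fold_enrichment": ov.fold_enrichment,
            "p_value": ov.p_value,
            "pct_targets_with_sites": 100.0 * k / len(t_expr) if t_expr else None,
        }

        stage = "screen"
        from .simulate import generate_phenotypes

        pheno = generate_phenotypes(
            list(config.screen_genotypes), rng_seed=config.rng_seed + 3
        )
        io.write_phenotypes(out / "phenotypes.tsv", pheno)
        screen = enhancer_screen(
            pheno, list(config.screen_references), alpha=config.alpha
        )
        screen.to_csv(out / "screen_stats.tsv", sep="\t", index=False)
        report["screen"] = json.loads(screen.to_json(orient="records"))
    except Exception as exc:  # noqa: BLE001 - tag failures with the stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.rng_seed,
        "param_hash": _param_hash(config),
        "stages": ["simulate", "enrich", "seedscan", "overlap", "screen"],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report


_CONFIG_CASTS = {
    "n_genes": int, "n_bound": int, "rng_seed": int, "n_families": int,
    "n_interacting": int, "isoforms_min": int, "isoforms_max": int,
    "utr_length_mean": float, "utr_length_sd": float, "utr_length_min": int,
    "ip_effect": float, "nb_dispersion": float, "interacting_weight": float,
    "planted_sites_bound": float, "planted_sites_unbound": float,
    "expressed_fraction": float, "q_threshold": float, "alpha": float,
    "site_count_mode": str,
    "use_enrichment_filter": lambda v: v.lower() in ("1", "true", "yes"),
}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file into a PipelineConfig.

    Unknown keys are an error; ``#`` starts a comment.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_CASTS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        raw[key] = val

    vals = {k: _CONFIG_CASTS[k](v) for k, v in raw.items()}
    sim_kwargs = {}
    for k in (
        "n_genes", "n_bound", "rng_seed", "n_families", "n_interacting",
        "ip_effect", "nb_dispersion", "interacting_weight",
        "planted_sites_bound", "planted_sites_unbound", "expressed_fraction",
        "site_count_mode",
    ):
        if k in vals:
            sim_kwargs[k] = vals[k]
    if {"isoforms_min", "isoforms_max"} & vals.keys():
        d = SimConfig()
        sim_kwargs["isoforms_per_gene"] = (
            vals.get("isoforms_min", d.isoforms_per_gene[0]),
            vals.get("isoforms_max", d.isoforms_per_gene[1]),
        )
    if {"utr_length_mean", "utr_length_sd", "utr_length_min"} & vals.keys():
        d = SimConfig()
        sim_kwargs["utr_length"] = (
            vals.get("utr_length_mean", d.utr_length[0]),
            vals.get("utr_length_sd", d.utr_length[1]),
            vals.get("utr_length_min", d.utr_length[2]),
        )
    pipe_kwargs = {
        k: vals[k]
        for k in ("q_threshold", "alpha", "use_enrichment_filter")
        if k in vals
    }
    return PipelineConfig(sim=SimConfig(**sim_kwargs), **pipe_kwargs)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
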