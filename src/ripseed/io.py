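"""Readers and writers for the plain-text formats used throughout.

Formats: FASTA for 3'UTR sequences (header = isoform ID, DNA alphabet),
TSV for counts / gene maps / miRNA families / phenotypes / ground truth,
and one-ID-per-line gene lists.  Files round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import CountMatrix
from .seeds import MirnaFamily, SeedSite
from .simulate import UtrRecord


def write_utr_fasta(path, utrs: Sequence[UtrRecord]) -> None:
    records = [
        SeqRecord(
            Seq(u.sequence.replace("U", "T")),
            id=u.isoform_id,
            description=f"gene={u.gene_id}",
        )
        for u in utrs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_utr_fasta(path) -> dict[str, str]:
    """Isoform -> sequence (as read; the scanner normalises T/U itself)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_map(path, gene_map: Mapping[str, str]) -> None:
    df = pd.DataFrame(
        sorted((g, i) for i, g in gene_map.items()),
        columns=["gene_id", "isoform_id"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["isoform_id"], df["gene_id"]))


def write_counts(path, matrix: CountMatrix) -> None:
    matrix.frame.to_csv(path, sep="\t", index_label="transcript_id")


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    return CountMatrix(df)


def write_families(path, families: Sequence[MirnaFamily]) -> None:
    rows = [
        (f.name, m, s)
        for f in families
        for m, s in zip(f.members, f.mature_sequences)
    ]
    pd.DataFrame(rows, columns=["family", "member", "mature_sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_families(path) -> list[MirnaFamily]:
    """Load a family TSV; members of a family must share one seed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams = []
    for name, grp in df.groupby("family", sort=True):
        fams.append(
            MirnaFamily(
                name=str(name),
                members=tuple(grp["member"]),
                mature_sequences=tuple(grp["mature_sequence"]),
            )
        )
    return fams


def write_gene_list(path, genes: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_sites_bed(path, sites: Sequence[SeedSite]) -> None:
    """BED-like TSV: isoform, start, end, family, site_type (0-based half-open)."""
    pd.DataFrame(
        [(s.isoform_id, s.start, s.end, s.family, s.site_type) for s in sites],
        columns=["isoform_id", "start", "end", "family", "site_type"],
    ).to_csv(path, sep="\t", index=False)


def read_sites_bed(path) -> list[SeedSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        SeedSite(r.isoform_id, int(r.start), int(r.end), r.family, r.site_type)
        for r in df.itertuples()
    ]


def write_phenotypes(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"genotype", "n_scored", "n_arrested"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df
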