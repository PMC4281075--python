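"""Tabular and sequence I/O shared by the CLI and the library surface.

Assignment TSV: header ``read_id\ttaxon_id``; taxon_id "0" or "-" denotes an
unassigned read.  Truth TSV: as written by the simulator.  Genome map TSV:
``genome_id\torganism_taxon_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import InputError, ParseError
from .simulator import Genome, SimulatedRead
from .strategies import ReadAssignment, ReconciliationReport
from .taxonomy import TaxonId

UNASSIGNED_TOKENS = ("0", "-")


def read_assignments(path: str | Path) -> list[ReadAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["read_id", "taxon_id"]:
        raise ParseError(
            f"{path}: expected columns ['read_id', 'taxon_id'], got {list(df.columns)}"
        )
    out = []
    for row in df.itertuples(index=False):
        token = str(row.taxon_id).strip()
        taxon = None if token in UNASSIGNED_TOKENS else int(token)
        out.append(ReadAssignment(str(row.read_id), taxon))
    return out


def write_assignments(assignments: Sequence[ReadAssignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\ttaxon_id\n")
        for a in assignments:
            fh.write(f"{a.read_id}\t{a.taxon_id if a.taxon_id is not None else '-'}\n")


def write_report(report: ReconciliationReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("relation\tcount\n")
        for name, count in report.as_rows():
            fh.write(f"{name}\t{count}\n")
        fh.write(f"pairs\t{report.n_pairs}\n")


def read_truth(path: str | Path) -> dict[str, TaxonId]:
    """Truth table as read_id -> organism taxon id."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    needed = {"read_id", "organism_taxon_id"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: truth table must contain columns {sorted(needed)}")
    if df["read_id"].duplicated().any():
        dup = df.loc[df["read_id"].duplicated(), "read_id"].iloc[0]
        raise InputError(f"{path}: duplicate read id {dup!r} in truth table")
    return dict(zip(df["read_id"], df["organism_taxon_id"].astype(int)))


def read_genome_map(path: str | Path) -> dict[str, TaxonId]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    needed = {"genome_id", "organism_taxon_id"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: genome map must contain columns {sorted(needed)}")
    return dict(zip(df["genome_id"], df["organism_taxon_id"].astype(int)))


def write_genome_map(genomes: Sequence[Genome], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\torganism_taxon_id\n")
        for g in genomes:
            fh.write(f"{g.genome_id}\t{g.organism_taxon_id}\n")


def read_genomes(
    fasta_path: str | Path, genome_map: Mapping[str, TaxonId]
) -> list[Genome]:
    """Load genomes from multi-FASTA, binding organisms via the genome map."""
    genomes = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in genome_map:
            raise InputError(f"genome {rec.id!r} missing from genome map")
        genomes.append(Genome(rec.id, genome_map[rec.id], str(rec.seq).upper()))
    if not genomes:
        raise InputError(f"{fasta_path}: no FASTA records found")
    return genomes


def write_genomes(genomes: Sequence[Genome], fasta_path: str | Path) -> None:
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i : i + 80] + "\n")


def read_reads(path: str | Path, fmt: str | None = None) -> list[SimulatedRead]:
    """Load sequencing reads (FASTA/FASTQ) as truth-less SimulatedRead shells."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [
        SimulatedRead(rec.id, str(rec.seq).upper(), 0, "", 0, len(rec.seq), "+")
        for rec in SeqIO.parse(str(path), fmt)
    ]
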