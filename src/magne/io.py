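"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython; output is canonical (upper case, 60-character
lines) so that write(read(f)) is byte-stable. Tables are TSV via pandas.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .families import GenomeRecord

logger = logging.getLogger("magne")

FASTA_LINE_WIDTH = 60


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are upper-cased on read. Duplicate IDs and empty files are
    rejected — both indicate a malformed genome file upstream.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    """Write records in canonical form (upper case, 60-char lines)."""
    seqs = [SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in records.items()]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_LINE_WIDTH)
        writer.write_file(seqs)


def genome_fasta_records(genome: GenomeRecord) -> dict[str, str]:
    """``>genomeID|familyID`` records for one genome's CDS set."""
    return {f"{genome.genome_id}|{fam}": seq for fam, seq in genome.cds.items()}


def write_genomes(genomes: Iterable[GenomeRecord], outdir: str | Path) -> list[Path]:
    """One multi-record CDS FASTA per genome, plus a metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    meta_rows = []
    for g in genomes:
        p = outdir / f"{g.genome_id}.fna"
        write_fasta(genome_fasta_records(g), p)
        paths.append(p)
        meta_rows.append(
            {
                "genome_id": g.genome_id,
                "source_class": g.source_class,
                "completeness": f"{g.completeness:.6g}",
                "contamination": f"{g.contamination:.6g}",
                "assembly_size": g.assembly_size,
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "genomes.tsv", sep="\t", index=False)
    return paths


def read_genomes(indir: str | Path) -> list[GenomeRecord]:
    """Load a directory written by :func:`write_genomes`.

    Headers of the form ``genomeID|familyID`` key the CDS by family ID; plain
    headers are used verbatim as gene IDs. Metadata comes from ``genomes.tsv``
    when present, else defaults (isolate, 100% complete) are assumed.
    """
    indir = Path(indir)
    meta: dict[str, dict] = {}
    meta_path = indir / "genomes.tsv"
    if meta_path.exists():
        df = pd.read_csv(meta_path, sep="\t", dtype={"genome_id": str})
        meta = {row["genome_id"]: row for _, row in df.iterrows()}
    genomes = []
    for p in sorted(indir.glob("*.fna")) + sorted(indir.glob("*.fasta")):
        gid = p.stem
        cds = {}
        for name, seq in read_fasta(p).items():
            key = name.split("|", 1)[1] if "|" in name else name
            if key in cds:
                raise ValueError(f"duplicate family/gene ID {key!r} in genome {gid}")
            cds[key] = seq
        row = meta.get(gid, {})
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                source_class=str(row.get("source_class", "isolate")),
                cds=cds,
                completeness=float(row.get("completeness", 100.0)),
                contamination=float(row.get("contamination", 0.0)),
                assembly_size=int(row.get("assembly_size", sum(len(s) for s in cds.values()))),
            )
        )
    if not genomes:
        raise ValueError(f"no genome FASTA files found in {indir}")
    return genomes


def read_ani_table(path: str | Path) -> pd.DataFrame:
    """Three-column ANI TSV (query, reference, ani_percent)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"query", "reference", "ani"}
    if not expected.issubset(df.columns):
        raise ValueError(f"ANI table must have columns {sorted(expected)}, got {list(df.columns)}")
    return df


def write_json(obj, path: str | Path) -> None:
    if is_dataclass(obj):
        obj = asdict(obj)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sig(value: float, digits: int) -> str:
    """Fixed significant-digit formatting for TSV output."""
    return f"{value:.{digits}g}"
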