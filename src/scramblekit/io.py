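"""Standard-format I/O: designs (FASTA + TSV + YAML), FASTQ, pool tables, GFF3.

Design on disk is three small text files: segment sequences as FASTA, a
layout TSV (columns order, segment_id, name, role) and a YAML meta file
holding the lox sequence, flanks and options.  FASTQ is read/written with
Biopython (gzip transparent).  Pool tables and genotype tables are TSV with
header rows and stable column order.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ModuleDesign, build_reference
from .simulate import Pool, PoolEntry

__all__ = [
    "write_design",
    "read_design",
    "write_fastq",
    "read_fastq",
    "write_fasta",
    "write_pool_tsv",
    "read_pool_tsv",
    "write_gff3",
    "write_json",
]

POOL_COLUMNS = ["genotype_key", "abundance", "frequency", "gfp_positive_fraction"]


def write_design(design: ModuleDesign, directory) -> dict[str, Path]:
    """Write a design as segments.fasta + layout.tsv + design.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "segments.fasta"
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description=f"segment_id={s.segment_id}")
        for s in design.segments
    ]
    SeqIO.write(records, fasta, "fasta")
    layout = directory / "layout.tsv"
    pd.DataFrame(
        [
            {"order": i + 1, "segment_id": s.segment_id, "name": s.name, "role": s.role}
            for i, s in enumerate(design.segments)
        ]
    ).to_csv(layout, sep="\t", index=False)
    meta = directory / "design.yaml"
    meta.write_text(
        yaml.safe_dump(
            {
                "lox_sequence": design.lox_sequence,
                "left_flank": design.left_flank,
                "right_flank": design.right_flank,
                "landing_pad_length": design.landing_pad_length,
                "marker_inside_lox_array": design.marker_inside_lox_array,
            },
            sort_keys=True,
        )
    )
    return {"fasta": fasta, "layout": layout, "meta": meta}


def read_design(directory) -> ModuleDesign:
    """Read a design written by write_design."""
    directory = Path(directory)
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(directory / "segments.fasta", "fasta")
    }
    layout = pd.read_csv(directory / "layout.tsv", sep="\t").to_dict("records")
    meta = yaml.safe_load((directory / "design.yaml").read_text())
    return build_reference(
        layout,
        sequences,
        lox_sequence=meta["lox_sequence"],
        left_flank=meta["left_flank"],
        right_flank=meta["right_flank"],
        landing_pad_length=int(meta.get("landing_pad_length", 23)),
        marker_inside_lox_array=bool(meta.get("marker_inside_lox_array", False)),
    )


def _open_maybe_gz(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    with _open_maybe_gz(path, "wt") as fh:
        return SeqIO.write(records, fh, "fastq")


def read_fastq(path) -> list[SeqRecord]:
    with _open_maybe_gz(path, "rt") as fh:
        return list(SeqIO.parse(fh, "fastq"))


def write_fasta(records: Iterable[SeqRecord], path) -> int:
    return SeqIO.write(records, Path(path), "fasta")


def write_pool_tsv(pool: Pool, path) -> None:
    pd.DataFrame(pool.to_rows(), columns=POOL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pool_tsv(path) -> Pool:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = {
        str(row["genotype_key"]): PoolEntry(
            float(row["abundance"]), float(row["gfp_positive_fraction"])
        )
        for _, row in df.iterrows()
    }
    return Pool(entries)


def write_gff3(lines: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
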