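"""Target-region extraction from genome FASTA plus GFF3/BED annotation.

The design stage works on a FASTA panel of annotated features (typically
exons) pulled from a chosen chromosome: 1-based inclusive GFF3 intervals
or 0-based half-open BED intervals, with minus-strand features
reverse-complemented.  Records are named ``chrom:start-end(strand)`` in
1-based coordinates regardless of the input convention.

Also provides a seeded synthetic genome builder (one autosomal and one
Z-linked mock chromosome with a configurable number of target features)
used to exercise the design pipeline end to end without real assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from zdose.thermo import reverse_complement

__all__ = [
    "TargetRegion",
    "read_fasta",
    "write_fasta",
    "extract_targets",
    "synthetic_design_panel",
    "random_dna",
]

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


@dataclass(frozen=True)
class TargetRegion:
    """An annotated genomic interval extracted for primer design."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    feature_type: str
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record (possibly line-wrapped) FASTA to an id → sequence map."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _read_annotation(path: str | Path) -> pd.DataFrame:
    """Normalise GFF3 or BED intervals to 1-based inclusive coordinates."""
    path = Path(path)
    fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    if fmt == "gff3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS,
            dtype={"seqid": str},
        )
        df = df[["seqid", "start", "end", "strand", "type"]].copy()
    else:
        raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
        df = pd.DataFrame(
            {
                "seqid": raw[0],
                "start": raw[1].astype(int) + 1,  # BED is 0-based half-open
                "end": raw[2].astype(int),
                "strand": raw[5] if raw.shape[1] > 5 else "+",
                "type": raw[3] if raw.shape[1] > 3 else "region",
            }
        )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["strand"] = df["strand"].fillna("+").replace(".", "+")
    return df


def extract_targets(
    genome: Mapping[str, str] | str | Path,
    annotation: str | Path,
    chrom: str | None = None,
    feature_type: str | None = None,
) -> list[TargetRegion]:
    """Extract annotated intervals as strand-aware target sequences.

    ``genome`` may be a FASTA path or an id → sequence mapping.  GFF3
    intervals are taken as 1-based inclusive, BED (by ``.bed`` suffix) as
    0-based half-open.  Filters restrict to one chromosome and/or one
    feature type (e.g. ``exon``).  Minus-strand sequences are
    reverse-complemented.  Intervals outside their sequence raise an error
    naming the record.
    """
    seqs = genome if isinstance(genome, Mapping) else read_fasta(genome)
    df = _read_annotation(annotation)
    if chrom is not None:
        df = df[df["seqid"] == chrom]
    if feature_type is not None:
        df = df[df["type"] == feature_type]
    regions: list[TargetRegion] = []
    for row in df.itertuples(index=False):
        if row.seqid not in seqs:
            raise ValueError(f"annotation references unknown sequence {row.seqid!r}")
        seq = seqs[row.seqid]
        if row.start < 1 or row.end > len(seq):
            raise ValueError(
                f"interval {row.seqid}:{row.start}-{row.end} outside sequence "
                f"of length {len(seq)}"
            )
        sub = seq[row.start - 1 : row.end]
        if row.strand == "-":
            sub = reverse_complement(sub)
        regions.append(
            TargetRegion(
                chrom=row.seqid,
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                feature_type=str(row.type),
                sequence=sub,
            )
        )
    return regions


def random_dna(
    length: int, rng: np.random.Generator, gc: float = 0.5
) -> str:
    """Random DNA with the given expected GC fraction."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def synthetic_design_panel(
    n_autosome: int = 12,
    n_sex: int = 12,
    target_length: int = 300,
    spacer_length: int = 50,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, list[TargetRegion]]:
    """Build a mock two-chromosome genome with annotated design targets.

    Lays ``n_autosome`` features on ``chrA`` and ``n_sex`` on ``chrZ``,
    each ``target_length`` bp of random near-50 %-GC sequence separated by
    spacers, mirroring the per-chromosome panel sizes used to build the
    real assays (12 autosomal + 12 sex-linked candidates per species).
    Returns the genome map, a GFF3-convention annotation table, and the
    extracted target regions.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    rows = []
    regions: list[TargetRegion] = []
    for chrom, n in (("chrA", n_autosome), ("chrZ", n_sex)):
        parts = [random_dna(spacer_length, rng, gc)]
        pos = spacer_length
        for i in range(n):
            target = random_dna(target_length, rng, gc)
            start, end = pos + 1, pos + target_length
            rows.append(
                {
                    "seqid": chrom, "source": "zdose", "type": "exon",
                    "start": start, "end": end, "score": ".", "strand": "+",
                    "phase": ".", "attributes": f"ID={chrom}_target_{i + 1:02d}",
                }
            )
            regions.append(
                TargetRegion(chrom, start, end, "+", "exon", target)
            )
            parts.append(target)
            parts.append(random_dna(spacer_length, rng, gc))
            pos = end + spacer_length
        genome[chrom] = "".join(parts)
    return genome, pd.DataFrame(rows), regions


def write_gff3(annotation: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        annotation.to_csv(fh, sep="\t", header=False, index=False)
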