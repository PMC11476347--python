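"""Sequence/feature data model and all external file formats.

Chromosomes are circular bacterial replicons stored as linear strings; every
interval operation accepts wrap-around intervals (``start_bp > end_bp`` means
the interval crosses the origin of the linear representation).  Coordinates
are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils.iterators
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FormatError

NUCLEOTIDES = set("ACGTN")

#: canonical feature kinds used by the pipeline
KINDS = ("tRNA", "PRS", "integrase", "other")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Chromosome:
    """A circular replicon with an oriC-anchored coordinate frame.

    ``origin_offset_bp`` records the rotation applied so that oriC starts at
    position 1 (0 when the record is unrotated).
    """

    id: str
    sequence: str
    circular: bool = True
    origin_offset_bp: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise FormatError(
                f"{self.id}: non-nucleotide characters {sorted(bad)!r}"
            )
        if not self.sequence:
            raise FormatError(f"{self.id}: empty sequence")
        if not 0 <= self.origin_offset_bp < len(self.sequence):
            raise CoordinateError(
                f"{self.id}: origin_offset_bp {self.origin_offset_bp} out of range"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def fetch(self, start_bp: int, end_bp: int) -> str:
        """Sequence of the 1-based inclusive interval; wraps when start > end."""
        L = self.length_bp
        if not (1 <= start_bp <= L and 1 <= end_bp <= L):
            raise CoordinateError(
                f"{self.id}: interval {start_bp}..{end_bp} outside 1..{L}"
            )
        if start_bp <= end_bp:
            return self.sequence[start_bp - 1 : end_bp]
        if not self.circular:
            raise CoordinateError(f"{self.id}: wrap-around interval on linear record")
        return self.sequence[start_bp - 1 :] + self.sequence[:end_bp]



@dataclass
class Feature:
    """A located annotation (tRNA gene, PRS element, integrase, ...).

    ``type`` holds the raw GFF3 type string; :attr:`kind` normalizes it to one
    of :data:`KINDS`.  Attribute keys follow the package convention:
    ``isotype``, ``anticodon``, ``prs_class``, ``integrase_origin``.
    """

    chrom_id: str
    start_bp: int
    end_bp: int
    strand: str
    type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.start_bp < 1 or self.end_bp < 1:
            raise FormatError(
                f"coordinates must be positive: {self.start_bp}..{self.end_bp}"
            )

    @property
    def kind(self) -> str:
        return self.type if self.type in KINDS[:3] else "other"

    @property
    def length_bp(self) -> int:
        # wrap-around features are resolved against a chromosome; plain span here
        return self.end_bp - self.start_bp + 1

    def shifted(self, delta_bp: int, length_bp: int) -> "Feature":
        """Feature re-coordinated by a circular rotation of ``delta_bp``."""
        s = (self.start_bp - 1 + delta_bp) % length_bp + 1
        e = (self.end_bp - 1 + delta_bp) % length_bp + 1
        return replace(self, start_bp=s, end_bp=e)


# ---------------------------------------------------------------------------
# FASTA


def read_sequences(path: str | Path, circular: bool = True) -> list[Chromosome]:
    """Read a FASTA file into :class:`Chromosome` records (order preserved)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    chroms = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id} is empty")
        chroms.append(Chromosome(id=rec.id, sequence=seq, circular=circular))
    return chroms


def write_sequences(chroms: list[Chromosome], path: str | Path) -> None:
    recs = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in chroms]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_features(path: str | Path) -> list[Feature]:
    """Read a GFF3 file; coordinates 1-based inclusive, unknown types kept."""
    feats: list[Feature] = []
    for f in gffutils.iterators.DataIterator(str(path)):
        if f.end < f.start:
            raise FormatError(
                f"{path}: feature with end < start ({f.start}..{f.end})"
            )
        attrs = {k: ",".join(v) for k, v in sorted(f.attributes.items())}
        strand = f.strand if f.strand in ("+", "-") else "+"
        feats.append(
            Feature(
                chrom_id=f.seqid,
                start_bp=f.start,
                end_bp=f.end,
                strand=strand,
                type=f.featuretype,
                attributes=attrs,
            )
        )
    return feats


def write_features(features: list[Feature], path: str | Path, source: str = "prsmap") -> None:
    """Write features as GFF3 (attribute keys in sorted order, deterministic)."""
    lines = ["##gff-version 3"]
    for f in features:
        attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attributes.items())) or "."
        lines.append(
            "\t".join(
                [
                    f.chrom_id,
                    source,
                    f.type,
                    str(f.start_bp),
                    str(f.end_bp),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def check_features_on(chrom: Chromosome, features: list[Feature]) -> None:
    """Validate that features fit on the chromosome (pipeline join check)."""
    for f in features:
        if f.chrom_id != chrom.id:
            continue
        if f.start_bp > chrom.length_bp or f.end_bp > chrom.length_bp:
            raise CoordinateError(
                f"feature {f.type} {f.start_bp}..{f.end_bp} beyond "
                f"{chrom.id} length {chrom.length_bp}"
            )


# ---------------------------------------------------------------------------
# Report bundle


def write_report(
    tables: dict[str, pd.DataFrame],
    path: str | Path,
    summary: dict | None = None,
) -> list[str]:
    """Write one TSV per table plus a JSON summary; returns the manifest.

    Output is deterministic: tables are written in sorted-name order with
    their existing column order, and the summary JSON has sorted keys.
    """
    if not tables:
        raise ValueError("no tables to write")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name in sorted(tables):
        fn = outdir / f"{name}.tsv"
        tables[name].to_csv(fn, sep="\t", index=False, lineterminator="\n")
        manifest.append(fn.name)
    doc = {
        "tables": {name: list(map(str, tables[name].columns)) for name in sorted(tables)},
        "summary": summary or {},
    }
    fn = outdir / "summary.json"
    fn.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    manifest.append(fn.name)
    return manifest
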