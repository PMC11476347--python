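"""tRNA gene catalog: ordinal numbering along the oriC->terC axis.

Genes are sorted by increasing rotated plus-strand coordinate (0 -> 360
degrees, passing through terC) and numbered 001 upward, reproducing the
single-pass numbering used for the reference chromosome.  Chromosome quarters
are fixed at 0/90/180/270 degrees regardless of the exact terC angle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError
from .io import Chromosome, Feature
from .replichore import bp_to_degrees
from .stats import GofResult, chi_square_gof

QUARTERS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class TRNAGene:
    feature: Feature
    isotype: str
    anticodon: str
    ordinal: int
    degree: float
    quarter: str

    @property
    def label(self) -> str:
        return f"{self.ordinal:03d}"

    @property
    def strand(self) -> str:
        return self.feature.strand

    @property
    def start_bp(self) -> int:
        return self.feature.start_bp

    @property
    def end_bp(self) -> int:
        return self.feature.end_bp


@dataclass(frozen=True)
class TRNACatalog:
    chrom_id: str
    genes: tuple[TRNAGene, ...]

    @property
    def n_plus(self) -> int:
        return sum(1 for g in self.genes if g.strand == "+")

    @property
    def n_minus(self) -> int:
        return sum(1 for g in self.genes if g.strand == "-")

    def by_label(self, label: str) -> TRNAGene:
        return self.genes[int(label) - 1]


def quarter_of(degree: float) -> str:
    return QUARTERS[int(degree // 90) % 4]


def assign_ordinals(features: list[Feature], chrom: Chromosome) -> TRNACatalog:
    """Number tRNA genes 001..NNN by increasing oriC-rotated coordinate.

    Ties on start position are broken by strand (+ first), then anticodon.
    The numbering is stable under permutation of the input feature order.
    """
    trnas = [f for f in features if f.kind == "tRNA"]
    for f in trnas:
        if f.chrom_id != chrom.id:
            raise CoordinateError(
                f"tRNA feature on {f.chrom_id}, expected {chrom.id}"
            )
    trnas.sort(
        key=lambda f: (
            f.start_bp,
            0 if f.strand == "+" else 1,
            f.attributes.get("anticodon", ""),
        )
    )
    genes = []
    for i, f in enumerate(trnas, start=1):
        deg = bp_to_degrees(f.start_bp, chrom.length_bp)
        genes.append(
            TRNAGene(
                feature=f,
                isotype=f.attributes.get("isotype", "?"),
                anticodon=f.attributes.get("anticodon", "???"),
                ordinal=i,
                degree=deg,
                quarter=quarter_of(deg),
            )
        )
    return TRNACatalog(chrom_id=chrom.id, genes=tuple(genes))


def strand_counts_test(catalog: TRNACatalog, grouping: str = "strand") -> GofResult:
    """Chi-square test of gene counts against a discrete uniform expectation.

    ``grouping`` is ``"strand"`` (2 categories) or ``"strand_quarter"``
    (8 categories).  The degrees of freedom behind the published strand
    asymmetry statistic are not recoverable, so both groupings are offered.
    """
    if not catalog.genes:
        raise ValueError("empty catalog")
    if grouping == "strand":
        cats = {"+": 0, "-": 0}
        for g in catalog.genes:
            cats[g.strand] += 1
    elif grouping == "strand_quarter":
        cats = {f"{s}{q}": 0 for s in "+-" for q in QUARTERS}
        for g in catalog.genes:
            cats[f"{g.strand}{g.quarter}"] += 1
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return chi_square_gof(cats)
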