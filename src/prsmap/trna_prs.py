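"""tRNA genes carried inside PRS elements and gene-replacement events.

An element may import extra tRNA genes into the host genome; when an
integration disrupts a chromosomal tRNA gene (central anchor) and the element
carries a tRNA of the same isotype and anticodon, the imported copy replaces
the broken one.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .attsites import ANCHOR_CENTRAL, IntegrationCall, PRSElement, circ_overlap, _span
from .io import Chromosome, Feature
from .trna import TRNACatalog


@dataclass(frozen=True)
class TrnaPrsRecord:
    element_id: str
    trna: Feature
    isotype: str
    anticodon: str
    counterpart_ordinal: int | None
    identity_pct: float | None
    coverage_pct: float | None


def find_trna_in_elements(
    elements: list[PRSElement],
    trna_features: list[Feature],
    chrom_length: int,
) -> list[TrnaPrsRecord]:
    """tRNA features fully contained in an element interval, as records.

    Containment is circular-aware; genes half-overlapping a boundary are
    excluded (they belong to the chromosomal catalog).
    """
    records = []
    for el in elements:
        for f in trna_features:
            if f.kind != "tRNA" or f.chrom_id != el.feature.chrom_id:
                continue
            ov, _, _ = circ_overlap(
                f.start_bp, f.end_bp, el.start_bp, el.end_bp, chrom_length
            )
            if ov == _span(f.start_bp, f.end_bp, chrom_length):
                records.append(
                    TrnaPrsRecord(
                        element_id=el.id,
                        trna=f,
                        isotype=f.attributes.get("isotype", "?"),
                        anticodon=f.attributes.get("anticodon", "???"),
                        counterpart_ordinal=None,
                        identity_pct=None,
                        coverage_pct=None,
                    )
                )
    return records


def compare_identity_coverage(query: str, subject: str) -> tuple[float, float]:
    """Identity over aligned columns and query coverage of a local alignment.

    Coverage is the aligned fraction of the query (x100); identity is
    computed over aligned columns only.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-7,
        extend_gap_score=-2,
    )
    aln = aligner.align(query.upper(), subject.upper())[0]
    qa = aln.aligned[0]
    covered = int(sum(e - s for s, e in qa))
    coverage = 100.0 * covered / len(query)
    # count matches over aligned columns (gap columns included in columns)
    cols = matches = 0
    a, b = aln[0], aln[1]
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y and x != "-":
            matches += 1
    identity = 100.0 * matches / cols if cols else 0.0
    return identity, coverage


def match_counterparts(
    records: list[TrnaPrsRecord],
    catalog: TRNACatalog,
    chrom: Chromosome,
    calls: list[IntegrationCall] | None = None,
) -> list[TrnaPrsRecord]:
    """Fill counterpart ordinal and identity/coverage vs the chromosomal gene.

    The counterpart is the catalog gene with the same isotype and anticodon
    (first by ordinal when several isoacceptor copies exist).  When the
    counterpart gene was itself disrupted by a central-anchor integration,
    its intact sequence is reconstructed by in-silico excision of the
    disrupting element before the comparison.
    """
    from dataclasses import replace

    from .attsites import excise
    from .io import revcomp

    disrupting = {
        id(c.host_gene.feature): c
        for c in (calls or [])
        if c.gene_disrupted and c.host_gene is not None and c.att_r is not None
    }
    out = []
    for rec in records:
        counterpart = next(
            (
                g
                for g in catalog.genes
                if g.isotype == rec.isotype and g.anticodon == rec.anticodon
            ),
            None,
        )
        if counterpart is None:
            out.append(rec)
            continue
        q = chrom.fetch(rec.trna.start_bp, rec.trna.end_bp)
        if rec.trna.strand == "-":
            q = revcomp(q)
        call = disrupting.get(id(counterpart.feature))
        if call is not None:
            restored = excise(chrom, call)
            removed = chrom.length_bp - restored.length_bp
            s = restored.fetch(counterpart.start_bp, counterpart.end_bp - removed)
        else:
            s = chrom.fetch(counterpart.start_bp, counterpart.end_bp)
        if counterpart.strand == "-":
            s = revcomp(s)
        ident, cov = compare_identity_coverage(q, s)
        out.append(
            replace(
                rec,
                counterpart_ordinal=counterpart.ordinal,
                identity_pct=ident,
                coverage_pct=cov,
            )
        )
    return out


def replacement_check(call: IntegrationCall, records: list[TrnaPrsRecord]) -> bool:
    """True iff a central-anchor (gene-disrupting) integration is compensated.

    The element must carry a tRNA of the same isotype and anticodon as the
    disrupted host gene.
    """
    if call.anchor_class != ANCHOR_CENTRAL or call.host_gene is None:
        return False
    for rec in records:
        if rec.element_id != call.element.id:
            continue
        if (
            rec.isotype == call.host_gene.isotype
            and rec.anticodon == call.host_gene.anticodon
        ):
            return True
    return False
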