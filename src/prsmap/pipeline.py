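"""End-to-end orchestration: per-strain analysis and cohort-level summaries.

Per strain: anchor the chromosome at oriC, call terC, number the tRNA genes,
detect and classify the att pair of every annotated PRS element, resolve
nested integrations and imported tRNA genes.  At cohort level: class and
per-gene frequency tables, the uniformity test, frequency tiers, diversity of
integrase-origin labels, and (optionally) synteny blocks with their pair-class
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import replichore, stats, synteny as synteny_mod, trna, trna_prs
from .attsites import (
    ANCHOR_NONE,
    IntegrationCall,
    PRSElement,
    classify_attachment,
    detect_nested,
    find_flanking_repeats,
)
from .errors import LowConfidenceError
from .io import Chromosome, Feature, check_features_on
from .trna import TRNACatalog


@dataclass
class StrainResult:
    chrom: Chromosome
    anchor: replichore.OriginAnchor
    terc: replichore.TerCCall | None
    catalog: TRNACatalog
    elements: list[PRSElement]
    calls: list[IntegrationCall]
    trna_prs_records: list[trna_prs.TrnaPrsRecord]
    replacements: dict[str, bool] = field(default_factory=dict)


def analyze_strain(
    chrom: Chromosome,
    features: list[Feature],
    probe: str,
    min_dr_len: int = 12,
    max_dr_len: int = 98,
    search_window_bp: int = 150,
    max_mismatch_frac: float = 0.05,
) -> StrainResult:
    """Run the full per-strain analysis on one annotated chromosome."""
    anchor = replichore.locate_oric(chrom, probe)
    chrom, features = replichore.rotate_to_origin(chrom, anchor, features)
    check_features_on(chrom, features)
    gc = replichore.gc_skew_profile(chrom)
    oc = replichore.octamer_profile(chrom)
    try:
        terc = replichore.call_terc(gc, oc, chrom)
    except LowConfidenceError:
        terc = None

    elements = [PRSElement(f) for f in features if f.kind == "PRS"]
    trna_feats = [f for f in features if f.kind == "tRNA"]
    records = trna_prs.find_trna_in_elements(elements, trna_feats, chrom.length_bp)
    imported = {id(r.trna) for r in records}
    chromosomal = [f for f in trna_feats if id(f) not in imported]
    catalog = trna.assign_ordinals(chromosomal, chrom)

    calls: list[IntegrationCall] = []
    for el in elements:
        pairs = find_flanking_repeats(
            chrom,
            el,
            min_len=min_dr_len,
            max_len=max_dr_len,
            search_window_bp=search_window_bp,
            max_mismatch_frac=max_mismatch_frac,
        )
        if not pairs:
            calls.append(
                IntegrationCall(el, None, None, None, ANCHOR_NONE, False)
            )
            continue
        call = classify_attachment(pairs[0], catalog, chrom)
        call = detect_nested(chrom, call)
        calls.append(call)

    records = trna_prs.match_counterparts(records, catalog, chrom, calls)
    replacements = {
        c.element.id: trna_prs.replacement_check(c, records) for c in calls
    }
    return StrainResult(
        chrom=chrom,
        anchor=anchor,
        terc=terc,
        catalog=catalog,
        elements=elements,
        calls=calls,
        trna_prs_records=records,
        replacements=replacements,
    )


# ---------------------------------------------------------------------------
# cohort summaries


def class_frequency_table(results: list[StrainResult]) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for r in results:
        for el in r.elements:
            counts[el.prs_class] = counts.get(el.prs_class, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["prs_class", "count", "frequency"])
    ft = stats.frequency_table(counts)
    return pd.DataFrame(
        {
            "prs_class": ft.categories,
            "count": ft.counts,
            "frequency": [round(f, 4) for f in ft.frequencies],
        }
    ).sort_values("prs_class", ignore_index=True)


def per_gene_frequencies(results: list[StrainResult]) -> dict[str, int]:
    """Integration counts per host gene label across the cohort."""
    counts: dict[str, int] = {}
    for r in results:
        for c in r.calls:
            if c.host_gene is None:
                continue
            counts[c.host_gene.label] = counts.get(c.host_gene.label, 0) + 1
    return counts


def hotspot_analysis(results: list[StrainResult], k: int = 3):
    """Uniformity test over genes with >= 1 integration, plus frequency tiers."""
    counts = per_gene_frequencies(results)
    if len(counts) < max(k, 2):
        raise ValueError("too few integrated genes for hot-spot analysis")
    gof = stats.chi_square_gof(counts)
    total = sum(counts.values())
    freqs = {g: c / total for g, c in counts.items()}
    tiers = stats.tier_frequencies(freqs, k=k)
    return counts, gof, tiers


def anchor_class_table(results: list[StrainResult]) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for r in results:
        for c in r.calls:
            counts[c.anchor_class] = counts.get(c.anchor_class, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["anchor_class", "count", "frequency"])
    ft = stats.frequency_table(counts)
    return pd.DataFrame(
        {
            "anchor_class": ft.categories,
            "count": ft.counts,
            "frequency": [round(f, 4) for f in ft.frequencies],
        }
    ).sort_values("anchor_class", ignore_index=True)


def integrase_diversity(results: list[StrainResult]) -> dict[str, float]:
    """Shannon index of integrase-origin labels per element group.

    Groups: prophages; GIs with phage-like fragments; GIs without.
    """
    groups: dict[str, dict[str, int]] = {
        "prophages": {},
        "gi_with_phage": {},
        "gi_without_phage": {},
    }
    for r in results:
        for el in r.elements:
            if el.prs_class == "GI":
                has = el.feature.attributes.get("has_phage_fragments") == "true"
                key = "gi_with_phage" if has else "gi_without_phage"
            else:
                key = "prophages"
            d = groups[key]
            d[el.integrase_origin] = d.get(el.integrase_origin, 0) + 1
    return {
        name: (stats.shannon_index(d) if d else float("nan"))
        for name, d in groups.items()
    }


def synteny_analysis(
    results: list[StrainResult],
    min_len: int = 8000,
    min_identity: float = 90.0,
):
    """Best block per element pair, the length/identity filter, pair classes."""
    seqs: dict[str, str] = {}
    classes: dict[str, str] = {}
    phage_flags: dict[str, bool] = {}
    elements: list[PRSElement] = []
    for r in results:
        for el in r.elements:
            eid = el.id
            seqs[eid] = r.chrom.fetch(el.start_bp, el.end_bp)
            classes[eid] = el.prs_class
            phage_flags[eid] = (
                el.feature.attributes.get("has_phage_fragments") == "true"
            )
            elements.append(el)
    ids = sorted(seqs)
    blocks = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = synteny_mod.best_block(
                seqs[ids[i]], seqs[ids[j]], id_a=ids[i], id_b=ids[j]
            )
            if b is not None:
                blocks.append(b)
    kept = synteny_mod.filter_blocks(blocks, min_len=min_len, min_identity=min_identity)
    counts = synteny_mod.classify_pairs(kept, classes, phage_flags)
    doc = synteny_mod.export_synteny_json(kept, elements)
    return blocks, kept, counts, doc


def calls_table(results: list[StrainResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for c in r.calls:
            rows.append(
                {
                    "element_id": c.element.id,
                    "prs_class": c.element.prs_class,
                    "host_ordinal": c.host_gene.label if c.host_gene else "",
                    "anchor_class": c.anchor_class,
                    "att_length": len(c.att_r) if c.att_r else 0,
                    "in_gene_bp": c.att_r.in_gene_bp if c.att_r else 0,
                    "spacer_bp": c.att_r.spacer_bp if c.att_r else 0,
                    "gene_disrupted": c.gene_disrupted,
                    "nested_sizes": ";".join(
                        str(n) for _, n in c.nested_children
                    ),
                    "replacement": r.replacements.get(c.element.id, False),
                }
            )
    return pd.DataFrame(rows)
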