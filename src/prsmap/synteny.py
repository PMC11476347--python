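"""Synteny blocks between PRS elements and their class-pair summary.

For every unordered pair of elements only the single best local-alignment
block (highest score; ties broken by longer block, then coordinates) enters
the analysis.  Retained blocks must exceed a length and identity floor
(8 kb and 90% by default).  Pair classes: Ph covers all prophage classes
(int-Ph, inc-Ph, q-Ph); GI/GI pairs are split by whether both members are
free of phage-like fragments.  The retained blocks exported as a JSON
document drive circular-plot rendering downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from ._align import LocalHit, best_local_hit
from .attsites import PROPHAGE_CLASSES, PRS_CLASSES, PRSElement
from .io import revcomp


@dataclass(frozen=True)
class SyntenyBlock:
    element_a: str
    element_b: str
    length_columns: int
    identity_pct: float
    score: float
    coords_a: tuple[int, int]
    coords_b: tuple[int, int]
    strand: str = "+"


@dataclass(frozen=True)
class PairClassCounts:
    ph_ph: int = 0
    ph_gi: int = 0
    gi_gi_phage: int = 0
    gi_gi_nophage: int = 0

    @property
    def total(self) -> int:
        return self.ph_ph + self.ph_gi + self.gi_gi_phage + self.gi_gi_nophage


def best_block(
    seq_a: str,
    seq_b: str,
    id_a: str = "a",
    id_b: str = "b",
    k: int = 15,
    x_drop: int = 50,
) -> SyntenyBlock | None:
    """Single highest-scoring local block between two sequences (both strands).

    Ties are broken by the longer block, then by lexicographic coordinates.
    Returns None when no positive-scoring block exists.
    """
    if len(seq_a) < k or len(seq_b) < k:
        return None
    fwd = best_local_hit(seq_a, seq_b, k=k, x_drop=x_drop)
    rev = best_local_hit(seq_a, revcomp(seq_b), k=k, x_drop=x_drop)
    m = len(seq_b)

    def _key(h: LocalHit | None):
        if h is None:
            return (-1, -1, 0, 0)
        return (h.score, h.columns, -h.a_start, -h.b_start)

    if fwd is None and rev is None:
        return None
    if _key(fwd) >= _key(rev):
        hit, strand = fwd, "+"
        cb = (hit.b_start, hit.b_end)
    else:
        hit, strand = rev, "-"
        cb = (m - rev.b_end + 1, m - rev.b_start + 1)
    return SyntenyBlock(
        element_a=id_a,
        element_b=id_b,
        length_columns=hit.columns,
        identity_pct=hit.identity_pct,
        score=float(hit.score),
        coords_a=(hit.a_start, hit.a_end),
        coords_b=cb,
        strand=strand,
    )


def filter_blocks(
    blocks: list[SyntenyBlock], min_len: int = 8000, min_identity: float = 90.0
) -> list[SyntenyBlock]:
    """Keep blocks longer than ``min_len`` columns and above ``min_identity``%."""
    return [
        b
        for b in blocks
        if b is not None and b.length_columns > min_len and b.identity_pct > min_identity
    ]


def _is_prophage(cls: str) -> bool:
    if cls not in PRS_CLASSES:
        raise ValueError(f"unknown PRS class {cls!r}")
    return cls in PROPHAGE_CLASSES


def classify_pairs(
    blocks: list[SyntenyBlock],
    classes: dict[str, str],
    has_phage_fragments: dict[str, bool] | None = None,
) -> PairClassCounts:
    """Count blocks by member-class pair (Ph/Ph, Ph/GI, GI/GI split by cargo).

    ``classes`` maps element id -> PRS class; ``has_phage_fragments`` flags
    GIs carrying phage-like fragments (required to split GI/GI pairs).
    """
    has_phage_fragments = has_phage_fragments or {}
    ph_ph = ph_gi = gi_gi_ph = gi_gi_no = 0
    for b in blocks:
        ca, cb = classes[b.element_a], classes[b.element_b]
        pa, pb = _is_prophage(ca), _is_prophage(cb)
        if pa and pb:
            ph_ph += 1
        elif pa or pb:
            ph_gi += 1
        else:
            both_free = not has_phage_fragments.get(
                b.element_a, False
            ) and not has_phage_fragments.get(b.element_b, False)
            if both_free:
                gi_gi_no += 1
            else:
                gi_gi_ph += 1
    return PairClassCounts(ph_ph, ph_gi, gi_gi_ph, gi_gi_no)


def geometric_ratio(counts: list[int]) -> tuple[float, float]:
    """Mean and SEM of successive count ratios (decreasing-progression check)."""
    if len(counts) < 2:
        raise ValueError("need at least 2 counts")
    if any(c <= 0 for c in counts):
        raise ValueError("counts must be positive")
    ratios = np.asarray(
        [counts[i] / counts[i + 1] for i in range(len(counts) - 1)], dtype=float
    )
    sem = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return float(ratios.mean()), sem


# ---------------------------------------------------------------------------
# JSON export (schema-validated, deterministic ordering)


class _ElementEntry(BaseModel):
    id: str
    prs_class: str = Field(pattern="^(GI|int-Ph|inc-Ph|q-Ph)$")
    host_ordinal: int | None = None
    color_class: str


class _LinkEntry(BaseModel):
    a: str
    b: str
    coords_a: tuple[int, int]
    coords_b: tuple[int, int]
    length_columns: int
    identity_pct: float


class SyntenyDocument(BaseModel):
    elements: list[_ElementEntry]
    links: list[_LinkEntry]


#: circular-plot legend colors by element class
COLOR_BY_CLASS = {"GI": "gray", "int-Ph": "green", "q-Ph": "blue", "inc-Ph": "red"}


def export_synteny_json(
    blocks: list[SyntenyBlock],
    elements: list[PRSElement],
    host_ordinals: dict[str, int] | None = None,
) -> dict:
    """Schema-validated JSON document of elements and synteny links."""
    host_ordinals = host_ordinals or {}
    entries = [
        _ElementEntry(
            id=el.id,
            prs_class=el.prs_class,
            host_ordinal=host_ordinals.get(el.id),
            color_class=COLOR_BY_CLASS[el.prs_class],
        )
        for el in sorted(elements, key=lambda e: e.id)
    ]
    links = [
        _LinkEntry(
            a=b.element_a,
            b=b.element_b,
            coords_a=b.coords_a,
            coords_b=b.coords_b,
            length_columns=b.length_columns,
            identity_pct=round(b.identity_pct, 2),
        )
        for b in sorted(blocks, key=lambda b: (b.element_a, b.element_b))
    ]
    doc = SyntenyDocument(elements=entries, links=links)
    return doc.model_dump(mode="json")
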