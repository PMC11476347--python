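"""Direct-repeat (attL/attR) detection and classification for PRS elements.

An integrated phage-related sequence (PRS) is flanked by two short direct
repeats, the recombinant attL/attR sites produced by attP x attB
site-specific recombination.  The copy coinciding with the host tRNA gene is
attR (regardless of which side of the element it falls on); the distal copy
is attL.  The attachment is classified by where attR matches the gene:
its 3' end (gene preserved), its 5' end (gene preserved) or its interior
(gene disrupted, anchor "central").  All interval logic is circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import AmbiguityError, PrsmapError
from .io import Chromosome, Feature
from .trna import TRNACatalog, TRNAGene

PRS_CLASSES = ("GI", "int-Ph", "inc-Ph", "q-Ph")
PROPHAGE_CLASSES = ("int-Ph", "inc-Ph", "q-Ph")

ANCHOR_THREE = "three_prime"
ANCHOR_FIVE = "five_prime"
ANCHOR_CENTRAL = "central"
ANCHOR_NONE = "none"


@dataclass(frozen=True)
class PRSElement:
    """An integrated element interval with its class annotation."""

    feature: Feature

    @property
    def id(self) -> str:
        return self.feature.attributes.get("ID", f"{self.feature.chrom_id}:{self.feature.start_bp}")

    @property
    def prs_class(self) -> str:
        cls = self.feature.attributes.get("prs_class", "")
        if cls not in PRS_CLASSES:
            raise PrsmapError(f"unknown PRS class {cls!r} for element {self.id}")
        return cls

    @property
    def integrase_origin(self) -> str:
        return self.feature.attributes.get("integrase_origin", "unknown")

    @property
    def start_bp(self) -> int:
        return self.feature.start_bp

    @property
    def end_bp(self) -> int:
        return self.feature.end_bp

    def length_bp(self, chrom_length: int) -> int:
        return (self.end_bp - self.start_bp) % chrom_length + 1


@dataclass(frozen=True)
class AttSite:
    sequence: str
    start_bp: int
    end_bp: int
    role: str  # attL | attR
    in_gene_bp: int = 0
    spacer_bp: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AttPair:
    """Candidate direct-repeat pair flanking an element (left/right copies)."""

    element: PRSElement
    left: AttSite
    right: AttSite
    mismatches: int

    @property
    def length(self) -> int:
        return len(self.left.sequence)


@dataclass(frozen=True)
class IntegrationCall:
    element: PRSElement
    host_gene: TRNAGene | None
    att_l: AttSite | None
    att_r: AttSite | None
    anchor_class: str
    gene_disrupted: bool
    nested_children: tuple[tuple[int, int], ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# circular interval helpers (1-based inclusive; start > end means wrap)


def _span(s: int, e: int, L: int) -> int:
    return (e - s) % L + 1


def circ_dist(a: int, b: int, L: int) -> int:
    """Shortest circular distance between two 1-based positions."""
    d = (a - b) % L
    return min(d, L - d)


def circ_overlap(s1: int, e1: int, s2: int, e2: int, L: int):
    """Overlap of two circular intervals.

    Returns (overlap_bp, o1, o2) where [o1, o2] is the overlapping stretch in
    1-based local coordinates of interval 1 (the earliest such stretch).
    """
    n1, n2 = _span(s1, e1, L), _span(s2, e2, L)
    d = (s2 - s1) % L  # 0-based start of interval 2 in interval-1 frame
    pieces = [(d, d + n2)]
    if d + n2 > L:
        pieces = [(d, L), (0, d + n2 - L)]
    best = (0, 0, 0)
    for a, b in pieces:
        lo, hi = max(a, 0), min(b, n1)
        if hi > lo and hi - lo > best[0]:
            best = (hi - lo, lo + 1, hi)
    return best


# ---------------------------------------------------------------------------
# repeat detection


def _maximal_matches(wa: str, wb: str, k: int, max_mismatch_frac: float):
    """Maximal ungapped matches between two windows from exact k-mer seeds.

    Extension proceeds through mismatches while the running mismatch fraction
    stays within budget; matches always begin and end on identical columns.
    Yields (ia, ib, length, mismatches) with 0-based starts.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(wb) - k + 1):
        index.setdefault(wb[j : j + k], []).append(j)
    seen: set[tuple[int, int, int, int]] = set()
    diag_cover: dict[int, int] = {}
    for i in range(len(wa) - k + 1):
        for j in index.get(wa[i : i + k], ()):
            d = i - j
            if diag_cover.get(d, -1) >= i:
                continue

            def _extend(side: int, other_len: int, mm_before: int, ia: int, ib: int, ln: int):
                # side +1: extend right; side -1: extend left
                mm = 0
                best_ext = 0
                best_mm = 0
                t = 1
                while True:
                    if side > 0:
                        pa, pb = ia + ln - 1 + t, ib + ln - 1 + t
                        if pa >= len(wa) or pb >= len(wb):
                            break
                    else:
                        pa, pb = ia - t, ib - t
                        if pa < 0 or pb < 0:
                            break
                    if wa[pa] == wb[pb]:
                        if (mm + mm_before) <= max_mismatch_frac * (ln + t):
                            best_ext, best_mm = t, mm
                    else:
                        mm += 1
                        if mm + mm_before > max_mismatch_frac * (ln + t) + 2:
                            break
                    t += 1
                return best_ext, best_mm

            ia, ib, ln, mm_total = i, j, k, 0
            ext, mm = _extend(+1, 0, 0, ia, ib, ln)
            ln += ext
            mm_total += mm
            ext, mm = _extend(-1, 0, mm_total, ia, ib, ln)
            ia -= ext
            ib -= ext
            ln += ext
            mm_total += mm
            key = (ia, ib, ln, mm_total)
            diag_cover[d] = ia + ln - 1
            if key in seen:
                continue
            seen.add(key)
            yield ia, ib, ln, mm_total


def find_flanking_repeats(
    chrom: Chromosome,
    element: PRSElement,
    min_len: int = 12,
    max_len: int = 98,
    search_window_bp: int = 150,
    max_mismatch_frac: float = 0.05,
) -> list[AttPair]:
    """Direct-repeat pairs flanking an element, longest first.

    One copy must end within ``search_window_bp`` of the element's left
    boundary and the other start within the window of its right boundary;
    copies are in the same orientation, ``min_len``..``max_len`` long, with at
    most ``max_mismatch_frac`` of their columns mismatched.
    """
    L = chrom.length_bp
    s, e = element.start_bp, element.end_bp
    w = search_window_bp
    lw_start = (s - 1 - w - max_len) % L + 1
    lw_end = (s - 1 + w - 1) % L + 1  # left copy must end before/at s-1+w
    rw_start = (e - 1 - w + 1) % L + 1
    rw_end = (e - 1 + w + max_len) % L + 1
    wa = chrom.fetch(lw_start, lw_end)
    wb = chrom.fetch(rw_start, rw_end)
    pairs: list[AttPair] = []
    seen: set[tuple[int, int]] = set()
    for ia, ib, ln, mm in _maximal_matches(wa, wb, min_len, max_mismatch_frac):
        if not (min_len <= ln <= max_len):
            continue
        l_start = (lw_start - 1 + ia) % L + 1
        l_end = (l_start - 1 + ln - 1) % L + 1
        r_start = (rw_start - 1 + ib) % L + 1
        r_end = (r_start - 1 + ln - 1) % L + 1
        # enforce the boundary-window rule in absolute coordinates
        if circ_dist(l_end, s, L) > w or circ_dist(r_start, e, L) > w:
            continue
        if (l_start, r_start) in seen:
            continue
        seen.add((l_start, r_start))
        pairs.append(
            AttPair(
                element=element,
                left=AttSite(chrom.fetch(l_start, l_end), l_start, l_end, "attL"),
                right=AttSite(chrom.fetch(r_start, r_end), r_start, r_end, "attR"),
                mismatches=mm,
            )
        )
    # longest first, then closest to the annotated boundaries
    def _boundary_dist(p: AttPair) -> int:
        dl = min(_span(p.left.end_bp, s, L), _span(s, p.left.end_bp, L)) - 1
        dr = min(_span(p.right.start_bp, e, L), _span(e, p.right.start_bp, L)) - 1
        return dl + dr

    pairs.sort(key=lambda p: (-p.length, _boundary_dist(p), p.left.start_bp))
    return pairs


# ---------------------------------------------------------------------------
# classification


def _gene_local(gene: TRNAGene, a1: int, a2: int) -> tuple[int, int]:
    """Map an absolute overlap interval into gene-local 5'->3' coordinates."""
    if gene.strand == "+":
        return a1 - gene.start_bp + 1, a2 - gene.start_bp + 1
    return gene.end_bp - a2 + 1, gene.end_bp - a1 + 1


def classify_attachment(
    pair: AttPair,
    catalog: TRNACatalog,
    chrom: Chromosome,
    central_core_frac: float = 0.4,
) -> IntegrationCall:
    """Resolve a repeat pair into an attL/attR integration call.

    The copy overlapping a tRNA gene becomes attR; anchoring is three_prime /
    five_prime when attR reaches the corresponding strand-aware terminal
    segment of the gene, central (gene disrupted) when the element itself lies
    inside the gene locus or attR matches only the gene interior.
    """
    L = chrom.length_bp
    el = pair.element

    def _overlapping_genes(site: AttSite):
        out = []
        for g in catalog.genes:
            ov, o1, o2 = circ_overlap(
                site.start_bp, site.end_bp, g.start_bp, g.end_bp, L
            )
            if ov > 0:
                out.append((g, ov))
        return out

    left_hits = _overlapping_genes(pair.left)
    right_hits = _overlapping_genes(pair.right)

    def _distinct(hits):
        return {id(g.feature) for g, _ in hits}

    if not left_hits and not right_hits:
        att_l = replace(pair.left, role="attL", in_gene_bp=0, spacer_bp=pair.length)
        att_r = replace(pair.right, role="attR", in_gene_bp=0, spacer_bp=pair.length)
        return IntegrationCall(el, None, att_l, att_r, ANCHOR_NONE, False)

    # the gene-side copy is attR
    if left_hits and right_hits and _distinct(left_hits) == _distinct(right_hits):
        # both copies fall within the same (disrupted) gene locus
        gene = left_hits[0][0]
        att_r_site, att_l_site = pair.left, pair.right
        g1, _ = _gene_local(gene, *_abs_overlap(pair.left, gene, L))
        g2, _ = _gene_local(gene, *_abs_overlap(pair.right, gene, L))
        if g2 < g1:
            att_r_site, att_l_site = pair.right, pair.left
    elif left_hits and (len(left_hits) >= len(right_hits) or not right_hits):
        att_r_site, att_l_site = pair.left, pair.right
    else:
        att_r_site, att_l_site = pair.right, pair.left
    hits = _overlapping_genes(att_r_site)
    if len(_distinct(hits)) > 1:
        raise AmbiguityError(
            f"attR of element {el.id} overlaps {len(hits)} tRNA genes"
        )
    gene = max(hits, key=lambda h: h[1])[0]

    ov, a1, a2 = _abs_overlap_full(att_r_site, gene, L)
    in_gene = ov
    spacer = pair.length - in_gene
    o1, o2 = _gene_local(gene, a1, a2)
    G = _span(gene.start_bp, gene.end_bp, L)

    # element contained in the gene locus => the gene was disrupted
    el_inside = (
        circ_overlap(el.start_bp, el.end_bp, gene.start_bp, gene.end_bp, L)[0]
        == el.length_bp(L)
    )
    if el_inside:
        anchor = ANCHOR_CENTRAL
    elif o2 >= G:
        anchor = ANCHOR_THREE
    elif o1 <= 1:
        anchor = ANCHOR_FIVE
    else:
        lo = central_core_frac / 2.0  # central core: middle 40% by default
        if o1 > (0.5 - lo) * G and o2 < (0.5 + lo) * G:
            anchor = ANCHOR_CENTRAL
        else:
            anchor = ANCHOR_THREE if (G - o2) <= (o1 - 1) else ANCHOR_FIVE

    att_r = replace(att_r_site, role="attR", in_gene_bp=in_gene, spacer_bp=spacer)
    att_l = replace(att_l_site, role="attL", in_gene_bp=0, spacer_bp=pair.length)
    return IntegrationCall(
        element=el,
        host_gene=gene,
        att_l=att_l,
        att_r=att_r,
        anchor_class=anchor,
        gene_disrupted=(anchor == ANCHOR_CENTRAL),
    )


def _abs_overlap(site: AttSite, gene: TRNAGene, L: int) -> tuple[int, int]:
    ov, o1, o2 = circ_overlap(site.start_bp, site.end_bp, gene.start_bp, gene.end_bp, L)
    a1 = (site.start_bp - 1 + o1 - 1) % L + 1
    a2 = (site.start_bp - 1 + o2 - 1) % L + 1
    return a1, a2


def _abs_overlap_full(site: AttSite, gene: TRNAGene, L: int) -> tuple[int, int, int]:
    ov, o1, o2 = circ_overlap(site.start_bp, site.end_bp, gene.start_bp, gene.end_bp, L)
    a1 = (site.start_bp - 1 + o1 - 1) % L + 1
    a2 = (site.start_bp - 1 + o2 - 1) % L + 1
    return ov, a1, a2


# ---------------------------------------------------------------------------
# nested integrations


def detect_nested(
    chrom: Chromosome,
    call: IntegrationCall,
    min_internal_identity: float = 0.90,
    min_len: int = 12,
) -> IntegrationCall:
    """Scan the element interior for near-copies of the flanking repeat.

    A match counts as an internal copy only when its agreeing columns cover at
    least ``min_internal_identity`` of the full flank length (a short chance
    match to a sub-segment of the flank is not a copy of the repeat).  Each
    internal copy splits the element into sequential sub-elements whose
    (offset_bp, length_bp) are recorded in ``nested_children``.
    """
    if call.att_l is None or call.att_r is None:
        return call
    L = chrom.length_bp
    el = call.element
    interior = chrom.fetch(el.start_bp, el.end_bp)
    flank = call.att_l.sequence
    matches = []
    for ia, ib, ln, mm in _maximal_matches(
        flank, interior, min_len, 1.0 - min_internal_identity
    ):
        if ln < min_len:
            continue
        if (ln - mm) / len(flank) < min_internal_identity:
            continue
        matches.append((ib, ib + ln - 1))
    if not matches:
        return call
    # merge overlapping matches, order along the element
    matches.sort()
    merged = [matches[0]]
    for s0, e0 in matches[1:]:
        if s0 <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(e0, merged[-1][1]))
        else:
            merged.append((s0, e0))
    children = []
    prev = 0
    for s0, e0 in merged:
        if s0 - prev > 0:
            children.append((prev, s0 - prev))
        prev = e0 + 1
    n = len(interior)
    if n - prev > 0:
        children.append((prev, n - prev))
    return replace(call, nested_children=tuple(children))


# ---------------------------------------------------------------------------
# in-silico excision


def excise(
    chrom: Chromosome,
    call: IntegrationCall,
    max_mismatch_frac: float = 0.0,
) -> Chromosome:
    """Remove the element plus exactly one repeat copy (validation round trip).

    The returned chromosome carries a single att copy at the junction; for a
    planted integration this reproduces the pre-integration genome.
    """
    if call.att_l is None or call.att_r is None:
        raise PrsmapError("call has no resolved att pair")
    a, b = call.att_l, call.att_r
    if len(a) != len(b):
        raise PrsmapError("att copies differ in length")
    mism = sum(1 for x, y in zip(a.sequence, b.sequence) if x != y)
    if mism > max_mismatch_frac * len(a):
        raise PrsmapError(f"att copies differ at {mism} positions")
    L = chrom.length_bp
    el = call.element
    # positional left copy ends just before the element start
    left, right = (a, b) if (a.end_bp % L) + 1 == el.start_bp else (b, a)
    if (left.end_bp % L) + 1 != el.start_bp or (el.end_bp % L) + 1 != right.start_bp:
        raise PrsmapError("att copies do not abut the element boundaries")
    s0, e0 = el.start_bp - 1, right.end_bp - 1  # 0-based removal [s0, e0]
    seq = chrom.sequence
    if s0 <= e0:
        new_seq = seq[:s0] + seq[e0 + 1 :]
    else:
        # removal spans the origin; re-linearize at the junction
        new_seq = seq[e0 + 1 : s0]
    return replace(chrom, sequence=new_seq, origin_offset_bp=0)
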