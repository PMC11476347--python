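"""Local alignment primitives for synteny-block extraction.

Scoring follows the package default throughout: match +1, mismatch -2, and
affine gaps costing ``gap_open + gap_extend * length`` (-5 - 2L).  For short
sequence pairs an exact Smith-Waterman (Gotoh) dynamic program with traceback
is used; for long pairs, exact k-mer seeds are extended with an ungapped
x-drop pass and colinear high-scoring segments are chained, bridging short
gaps with an exact global dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2

#: pairs with product of lengths at or below this use the exact DP directly
EXACT_DP_LIMIT = 400_000
#: longest inter-segment gap bridged exactly during chaining
MAX_BRIDGE = 200

_NEG = -(10**9)


@dataclass(frozen=True)
class LocalHit:
    """A local alignment block between two sequences (1-based inclusive)."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    columns: int
    matches: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def smith_waterman(a: str, b: str) -> LocalHit | None:
    """Exact affine-gap local alignment (Gotoh) with traceback.

    Returns None when no positive-scoring block exists.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return None
    open_ext = GAP_OPEN + GAP_EXTEND
    H_prev = [0] * (m + 1)
    F_col = [_NEG] * (m + 1)
    tb = [bytearray(m + 1) for _ in range(n + 1)]  # 0 stop, 1 diag, 2 up, 3 left
    tb_e = [bytearray(m + 1) for _ in range(n + 1)]  # 1: gap-in-a extends left
    tb_f = [bytearray(m + 1) for _ in range(n + 1)]  # 1: gap-in-b extends up
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        H_row = [0] * (m + 1)
        E = _NEG
        tbi, tbei, tbfi = tb[i], tb_e[i], tb_f[i]
        Hp = H_prev
        for j in range(1, m + 1):
            e_open = H_row[j - 1] + open_ext
            e_ext = E + GAP_EXTEND
            if e_ext > e_open:
                E = e_ext
                tbei[j] = 1
            else:
                E = e_open
            f_open = Hp[j] + open_ext
            f_ext = F_col[j] + GAP_EXTEND
            if f_ext > f_open:
                F_col[j] = f_ext
                tbfi[j] = 1
            else:
                F_col[j] = f_open
            h = Hp[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            ptr = 1
            if E > h:
                h, ptr = E, 3
            if F_col[j] > h:
                h, ptr = F_col[j], 2
            if h <= 0:
                h, ptr = 0, 0
            H_row[j] = h
            tbi[j] = ptr
            if h > best:
                best, bi, bj = h, i, j
        H_prev = H_row
    if best <= 0:
        return None
    # traceback
    i, j = bi, bj
    cols = matches = 0
    while True:
        p = tb[i][j]
        if p == 0:
            break
        if p == 1:
            cols += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == 3:  # gap in a, consume b
            while True:
                cols += 1
                ext = tb_e[i][j]
                j -= 1
                if not ext:
                    break
        else:  # gap in b, consume a
            while True:
                cols += 1
                ext = tb_f[i][j]
                i -= 1
                if not ext:
                    break
    return LocalHit(
        score=best,
        a_start=i + 1,
        a_end=bi,
        b_start=j + 1,
        b_end=bj,
        columns=cols,
        matches=matches,
    )


def needleman_wunsch(a: str, b: str) -> tuple[int, int, int]:
    """Exact global affine alignment; returns (score, columns, matches).

    Used to bridge short gaps between chained local segments.
    """
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0, 0, 0
    if n == 0 or m == 0:
        g = max(n, m)
        return GAP_OPEN + GAP_EXTEND * g, g, 0
    open_ext = GAP_OPEN + GAP_EXTEND
    H = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Ew = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Fw = [[_NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        Ew[0][j] = (Ew[0][j - 1] + GAP_EXTEND) if j > 1 else (open_ext)
        H[0][j] = Ew[0][j]
    for i in range(1, n + 1):
        Fw[i][0] = (Fw[i - 1][0] + GAP_EXTEND) if i > 1 else (open_ext)
        H[i][0] = Fw[i][0]
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ew[i][j] = max(H[i][j - 1] + open_ext, Ew[i][j - 1] + GAP_EXTEND)
            Fw[i][j] = max(H[i - 1][j] + open_ext, Fw[i - 1][j] + GAP_EXTEND)
            diag = H[i - 1][j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            H[i][j] = max(diag, Ew[i][j], Fw[i][j])
    # traceback for columns/matches
    i, j = n, m
    cols = matches = 0
    state = "M"
    while i > 0 or j > 0:
        if state == "M":
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + (
                MATCH if a[i - 1] == b[j - 1] else MISMATCH
            ):
                cols += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif j > 0 and (i == 0 or H[i][j] == Ew[i][j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if Ew[i][j] == Ew[i][j - 1] + GAP_EXTEND and j > 1:
                j -= 1
            else:
                j -= 1
                state = "M"
        else:
            cols += 1
            if Fw[i][j] == Fw[i - 1][j] + GAP_EXTEND and i > 1:
                i -= 1
            else:
                i -= 1
                state = "M"
    return H[n][m], cols, matches


@dataclass
class _HSP:
    score: int
    a_start: int  # 0-based inclusive
    a_end: int  # 0-based inclusive
    b_start: int
    b_end: int
    matches: int


def _ungapped_hsps(a: str, b: str, k: int, x_drop: int) -> list[_HSP]:
    """Exact k-mer seeds extended without gaps under an x-drop rule."""
    n, m = len(a), len(b)
    if n < k or m < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(m - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    diag_cover: dict[int, int] = {}
    hsps: list[_HSP] = []
    for i in range(n - k + 1):
        positions = index.get(a[i : i + k])
        if not positions:
            continue
        for j in positions:
            d = i - j
            if diag_cover.get(d, -1) >= i:
                continue
            # extend right from the seed end
            s = bestr = 0
            mr = best_mr = 0
            off = 0
            while i + k + off < n and j + k + off < m:
                if a[i + k + off] == b[j + k + off]:
                    s += MATCH
                    mr += 1
                else:
                    s += MISMATCH
                if s > bestr:
                    bestr, best_mr = s, mr
                    endr = off
                if bestr - s > x_drop:
                    break
                off += 1
            endr = -1 if bestr == 0 else endr
            # extend left from the seed start
            s = bestl = 0
            ml = best_ml = 0
            off = 1
            while i - off >= 0 and j - off >= 0:
                if a[i - off] == b[j - off]:
                    s += MATCH
                    ml += 1
                else:
                    s += MISMATCH
                if s > bestl:
                    bestl, best_ml = s, ml
                    endl = off
                if bestl - s > x_drop:
                    break
                off += 1
            endl = 0 if bestl == 0 else endl
            a_s, a_e = i - endl, i + k + endr
            hsps.append(
                _HSP(
                    score=k * MATCH + bestr + bestl,
                    a_start=a_s,
                    a_end=a_e,
                    b_start=j - endl,
                    b_end=j + k + endr,
                    matches=k + best_mr + best_ml,
                )
            )
            diag_cover[d] = a_e
    return hsps


def _chain_best(a: str, b: str, hsps: list[_HSP]) -> LocalHit | None:
    """Greedy chain around the top-scoring segment, bridging short gaps."""
    if not hsps:
        return None
    hsps = sorted(hsps, key=lambda h: (-h.score, h.a_start, h.b_start))
    anchor = hsps[0]
    chain = [anchor]
    # candidates strictly colinear with the anchor, bridgeable gaps only
    rest = sorted(hsps[1:], key=lambda h: h.a_start)
    # extend to the right of the anchor
    cur = anchor
    for h in rest:
        ga, gb = h.a_start - cur.a_end - 1, h.b_start - cur.b_end - 1
        if 0 <= ga <= MAX_BRIDGE and 0 <= gb <= MAX_BRIDGE:
            chain.append(h)
            cur = h
    # extend to the left of the anchor
    cur = anchor
    for h in reversed(rest):
        ga, gb = cur.a_start - h.a_end - 1, cur.b_start - h.b_end - 1
        if 0 <= ga <= MAX_BRIDGE and 0 <= gb <= MAX_BRIDGE:
            chain.insert(0, h)
            cur = h
    chain.sort(key=lambda h: h.a_start)
    score = chain[0].score
    cols = chain[0].a_end - chain[0].a_start + 1
    matches = chain[0].matches
    for prev, nxt in zip(chain[:-1], chain[1:]):
        bridge_a = a[prev.a_end + 1 : nxt.a_start]
        bridge_b = b[prev.b_end + 1 : nxt.b_start]
        # canonical argument order keeps columns/matches symmetric in (a, b)
        if (len(bridge_a), bridge_a) <= (len(bridge_b), bridge_b):
            s, c, mt = needleman_wunsch(bridge_a, bridge_b)
        else:
            s, c, mt = needleman_wunsch(bridge_b, bridge_a)
        score += s + nxt.score
        cols += c + (nxt.a_end - nxt.a_start + 1)
        matches += mt + nxt.matches
    first, last = chain[0], chain[-1]
    if len(chain) > 1 and score < anchor.score:
        # chaining did not pay off; fall back to the anchor alone
        return LocalHit(
            score=anchor.score,
            a_start=anchor.a_start + 1,
            a_end=anchor.a_end + 1,
            b_start=anchor.b_start + 1,
            b_end=anchor.b_end + 1,
            columns=anchor.a_end - anchor.a_start + 1,
            matches=anchor.matches,
        )
    return LocalHit(
        score=score,
        a_start=first.a_start + 1,
        a_end=last.a_end + 1,
        b_start=first.b_start + 1,
        b_end=last.b_end + 1,
        columns=cols,
        matches=matches,
    )


def best_local_hit(a: str, b: str, k: int = 15, x_drop: int = 50) -> LocalHit | None:
    """Highest-scoring local block on the given orientation of a vs b.

    Exact DP for small pairs; seed-and-extend with chaining otherwise.
    """
    if len(a) * len(b) <= EXACT_DP_LIMIT:
        return smith_waterman(a, b)
    return _chain_best(a, b, _ungapped_hsps(a, b, k, x_drop))
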