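"""Replichore geometry: oriC anchoring, degree coordinates, terC calling.

The chromosome is anchored so that the first nucleotide of the oriC region is
position 1 = 0 degrees; the coordinate in degrees of a bp position is
``C_deg = C_bp * 360 / L_bp``, reduced mod 360.  The replication terminus is
called from two strand-asymmetry signals computed in windows of 0.1% of the
chromosome length: the (G-C)/(G+C) skew and the strand difference in
occurrences of an octamer motif (GGGCAGGG by default) that is maximally
asymmetric around terC in Alphaproteobacteria.  Sign convention: with oriC at
0 degrees and leading strands G-rich (and forward-motif-rich), the cumulative
profile attains its global maximum near terC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
import numpy as np

from .errors import CoordinateError, LowConfidenceError, NotFoundError
from .io import Chromosome, Feature, revcomp

DEFAULT_OCTAMER = "GGGCAGGG"


@dataclass(frozen=True)
class OriginAnchor:
    """Best match of the oriC probe on a chromosome (plus-strand coords)."""

    chrom_id: str
    start_bp: int
    probe_identity_pct: float
    probe_coverage_pct: float
    strand: str = "+"


@dataclass(frozen=True)
class SkewProfile:
    """Windowed strand-asymmetry profile over a circular chromosome.

    ``positions_bp`` are the 1-based starts of the windows; the last window
    wraps past the origin so the windows tile the circle.  ``cumulative`` is
    the running sum of ``window_values``.
    """

    window_bp: int
    step_bp: int
    positions_bp: np.ndarray
    window_values: np.ndarray
    cumulative: np.ndarray
    length_bp: int


@dataclass(frozen=True)
class TerCCall:
    position_bp: int
    position_deg: float
    method: str  # octamer | gcskew | consensus
    agreement_deg: float


def bp_to_degrees(pos_bp: int, length_bp: int) -> float:
    """Degree coordinate of a bp position: 360 * C_bp / L_bp, reduced mod 360."""
    if not 1 <= pos_bp <= length_bp:
        raise CoordinateError(f"position {pos_bp} outside 1..{length_bp}")
    return (pos_bp * 360.0 / length_bp) % 360.0


def degrees_distance(a: float, b: float) -> float:
    """Shortest angular distance between two degree coordinates."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def locate_oric(
    chrom: Chromosome,
    probe: str,
    min_identity_pct: float = 90.0,
    min_coverage_pct: float = 80.0,
) -> OriginAnchor:
    """Best local match of the oriC probe on either strand.

    The probe is aligned semi-globally (whole probe, anywhere on the
    chromosome, circularly) with edlib; the anchor is the first bp of the
    matched region on the plus strand.
    """
    if len(probe) < 50:
        raise ValueError("oriC probe must be at least 50 bp")
    probe = probe.upper()
    L = chrom.length_bp
    # allow matches across the origin of the linear representation
    target = chrom.sequence + chrom.sequence[: len(probe) - 1] if chrom.circular else chrom.sequence
    k = int(len(probe) * (1 - min_identity_pct / 100.0) * 2) + 8
    best = None
    for strand, query in (("+", probe), ("-", revcomp(probe))):
        res = edlib.align(query, target, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[1]["editDistance"]:
            best = (strand, res)
    if best is None:
        raise NotFoundError(f"{chrom.id}: oriC probe not found")
    strand, res = best
    start0, end0 = res["locations"][0]
    aln_len = end0 - start0 + 1
    identity = 100.0 * max(0, len(probe) - res["editDistance"]) / max(aln_len, len(probe))
    coverage = 100.0  # semi-global alignment always covers the whole probe
    if identity < min_identity_pct or coverage < min_coverage_pct:
        raise NotFoundError(
            f"{chrom.id}: best oriC probe match below thresholds "
            f"(identity {identity:.1f}%, coverage {coverage:.1f}%)"
        )
    return OriginAnchor(
        chrom_id=chrom.id,
        start_bp=start0 % L + 1,
        probe_identity_pct=identity,
        probe_coverage_pct=coverage,
        strand=strand,
    )


def rotate_to_origin(
    chrom: Chromosome,
    anchor: OriginAnchor,
    features: list[Feature] | None = None,
):
    """Circularly rotate the chromosome so the anchor starts at position 1.

    Features, when given, are re-coordinated by the same rotation and the
    rotated ``(Chromosome, features)`` pair is returned.
    """
    if anchor.chrom_id != chrom.id:
        raise CoordinateError(
            f"anchor is for {anchor.chrom_id}, chromosome is {chrom.id}"
        )
    L = chrom.length_bp
    offset = anchor.start_bp - 1
    seq = chrom.sequence[offset:] + chrom.sequence[:offset]
    rotated = replace(chrom, sequence=seq, origin_offset_bp=offset)
    if features is None:
        return rotated
    shifted = [f.shifted(-offset, L) for f in features]
    return rotated, shifted


def _window_grid(length_bp: int, window_bp: int | None, step_bp: int | None):
    """Window/step = 0.1% of the chromosome length (rounded, floor 100 bp)."""
    if window_bp is None:
        window_bp = max(100, round(0.001 * length_bp))
    if step_bp is None:
        step_bp = window_bp
    n = -(-length_bp // step_bp)  # ceil
    starts = np.arange(n) * step_bp  # 0-based starts
    return window_bp, step_bp, starts


def gc_skew_profile(
    chrom: Chromosome, window_bp: int | None = None, step_bp: int | None = None
) -> SkewProfile:
    """Per-window (G-C)/(G+C) on the plus strand; windows tile the circle."""
    window_bp, step_bp, starts = _window_grid(chrom.length_bp, window_bp, step_bp)
    L = chrom.length_bp
    arr = np.frombuffer((chrom.sequence + chrom.sequence[:window_bp]).encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    ends = starts + window_bp
    g = cg[ends] - cg[starts]
    c = cc[ends] - cc[starts]
    denom = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return SkewProfile(
        window_bp=window_bp,
        step_bp=step_bp,
        positions_bp=starts + 1,
        window_values=vals.astype(float),
        cumulative=np.cumsum(vals, dtype=float),
        length_bp=L,
    )


def _motif_starts(seq: str, motif: str, circular: bool) -> np.ndarray:
    """0-based start positions of (possibly overlapping) motif occurrences."""
    hay = seq + seq[: len(motif) - 1] if circular else seq
    out = []
    i = hay.find(motif)
    while 0 <= i < len(seq):
        out.append(i)
        i = hay.find(motif, i + 1)
    return np.asarray(out, dtype=np.int64)


def octamer_profile(
    chrom: Chromosome,
    motif: str = DEFAULT_OCTAMER,
    window_bp: int | None = None,
    step_bp: int | None = None,
) -> SkewProfile:
    """Per-window (forward motif count) - (reverse-complement motif count)."""
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    window_bp, step_bp, starts = _window_grid(chrom.length_bp, window_bp, step_bp)
    fwd = _motif_starts(chrom.sequence, motif, chrom.circular)
    rev = _motif_starts(chrom.sequence, revcomp(motif), chrom.circular)
    n = len(starts)
    # windows tile the circle; assign each occurrence to the window of its start
    idx_f = np.minimum(fwd // step_bp, n - 1)
    idx_r = np.minimum(rev // step_bp, n - 1)
    vals = np.bincount(idx_f, minlength=n).astype(float) - np.bincount(
        idx_r, minlength=n
    ).astype(float)
    return SkewProfile(
        window_bp=window_bp,
        step_bp=step_bp,
        positions_bp=starts + 1,
        window_values=vals,
        cumulative=np.cumsum(vals, dtype=float),
        length_bp=chrom.length_bp,
    )


def _extremum_position(profile: SkewProfile, noise_sd: float = 3.0) -> int:
    """Position (bp) of the global maximum of the cumulative profile.

    The extremum must exceed the noise floor of a random walk whose steps have
    the observed window standard deviation: range(cumulative) must exceed
    ``noise_sd * sd(window values) * sqrt(n windows)``.
    """
    c = profile.cumulative
    sd = float(np.std(profile.window_values))
    floor = noise_sd * sd * np.sqrt(len(c))
    if float(c.max() - c.min()) <= floor:
        raise LowConfidenceError(
            "cumulative profile extremum does not exceed the noise floor"
        )
    # the cumulative curve may plateau between the last forward-biased and
    # first reverse-biased window; the sign switch lies mid-plateau
    k_first = int(np.argmax(c))
    k_last = k_first
    while k_last + 1 < len(c) and c[k_last + 1] >= c[k_first] - 1e-9:
        k_last += 1
    end_first = int(profile.positions_bp[k_first]) - 1 + profile.window_bp
    end_last = int(profile.positions_bp[k_last]) - 1 + profile.window_bp
    pos0 = (end_first + end_last) // 2
    return pos0 % profile.length_bp + 1


def call_terc(
    gc: SkewProfile, oct_profile: SkewProfile, chrom: Chromosome
) -> TerCCall:
    """Consensus terC call: octamer extremum (primary), GC skew as check."""
    L = chrom.length_bp
    oct_bp = _extremum_position(oct_profile)
    gc_bp = _extremum_position(gc)
    oct_deg = bp_to_degrees(oct_bp, L)
    gc_deg = bp_to_degrees(gc_bp, L)
    return TerCCall(
        position_bp=oct_bp,
        position_deg=oct_deg,
        method="consensus",
        agreement_deg=degrees_distance(oct_deg, gc_deg),
    )


def nucleotide_diversity(seqs: list[str]) -> float:
    """Nucleotide diversity pi: mean pairwise difference per compared site.

    Sequences must be aligned to equal length; columns with a gap in either
    member of a pair are excluded from that pair's comparison.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    arrs = [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs]
    gap = ord("-")
    total = 0.0
    pairs = 0
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            ok = (arrs[i] != gap) & (arrs[j] != gap)
            sites = int(ok.sum())
            if sites == 0:
                continue
            diffs = int(((arrs[i] != arrs[j]) & ok).sum())
            total += diffs / sites
            pairs += 1
    return total / pairs if pairs else 0.0
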