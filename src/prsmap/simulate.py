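"""Synthetic circular chromosomes with planted, fully-known ground truth.

The generator emulates the structure of an alphaproteobacterial chromosome at
desk scale (400 kb by default; all degree-based logic is length-invariant):

* an oriC probe planted verbatim at position 1 (0 degrees);
* a (G-C) composition bias of ``+skew_amplitude`` on [0, terc_deg) and the
  opposite sign beyond, so the cumulative GC skew peaks at terC;
* the octamer GGGCAGGG planted forward-only before terC and
  reverse-complement-only after it, at ``octamer_rate_per_kb``;
* 52 tRNA genes (76 bp canonical bodies, anticodon at offset 34) laid out in
  the reference ordinal order on both strands;
* PRS integrations flanked by direct repeats copied from tRNA gene ends,
  including nested insertions and gene-disrupting insertions that carry
  replacement tRNA genes.

Planted repeats are made maximal: six columns on each side of every repeat
copy are forced to mismatch, so the planted att pair is exactly the maximal
repeat the detector should report.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import PrsmapError
from .io import Chromosome, Feature, revcomp

TRNA_LEN = 76
ANTICODON_OFFSET = 34  # 0-based offset of the anticodon triplet in the body
_BOUNDARY_MISMATCH_COLS = 6

#: reference chromosomal tRNA layout: (isotype, anticodon, strand) in ordinal
#: order 001..052; 25 of the genes are integration sites, split 13/12 between
#: the strands, hot spots at ordinals 010 (Thr/GGT), 030 (Asn/GTT),
#: 039 (Lys/CTT)
REFERENCE_TRNA_LAYOUT: tuple[tuple[str, str, str], ...] = (
    ("Ile", "GAT", "+"),    # 001
    ("Ala", "TGC", "+"),    # 002
    ("fMet", "CAT", "+"),   # 003
    ("Ser", "GGA", "+"),    # 004 *
    ("Ala", "GGC", "-"),    # 005 *
    ("Leu", "CAG", "+"),    # 006 *
    ("Arg", "ACG", "-"),    # 007 *
    ("Thr", "CGT", "+"),    # 008 *
    ("Gly", "CCC", "+"),    # 009
    ("Thr", "GGT", "-"),    # 010 * hot spot
    ("Phe", "GAA", "+"),    # 011 *
    ("His", "GTG", "+"),    # 012
    ("Gln", "CTG", "-"),    # 013 *
    ("Gln", "TTG", "+"),    # 014
    ("Pro", "CGG", "+"),    # 015
    ("Ser", "GCT", "+"),    # 016 *
    ("Pro", "GGG", "-"),    # 017 *
    ("Val", "TAC", "+"),    # 018 *
    ("Asp", "GTC", "+"),    # 019
    ("Asp", "GTC", "+"),    # 020
    ("Thr", "TGT", "-"),    # 021 *
    ("Tyr", "GTA", "+"),    # 022
    ("Gly", "TCC", "+"),    # 023
    ("Trp", "CCA", "+"),    # 024
    ("Leu", "GAG", "+"),    # 025
    ("Leu", "TAG", "+"),    # 026 *
    ("Ser", "TGA", "-"),    # 027 *
    ("Ala", "CGC", "+"),    # 028
    ("Cys", "GCA", "+"),    # 029
    ("Asn", "GTT", "+"),    # 030 * hot spot
    ("Leu", "TAA", "-"),    # 031 *
    ("Lys", "TTT", "+"),    # 032 *
    ("Arg", "TCT", "+"),    # 033
    ("Pro", "TGG", "-"),    # 034 *
    ("Glu", "TTC", "+"),    # 035
    ("Glu", "TTC", "+"),    # 036
    ("Glu", "CTC", "+"),    # 037
    ("Glu", "TTC", "+"),    # 038
    ("Lys", "CTT", "+"),    # 039 * hot spot
    ("Ile", "CAT", "-"),    # 040 *
    ("fMet", "CAT", "+"),   # 041
    ("Ala", "TGC", "+"),    # 042
    ("Ile", "GAT", "+"),    # 043
    ("Leu", "CAA", "+"),    # 044
    ("Met", "CAT", "+"),    # 045 *
    ("Val", "GAC", "-"),    # 046 *
    ("fMet", "CAT", "+"),   # 047 *
    ("Ala", "TGC", "+"),    # 048
    ("Ile", "GAT", "+"),    # 049
    ("Arg", "CCT", "-"),    # 050 *
    ("Ser", "CGA", "+"),    # 051 *
    ("Gly", "GCC", "-"),    # 052
)

HOT_SPOT_ORDINALS = (10, 30, 39)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FLIP = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}


def _fixed_probe(length: int = 477) -> str:
    rng = np.random.default_rng(zlib.crc32(b"oriC-probe"))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


DEFAULT_ORIC_PROBE = _fixed_probe()


def trna_body(isotype: str, anticodon: str) -> str:
    """Deterministic canonical 76 bp gene body for an isotype/anticodon."""
    seed = zlib.crc32(f"{isotype}:{anticodon}".encode())
    rng = np.random.default_rng(seed)
    body = list("ACGT"[i] for i in rng.integers(0, 4, size=TRNA_LEN))
    body[ANTICODON_OFFSET : ANTICODON_OFFSET + 3] = list(anticodon)
    return "".join(body)


def diverged_trna_body(isotype: str, anticodon: str, every: int = 5) -> str:
    """Gene body with substitutions every ``every`` bp (anticodon preserved).

    Emulates a phage-borne tRNA gene of foreign origin (~80% identity to the
    chromosomal counterpart); the substitution spacing keeps identical runs
    short so the copy is never mistaken for an internal att repeat.
    """
    body = list(trna_body(isotype, anticodon))
    for i in range(0, TRNA_LEN, every):
        if ANTICODON_OFFSET <= i < ANTICODON_OFFSET + 3:
            continue
        body[i] = _FLIP[body[i]]
    return "".join(body)


@dataclass(frozen=True)
class IntegrationSpec:
    """A planted integration event at a host tRNA gene."""

    host_ordinal: int
    anchor: str  # three_prime | five_prime | central
    att_in_gene_bp: int
    att_spacer_bp: int
    payload_len_bp: int
    prs_class: str = "int-Ph"
    integrase_origin: str = "Azospirillum phage Cd"
    carried_trnas: tuple[tuple[str, str], ...] = ()
    nested: tuple[int, int] | None = None  # (inner_len_bp, inner_att_len_bp)
    has_phage_fragments: bool = False

    def __post_init__(self) -> None:
        total = self.att_in_gene_bp + self.att_spacer_bp
        if not 12 <= total <= 98:
            raise PrsmapError(f"att length {total} outside 12..98")
        if self.payload_len_bp < 1000:
            raise PrsmapError("payload must be at least 1000 bp")
        if self.anchor == "central" and self.att_spacer_bp != 0:
            raise PrsmapError("central anchors have no intergenic spacer")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    length_bp: int = 400_000
    gc_frac: float = 0.62
    oric_probe: str | None = None
    terc_deg: float = 170.0
    skew_amplitude: float = 0.04
    octamer_rate_per_kb: float = 2.0
    trna_layout: tuple[tuple[str, str, str], ...] = REFERENCE_TRNA_LAYOUT
    integrations: tuple[IntegrationSpec, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.terc_deg < 360:
            raise PrsmapError("terc_deg must be in (0, 360)")


@dataclass
class PlantedIntegration:
    """Exact coordinates of one planted integration (updated as truth shifts)."""

    element_id: str
    spec: IntegrationSpec
    element_start_bp: int
    element_end_bp: int
    att_left: tuple[int, int]
    att_right: tuple[int, int]
    att_sequence: str
    host_ordinal: int
    gene_disrupted: bool
    nested_children: tuple[tuple[int, int], ...] = ()
    carried_trna_features: list[Feature] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated genome (all coordinates 1-based)."""

    chrom_id: str
    seed: int
    oric_bp: int
    terc_bp: int
    probe: str
    gc_frac: float
    trna_features: list[Feature]
    integrations: list[PlantedIntegration] = field(default_factory=list)
    pre_integration_sequence: str = ""
    rng: np.random.Generator | None = None

    def element_features(self) -> list[Feature]:
        feats = []
        for pl in self.integrations:
            attrs = {
                "ID": pl.element_id,
                "prs_class": pl.spec.prs_class,
                "integrase_origin": pl.spec.integrase_origin,
                "has_phage_fragments": str(pl.spec.has_phage_fragments).lower(),
            }
            feats.append(
                Feature(
                    chrom_id=self.chrom_id,
                    start_bp=pl.element_start_bp,
                    end_bp=pl.element_end_bp,
                    strand="+",
                    type="PRS",
                    attributes=attrs,
                )
            )
        return feats

    def all_features(self) -> list[Feature]:
        feats = list(self.trna_features) + self.element_features()
        for pl in self.integrations:
            feats.extend(pl.carried_trna_features)
        return feats

    def host_gene(self, ordinal: int) -> Feature:
        genes = sorted(self.trna_features, key=lambda f: f.start_bp)
        if not 1 <= ordinal <= len(genes):
            raise PrsmapError(f"no tRNA gene with ordinal {ordinal}")
        return genes[ordinal - 1]

    def _shift(self, insert_at0: int, ins_len: int, extend_spanning: bool = True):
        """Re-coordinate all truth features for an insertion of ins_len at
        0-based position insert_at0 (sequence index where insertion begins)."""

        def shift_feat(f: Feature) -> Feature:
            from dataclasses import replace as _r

            if f.start_bp - 1 >= insert_at0:
                return _r(f, start_bp=f.start_bp + ins_len, end_bp=f.end_bp + ins_len)
            if f.end_bp - 1 >= insert_at0 and extend_spanning:
                return _r(f, end_bp=f.end_bp + ins_len)
            return f

        def shift_pos(p: int) -> int:
            return p + ins_len if p - 1 >= insert_at0 else p

        self.trna_features = [shift_feat(f) for f in self.trna_features]
        for pl in self.integrations:
            pl.element_start_bp = shift_pos(pl.element_start_bp)
            pl.element_end_bp = shift_pos(pl.element_end_bp)
            pl.att_left = (shift_pos(pl.att_left[0]), shift_pos(pl.att_left[1]))
            pl.att_right = (shift_pos(pl.att_right[0]), shift_pos(pl.att_right[1]))
            pl.carried_trna_features = [shift_feat(f) for f in pl.carried_trna_features]
        if self.terc_bp - 1 >= insert_at0:
            self.terc_bp += ins_len


def _random_seq(rng: np.random.Generator, n: int, gc: float, skew: float = 0.0) -> str:
    pg = gc * (1 + skew) / 2
    pc = gc * (1 - skew) / 2
    pa = pt = (1 - gc) / 2
    idx = rng.choice(4, size=n, p=[pa, pc, pg, pt])
    return bytes(_BASES[idx]).decode()


def generate_chromosome(config: GeneratorConfig) -> tuple[Chromosome, SyntheticTruth]:
    """Build a synthetic chromosome and its ground truth (no integrations yet).

    Deterministic given ``config.seed``; integrations listed in the config are
    planted afterwards in order.
    """
    rng = np.random.default_rng(config.seed)
    L = config.length_bp
    terc_bp = int(round(L * config.terc_deg / 360.0))
    probe = (config.oric_probe or DEFAULT_ORIC_PROBE).upper()

    # background with opposite (G-C) bias on the two replichores
    left = _random_seq(rng, terc_bp, config.gc_frac, +config.skew_amplitude)
    right = _random_seq(rng, L - terc_bp, config.gc_frac, -config.skew_amplitude)
    seq = bytearray((left + right).encode())

    # octamer motif: forward copies before terC, reverse-complement after
    motif = b"GGGCAGGG"
    rc_motif = revcomp(motif.decode()).encode()
    n_left = int(round(config.octamer_rate_per_kb * terc_bp / 1000.0))
    n_right = int(round(config.octamer_rate_per_kb * (L - terc_bp) / 1000.0))
    for pos in rng.integers(len(probe) + 10, terc_bp - 8, size=n_left):
        seq[pos : pos + 8] = motif
    for pos in rng.integers(terc_bp, L - 8, size=n_right):
        seq[pos : pos + 8] = rc_motif

    # oriC probe at position 1
    seq[0 : len(probe)] = probe.encode()

    # tRNA genes at their layout degrees (evenly spaced by default)
    n_genes = len(config.trna_layout)
    trna_features: list[Feature] = []
    chrom_id = f"synth_{config.seed}"
    for i, entry in enumerate(config.trna_layout, start=1):
        if len(entry) == 4:
            isotype, anticodon, strand, deg = entry
        else:
            isotype, anticodon, strand = entry
            deg = 360.0 * i / (n_genes + 1)
        start0 = int(round(L * deg / 360.0))
        if start0 < len(probe) + 20 or start0 + TRNA_LEN > L - 20:
            raise PrsmapError(f"tRNA gene at {deg} deg collides with the oriC probe")
        body = trna_body(isotype, anticodon)
        if strand == "-":
            body = revcomp(body)
        seq[start0 : start0 + TRNA_LEN] = body.encode()
        trna_features.append(
            Feature(
                chrom_id=chrom_id,
                start_bp=start0 + 1,
                end_bp=start0 + TRNA_LEN,
                strand=strand,
                type="tRNA",
                attributes={"isotype": isotype, "anticodon": anticodon},
            )
        )

    chrom = Chromosome(id=chrom_id, sequence=seq.decode(), circular=True)
    truth = SyntheticTruth(
        chrom_id=chrom_id,
        seed=config.seed,
        oric_bp=1,
        terc_bp=terc_bp,
        probe=probe,
        gc_frac=config.gc_frac,
        trna_features=trna_features,
        pre_integration_sequence=chrom.sequence,
        rng=rng,
    )
    for spec in config.integrations:
        chrom, truth = plant_integration(chrom, truth, spec)
    return chrom, truth


def _mismatch_patch(buf: list[str], idx: int, against: str) -> None:
    if 0 <= idx < len(buf):
        if buf[idx] == against:
            buf[idx] = _FLIP[against]


def plant_integration(
    chrom: Chromosome, truth: SyntheticTruth, spec: IntegrationSpec
) -> tuple[Chromosome, SyntheticTruth]:
    """Insert one element at its host gene per the duplication model.

    The att segment (gene end or interior, plus any spacer) is copied; the
    payload is inserted between the two copies on the far side of the gene
    body, so the copy coinciding with the gene is attR.  A nested spec places
    an inner element between the gene-side flank and an internal repeat copy.
    """
    rng = truth.rng or np.random.default_rng(truth.seed)
    gene = truth.host_gene(spec.host_ordinal)
    gs, ge = gene.start_bp, gene.end_bp
    L = chrom.length_bp
    ing, sp = spec.att_in_gene_bp, spec.att_spacer_bp
    att_len = ing + sp

    if spec.anchor == "three_prime":
        if gene.strand == "+":
            a1, a2 = ge - ing + 1, ge + sp
            side = "after"
        else:
            a1, a2 = gs - sp, gs + ing - 1
            side = "before"
    elif spec.anchor == "five_prime":
        if gene.strand == "+":
            a1, a2 = gs - sp, gs + ing - 1
            side = "before"
        else:
            a1, a2 = ge - ing + 1, ge + sp
            side = "after"
    elif spec.anchor == "central":
        if ing >= ge - gs + 1 - 8:
            raise PrsmapError("central att does not fit inside the gene")
        a1 = gs + (ge - gs + 1 - ing) // 2
        a2 = a1 + ing - 1
        side = "after"
    else:
        raise PrsmapError(f"unknown anchor {spec.anchor!r}")
    if a1 < 1 or a2 > L:
        raise PrsmapError("att interval falls off the chromosome")

    # packing check: nothing else may sit in the att neighbourhood
    for f in truth.trna_features:
        if f is gene:
            continue
        if f.start_bp <= a2 + 10 and f.end_bp >= a1 - 10:
            raise PrsmapError("att neighbourhood overlaps another tRNA gene")
    for pl in truth.integrations:
        if pl.element_start_bp - att_len - 10 <= a2 and pl.element_end_bp + att_len + 10 >= a1:
            raise PrsmapError("att neighbourhood overlaps another element")

    att = chrom.fetch(a1, a2)
    payload = list(_random_seq(rng, spec.payload_len_bp, truth.gc_frac))

    # carried tRNA genes: diverged bodies planted inside the payload
    carried: list[tuple[int, str, str, str]] = []  # (offset0, isotype, anticodon, body)
    off = 200
    for isotype, anticodon in spec.carried_trnas:
        body = diverged_trna_body(isotype, anticodon)
        if off + TRNA_LEN > len(payload) - 200:
            raise PrsmapError("payload too short for carried tRNA genes")
        payload[off : off + TRNA_LEN] = list(body)
        carried.append((off, isotype, anticodon, body))
        off += TRNA_LEN + 224

    inner: list[str] = []
    inner_att = ""
    if spec.nested is not None:
        inner_len, inner_att_len = spec.nested
        if not 12 <= inner_att_len <= att_len:
            raise PrsmapError("inner att length outside 12..att length")
        inner = list(_random_seq(rng, inner_len, truth.gc_frac))
        if side == "after":
            inner_att = att[-inner_att_len:]  # suffix anchored at the gene end
        else:
            inner_att = att[:inner_att_len]

    K = _BOUNDARY_MISMATCH_COLS
    seq0 = chrom.sequence

    if side == "after":
        # layout: ATT(orig) | inner | innerATT | payload | ATT(copy)
        ins_parts = inner + list(inner_att) + payload + list(att)
        p0 = a2  # 0-based insertion index (right after the att)
        # make the planted repeat maximal: boundary columns must mismatch
        for t in range(K):
            _mismatch_patch(ins_parts, len(ins_parts) - att_len - 1 - t, seq0[a1 - 2 - t])
            _mismatch_patch(ins_parts, t, seq0[(a2 + t) % L])
        if inner:
            # internal copy = att suffix; block leftward over-extension
            m = len(inner_att)
            for t in range(K):
                if m + t < att_len:
                    _mismatch_patch(ins_parts, len(inner) - 1 - t, att[-m - 1 - t])
        el_start = a2 + 1
        el_end = a2 + len(ins_parts) - att_len
        att_left = (a1, a2)
        att_right = (el_end + 1, el_end + att_len)
    else:
        # layout: ATT(copy) | payload | innerATT | inner | ATT(orig)
        ins_parts = list(att) + payload + list(inner_att) + inner
        p0 = a1 - 1
        for t in range(K):
            _mismatch_patch(ins_parts, att_len + t, seq0[(a2 + t) % L])
            _mismatch_patch(ins_parts, len(ins_parts) - 1 - t, seq0[a1 - 2 - t])
        if inner:
            # internal copy = att prefix; block rightward over-extension
            m = len(inner_att)
            for t in range(K):
                if m + t < att_len:
                    _mismatch_patch(
                        ins_parts, att_len + len(payload) + m + t, att[m + t]
                    )
        el_start = a1 + att_len
        el_end = a1 - 1 + len(ins_parts)
        att_left = (a1, a1 + att_len - 1)
        att_right = (el_end + 1, el_end + att_len)

    ins = "".join(ins_parts)
    new_seq = seq0[:p0] + ins + seq0[p0:]

    disrupted = spec.anchor == "central"
    truth._shift(p0, len(ins), extend_spanning=True)
    # recompute this element's own coordinates in the post-insertion frame
    el_id = f"{truth.chrom_id}_el{len(truth.integrations) + 1:02d}"

    children: tuple[tuple[int, int], ...] = ()
    if spec.nested is not None:
        inner_len, inner_att_len = spec.nested
        if side == "after":
            children = ((0, inner_len), (inner_len + inner_att_len, spec.payload_len_bp))
        else:
            children = ((0, spec.payload_len_bp), (spec.payload_len_bp + inner_att_len, inner_len))

    carried_feats = [
        Feature(
            chrom_id=truth.chrom_id,
            start_bp=el_start + off_c + (len(inner) + len(inner_att) if side == "after" else 0),
            end_bp=el_start + off_c + (len(inner) + len(inner_att) if side == "after" else 0) + TRNA_LEN - 1,
            strand="+",
            type="tRNA",
            attributes={"isotype": iso, "anticodon": ac, "origin": "prs"},
        )
        for off_c, iso, ac, _ in carried
    ]

    planted = PlantedIntegration(
        element_id=el_id,
        spec=spec,
        element_start_bp=el_start,
        element_end_bp=el_end,
        att_left=att_left,
        att_right=att_right,
        att_sequence=att,
        host_ordinal=spec.host_ordinal,
        gene_disrupted=disrupted,
        nested_children=children,
        carried_trna_features=carried_feats,
    )
    truth.integrations.append(planted)
    new_chrom = Chromosome(
        id=chrom.id, sequence=new_seq, circular=chrom.circular,
        origin_offset_bp=chrom.origin_offset_bp,
    )
    return new_chrom, truth


def duplicate_region(
    chrom: Chromosome, truth: SyntheticTruth, start_deg: float, end_deg: float
) -> tuple[Chromosome, SyntheticTruth]:
    """Tandem duplication of a degree interval (no planted element inside)."""
    L = chrom.length_bp
    s0 = int(round(L * start_deg / 360.0))
    e0 = int(round(L * end_deg / 360.0))
    if e0 <= s0:
        raise PrsmapError("duplication region is empty or reversed")
    for pl in truth.integrations:
        if pl.att_left[0] - 1 < e0 and pl.att_right[1] > s0:
            raise PrsmapError("duplication region overlaps a planted element")
    dup = chrom.sequence[s0:e0]
    new_seq = chrom.sequence[:e0] + dup + chrom.sequence[e0:]
    K = e0 - s0
    copies = [
        f
        for f in truth.trna_features
        if f.start_bp - 1 >= s0 and f.end_bp <= e0
    ]
    if any(f.start_bp - 1 < e0 <= f.end_bp - 1 for f in truth.trna_features):
        raise PrsmapError("duplication boundary cuts a tRNA gene")
    truth._shift(e0, K, extend_spanning=False)
    from dataclasses import replace as _r

    truth.trna_features.extend(
        _r(f, start_bp=f.start_bp + K, end_bp=f.end_bp + K) for f in copies
    )
    truth.trna_features.sort(key=lambda f: f.start_bp)
    new_chrom = Chromosome(
        id=chrom.id, sequence=new_seq, circular=chrom.circular,
        origin_offset_bp=chrom.origin_offset_bp,
    )
    return new_chrom, truth


#: tier probabilities of the three hot-spot frequency classes; per-gene
#: integration probability is tier_prob x EXPECTED_MULTIPLICITY per strain
DEFAULT_TIER_PROBS: dict[int, float] = (
    {o: 0.11 for o in HOT_SPOT_ORDINALS}
    | {o: 0.05 for o in (8, 13, 16, 32, 40, 45)}
    | {o: 0.02 for o in (4, 5, 6, 7, 11, 17, 18, 21, 26, 27, 31, 34, 46, 47, 50, 51)}
)

#: per-strain integration load scale: per-gene probability is
#: multiplicity x tier probability (capped at 1).  The per-gene shares of
#: integrations are invariant to this scale; it is set so that hot-spot genes
#: recruit an integration in nearly every strain, which a 27-strain cohort
#: needs for the three-gene top tier to be statistically identifiable.
EXPECTED_MULTIPLICITY = 9.0

_PH_ORIGINS = ("Azospirillum phage Cd", "Caulobacter phage Cr30",
               "Ralstonia phage RSY1", "Pseudomonas phage YMC11",
               "Mycobacterium phage Dori")
_PH_ORIGIN_P = (0.65, 0.15, 0.10, 0.05, 0.05)
_GI_ORIGINS = ("Pseudomonas phage vB_PsyP_3MF5", "Sulfitobacter phage NYA-2014a",
               "Salmonella phage epsilon15", "Burkholderia phage KS9",
               "Ralstonia phage RSY1", "Synechococcus phage S-CBP1")
_GI_ORIGIN_P = (0.35, 0.20, 0.15, 0.12, 0.10, 0.08)
_PRS_CLASSES = ("GI", "int-Ph", "inc-Ph", "q-Ph")
_PRS_CLASS_P = (51 / 88, 30 / 88, 1 / 88, 6 / 88)


def generate_cohort(
    n_strains: int = 27,
    tier_probs: dict[int, float] | None = None,
    seed: int = 0,
    length_bp: int = 400_000,
    multiplicity: float = EXPECTED_MULTIPLICITY,
) -> list[tuple[Chromosome, SyntheticTruth]]:
    """Generate a cohort of strains with tiered per-gene integration rates.

    Each tRNA gene independently receives at most one integration per strain
    with probability ``min(1, multiplicity * tier_prob)``; across the cohort
    the per-gene share of integrations then matches the tier probabilities in
    expectation (up to their sum).
    """
    tier_probs = DEFAULT_TIER_PROBS if tier_probs is None else tier_probs
    out = []
    for i in range(n_strains):
        cfg = GeneratorConfig(seed=seed + i, length_bp=length_bp)
        chrom, truth = generate_chromosome(cfg)
        rng = truth.rng
        # plant right-to-left so host coordinates stay valid during insertion
        for ordinal in sorted(tier_probs, reverse=True):
            p = min(1.0, multiplicity * tier_probs[ordinal])
            if rng.random() >= p:
                continue
            anchor = rng.choice(
                ["three_prime", "five_prime", "central"], p=[0.875, 0.102, 0.023]
            )
            gene = truth.host_gene(ordinal)
            carried: tuple[tuple[str, str], ...] = ()
            if anchor == "central":
                ing = int(rng.integers(20, 41))
                sp = 0
                iso = gene.attributes["isotype"]
                ac = gene.attributes["anticodon"]
                carried = ((iso, ac),)
            else:
                ing = int(rng.integers(14, 48))
                sp = int(rng.integers(0, 11))
                if rng.random() < 0.25:
                    pool = (("fMet", "CAT"), ("Met", "CAT"), ("Thr", "GGT"))
                    n_car = 1 + int(rng.random() < 0.5)
                    carried = tuple(
                        pool[int(rng.integers(0, len(pool)))] for _ in range(n_car)
                    )
            prs_class = str(rng.choice(_PRS_CLASSES, p=_PRS_CLASS_P))
            if prs_class == "GI":
                origin = str(rng.choice(_GI_ORIGINS, p=_GI_ORIGIN_P))
                has_ph = bool(rng.random() < 19 / 51)
            else:
                origin = str(rng.choice(_PH_ORIGINS, p=_PH_ORIGIN_P))
                has_ph = True
            spec = IntegrationSpec(
                host_ordinal=ordinal,
                anchor=str(anchor),
                att_in_gene_bp=ing,
                att_spacer_bp=sp,
                payload_len_bp=int(rng.integers(1500, 3001)),
                prs_class=prs_class,
                integrase_origin=origin,
                carried_trnas=carried,
                has_phage_fragments=has_ph,
            )
            chrom, truth = plant_integration(chrom, truth, spec)
        out.append((chrom, truth))
    return out
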