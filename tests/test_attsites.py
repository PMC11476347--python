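"""Direct-repeat detection, attachment classification, nesting and excision,
exercised against generator ground truth (planted repeats are exact and
maximal, so recovery must be boundary-exact)."""

from dataclasses import replace

import pytest

from prsmap.attsites import (
    ANCHOR_CENTRAL,
    ANCHOR_FIVE,
    ANCHOR_THREE,
    AttSite,
    IntegrationCall,
    PRSElement,
    classify_attachment,
    detect_nested,
    excise,
    find_flanking_repeats,
)
from prsmap.errors import PrsmapError
from prsmap.io import Chromosome, Feature
from prsmap.simulate import (
    GeneratorConfig,
    IntegrationSpec,
    generate_chromosome,
)
from prsmap.trna import assign_ordinals
from tests.conftest import PLANTED_SPECS, random_seq


def _element(truth, i=0):
    return PRSElement(truth.element_features()[i])


def _catalog(truth, chrom):
    return assign_ordinals(truth.trna_features, chrom)


class TestFindFlankingRepeats:
    def test_all_planted_pairs_recovered_boundary_exact(self, planted_genome):
        chrom, truth = planted_genome
        for i, pl in enumerate(truth.integrations):
            pairs = find_flanking_repeats(chrom, _element(truth, i))
            assert pairs, pl.element_id
            best = pairs[0]
            assert (best.left.start_bp, best.left.end_bp) == pl.att_left
            assert (best.right.start_bp, best.right.end_bp) == pl.att_right
            assert best.left.sequence == best.right.sequence == pl.att_sequence

    def test_repeat_below_minimum_rejected(self):
        spec = IntegrationSpec(host_ordinal=8, anchor="three_prime",
                               att_in_gene_bp=8, att_spacer_bp=4,
                               payload_len_bp=2000)
        chrom, truth = generate_chromosome(GeneratorConfig(seed=21, integrations=(spec,)))
        pairs = find_flanking_repeats(chrom, _element(truth), min_len=13)
        assert pairs == []

    def test_repeat_at_maximum_accepted(self):
        spec = IntegrationSpec(host_ordinal=8, anchor="three_prime",
                               att_in_gene_bp=76, att_spacer_bp=22,
                               payload_len_bp=2000)
        chrom, truth = generate_chromosome(GeneratorConfig(seed=22, integrations=(spec,)))
        pairs = find_flanking_repeats(chrom, _element(truth))
        assert pairs and pairs[0].length == 98

    def test_recovery_invariant_under_rotation_across_origin(self, planted_genome):
        chrom, truth = planted_genome
        pl = truth.integrations[0]
        L = chrom.length_bp
        mid = (pl.element_start_bp + pl.element_end_bp) // 2
        rotated = replace(
            chrom, sequence=chrom.sequence[mid - 1 :] + chrom.sequence[: mid - 1]
        )
        el = PRSElement(truth.element_features()[0].shifted(-(mid - 1), L))
        assert el.start_bp > el.end_bp  # the element now crosses the origin
        pairs = find_flanking_repeats(rotated, el)
        want_left = tuple((x - mid) % L + 1 for x in pl.att_left)
        want_right = tuple((x - mid) % L + 1 for x in pl.att_right)
        assert (pairs[0].left.start_bp, pairs[0].left.end_bp) == want_left
        assert (pairs[0].right.start_bp, pairs[0].right.end_bp) == want_right


class TestClassification:
    @pytest.mark.parametrize(
        "idx,anchor,in_gene,spacer,disrupted",
        [
            (0, ANCHOR_THREE, 17, 10, False),
            (1, ANCHOR_THREE, 40, 6, False),  # minus-strand host gene
            (2, ANCHOR_FIVE, 20, 0, False),
            (3, ANCHOR_CENTRAL, 30, 0, True),
        ],
    )
    def test_anchor_classes_and_composition(
        self, planted_genome, idx, anchor, in_gene, spacer, disrupted
    ):
        chrom, truth = planted_genome
        cat = _catalog(truth, chrom)
        pairs = find_flanking_repeats(chrom, _element(truth, idx))
        call = classify_attachment(pairs[0], cat, chrom)
        assert call.anchor_class == anchor
        assert call.att_r.in_gene_bp == in_gene
        assert call.att_r.spacer_bp == spacer
        assert call.att_r.in_gene_bp + call.att_r.spacer_bp == pairs[0].length
        assert call.gene_disrupted is disrupted
        assert call.host_gene.ordinal == truth.integrations[idx].host_ordinal

    def test_attr_is_the_gene_side_copy(self, planted_genome):
        chrom, truth = planted_genome
        cat = _catalog(truth, chrom)
        for i in range(3):
            call = classify_attachment(
                find_flanking_repeats(chrom, _element(truth, i))[0], cat, chrom
            )
            assert call.att_r.in_gene_bp > 0
            assert call.att_l.in_gene_bp == 0

    def test_no_gene_overlap_gives_none_anchor(self, rng):
        seq = list(random_seq(rng, 20000))
        att = random_seq(rng, 30)
        payload = random_seq(rng, 3000)
        s = 5000
        ins = att + payload + att
        chrom = Chromosome(id="c", sequence="".join(seq[:s]) + ins + "".join(seq[s:]))
        el = PRSElement(
            Feature("c", s + 31, s + 30 + 3000, "+", "PRS", {"prs_class": "GI", "ID": "x"})
        )
        cat = assign_ordinals(
            [Feature("c", 100, 175, "+", "tRNA", {"isotype": "Lys", "anticodon": "CTT"})],
            chrom,
        )
        call = classify_attachment(find_flanking_repeats(chrom, el)[0], cat, chrom)
        assert call.anchor_class == "none" and call.host_gene is None


class TestNested:
    def test_nested_children_sizes(self, planted_genome):
        chrom, truth = planted_genome
        cat = _catalog(truth, chrom)
        idx = 4  # nested spec: 15000 inner + 46 bp internal copy + 20000 outer
        call = detect_nested(
            chrom,
            classify_attachment(
                find_flanking_repeats(chrom, _element(truth, idx))[0], cat, chrom
            ),
        )
        assert call.nested_children == truth.integrations[idx].nested_children
        assert [n for _, n in call.nested_children] == [15000, 20000]

    def test_kh46_scale_split(self):
        """137.5 kb element splits into 84.2 and 53.3 kb sub-elements."""
        spec = IntegrationSpec(host_ordinal=39, anchor="three_prime",
                               att_in_gene_bp=46, att_spacer_bp=0,
                               payload_len_bp=84_200, prs_class="GI",
                               nested=(53_300, 46))
        chrom, truth = generate_chromosome(GeneratorConfig(seed=46, integrations=(spec,)))
        cat = _catalog(truth, chrom)
        call = detect_nested(
            chrom,
            classify_attachment(find_flanking_repeats(chrom, _element(truth))[0], cat, chrom),
        )
        assert sorted(n for _, n in call.nested_children) == [53_300, 84_200]
        el = _element(truth)
        assert el.length_bp(chrom.length_bp) == 84_200 + 53_300 + 46

    def test_element_without_internal_copy_has_no_children(self, planted_genome):
        chrom, truth = planted_genome
        cat = _catalog(truth, chrom)
        call = detect_nested(
            chrom,
            classify_attachment(
                find_flanking_repeats(chrom, _element(truth, 0))[0], cat, chrom
            ),
        )
        assert call.nested_children == ()

    def test_internal_copy_below_identity_threshold_ignored(self, rng):
        # an 80%-identity internal copy (mismatch every 5th bp) is not counted
        seq = list(random_seq(rng, 30000))
        att = random_seq(rng, 40)
        degraded = list(att)
        for i in range(0, 40, 5):
            degraded[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[degraded[i]]
        payload = random_seq(rng, 2000) + "".join(degraded) + random_seq(rng, 2000)
        s = 9000
        chrom = Chromosome(
            id="c", sequence="".join(seq[:s]) + att + payload + att + "".join(seq[s:])
        )
        el = PRSElement(
            Feature("c", s + 41, s + 40 + len(payload), "+", "PRS",
                    {"prs_class": "GI", "ID": "x"})
        )
        pair = find_flanking_repeats(chrom, el)[0]
        call = IntegrationCall(el, None, pair.left, pair.right, "none", False)
        assert detect_nested(chrom, call).nested_children == ()


def _shift_features_after_excision(features, cut_start_bp, removed_bp):
    out = []
    for f in features:
        if f.start_bp >= cut_start_bp:
            out.append(replace(f, start_bp=f.start_bp - removed_bp, end_bp=f.end_bp - removed_bp))
        elif f.end_bp >= cut_start_bp:
            out.append(replace(f, end_bp=f.end_bp - removed_bp))
        else:
            out.append(f)
    return out


class TestExcision:
    @pytest.mark.parametrize("idx", range(len(PLANTED_SPECS)))
    def test_excise_restores_pre_integration_genome(self, idx):
        cfg = GeneratorConfig(seed=60 + idx, integrations=(PLANTED_SPECS[idx],))
        chrom, truth = generate_chromosome(cfg)
        cat = _catalog(truth, chrom)
        call = classify_attachment(
            find_flanking_repeats(chrom, _element(truth))[0], cat, chrom
        )
        restored = excise(chrom, call)
        assert restored.sequence == truth.pre_integration_sequence

    def test_central_excision_restores_intact_gene(self):
        spec = IntegrationSpec(host_ordinal=26, anchor="central", att_in_gene_bp=30,
                               att_spacer_bp=0, payload_len_bp=3000,
                               prs_class="int-Ph", carried_trnas=(("Leu", "TAG"),))
        chrom, truth = generate_chromosome(GeneratorConfig(seed=70, integrations=(spec,)))
        cat = _catalog(truth, chrom)
        call = classify_attachment(
            find_flanking_repeats(chrom, _element(truth))[0], cat, chrom
        )
        assert call.gene_disrupted
        restored = excise(chrom, call)
        from prsmap.simulate import trna_body

        pre = Chromosome(id=truth.chrom_id, sequence=truth.pre_integration_sequence)
        cat_pre = assign_ordinals(_pre_catalog_features(truth), pre)
        g26 = cat_pre.genes[25]
        assert restored.fetch(g26.start_bp, g26.end_bp) == trna_body("Leu", "TAG")

    def test_sequential_nested_excision_restores_genome(self):
        spec = IntegrationSpec(host_ordinal=39, anchor="three_prime",
                               att_in_gene_bp=46, att_spacer_bp=0,
                               payload_len_bp=20000, prs_class="GI",
                               nested=(15000, 46))
        chrom, truth = generate_chromosome(GeneratorConfig(seed=71, integrations=(spec,)))
        cat = _catalog(truth, chrom)
        el = _element(truth)
        pair = find_flanking_repeats(chrom, el)[0]
        call = detect_nested(chrom, classify_attachment(pair, cat, chrom))
        (o1, n1), (o2, n2) = call.nested_children
        m = 46
        es = el.start_bp
        inner_el = PRSElement(replace(el.feature, start_bp=es + o1, end_bp=es + o1 + n1 - 1))
        inner_call = IntegrationCall(
            inner_el,
            None,
            AttSite(chrom.fetch(es - m, es - 1), es - m, es - 1, "attL"),
            AttSite(chrom.fetch(es + n1, es + n1 + m - 1), es + n1, es + n1 + m - 1, "attR"),
            "none",
            False,
        )
        after_inner = excise(chrom, inner_call)
        removed = n1 + m
        outer_el = PRSElement(replace(el.feature, start_bp=es, end_bp=es + n2 - 1))
        feats = _shift_features_after_excision(truth.trna_features, es, removed)
        cat2 = assign_ordinals(feats, after_inner)
        outer_call = classify_attachment(
            find_flanking_repeats(after_inner, outer_el)[0], cat2, after_inner
        )
        final = excise(after_inner, outer_call)
        assert final.sequence == truth.pre_integration_sequence

    def test_mismatched_copies_rejected(self, planted_genome):
        chrom, truth = planted_genome
        cat = _catalog(truth, chrom)
        call = classify_attachment(
            find_flanking_repeats(chrom, _element(truth, 0))[0], cat, chrom
        )
        bad = replace(
            call,
            att_l=replace(call.att_l, sequence="A" * len(call.att_l.sequence)),
        )
        with pytest.raises(PrsmapError):
            excise(chrom, bad)


def _pre_catalog_features(truth):
    """tRNA features in pre-integration coordinates (single planted element)."""
    pl = truth.integrations[0]
    ins_len = pl.att_right[1] - pl.element_start_bp + 1
    out = []
    for f in truth.trna_features:
        if f.end_bp >= pl.att_right[1]:
            if f.start_bp > pl.att_right[1]:
                out.append(replace(f, start_bp=f.start_bp - ins_len, end_bp=f.end_bp - ins_len))
            else:
                out.append(replace(f, end_bp=f.end_bp - ins_len))
        else:
            out.append(f)
    return out
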