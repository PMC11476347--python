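import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsmap.errors import CoordinateError, LowConfidenceError, NotFoundError
from prsmap.io import Chromosome, revcomp
from prsmap.replichore import (
    bp_to_degrees,
    call_terc,
    degrees_distance,
    gc_skew_profile,
    locate_oric,
    nucleotide_diversity,
    octamer_profile,
    rotate_to_origin,
)
from prsmap.simulate import DEFAULT_ORIC_PROBE, GeneratorConfig, generate_chromosome
from tests.conftest import random_seq


class TestLocateOric:
    def test_exact_probe_found_at_planted_position(self, rng):
        probe = random_seq(rng, 477)
        background = random_seq(rng, 20000)
        chrom = Chromosome(id="c", sequence=background[:5000] + probe + background[5000:])
        a = locate_oric(chrom, probe)
        assert a.start_bp == 5001
        assert a.probe_identity_pct == 100.0 and a.probe_coverage_pct == 100.0

    def test_two_substitutions_reported_in_identity(self, rng):
        probe = random_seq(rng, 477)
        planted = list(probe)
        for i in (100, 300):
            planted[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[planted[i]]
        background = random_seq(rng, 20000)
        chrom = Chromosome(id="c", sequence=background[:5000] + "".join(planted) + background[5000:])
        a = locate_oric(chrom, probe)
        assert a.start_bp == 5001
        assert a.probe_identity_pct == pytest.approx(100 * 475 / 477, abs=0.05)

    def test_reverse_strand_probe(self, rng):
        probe = random_seq(rng, 477)
        background = random_seq(rng, 20000)
        chrom = Chromosome(id="c", sequence=background[:7000] + revcomp(probe) + background[7000:])
        a = locate_oric(chrom, probe)
        assert a.start_bp == 7001 and a.strand == "-"

    def test_absent_probe_raises(self, rng):
        chrom = Chromosome(id="c", sequence=random_seq(rng, 50000))
        with pytest.raises(NotFoundError):
            locate_oric(chrom, random_seq(rng, 477))


class TestRotation:
    def test_identity_and_inverse(self, rng):
        chrom = Chromosome(id="c", sequence=random_seq(rng, 1000))
        from prsmap.replichore import OriginAnchor

        a1 = OriginAnchor("c", 1, 100.0, 100.0)
        assert rotate_to_origin(chrom, a1).sequence == chrom.sequence
        a = OriginAnchor("c", 301, 100.0, 100.0)
        rotated = rotate_to_origin(chrom, a)
        assert rotated.origin_offset_bp == 300
        back = rotate_to_origin(
            rotated, OriginAnchor("c", 1000 - 300 + 1, 100.0, 100.0)
        )
        assert back.sequence == chrom.sequence
        assert sorted(rotated.sequence) == sorted(chrom.sequence)

    def test_feature_rotation_follows_sequence(self, rng):
        from prsmap.io import Feature
        from prsmap.replichore import OriginAnchor

        chrom = Chromosome(id="c", sequence=random_seq(rng, 1000))
        feats = [Feature("c", 500, 520, "+", "tRNA", {})]
        rot, f2 = rotate_to_origin(chrom, OriginAnchor("c", 500, 100.0, 100.0), feats)
        assert f2[0].start_bp == 1 and f2[0].end_bp == 21
        assert rot.fetch(1, 21) == chrom.fetch(500, 520)


class TestDegrees:
    @pytest.mark.parametrize(
        "pos,length,expected",
        [(1_700_000, 3_600_000, 170.0), (1_800_000, 3_600_000, 180.0), (3_600_000, 3_600_000, 0.0)],
    )
    def test_examples(self, pos, length, expected):
        assert bp_to_degrees(pos, length) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(CoordinateError):
            bp_to_degrees(0, 100)
        with pytest.raises(CoordinateError):
            bp_to_degrees(101, 100)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=100, max_value=10_000))
    def test_monotone_and_bounded(self, L):
        degs = [bp_to_degrees(p, L) for p in range(1, L)]
        assert all(0 <= d < 360 for d in degs)
        assert all(b > a for a, b in zip(degs, degs[1:]))


class TestSkewProfiles:
    def test_all_g_sequence(self):
        chrom = Chromosome(id="c", sequence="G" * 5000)
        prof = gc_skew_profile(chrom)
        assert np.all(prof.window_values == 1.0)
        assert np.all(np.diff(prof.cumulative) > 0)

    def test_reverse_complement_negates_window_skew(self, rng):
        seq = random_seq(rng, 10000)
        p1 = gc_skew_profile(Chromosome(id="c", sequence=seq))
        p2 = gc_skew_profile(Chromosome(id="c", sequence=revcomp(seq)))
        # same windows read from the other strand, reversed order
        assert np.allclose(p1.window_values, -p2.window_values[::-1])

    def test_gc_half_structure_peaks_at_midpoint(self, rng):
        # G-rich first half, C-rich second half: cumulative max at midpoint
        n = 10000
        first = "".join(rng.choice(list("GGGA"), n // 2))
        second = "".join(rng.choice(list("CCCA"), n // 2))
        prof = gc_skew_profile(Chromosome(id="c", sequence=first + second))
        k = int(np.argmax(prof.cumulative))
        peak_bp = prof.positions_bp[k] + prof.window_bp - 1
        assert abs(peak_bp - n // 2) <= 2 * prof.window_bp
        # direct-count oracle for the window values
        seq = first + second
        w = prof.window_bp
        for i in (0, 3, len(prof.positions_bp) - 2):
            s = prof.positions_bp[i] - 1
            win = seq[s : s + w]
            g, c = win.count("G"), win.count("C")
            expect = (g - c) / (g + c) if g + c else 0.0
            assert prof.window_values[i] == pytest.approx(expect)

    def test_octamer_window_counting(self):
        motif = "GGGCAGGG"
        rc = revcomp(motif)
        seq = ("A" * 50 + motif + "A" * 30 + motif + "T" * 12 + motif + rc + "A" * 300)
        seq = seq + "A" * (1000 - len(seq))
        prof = octamer_profile(Chromosome(id="c", sequence=seq), window_bp=1000, step_bp=1000)
        assert prof.window_values[0] == 3 - 1

    def test_motif_free_chromosome_all_zero(self, rng):
        seq = ("AC" * 5000)
        prof = octamer_profile(Chromosome(id="c", sequence=seq))
        assert np.all(prof.window_values == 0)

    def test_overlapping_occurrences_counted(self):
        # AAAA in GAAAAA occurs twice (overlap)
        seq = "GAAAAAG" + "C" * 993
        prof = octamer_profile(Chromosome(id="c", sequence=seq), motif="AAAA",
                               window_bp=1000, step_bp=1000)
        assert prof.window_values[0] == 2 - 0


class TestTerC:
    def test_planted_angle_recovered(self, bare_genome):
        chrom, truth = bare_genome
        call = call_terc(gc_skew_profile(chrom), octamer_profile(chrom), chrom)
        assert degrees_distance(call.position_deg, 170.0) <= 2.0
        assert call.agreement_deg <= 5.0

    def test_symmetric_random_chromosome_low_confidence(self, rng):
        chrom = Chromosome(id="c", sequence=random_seq(rng, 100_000))
        with pytest.raises(LowConfidenceError):
            call_terc(gc_skew_profile(chrom), octamer_profile(chrom), chrom)

    def test_recovery_across_seeded_genomes(self):
        """Parameter recovery: |call - planted| <= 2 deg in >= 95% of runs."""
        hits = []
        agreements = []
        for seed in range(20):
            chrom, truth = generate_chromosome(GeneratorConfig(seed=seed, length_bp=300_000))
            call = call_terc(gc_skew_profile(chrom), octamer_profile(chrom), chrom)
            hits.append(degrees_distance(call.position_deg, 170.0) <= 2.0)
            agreements.append(call.agreement_deg)
        assert sum(hits) >= 19
        assert max(agreements) <= 5.0


class TestNucleotideDiversity:
    def test_identical_and_single_difference(self):
        assert nucleotide_diversity(["ACGT" * 5, "ACGT" * 5]) == 0.0
        assert nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAAAT"]) == pytest.approx(0.1)

    def test_three_sequences_brute_force_value(self):
        # pairs differ at 1+2+1 sites over length 4: mean 4/3/4 = 1/3
        assert nucleotide_diversity(["AAAA", "AAAT", "AATT"]) == pytest.approx(1 / 3)

    def test_gap_columns_excluded_pairwise(self):
        assert nucleotide_diversity(["AAC-", "AAT-"]) == pytest.approx(1 / 3)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["AAA", "AAAA"])
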