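"""Windowed skew profiles, cumulative skew and ori/ter prediction."""

import numpy as np
import pytest

from replichore.io import AnnotationSet, CircularSequence, FeatureAnnotation
from replichore.simulate import SyntheticGenomeSpec, simulate_genome
from replichore.skew import (
    SkewSignalError,
    circular_distance,
    cumulative_skew,
    predict_ori_ter,
    rotate_to_origin,
    strand_bias,
    windowed_profile,
)


class TestWindowedProfile:
    def test_all_g_has_skew_one(self):
        prof = windowed_profile(CircularSequence("s", "G" * 500), 100, 50)
        assert np.all(prof.skew == 1.0)
        assert np.all(prof.gc_percent == 1.0)

    def test_balanced_window(self):
        prof = windowed_profile(CircularSequence("s", "GGGGCCCC"), 8, 8)
        assert prof.skew[0] == 0.0 and prof.gc_percent[0] == 1.0

    def test_matches_naive_recount(self, rng):
        # oracle: brute-force per-window base counting with explicit wrap
        res = "".join(rng.choice(list("ACGT"), size=5000))
        seq = CircularSequence("s", res)
        window, step = 500, 100
        prof = windowed_profile(seq, window, step)
        doubled = res + res
        for i, start in enumerate(range(0, 5000, step)):
            w = doubled[start : start + window]
            g, c = w.count("G"), w.count("C")
            assert prof.skew[i] == pytest.approx((g - c) / (g + c))
            assert prof.gc_percent[i] == pytest.approx((g + c) / window)
            assert prof.centers[i] == (start + window // 2) % 5000 + 1

    def test_window_count_is_ceil_length_over_step(self):
        prof = windowed_profile(CircularSequence("s", "ACGT" * 300), 100, 7)
        assert len(prof.centers) == int(np.ceil(1200 / 7))

    def test_ambiguous_bases_excluded(self):
        prof = windowed_profile(CircularSequence("s", "GGNNCC" * 10), 6, 6)
        assert np.all(prof.gc_percent == 1.0)  # N not in denominator
        assert np.all(prof.skew == 0.0)

    def test_no_gc_window_skew_zero(self):
        prof = windowed_profile(CircularSequence("s", "AT" * 50), 10, 10)
        assert np.all(prof.skew == 0.0) and np.all(prof.gc_percent == 0.0)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            windowed_profile(CircularSequence("s", "ACGT"), 10, 1)

    def test_sign_convention_negates(self):
        seq = CircularSequence("s", "GGGAC" * 40)
        a = windowed_profile(seq, 20, 20, "G_minus_C")
        b = windowed_profile(seq, 20, 20, "C_minus_G")
        assert np.allclose(a.skew, -b.skew)


class TestCumulativeSkew:
    def test_tiny_examples(self):
        assert list(cumulative_skew(CircularSequence("s", "GC")).values) == [1, 0]
        assert list(cumulative_skew(CircularSequence("s", "AAAA")).values) == [0] * 4

    def test_final_value_is_g_minus_c(self, rng):
        res = "".join(rng.choice(list("ACGTN"), size=2000))
        cs = cumulative_skew(CircularSequence("s", res))
        assert cs.values[-1] == res.count("G") - res.count("C")
        assert len(cs.values) == 2000

    def test_start_phase_wraps(self):
        cs = cumulative_skew(CircularSequence("s", "GAAC"), start_phase=3)
        # walk order A,C,G,A -> contributions 0,-1,+1,0
        assert list(cs.values) == [0, -1, 0, 0]


class TestPredictOriTer:
    def test_flat_skew_raises(self):
        cs = cumulative_skew(CircularSequence("s", "AT" * 100))
        with pytest.raises(SkewSignalError):
            predict_ori_ter(cs)

    def test_recovers_planted_architecture(self):
        seq, ann, truth = simulate_genome(
            SyntheticGenomeSpec(seed=5, n_genes=0, n_rrna_operons=0, n_trna=0,
                                place_replication_genes=False)
        )
        pred = predict_ori_ter(cumulative_skew(seq))
        assert circular_distance(pred.ori, truth.ori, seq.length) <= 200
        assert circular_distance(pred.ter, truth.ter, seq.length) <= 200
        assert pred.replichore_1_len + pred.replichore_2_len == seq.length

    def test_dnaa_support_flag(self, default_genome):
        seq, ann, truth = default_genome
        pred = predict_ori_ter(cumulative_skew(seq), ann)
        assert pred.dnaA_supported and pred.dnaA_distance <= 20_000

    def test_rotation_shifts_prediction(self, default_genome):
        seq, ann, _ = default_genome
        pred = predict_ori_ter(cumulative_skew(seq))
        offset = 31_000
        rot, _ = rotate_to_origin(seq, None, offset)
        pred_rot = predict_ori_ter(cumulative_skew(rot))
        expected_ori = (pred.ori - offset) % seq.length + 1
        assert circular_distance(pred_rot.ori, expected_ori, seq.length) <= 200

    def test_sign_convention_swaps_ori_and_ter(self, default_genome):
        seq, _, _ = default_genome
        cs = cumulative_skew(seq)
        a = predict_ori_ter(cs)
        cs.sign_convention = "C_minus_G"
        b = predict_ori_ter(cs)
        assert (a.ori, a.ter) == (b.ter, b.ori)


class TestRotation:
    def test_rotate_string(self):
        seq = CircularSequence("s", "ACGT")
        rot, _ = rotate_to_origin(seq, None, 3)
        assert rot.residues == "GTAC"

    def test_rotate_by_one_is_identity(self, default_genome):
        seq, ann, _ = default_genome
        rot, rot_ann = rotate_to_origin(seq, ann, 1)
        assert rot.residues == seq.residues
        assert [(f.start, f.end, f.wraps) for f in rot_ann] == [
            (f.start, f.end, f.wraps) for f in ann
        ]

    def test_rotation_roundtrip_restores_coordinates(self, default_genome):
        seq, ann, _ = default_genome
        L = seq.length
        ori = 40_321
        rot, rot_ann = rotate_to_origin(seq, ann, ori)
        inverse = (L - ori + 1) % L + 1
        back, back_ann = rotate_to_origin(rot, rot_ann, inverse)
        assert back.residues == seq.residues
        assert sorted((f.start, f.end) for f in back_ann) == sorted(
            (f.start, f.end) for f in ann
        )

    def test_linear_rejected(self):
        with pytest.raises(ValueError):
            rotate_to_origin(CircularSequence("s", "ACGT", "linear"), None, 2)

    def test_wrap_flags_set_on_junction_spanning_features(self):
        seq = CircularSequence("s", "A" * 100)
        ann = AnnotationSet("s", [FeatureAnnotation("CDS", 40, 60, "+", locus_tag="x")])
        _, rot_ann = rotate_to_origin(seq, ann, 50)
        (f,) = rot_ann.features
        assert f.wraps and f.length == 21 and f.start == 91 and f.end == 111


class TestStrandBias:
    def _pred(self, L=1000, ori=1, ter=501):
        from replichore.skew import ReplicationPrediction

        return ReplicationPrediction(
            ori=ori, ter=ter, method="planted", replichore_1_len=(ter - ori) % L,
            replichore_2_len=L - (ter - ori) % L, sign_convention="G_minus_C",
            length=L,
        )

    def test_all_leading_gives_fraction_one(self):
        ann = AnnotationSet(
            "s", [FeatureAnnotation("CDS", 10 * i + 1, 10 * i + 9, "+") for i in range(10)]
        )
        sb = strand_bias(self._pred(), ann)
        assert sb.fraction_replichore_1 == 1.0

    def test_balanced_strands_near_half(self):
        feats = [
            FeatureAnnotation("CDS", 10 * i + 1, 10 * i + 9, "+" if i % 2 else "-")
            for i in range(40)
        ]
        sb = strand_bias(self._pred(), AnnotationSet("s", feats))
        assert sb.pooled_fraction == pytest.approx(0.5)
        assert sb.p_value > 0.5

    def test_planted_bias_recovered(self, default_genome):
        seq, ann, truth = default_genome
        pred = self._pred(L=seq.length, ori=truth.ori, ter=truth.ter)
        sb = strand_bias(pred, ann)
        n = len(ann.of_type("CDS"))
        se = 3 * np.sqrt(0.8 * 0.2 / n)
        # dnaA/dnaN always leading: small upward shift is expected
        assert abs(sb.pooled_fraction - 0.8) <= se + 2 / n

    def test_no_cds_rejected(self):
        with pytest.raises(ValueError):
            strand_bias(self._pred(), AnnotationSet("s", []))


def test_window_skew_mass_approximates_total_g_minus_c(rng):
    # with step == window the windows tile the circle exactly
    res = "".join(rng.choice(list("ACGT"), size=4000))
    seq = CircularSequence("s", res)
    prof = windowed_profile(seq, 200, 200)
    gc_per_window = prof.gc_percent * 200
    total = float(np.sum(prof.skew * gc_per_window))
    assert total == pytest.approx(res.count("G") - res.count("C"), abs=1e-6)
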