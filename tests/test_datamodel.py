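import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slamkin as sk
from slamkin.datamodel import (compute_size_factors, filter_genes, normalize,
                               parse_systematic_names)


class TestParseSystematicNames:
    roles = ["condition", "duration", "replicate"]

    @pytest.mark.parametrize("name,cond,time,no4su,rep", [
        ("mock.2h.A", "mock", 2.0, False, "A"),
        ("SARS.no4sU.B", "SARS", 0.0, True, "B"),
        ("mock.30min.A", "mock", 0.5, False, "A"),
        ("x.90min.1", "x", 1.5, False, "1"),
    ])
    def test_examples(self, name, cond, time, no4su, rep):
        (d,) = parse_systematic_names([name], self.roles)
        assert d.condition == cond
        assert d.labeling_time_nominal == pytest.approx(time)
        assert d.is_no4sU is no4su
        assert d.replicate == rep

    def test_field_count_mismatch_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            parse_systematic_names(["a.2h.A", "b.2h"], self.roles)

    def test_unparseable_duration_names_token(self):
        with pytest.raises(ValueError, match="2fortnights"):
            parse_systematic_names(["a.2fortnights.A"], self.roles)


class TestSizeFactors:
    def test_identical_columns_are_one(self):
        counts = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 2))
        assert compute_size_factors(counts) == pytest.approx([1.0, 1.0])

    def test_three_gene_toy_hand_computed(self):
        # column B = 2 x column A: geometric mean per gene sqrt(2)*A, so the
        # per-sample ratios are 1/sqrt(2) and sqrt(2): proportional to (1, 2)
        a = np.array([10.0, 20.0, 40.0])
        counts = np.column_stack([a, 2 * a])
        f = compute_size_factors(counts)
        assert f[1] / f[0] == pytest.approx(2.0)
        assert f[0] == pytest.approx(1 / np.sqrt(2))

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError, match="filter"):
            compute_size_factors(np.array([[10.0, 0.0]]))

    @settings(derandomize=True, max_examples=25)
    @given(scales=st.lists(st.floats(0.2, 5.0), min_size=2, max_size=5))
    def test_recovers_known_column_scalings(self, scales):
        base = np.array([5.0, 50.0, 500.0, 20.0])
        counts = np.column_stack([base * s for s in scales])
        f = compute_size_factors(counts)
        ratio = f / np.asarray(scales)
        assert np.allclose(ratio, ratio[0], rtol=1e-9)


class TestNormalizeFilter:
    def test_unit_factors_identity(self, tiny_experiment):
        out = normalize(tiny_experiment, np.ones(3))
        assert np.array_equal(out.slots["norm"], tiny_experiment.slots["count"])

    def test_division_and_ntr_invariance(self, tiny_experiment):
        out = normalize(tiny_experiment, np.array([2.0, 1.0, 1.0]))
        assert out.slots["norm"][0, 0] == pytest.approx(50.0)
        assert np.array_equal(
            np.nan_to_num(out.slots["ntr"]),
            np.nan_to_num(tiny_experiment.slots["ntr"]),
        )

    def test_nonpositive_factor_rejected(self, tiny_experiment):
        with pytest.raises(ValueError):
            normalize(tiny_experiment, np.array([1.0, 0.0, 1.0]))

    @pytest.mark.parametrize("min_count,min_samples,expect", [
        (0, 0, 4),      # no filtering
        (50, 3, 2),     # g1 (>=50 everywhere) and g3 survive
        (1000, 1, 1),   # only g3
    ])
    def test_filter_thresholds(self, tiny_experiment, min_count, min_samples,
                               expect):
        assert filter_genes(tiny_experiment, min_count, min_samples).n_genes == expect

    def test_filter_normalize_commute(self, tiny_experiment):
        f = compute_size_factors(tiny_experiment.slots["count"])
        a = filter_genes(normalize(tiny_experiment, f), 50, 3)
        b = normalize(filter_genes(tiny_experiment, 50, 3), f)
        assert a.gene_ids == b.gene_ids
        assert np.allclose(a.slots["norm"], b.slots["norm"])


class TestInvariants:
    def test_no4su_missing_markers_are_nan_not_zero(self, tiny_experiment):
        assert np.all(np.isnan(tiny_experiment.slots["ntr"][:, 0]))

    def test_halflife_delta_identity(self):
        kin = sk.GeneKinetics(sigma=np.array([2.0]), delta=np.array([0.3]))
        assert np.allclose(kin.halflife * kin.delta, np.log(2))

    def test_slot_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sk.ExperimentData(
                ["g1"], [sk.SampleDesign("s", is_no4sU=True)],
                {"count": np.ones((2, 1))},
            )
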