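import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrmarker import preprocess as pre
from nmrmarker import synthdata as syn


def make_spectrum(lo=0.0, hi=10.0, step=0.0005, sample_type="serum", fill=1.0):
    ppm = np.arange(0, round((hi - lo) / step) + 1) * step + lo
    return pre.Spectrum(
        ppm=ppm, intensity=np.full_like(ppm, fill), sample_id="s1", sample_type=sample_type
    )


def test_bucket_width_in_hz():
    assert pre.ppm_width_to_hz(0.004) == pytest.approx(2.4)


class TestReferenceShift:
    def _tsp_spectrum(self, apex):
        ppm = np.arange(-0.25, 2.0, 0.0005)
        y = 1.0 / (1.0 + ((ppm - apex) / 0.001) ** 2)
        return pre.Spectrum(ppm=ppm, intensity=y, sample_id="s", sample_type="urine")

    def test_tsp_apex_translated_to_zero(self):
        sp = pre.reference_shift(self._tsp_spectrum(0.020), "tsp")
        apex = sp.ppm[int(np.argmax(sp.intensity))]
        assert abs(apex) <= 0.0005 / 2

    def test_already_on_target_is_identity(self):
        before = self._tsp_spectrum(0.0)
        after = pre.reference_shift(before, "tsp")
        np.testing.assert_array_equal(before.ppm, after.ppm)

    def test_lactate_left_split_moved_to_1336(self, library):
        # doublet centred at 1.350: left split at 1.344 must land on 1.336
        ppm = np.arange(0.5, 3.0, 0.0005)
        hw = 0.0008
        y = sum(
            1.0 / (1.0 + ((ppm - c) / hw) ** 2) for c in (1.344, 1.356)
        )
        sp = pre.Spectrum(ppm=ppm, intensity=np.asarray(y), sample_id="s",
                          sample_type="serum")
        out = pre.reference_shift(sp, "lactate")
        # whole spectrum translated by -0.008: left line at 1.336, right at 1.348
        win = (out.ppm > 1.330) & (out.ppm < 1.342)
        apex = out.ppm[win][int(np.argmax(out.intensity[win]))]
        assert apex == pytest.approx(1.336, abs=0.0005 / 2)
        np.testing.assert_allclose(out.ppm, sp.ppm - 0.008, atol=1e-12)

    def test_no_peak_in_window_raises(self):
        flat = make_spectrum(lo=-0.25, hi=2.0, fill=1.0)
        with pytest.raises(ValueError, match=r"noise floor"):
            pre.reference_shift(flat, "tsp")

    def test_window_off_grid_raises(self):
        sp = make_spectrum(lo=0.5, hi=2.0)
        with pytest.raises(ValueError, match="window"):
            pre.reference_shift(sp, "tsp")


class TestExclusions:
    def test_serum_water_region_removed(self, default_study):
        plan = pre.default_exclusion_plan()
        out = pre.apply_exclusions(default_study.spectra["serum"][0], plan)
        assert not np.any((out.ppm >= 4.7) & (out.ppm < 5.0))

    def test_retained_range_bounds(self, default_study):
        plan = pre.default_exclusion_plan()
        out = pre.apply_exclusions(default_study.spectra["urine"][0], plan)
        assert out.ppm.min() >= 0.5
        assert out.ppm.max() <= 10.0

    def test_no_exclusions_identity_on_retained_range(self):
        plan = pre.ExclusionPlan(retained={"serum": (0.5, 9.0)}, excluded={"serum": []})
        sp = make_spectrum()
        out = pre.apply_exclusions(sp, plan)
        assert out.ppm.min() >= 0.5 and out.ppm.max() <= 9.0
        keep = (sp.ppm >= 0.5) & (sp.ppm <= 9.0)
        np.testing.assert_array_equal(out.ppm, sp.ppm[keep])

    def test_half_open_membership(self):
        plan = pre.ExclusionPlan(
            retained={"serum": (0.5, 9.0)}, excluded={"serum": [(1.0, 2.0)]}
        )
        out = pre.apply_exclusions(make_spectrum(), plan)
        assert not np.any((out.ppm >= 1.0) & (out.ppm < 2.0))
        assert np.any(np.isclose(out.ppm, 2.0))  # right edge retained

    def test_empty_result_raises(self):
        plan = pre.ExclusionPlan(retained={"serum": (9.5, 9.6)}, excluded={"serum": []})
        sp = make_spectrum(lo=0.0, hi=5.0)
        with pytest.raises(ValueError, match="every point"):
            pre.apply_exclusions(sp, plan)

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            pre.ExclusionPlan(retained={"serum": (0.5, 9.0)},
                              excluded={"serum": [(9.5, 9.9)]})
        with pytest.raises(ValueError, match="overlapping"):
            pre.ExclusionPlan(retained={"serum": (0.5, 9.0)},
                              excluded={"serum": [(1.0, 2.0), (1.5, 2.5)]})


class TestBucketing:
    def test_serum_range_gives_2125_buckets(self):
        plan = pre.ExclusionPlan(retained={"serum": (0.5, 9.0)}, excluded={"serum": []})
        sp = pre.apply_exclusions(make_spectrum(), plan)
        bm = pre.bucket_spectra([sp], width=0.004)
        assert len(bm.edges) == 2125

    def test_flat_intensity_bucket_value_is_width(self):
        plan = pre.ExclusionPlan(retained={"serum": (0.5, 9.0)}, excluded={"serum": []})
        sp = pre.apply_exclusions(make_spectrum(fill=1.0), plan)
        bm = pre.bucket_spectra([sp], width=0.004)
        np.testing.assert_allclose(bm.values, 0.004, rtol=1e-9)

    def test_linearity_across_samples(self):
        plan = pre.ExclusionPlan(retained={"serum": (0.5, 9.0)}, excluded={"serum": []})
        rng = np.random.default_rng(0)
        a = make_spectrum()
        a.intensity = rng.random(len(a.ppm))
        b = pre.Spectrum(ppm=a.ppm, intensity=2 * a.intensity, sample_id="s2",
                         sample_type="serum")
        sa = pre.apply_exclusions(a, plan)
        sb = pre.apply_exclusions(b, plan)
        bm = pre.bucket_spectra([sa, sb])
        np.testing.assert_allclose(bm.values[1], 2 * bm.values[0], rtol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_bucketing_commutes_with_scalar_multiplication(self, scale):
        plan = pre.ExclusionPlan(retained={"serum": (0.5, 2.0)}, excluded={"serum": []})
        base = make_spectrum(hi=3.0)
        base.intensity = np.sin(base.ppm) ** 2
        scaled = pre.Spectrum(ppm=base.ppm, intensity=scale * base.intensity,
                              sample_id="s1", sample_type="serum")
        m1 = pre.bucket_spectra([pre.apply_exclusions(base, plan)])
        m2 = pre.bucket_spectra([pre.apply_exclusions(scaled, plan)])
        np.testing.assert_allclose(m2.values, scale * m1.values, rtol=1e-9)

    def test_buckets_crossing_gaps_dropped(self):
        plan = pre.ExclusionPlan(
            retained={"serum": (0.5, 9.0)}, excluded={"serum": [(1.0015, 2.0015)]}
        )
        sp = pre.apply_exclusions(make_spectrum(), plan)
        bm = pre.bucket_spectra([sp], width=0.004)
        # the buckets straddling either gap border are incomplete -> dropped
        for edge in bm.edges:
            assert not (edge < 1.0015 < edge + 0.004)
            assert not (edge < 2.0015 < edge + 0.004)

    def test_mixed_sample_types_rejected(self):
        a = make_spectrum(sample_type="serum")
        b = make_spectrum(sample_type="urine")
        with pytest.raises(ValueError, match="sample type"):
            pre.bucket_spectra([a, b])


class TestNormalization:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        edges = 0.5 + 0.004 * np.arange(values.shape[1])
        ids = [f"s{i}" for i in range(values.shape[0])]
        return pre.BucketMatrix(sample_ids=ids, sample_type="serum", edges=edges,
                                width=0.004, values=values)

    def test_total_area_example(self):
        out = pre.total_area_normalize(self._matrix([[1, 1, 2]]))
        np.testing.assert_allclose(out.values, [[25, 25, 50]])
        assert out.state == "total_area"

    def test_total_area_row_sums_100(self, default_study):
        plan = pre.default_exclusion_plan()
        sps = [pre.apply_exclusions(s, plan) for s in default_study.spectra["serum"][:4]]
        out = pre.total_area_normalize(pre.bucket_spectra(sps))
        np.testing.assert_allclose(out.values.sum(axis=1), 100.0, atol=1e-9)

    def test_total_area_row_already_100_unchanged(self):
        out = pre.total_area_normalize(self._matrix([[20, 30, 50]]))
        np.testing.assert_allclose(out.values, [[20, 30, 50]])

    def test_zero_row_raises_with_sample_name(self):
        with pytest.raises(ValueError, match="s1"):
            pre.total_area_normalize(self._matrix([[1, 2, 3], [0, 0, 0]]))

    def test_pqn_exact_double(self):
        m = pre.total_area_normalize(self._matrix([[1, 2, 3], [2, 4, 6], [1, 2, 3]]))
        # after total-area normalization the doubled row equals the others;
        # feed an explicitly scaled matrix through the quotient step instead
        m = pre.BucketMatrix(
            sample_ids=["a", "b"], sample_type="serum",
            edges=m.edges, width=0.004,
            values=np.array([[10.0, 20.0, 70.0], [20.0, 40.0, 140.0]]),
            state="total_area", area_factors=np.array([1.0, 1.0]),
        )
        out = pre.pqn_normalize(m, floor_quantile=0.0)
        assert out.quotients[1] / out.quotients[0] == pytest.approx(2.0)
        np.testing.assert_allclose(out.values[1], out.values[0])

    def test_pqn_median_robustness_example(self):
        m = pre.BucketMatrix(
            sample_ids=["a"], sample_type="serum",
            edges=np.array([0.5, 0.504, 0.508]), width=0.004,
            values=np.array([[1.0, 2.0, 4.5]]),
            state="total_area", area_factors=np.array([1.0]),
        )
        ref = np.array([1.0, 2.0, 3.0])
        # reference built from explicit rows: append the reference sample
        m2 = pre.BucketMatrix(
            sample_ids=["a", "ref"], sample_type="serum", edges=m.edges, width=0.004,
            values=np.vstack([m.values, ref]), state="total_area",
            area_factors=np.array([1.0, 1.0]),
        )
        out = pre.pqn_normalize(
            m2, groups=["x", "r"], reference_group="r", floor_quantile=0.0
        )
        # quotients {1, 1, 1.5} -> median 1 -> row unchanged
        assert out.quotients[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.values[0], [1.0, 2.0, 4.5])

    def test_pqn_idempotent(self, default_study):
        plan = pre.default_exclusion_plan()
        sps = [pre.apply_exclusions(s, plan) for s in default_study.spectra["urine"][:6]]
        m = pre.pqn_normalize(pre.total_area_normalize(pre.bucket_spectra(sps)))
        again = pre.pqn_normalize(m)
        np.testing.assert_allclose(again.values, m.values, atol=1e-9)

    def test_pqn_missing_reference_group_raises(self):
        m = pre.total_area_normalize(self._matrix([[1, 2, 3], [2, 3, 4]]))
        with pytest.raises(ValueError, match="absent"):
            pre.pqn_normalize(m, groups=["a", "a"], reference_group="control")

    def test_pqn_requires_total_area_state(self):
        with pytest.raises(ValueError, match="total_area"):
            pre.pqn_normalize(self._matrix([[1, 2, 3]]))

    def test_dilution_recovery_on_urine_like_samples(self):
        """PQN factors track the true per-sample dilution (effects off)."""
        study = syn.simulate_study(effects=[], seed=1)
        plan = pre.default_exclusion_plan()
        sps = [pre.apply_exclusions(s, plan) for s in study.spectra["urine"]]
        m = pre.pqn_normalize(pre.total_area_normalize(pre.bucket_spectra(sps)))
        true = study.dilution[m.sample_ids].to_numpy()
        r = np.corrcoef(m.dilution_estimates, true)[0, 1]
        assert r > 0.99
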