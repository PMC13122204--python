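"""Replicate QC, dCq/ddCq arithmetic, clustering, and sex calls."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from zdose.genotyping import (
    CqMeasurement,
    GenotypeConfig,
    NoMaleReferenceError,
    NoUsableReplicatesError,
    SexCall,
    TargetRole,
    call_sex,
    compute_delta_cq,
    genotype_cohort,
    normalize_ddcq,
    split_two_clusters,
    summarize_replicates,
)
from zdose.simulate import SimConfig, simulate_cohort


def _truth_map(truth):
    return dict(zip(truth.sample_id, truth.true_sex))


class TestCqMeasurement:
    def test_nan_becomes_missing(self):
        assert CqMeasurement("s", "sex", cq=float("nan")).cq is None

    @pytest.mark.parametrize("bad", [0.0, -1.0, 46.0, math.inf])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            CqMeasurement("s", "autosome", cq=bad)


class TestSummarizeReplicates:
    def test_identical_replicates(self):
        g = summarize_replicates([20.0, 20.0, 20.0, 20.0])
        assert (g.mean_cq, g.sem_cq, g.n_discarded) == (20.0, 0.0, 0)

    def test_single_pass_outlier_discard(self):
        # screening mean of all four is 20.5; only 22.0 deviates by >1
        g = summarize_replicates([20.0, 20.1, 19.9, 22.0])
        assert g.kept_cqs == (20.0, 20.1, 19.9)
        assert g.n_discarded == 1
        assert g.mean_cq == pytest.approx(20.0)
        # direct arithmetic: sd([20.0, 20.1, 19.9]) / sqrt(3)
        expected_sem = float(np.std([20.0, 20.1, 19.9], ddof=1) / np.sqrt(3))
        assert g.sem_cq == pytest.approx(expected_sem)
        assert g.sem_cq == pytest.approx(0.0577, abs=1e-4)

    def test_deviation_exactly_threshold_is_kept(self):
        # strict ">" comparison: deviations of exactly 1.0 survive
        g = summarize_replicates([19.0, 21.0])
        assert g.kept_cqs == (19.0, 21.0)
        assert g.n_discarded == 0

    def test_two_replicate_half_cycle_apart_both_kept(self):
        g = summarize_replicates([20.0, 21.0])
        assert g.n_discarded == 0 and g.mean_cq == pytest.approx(20.5)

    def test_missing_dropped_before_screening(self):
        g = summarize_replicates([None, 20.0, float("nan"), 20.2])
        assert g.raw_cqs == (20.0, 20.2)

    def test_empty_input_errors(self):
        with pytest.raises(NoUsableReplicatesError):
            summarize_replicates([])
        with pytest.raises(NoUsableReplicatesError):
            summarize_replicates([None, float("nan")])

    def test_single_survivor_is_low_confidence(self):
        g = summarize_replicates([20.0])
        assert g.sem_cq == 0.0
        assert g.low_confidence
        assert g.sem_for_repeat_rule == math.inf

    def test_pathological_spread_all_discarded(self):
        g = summarize_replicates([10.0, 30.0])
        assert g.n_kept == 0 and math.isnan(g.mean_cq)


class TestDeltaCq:
    def test_worked_example(self):
        a = summarize_replicates([21.25, 21.35], sample_id="x")
        s = summarize_replicates([22.23, 22.37], sample_id="x")
        delta, sem = compute_delta_cq(a, s)
        assert delta == pytest.approx(-1.0)
        assert sem == pytest.approx(a.sem_cq + s.sem_cq)

    def test_identical_groups_give_zero(self):
        g = summarize_replicates([20.0, 20.2, 19.8], sample_id="x")
        delta, _ = compute_delta_cq(g, g)
        assert delta == 0.0

    def test_mismatched_samples_error(self):
        a = summarize_replicates([20.0, 20.0], sample_id="a")
        b = summarize_replicates([20.0, 20.0], sample_id="b")
        with pytest.raises(ValueError, match="mismatch"):
            compute_delta_cq(a, b)


def _oracle_split(values):
    """Exhaustive sorted-split search with direct per-block arithmetic."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    xs = [values[i] for i in order]

    def ss(block):
        m = sum(block) / len(block)
        return sum((x - m) ** 2 for x in block)

    best_key, best_k = None, None
    for k in range(1, n):
        key = (ss(xs[:k]) + ss(xs[k:]), -(xs[k] - xs[k - 1]), k)
        if best_key is None or key < best_key:
            best_key, best_k = key, k
    return set(order[best_k:]), set(order[:best_k])


class TestSplitTwoClusters:
    def test_well_separated(self):
        split = split_two_clusters(
            [0.0, 0.02, -0.98, -1.0], ids=["a", "b", "c", "d"]
        )
        assert set(split.high_ids) == {"a", "b"}
        assert set(split.low_ids) == {"c", "d"}
        assert split.gap == pytest.approx(0.98)
        assert split.median_distance == pytest.approx(1.0)
        assert not split.unimodal

    def test_identical_values_flagged_unimodal(self):
        split = split_two_clusters([5.0, 5.0, 5.0, 5.0])
        assert split.gap == 0.0 and split.unimodal

    def test_fewer_than_two_samples_errors(self):
        with pytest.raises(ValueError, match="male standard"):
            split_two_clusters([0.5])

    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False, width=32), min_size=2, max_size=12
        )
    )
    def test_matches_exhaustive_oracle(self, values):
        values = [float(v) for v in values]
        split = split_two_clusters(values, ids=[str(i) for i in range(len(values))])
        high, low = _oracle_split(values)
        assert {int(i) for i in split.high_ids} == high
        assert {int(i) for i in split.low_ids} == low


class TestNormalizeAndCall:
    def test_cluster_median_normalisation(self):
        ddcqs = normalize_ddcq([0.5, 0.52, 0.48, -0.5], reference=0.5)
        assert ddcqs == pytest.approx([0.0, 0.02, -0.02, -1.0])

    def test_reference_maps_to_zero(self):
        assert normalize_ddcq([1.23], reference=1.23) == [0.0]

    @pytest.mark.parametrize(
        "ddcq,sem,expected",
        [
            (0.0, 0.1, SexCall.MALE),
            (-1.0, 0.1, SexCall.FEMALE),
            (-0.5, 0.0, SexCall.REPEAT),   # exactly at threshold
            (-0.5, 5.0, SexCall.REPEAT),
            (-0.42, 0.1, SexCall.REPEAT),  # |−0.42+0.5| = 0.08 < 0.1
            (-0.42, 0.05, SexCall.MALE),
            (-0.58, 0.05, SexCall.FEMALE),
            (0.3, math.inf, SexCall.REPEAT),
        ],
    )
    def test_call_sex(self, ddcq, sem, expected):
        assert call_sex(ddcq, sem) is expected

    @given(
        st.floats(-2, 1, allow_nan=False),
        st.floats(-2, 1, allow_nan=False),
        st.floats(0, 0.3, allow_nan=False),
    )
    def test_call_monotone_in_ddcq(self, d1, d2, sem):
        lo, hi = sorted([d1, d2])
        c_lo, c_hi = call_sex(lo, sem), call_sex(hi, sem)
        # increasing ddcq never flips male -> female
        assert not (c_lo is SexCall.MALE and c_hi is SexCall.FEMALE)


class TestGenotypeCohort:
    def test_noiseless_plate_fully_correct(self, noiseless_plate):
        wells, truth = noiseless_plate
        result = genotype_cohort(wells)
        truth_map = _truth_map(truth)
        assert all(
            result.calls[s].value == truth_map[s] for s in truth_map
        )
        males = [s.ddcq for s in result.samples if s.call is SexCall.MALE]
        females = [s.ddcq for s in result.samples if s.call is SexCall.FEMALE]
        assert float(np.median(males)) == 0.0
        assert float(np.median(females)) == pytest.approx(-1.0, abs=1e-12)

    def test_simulated_cohort_with_noise(self):
        config = SimConfig(n_male=40, n_female=41, noise_sd=0.12, seed=5)
        wells, truth = simulate_cohort(config)
        result = genotype_cohort(wells)
        truth_map = _truth_map(truth)
        assert all(result.calls[s].value == truth_map[s] for s in truth_map)

    def test_missing_role_reported_not_dropped(self):
        wells = [
            CqMeasurement("ok", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("ok", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("ok", TargetRole.SEX, cq=21.0),
            CqMeasurement("ok", TargetRole.SEX, cq=21.0),
            CqMeasurement("ok2", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("ok2", TargetRole.SEX, cq=20.0),
            CqMeasurement("half", TargetRole.AUTOSOME, cq=20.0),
        ]
        result = genotype_cohort(wells)
        assert "half" in result.excluded
        assert "missing target role" in result.excluded["half"]
        assert {s.sample_id for s in result.samples} == {"ok", "ok2"}

    def test_heavy_outlier_discard_still_called(self):
        # one sample loses 2 of 4 sex replicates to the screen but is called
        def sample(sid, auto, sex):
            return [
                CqMeasurement(sid, TargetRole.AUTOSOME, cq=c) for c in auto
            ] + [CqMeasurement(sid, TargetRole.SEX, cq=c) for c in sex]

        wells = (
            sample("m1", [20.0] * 4, [20.0] * 4)
            + sample("m2", [20.1] * 4, [20.1] * 4)
            + sample("f1", [20.0] * 4, [21.0] * 4)
            + sample("f2", [20.0] * 4, [21.0, 21.1, 24.0, 18.0])
        )
        result = genotype_cohort(wells)
        f2 = next(s for s in result.samples if s.sample_id == "f2")
        assert f2.call is SexCall.FEMALE
        assert any(f.startswith("low-replicate") for f in f2.flags)

    def test_single_surviving_replicate_forces_repeat(self):
        wells = [
            CqMeasurement("m", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("m", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("m", TargetRole.SEX, cq=20.0),
            CqMeasurement("m", TargetRole.SEX, cq=20.0),
            CqMeasurement("f", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("f", TargetRole.AUTOSOME, cq=20.0),
            CqMeasurement("f", TargetRole.SEX, cq=21.0),  # single well
        ]
        result = genotype_cohort(wells)
        f = next(s for s in result.samples if s.sample_id == "f")
        assert f.call is SexCall.REPEAT
        assert any(fl.startswith("low-confidence") for fl in f.flags)

    def test_all_female_batch_without_standard_errors(self):
        wells, _ = simulate_cohort(
            SimConfig(n_male=0, n_female=8, noise_sd=0.05, seed=2)
        )
        with pytest.raises(NoMaleReferenceError, match="male standard"):
            genotype_cohort(wells)

    def test_all_female_batch_with_male_standard(self):
        config = SimConfig(
            n_male=0, n_female=8, noise_sd=0.05, sample_offset_sd=0.0, seed=2
        )
        wells, _ = simulate_cohort(config)
        # a male of this run would have dCq = cq_ref(auto)-1 - (cq_ref(sex)-1)
        male_dcq = config.autosome.cq_ref - config.sex.cq_ref
        result = genotype_cohort(
            wells, GenotypeConfig(male_standard=male_dcq)
        )
        assert all(s.call is SexCall.FEMALE for s in result.samples)
        assert result.reference_used == "male_standard"


class TestPlateInvariances:
    def _plate(self, seed=0):
        return simulate_cohort(SimConfig(n_male=5, n_female=5, seed=seed))

    def test_global_cq_shift_leaves_results_unchanged(self):
        wells, _ = self._plate()
        shifted = [
            CqMeasurement(w.sample_id, w.target_role, w.well_id, w.cq + 3.25)
            for w in wells
        ]
        r1, r2 = genotype_cohort(wells), genotype_cohort(shifted)
        for s1, s2 in zip(r1.samples, r2.samples):
            assert s1.delta_cq == pytest.approx(s2.delta_cq, abs=1e-9)
            assert s1.ddcq == pytest.approx(s2.ddcq, abs=1e-9)
            assert s1.call is s2.call

    def test_per_sample_offset_cancels_in_delta_cq(self):
        # input-DNA amount shifts both targets of a sample identically
        wells, _ = self._plate(seed=3)
        rng = np.random.default_rng(0)
        offsets = {}
        shifted = []
        for w in wells:
            off = offsets.setdefault(w.sample_id, float(rng.uniform(-2, 2)))
            shifted.append(
                CqMeasurement(w.sample_id, w.target_role, w.well_id, w.cq + off)
            )
        r1, r2 = genotype_cohort(wells), genotype_cohort(shifted)
        for s1, s2 in zip(r1.samples, r2.samples):
            assert s1.delta_cq == pytest.approx(s2.delta_cq, abs=1e-9)

    def test_male_cluster_median_is_zero_after_normalisation(self):
        for seed in range(5):
            wells, _ = self._plate(seed=seed)
            result = genotype_cohort(wells)
            male_ddcqs = [
                s.ddcq
                for s in result.samples
                if s.sample_id in result.male_cluster_ids
            ]
            assert abs(float(np.median(male_ddcqs))) < 1e-12
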