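import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicdyn import (
    bin_genome,
    classify_differential,
    exp_strength,
    fold_change_to_ratio,
    gain_loss_profile,
    ratio_to_fold_change,
    relative_ratio,
    relative_ratio_matrix,
)
from hicdyn.differential import calls_to_frame
from conftest import make_zscores


class TestExpStrength:
    def test_sentinel_maps_to_zero(self):
        assert exp_strength(3.7, False) == 0.0
        assert exp_strength(0.0, False) == 0.0

    def test_observed_is_exponential(self):
        assert exp_strength(0.0, True) == 1.0
        assert exp_strength(math.log(2), True) == pytest.approx(2.0)


class TestRelativeRatio:
    @pytest.mark.parametrize(
        "fold, exact, printed",
        [(2, 2 / 3, 0.67), (5, 4 / 3, 1.33), (10, 18 / 11, 1.63)],
    )
    def test_fold_change_calibration(self, fold, exact, printed):
        # strengths (fold, 1): z1 = ln(fold), z0 = 0.  18/11 = 1.6363...
        # displays as 1.63 at truncated two-decimal precision
        r = relative_ratio(0.0, True, math.log(fold), True)
        assert r == pytest.approx(exact, rel=1e-12)
        assert math.floor(round(r, 9) * 100) / 100 == pytest.approx(printed, abs=0.011)

    def test_equal_strengths_give_zero(self):
        assert relative_ratio(1.3, True, 1.3, True) == 0.0

    def test_pure_gain_and_loss_saturate(self):
        assert relative_ratio(0.0, False, 2.4, True) == 2.0
        assert relative_ratio(2.4, True, 0.0, False) == -2.0
        assert relative_ratio(0.0, False, -1.0, True) == 2.0

    def test_both_unobserved_is_zero(self):
        assert relative_ratio(0.0, False, 0.0, False) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        z0=st.floats(-10, 10), z1=st.floats(-10, 10),
        o0=st.booleans(), o1=st.booleans(),
    )
    def test_bounded_and_antisymmetric(self, z0, z1, o0, o1):
        r = relative_ratio(z0, o0, z1, o1)
        assert abs(r) <= 2.0
        assert relative_ratio(z1, o1, z0, o0) == pytest.approx(-r, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(1e-3, 1e3))
    def test_monotone_closed_form_roundtrip(self, k):
        # 1e-12 relative recovery holds away from the saturation points,
        # where (2 - r) cancellation caps float64 accuracy
        r = fold_change_to_ratio(k)
        assert ratio_to_fold_change(r) == pytest.approx(k, rel=1e-12)
        # strictly increasing in fold change
        assert fold_change_to_ratio(k * 1.01) > r

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1e-8, 1e8))
    def test_roundtrip_wide_range(self, k):
        assert ratio_to_fold_change(fold_change_to_ratio(k)) == pytest.approx(k, rel=1e-8)


@pytest.fixture
def genome2c():
    return bin_genome([("c1", 30), ("c2", 20)], window=10)  # 3 + 2 bins


class TestClassify:
    def test_identical_conditions_empty(self, genome2c):
        z = make_zscores(genome2c, {(0, 1): 1.5, (0, 3): 2.0})
        assert classify_differential(z, z) == []

    def test_single_gain_intra_call(self, genome2c):
        z0 = make_zscores(genome2c, {})
        z1 = make_zscores(genome2c, {(0, 2): 1.5})
        calls = classify_differential(z0, z1)
        assert len(calls) == 1
        c = calls[0]
        assert (c.bin1, c.bin2) == (0, 2)
        assert c.call_type == "gain-intra" and c.ratio == 2.0
        assert c.z1 == 1.5

    def test_z_threshold_boundary(self, genome2c):
        z0 = make_zscores(genome2c, {})
        z1 = make_zscores(genome2c, {(0, 2): 0.5})
        assert classify_differential(z0, z1, z_cut=1.0) == []
        calls = classify_differential(z0, z1, z_cut=0.4)
        assert len(calls) == 1 and calls[0].kind == "gain"

    def test_loss_inter_call(self, genome2c):
        z0 = make_zscores(genome2c, {(1, 4): 1.2})
        z1 = make_zscores(genome2c, {})
        calls = classify_differential(z0, z1)
        assert [c.call_type for c in calls] == ["loss-inter"]
        assert calls[0].ratio == -2.0

    def test_relaxed_mode_drops_z_cut(self, genome2c):
        z0 = make_zscores(genome2c, {(0, 1): -0.5})
        z1 = make_zscores(genome2c, {(0, 1): 0.5})
        # fold change e^1 ~ 2.72 -> r ~ 0.924 >= 0.67, but |r| < 2
        assert classify_differential(z0, z1) == []
        calls = classify_differential(z0, z1, ratio_cut=0.67, mode="relaxed")
        assert len(calls) == 1 and calls[0].kind == "gain"

    def test_partition_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            genome = bin_genome([("c1", 100), ("c2", 70), ("c3", 30)], window=10)
            n = genome.n_bins  # 20 bins
            cells0 = {
                (i, j): float(rng.normal())
                for i in range(n) for j in range(i, n) if rng.random() < 0.3
            }
            cells1 = {
                (i, j): float(rng.normal())
                for i in range(n) for j in range(i, n) if rng.random() < 0.3
            }
            z0 = make_zscores(genome, cells0)
            z1 = make_zscores(genome, cells1)
            for cut, z_cut, mode in ((2.0, 1.0, "strict"), (0.67, 1.0, "relaxed")):
                calls = classify_differential(z0, z1, ratio_cut=cut, z_cut=z_cut, mode=mode)
                got = {(c.bin1, c.bin2): c.call_type for c in calls}
                # brute force over every unordered cell
                cid = genome.chrom_ids()
                want = {}
                for i in range(n):
                    for j in range(i, n):
                        o0, o1 = (i, j) in cells0, (i, j) in cells1
                        e0 = math.exp(cells0[(i, j)]) if o0 else 0.0
                        e1 = math.exp(cells1[(i, j)]) if o1 else 0.0
                        if e0 == e1 == 0:
                            continue
                        r = (e1 - e0) / ((e1 + e0) / 2)
                        if abs(r) < cut - 1e-12:
                            continue
                        if mode == "strict":
                            zs = [v for v, o in ((cells0.get((i, j)), o0), (cells1.get((i, j)), o1)) if o]
                            if max(zs) <= z_cut:
                                continue
                        kind = "gain" if r > 0 else "loss"
                        span = "intra" if cid[i] == cid[j] else "inter"
                        want[(i, j)] = f"{kind}-{span}"
                assert got == want
                # a partition: no cell typed twice
                assert len(got) == len(calls)

    def test_ratio_matrix_antisymmetric_under_condition_swap(self, genome2c):
        rng = np.random.default_rng(4)
        cells0 = {(0, 1): 0.3, (1, 2): -1.0, (0, 3): 0.9}
        cells1 = {(0, 1): 1.3, (2, 4): 0.2}
        z0, z1 = make_zscores(genome2c, cells0), make_zscores(genome2c, cells1)
        fwd = relative_ratio_matrix(z0, z1)
        rev = relative_ratio_matrix(z1, z0)
        assert np.allclose(fwd.r, -rev.r)
        assert np.array_equal(fwd.excluded, rev.excluded)
        assert fwd.excluded[3, 4] and not fwd.excluded[0, 1]


class TestGainLossProfile:
    def test_empty_calls_zero_profile(self, genome2c):
        prof = gain_loss_profile([], genome2c)
        assert (prof["gains"] == 0).all() and (prof["losses"] == 0).all()

    def test_shared_bin_counts(self, genome2c):
        z0 = make_zscores(genome2c, {(3, 4): 1.4})
        z1 = make_zscores(genome2c, {(0, 2): 1.5, (1, 2): 1.2})
        calls = classify_differential(z0, z1)
        prof = gain_loss_profile(calls, genome2c)
        # two gains share bin 2; one loss on bins 3 and 4
        assert prof["gains"].tolist() == [1, 1, 2, 0, 0]
        assert prof["losses"].tolist() == [0, 0, 0, -1, -1]

    def test_within_bin_call_increments_once(self, genome2c):
        z0 = make_zscores(genome2c, {})
        z1 = make_zscores(genome2c, {(1, 1): 1.5})
        prof = gain_loss_profile(classify_differential(z0, z1), genome2c)
        assert prof["gains"].tolist() == [0, 1, 0, 0, 0]


def test_calls_frame_prints_two_decimal_ratios(genome2c):
    z0 = make_zscores(genome2c, {})
    z1 = make_zscores(genome2c, {(0, 1): 1.5})
    df = calls_to_frame(classify_differential(z0, z1), genome2c)
    assert df.loc[0, "relative_ratio"] == 2.0
    assert df.loc[0, ["chrom1", "start1", "end1"]].tolist() == ["c1", 1, 10]
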