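import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from acylscan import (
    ImputationConfig,
    SimConfig,
    Thresholds,
    bh_adjust,
    call_prey,
    differential_table,
    fold_change,
    impute_missing,
    simulate_experiment,
    welch_one_tailed_greater,
)
from acylscan.differential import FLAG_CONTROL_ALL_MISSING, FLAG_OK


class TestFoldChange:
    def test_simple_ratio(self):
        fc, flag = fold_change([4, 4, 4], [2, 2, 2, 2])
        assert fc == 2.0 and flag == FLAG_OK

    def test_identical_means_give_one(self):
        fc, _ = fold_change([3, 5], [4, 4])
        assert fc == 1.0

    def test_all_missing_control_floored(self):
        fc, flag = fold_change([10, 10], [0, 0, 0], denominator_floor=2.0)
        assert fc == 5.0 and flag == FLAG_CONTROL_ALL_MISSING

    def test_empty_bait_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1, 2])

    def test_zero_control_without_floor_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0], [0.0, 0.0])


class TestWelchOneTailed:
    def test_separated_samples(self):
        """bait {10,12,14} vs control {1,2,3}: Welch formulas give t = 7.746,
        df = 2.94, upper-tail p ~ 0.0024."""
        t, df, p = welch_one_tailed_greater([10, 12, 14], [1, 2, 3])
        assert t == pytest.approx(7.74597, abs=1e-4)
        assert df == pytest.approx(2.94118, abs=1e-4)
        assert p == pytest.approx(0.0023990, abs=1e-6)

    def test_identical_samples_give_half(self):
        t, _, p = welch_one_tailed_greater([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_swap_antisymmetry(self):
        x, y = [5.0, 7.0, 6.0], [1.0, 2.0, 1.5]
        t1, _, p1 = welch_one_tailed_greater(x, y)
        t2, _, p2 = welch_one_tailed_greater(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(1.0 - p1)

    def test_zero_variance_conventions(self):
        assert welch_one_tailed_greater([2.0, 2.0], [2.0, 2.0])[2] == 0.5
        assert welch_one_tailed_greater([3.0, 3.0], [2.0, 2.0])[2] == 0.0
        assert welch_one_tailed_greater([1.0, 1.0], [2.0, 2.0])[2] == 1.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            welch_one_tailed_greater([1.0], [1.0, 2.0])

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(2, 8))
            y = rng.normal(0, rng.uniform(0.5, 3), rng.integers(2, 8))
            t, df, p = welch_one_tailed_greater(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)


def brute_force_bh(p):
    """Literal step-up definition: adj_(i) = min_{j >= i} p_(j) * m / j, capped."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBHAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestDifferentialTable:
    def test_absent_protein_gets_adj_p_one(self, small_sim):
        (matrix, truth), config = small_sim
        imputed = impute_missing(matrix, ImputationConfig(seed=0))
        diff = differential_table(imputed)
        untested = diff[~diff["tested"]]
        assert len(untested) > 0
        assert (untested["adj_p"] == 1.0).all()
        assert untested["p_value"].isna().all()
        # and those proteins really are absent from that bait pre-imputation
        row = untested.iloc[0]
        detected = imputed.detected_in_condition(row["bait"])
        assert not detected[row["protein"]]

    def test_bh_family_is_per_bait(self, small_sim):
        (matrix, _), _ = small_sim
        imputed = impute_missing(matrix, ImputationConfig(seed=0))
        diff = differential_table(imputed)
        bait = matrix.baits[0]
        sub = diff[(diff["bait"] == bait) & diff["tested"]]
        np.testing.assert_allclose(
            sub["adj_p"].to_numpy(), bh_adjust(sub["p_value"].to_numpy()), atol=1e-12
        )

    def test_spiked_prey_recovered(self):
        """A strong prey effect (log2fc = 3) at low noise yields fc >= 2 and a
        small adjusted P for essentially all true prey."""
        config = SimConfig(
            n_proteins=300,
            baits=("A",),
            noise_sd_log2=0.1,
            prey_fraction=0.1,
            prey_log2fc_mean=3.0,
            prey_log2fc_sd=0.0,
            shared_prey_fraction=1.0,
            short_rep_bait=None,
            censor_midpoint_log2=-1e6,
            seed=21,
        )
        matrix, truth = simulate_experiment(config)
        imputed = impute_missing(matrix, ImputationConfig(seed=0))
        diff = differential_table(imputed)
        prey_rows = diff[diff["protein"].isin(truth.prey_of("A"))]
        assert (prey_rows["fc"] >= 2).mean() == 1.0
        assert (prey_rows["adj_p"] <= 0.1).mean() >= 0.95

    def test_unknown_control_label_rejected(self, small_sim):
        (matrix, _), _ = small_sim
        imputed = impute_missing(matrix, ImputationConfig(seed=0))
        with pytest.raises(KeyError):
            differential_table(imputed, control_label="NOPE")


class TestCallPrey:
    def _rows(self, records):
        return pd.DataFrame(records, columns=["protein", "bait", "fc", "adj_p"])

    def test_inclusive_boundaries(self):
        rows = self._rows(
            [("P1", "A", 2.0, 0.1), ("P2", "A", 1.999, 0.001), ("P3", "A", 5.0, 0.100001)]
        )
        membership, gate, universe = call_prey(rows, Thresholds())
        assert membership["A"] == {"P1", "P3"}  # fc >= 2 inclusive
        assert gate == {"P1", "P2"}  # adj_p <= 0.1 inclusive
        assert universe == {"P1"}

    def test_high_fc_without_gate_excluded(self):
        rows = self._rows([("P1", "A", 10.0, 0.5), ("P1", "B", 10.0, 0.2)])
        _, _, universe = call_prey(rows, Thresholds())
        assert universe == set()

    def test_gate_from_any_bait_suffices(self):
        rows = self._rows([("P1", "A", 3.0, 0.9), ("P1", "B", 1.0, 0.05)])
        membership, gate, universe = call_prey(rows, Thresholds())
        assert universe == {"P1"}
        assert membership["B"] == set()
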