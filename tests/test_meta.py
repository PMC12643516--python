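"""Normalization, batch adjustment, moderated t, and Fisher combination."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernascout.datasets import FormatError
from cernascout import meta as cmeta

from conftest import make_dataset


def chi2_upper_tail_2k(x2: float, k: int) -> float:
    """Closed-form chi-square survival function with even df = 2k."""
    return math.exp(-x2 / 2) * sum((x2 / 2) ** i / math.factorial(i) for i in range(k))


class TestQuantileNormalize:
    def test_two_column_hand_computation(self):
        ds = make_dataset(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), n_control=1)
        out = cmeta.quantile_normalize(ds)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_identical_columns_fixed_point(self, rng):
        col = rng.normal(size=20)
        ds = make_dataset(np.column_stack([col, col, col]), n_control=1)
        out = cmeta.quantile_normalize(ds)
        np.testing.assert_allclose(out.values.to_numpy(), ds.values.to_numpy())

    def test_single_column_unchanged(self, rng):
        ds = make_dataset(rng.normal(size=(10, 1)), n_control=0)
        out = cmeta.quantile_normalize(ds)
        np.testing.assert_array_equal(out.values.to_numpy(), ds.values.to_numpy())

    def test_idempotent(self, rng):
        ds = make_dataset(rng.normal(size=(30, 6)), n_control=3)
        once = cmeta.quantile_normalize(ds)
        twice = cmeta.quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(),
                                   atol=1e-12)

    def test_masked_values_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0]])
        ds = make_dataset(values, n_control=1)
        with pytest.raises(FormatError, match="masked"):
            cmeta.quantile_normalize(ds)

    def test_all_columns_share_reference_distribution(self, rng):
        ds = make_dataset(rng.normal(size=(50, 5)), n_control=2)
        out = cmeta.quantile_normalize(ds).values.to_numpy()
        ref = np.sort(out[:, 0])
        for col in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, col]), ref, atol=1e-12)


class TestCombat:
    @staticmethod
    def _batched(values, n_control, batch_labels):
        ds = make_dataset(values, n_control=n_control)
        return ds, pd.Series(batch_labels, index=ds.sample_ids)

    def test_noiseless_location_only_shift_removed(self, rng):
        # noiseless: per-feature baseline + group effect; batch 2 adds a
        # per-feature constant shift, which adjustment must remove exactly
        mu = rng.normal(size=(20, 1))
        alpha = rng.normal(size=(20, 1))
        shift = rng.normal(size=(20, 1)) * 3
        case = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        batch1 = mu + alpha * case
        values = np.concatenate([batch1, batch1 + shift], axis=1)
        group = (["control"] * 4 + ["case"] * 4) * 2
        ds = make_dataset(values, n_control=0)
        ds.group[:] = group
        batch = pd.Series(["b1"] * 8 + ["b2"] * 8, index=ds.sample_ids)
        out = cmeta.combat_adjust(ds, batch).values.to_numpy()
        np.testing.assert_allclose(out[:, :8], out[:, 8:], atol=1e-6)
        # the group effect survives adjustment
        diff = out[:, 4:8].mean(axis=1) - out[:, :4].mean(axis=1)
        np.testing.assert_allclose(diff, alpha[:, 0], atol=1e-6)

    def test_single_batch_identity(self, rng):
        ds, batch = self._batched(rng.normal(size=(10, 6)), 3, ["b"] * 6)
        out = cmeta.combat_adjust(ds, batch)
        np.testing.assert_array_equal(out.values.to_numpy(), ds.values.to_numpy())

    def test_confounded_batch_rejected(self, rng):
        ds, batch = self._batched(rng.normal(size=(10, 6)), 3, ["b1"] * 3 + ["b2"] * 3)
        with pytest.raises(FormatError, match="confounded"):
            cmeta.combat_adjust(ds, batch)

    def test_simulated_shift_attenuated(self):
        # 2 batches, sigma=1, additive shift 2: residual between-batch
        # mean difference should be near zero after adjustment
        residuals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(50, 40))
            x[:, 20:] += 2.0
            group = (["control"] * 10 + ["case"] * 10) * 2
            ds = make_dataset(x, n_control=0)
            ds.group[:] = group
            batch = pd.Series(["b1"] * 20 + ["b2"] * 20, index=ds.sample_ids)
            out = cmeta.combat_adjust(ds, batch).values.to_numpy()
            diff = out[:, :20].mean(axis=1) - out[:, 20:].mean(axis=1)
            residuals.append(abs(diff.mean()))
        assert np.mean(residuals) < 0.1


class TestModeratedT:
    def test_single_feature_equals_ordinary_pooled_t(self, rng):
        x = rng.normal(size=(1, 12))
        ds = make_dataset(x, n_control=6)
        res = cmeta.moderated_t(ds)
        t_ref, _ = stats.ttest_ind(x[0, 6:], x[0, :6], equal_var=True)
        assert res.table["t_mod"].iloc[0] == pytest.approx(t_ref, rel=1e-10)

    def test_zero_logfc_gives_zero_t_and_p_one(self, rng):
        x = rng.normal(size=(5, 10))
        x[0, 5:] = x[0, :5]  # identical case values -> logFC 0
        ds = make_dataset(x, n_control=5)
        res = cmeta.moderated_t(ds)
        assert res.table["t_mod"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_sign_consistency_and_p_bounds(self, rng):
        ds = make_dataset(rng.normal(size=(100, 16)), n_control=8)
        table = cmeta.moderated_t(ds).table
        nonzero = table["logFC"] != 0
        assert (np.sign(table.loc[nonzero, "t_mod"])
                == np.sign(table.loc[nonzero, "logFC"])).all()
        assert table["p"].between(0, 1).all()
        assert (table["p_adj"] >= table["p"] - 1e-15).all()

    def test_shrinkage_interpolates_between_limits(self, rng):
        x = rng.normal(size=(50, 12))
        ds = make_dataset(x, n_control=6)
        ordinary = cmeta.moderated_t(ds, d0_override=1e-9).table["t_mod"]
        heavy = cmeta.moderated_t(ds, d0_override=1e9).table["t_mod"]
        mid = cmeta.moderated_t(ds, d0_override=4.0).table["t_mod"]
        t_ref = stats.ttest_ind(x[:, 6:], x[:, :6], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(ordinary, t_ref, rtol=1e-6)
        # |t| with intermediate prior df lies between the two limits
        lo = np.minimum(np.abs(ordinary), np.abs(heavy))
        hi = np.maximum(np.abs(ordinary), np.abs(heavy))
        assert ((np.abs(mid) >= lo - 1e-9) & (np.abs(mid) <= hi + 1e-9)).all()

    def test_zero_variance_everywhere_rejected(self):
        ds = make_dataset(np.ones((3, 8)), n_control=4)
        with pytest.raises(FormatError, match="variance"):
            cmeta.moderated_t(ds)


class TestFisherCombine:
    def test_single_p_of_one(self):
        x2, k, p = cmeta.fisher_combine([1.0])
        assert (x2, k, p) == (0.0, 1, 1.0)

    def test_two_p05_matches_closed_form(self):
        x2, k, p = cmeta.fisher_combine([0.05, 0.05])
        assert x2 == pytest.approx(-4 * math.log(0.05), rel=1e-12)
        assert p == pytest.approx(chi2_upper_tail_2k(x2, 2), rel=1e-10)
        assert p == pytest.approx(0.01747, abs=5e-5)

    def test_k1_identity(self, rng):
        for p_in in rng.uniform(0.001, 1.0, size=10):
            _, _, p_out = cmeta.fisher_combine([p_in])
            assert p_out == pytest.approx(p_in, rel=1e-10)

    def test_monotone_in_inputs(self):
        _, _, p_base = cmeta.fisher_combine([0.2, 0.3, 0.4])
        _, _, p_lower = cmeta.fisher_combine([0.1, 0.3, 0.4])
        assert p_lower < p_base

    def test_zero_clamped(self):
        x2, _, p = cmeta.fisher_combine([0.0, 0.5])
        assert np.isfinite(x2) and 0 <= p <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cmeta.fisher_combine([])

    def test_matches_closed_form_oracle_random_battery(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 6))
            ps = rng.uniform(1e-6, 1.0, size=k)
            x2, k_out, p = cmeta.fisher_combine(list(ps))
            assert x2 == pytest.approx(-2 * np.log(ps).sum(), rel=1e-12)
            assert p == pytest.approx(chi2_upper_tail_2k(x2, k), rel=1e-10)


class TestCombinedT:
    def test_plain_sum(self):
        t, direction = cmeta.combined_t([3.0, -1.0])
        assert (t, direction) == (2.0, 1)

    def test_zero_sum_zero_direction(self):
        assert cmeta.combined_t([0.0]) == (0.0, 0)

    def test_permutation_invariant(self, rng):
        vals = list(rng.normal(size=8))
        t1, _ = cmeta.combined_t(vals)
        t2, _ = cmeta.combined_t(list(reversed(vals)))
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestRunMeta:
    def test_single_cohort_reduces_to_de_result(self, rng):
        ds = make_dataset(rng.normal(size=(30, 12)), n_control=6)
        table = cmeta.run_meta([ds])
        de = cmeta.moderated_t(cmeta.preprocess(ds)).table
        np.testing.assert_allclose(table["p_comb"], de.loc[table.index, "p"], rtol=1e-10)
        np.testing.assert_allclose(table["T_comb"], de.loc[table.index, "t_mod"], rtol=1e-10)
        assert (table["k"] == 1).all()

    def test_combine_on_adjusted_p_is_more_conservative(self, rng):
        cohorts = [make_dataset(rng.normal(size=(40, 10)), n_control=5,
                                cohort_id=f"c{i}") for i in range(2)]
        raw = cmeta.run_meta(cohorts, combine_on="p")
        adj = cmeta.run_meta(cohorts, combine_on="p_adj")
        assert (adj["p_comb"] >= raw["p_comb"] - 1e-12).all()

    def test_planted_effects_detected_and_signed(self, rng):
        # 8 cohorts, delta=1 on the first 20 of 200 features
        cohorts = []
        for i in range(8):
            x = rng.normal(size=(200, 40))
            x[:20, 20:] += 1.0
            cohorts.append(make_dataset(x, n_control=20, cohort_id=f"c{i}"))
        table = cmeta.run_meta(cohorts, alpha=0.05)
        planted = table.iloc[:20] if table.index[0].endswith("000") else table.loc[
            [f"mRNA:F{i:03d}" for i in range(20)]
        ]
        assert planted["significant"].mean() >= 0.95
        assert (planted["direction"] == 1).all()

    def test_no_overlap_rejected(self, rng):
        a = make_dataset(rng.normal(size=(5, 8)), n_control=4,
                         feature_ids=[f"a{i}" for i in range(5)], cohort_id="a")
        b = make_dataset(rng.normal(size=(5, 8)), n_control=4,
                         feature_ids=[f"b{i}" for i in range(5)], cohort_id="b")
        with pytest.raises(FormatError, match="overlap"):
            cmeta.run_meta([a, b])


class TestBhAdjust:
    def test_hand_step_up(self):
        from cernascout.enrichment import bh_adjust

        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_q_monotone_in_p_rank_and_geq_p(self, rng):
        from cernascout.enrichment import bh_adjust

        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_single_p_unchanged(self):
        from cernascout.enrichment import bh_adjust

        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
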