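"""Shuffle significance of comparison loadings, activation reconstruction,
and inter-structure dependencies."""

import numpy as np
import pytest

from latnets import structure_inference as si
from latnets import tensor_factorization as tf
from latnets.causality_normalization import build_comparisons
from latnets.structure_inference import LoadingSignificance
from latnets.types import TRIAL_TYPES


def _planted_model_and_tensor(rank=3, seed=0, noise=0.02):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((18, rank))
    b = np.abs(rng.standard_normal((30, rank)))
    c = np.abs(rng.standard_normal((40, rank)))
    t = np.einsum("ir,jr,kr->ijk", a, b, c)
    t += noise * np.linalg.norm(t) / np.sqrt(t.size) * rng.standard_normal(t.shape)
    model = tf.parafac(t, rank, n_restarts=6, seed=seed)
    return model, t


class TestRefitMode0:
    def test_fixed_point_reproduces_model_loadings(self):
        model, t = _planted_model_and_tensor()
        refit = si.refit_mode0(t, model)
        np.testing.assert_allclose(refit, model.mode0, atol=1e-6)


class TestLoadingSignificance:
    def test_exchangeable_null_flag_rate_matches_alpha_floor(self):
        """With labels carrying no information the observed tensor is
        exchangeable with the shuffles, so the two-sided empirical-quantile
        flag rate equals its nominal level (~2/(n+1) per tail pair at
        n = 50 shuffles, i.e. ≈ 3.9%)."""
        model, _ = _planted_model_and_tensor(rank=2, seed=1)
        rng0 = np.random.default_rng(42)

        def builder(rng):
            # label-noise surrogate: every build (observed included) draws
            # from the same distribution
            return np.einsum(
                "ir,jr,kr->ijk",
                rng.standard_normal((18, 2)),
                model.mode1,
                model.mode2,
            ) + 0.1 * rng.standard_normal((18, 30, 40))

        flags = []
        for rep in range(40):
            obs = builder(np.random.default_rng(1000 + rep))
            sig = si.loading_significance(
                builder, obs, model, n_shuffles=50, seed=rep
            )
            flags.append(sig.significant.mean())
        rate = float(np.mean(flags))
        nominal = 2 * np.floor(51 * 0.025) / 51  # achievable two-sided level
        se = np.std(flags) / np.sqrt(len(flags))
        assert abs(rate - nominal) < max(3 * se, 0.015)

    def test_planted_shift_is_flagged(self):
        model, t = _planted_model_and_tensor(rank=2, seed=3)
        rng_obs = np.random.default_rng(0)

        def builder(rng):
            return t + 0.01 * rng.standard_normal(t.shape)

        shifted = t.copy()
        # boost one comparison row far outside the null spread
        shifted[4] += 10 * np.abs(t).max()
        sig = si.loading_significance(builder, shifted, model, n_shuffles=40, seed=0)
        assert sig.significant[4].any()

    def test_too_few_shuffles_warns(self):
        model, t = _planted_model_and_tensor(rank=2, seed=4)
        with pytest.warns(UserWarning, match="shuffles"):
            si.loading_significance(
                lambda rng: t, t, model, n_shuffles=5, alpha=0.05, seed=0
            )


def _sig(observed, significant_keys, alpha=0.05):
    specs = build_comparisons()
    obs = np.zeros((18, 1))
    flags = np.zeros((18, 1), dtype=bool)
    for key, val in observed.items():
        idx = next(i for i, sp in enumerate(specs) if sp.key == key)
        obs[idx, 0] = val
        flags[idx, 0] = key in significant_keys
    return LoadingSignificance(
        observed=obs,
        null_loadings=np.zeros((1, 18, 1)),
        significant=flags,
        alpha=alpha,
        comparisons=specs,
    )


class TestReconstructActivation:
    def test_single_difference_splits_evenly(self):
        sig = _sig({"ChRf-CmRf:Cplus": 1.0}, {"ChRf-CmRf:Cplus"})
        levels = si.reconstruct_activation(sig)["Cplus"][:, 0]
        lv = dict(zip(TRIAL_TYPES, levels))
        assert lv["ChRf"] == pytest.approx(0.5)
        assert lv["CmRf"] == pytest.approx(-0.5)
        assert sum(abs(v) for t, v in lv.items() if t not in ("ChRf", "CmRf")) == 0

    def test_consistent_cycle_reproduced_exactly(self):
        vals = {"ChRf-CmRf:Cplus": 1.0, "CmRf-CwRf:Cplus": -1.0, "CwRf-ChRf:Cplus": 0.0}
        sig = _sig(vals, set(vals))
        levels = si.reconstruct_activation(sig)["Cplus"][:, 0]
        lv = dict(zip(TRIAL_TYPES, levels))
        assert lv["ChRf"] - lv["CmRf"] == pytest.approx(1.0)
        assert lv["CmRf"] - lv["CwRf"] == pytest.approx(-1.0)
        assert lv["CwRf"] - lv["ChRf"] == pytest.approx(0.0)

    def test_inconsistent_cycle_least_squares_compromise(self):
        vals = {"ChRf-CmRf:Cplus": 1.0, "CmRf-CwRf:Cplus": 1.0, "CwRf-ChRf:Cplus": 1.0}
        sig = _sig(vals, set(vals))
        levels = si.reconstruct_activation(sig)["Cplus"][:, 0]
        lv = dict(zip(TRIAL_TYPES, levels))
        resid = (
            (lv["ChRf"] - lv["CmRf"] - 1) ** 2
            + (lv["CmRf"] - lv["CwRf"] - 1) ** 2
            + (lv["CwRf"] - lv["ChRf"] - 1) ** 2
        )
        # brute-force oracle over a fine grid of the two free differences
        grid = np.linspace(-2, 2, 161)
        best = np.inf
        for d1 in grid:  # ChRf - CmRf
            for d2 in grid:  # CmRf - CwRf
                r = (d1 - 1) ** 2 + (d2 - 1) ** 2 + (-d1 - d2 - 1) ** 2
                best = min(best, r)
        assert resid == pytest.approx(best, abs=1e-6)

    def test_scale_equivariance(self):
        vals = {"ChRf-CmRf:Cplus": 1.0, "ChRf-ChRn:Cplus": 2.0}
        sig1 = _sig(vals, set(vals))
        sig2 = _sig({k: 2 * v for k, v in vals.items()}, set(vals))
        l1 = si.reconstruct_activation(sig1)["Cplus"]
        l2 = si.reconstruct_activation(sig2)["Cplus"]
        np.testing.assert_allclose(l2, 2 * l1, atol=1e-10)

    def test_no_significant_comparisons_gives_zeros(self):
        sig = _sig({"ChRf-CmRf:Cplus": 3.0}, set())
        for levels in si.reconstruct_activation(sig).values():
            np.testing.assert_array_equal(levels, 0.0)

    def test_levels_are_mean_zero_over_involved_types(self):
        vals = {"ChRf-CmRf:Cplus": 1.7, "CmRf-CwRf:Cplus": 0.4}
        sig = _sig(vals, set(vals))
        levels = si.reconstruct_activation(sig)["Cplus"][:, 0]
        assert levels.sum() == pytest.approx(0.0, abs=1e-10)


class TestInterdependency:
    def _model(self, mode0):
        r = mode0.shape[1]
        return tf.ParafacModel(
            mode0=mode0,
            mode1=np.abs(np.random.default_rng(0).standard_normal((10, r))),
            mode2=np.abs(np.random.default_rng(1).standard_normal((12, r))),
            fit_percent=100.0,
        )

    def test_identical_structures_fully_correlated(self):
        rng = np.random.default_rng(5)
        col = rng.standard_normal(18)
        model = self._model(np.column_stack([col, col]))
        out = si.interdependency(model)
        for fam in out.values():
            assert fam["correlation"][0, 1] == pytest.approx(1.0)

    def test_sign_flipped_structures_anticorrelated(self):
        rng = np.random.default_rng(6)
        col = rng.standard_normal(18)
        model = self._model(np.column_stack([col, -col]))
        out = si.interdependency(model)
        for fam in out.values():
            assert fam["correlation"][0, 1] == pytest.approx(-1.0)

    def test_null_calibration_of_p_values(self):
        """Independent loadings: p < 0.05 occurs at roughly the nominal
        rate over replicates (n = 6 points per correlation)."""
        rng = np.random.default_rng(7)
        hits, total = 0, 0
        for _ in range(300):
            model = self._model(rng.standard_normal((18, 2)))
            out = si.interdependency(model)
            for fam in out.values():
                hits += out["response"]["p_values"][0, 1] < 0.05
                total += 1
                break
        rate = hits / total
        assert 0.01 < rate < 0.10

    def test_single_structure_rejected(self):
        model = self._model(np.random.default_rng(8).standard_normal((18, 1)))
        with pytest.raises(ValueError):
            si.interdependency(model)
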