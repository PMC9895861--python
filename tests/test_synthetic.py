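"""Gaussian-copula generator: thresholds, calibration, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symptomnet import (
    CopulaSpec,
    MarginalTarget,
    clustered_latent_corr,
    calibrated_spec,
    default_instrument,
    generate_responses,
    marginal_to_categories,
    nearest_psd,
    plant_hub,
    thresholds_from_marginals,
)
from symptomnet.errors import (
    InfeasibleMarginalError,
    InvalidDesignError,
    InvalidMarginalError,
    MissingItemError,
    NotPositiveSemidefiniteError,
)

from oracles import spearman_oracle


def _uniform_spec(n, p, corr=None, seed=0):
    R = np.eye(p) if corr is None else corr
    P = np.full((p, 4), 0.25)
    return CopulaSpec(n_participants=n, latent_corr=R, category_probs=P, seed=seed)


# ---------------------------------------------------------------------------
# thresholds_from_marginals
# ---------------------------------------------------------------------------

class TestThresholds:
    def test_uniform_marginal_is_symmetric(self):
        # quantiles of 0.25 / 0.50 / 0.75; middle cutpoint exactly zero
        cuts = thresholds_from_marginals((0.25, 0.25, 0.25, 0.25))
        assert cuts[1] == 0.0
        # frozen from statistics.NormalDist().inv_cdf (independent oracle)
        np.testing.assert_allclose(
            cuts, [-0.6744897502, 0.0, 0.6744897502], atol=1e-9
        )

    def test_degenerate_all_zero_scores(self):
        cuts = thresholds_from_marginals((1.0, 0.0, 0.0, 0.0))
        assert np.all(np.isinf(cuts)) and np.all(cuts > 0)
        spec = CopulaSpec(50, np.eye(1), np.array([[1.0, 0, 0, 0]]), seed=3)
        assert (generate_responses(spec).to_numpy() == 0).all()

    def test_general_marginal_matches_quantile_oracle(self):
        # frozen from statistics.NormalDist().inv_cdf at 0.288, 0.600, 0.850
        cuts = thresholds_from_marginals((0.288, 0.312, 0.25, 0.15))
        np.testing.assert_allclose(
            cuts, [-0.5592369776, 0.2533471031, 1.0364333895], atol=1e-9
        )
        assert np.all(np.diff(cuts) >= 0)

    def test_zero_probability_category_gives_coincident_cutpoints(self):
        cuts = thresholds_from_marginals((0.5, 0.0, 0.3, 0.2))
        assert cuts[0] == cuts[1]

    @pytest.mark.parametrize(
        "probs", [(-0.1, 0.5, 0.3, 0.3), (0.3, 0.3, 0.3, 0.3), (0.2, 0.2, 0.2, 0.2)]
    )
    def test_invalid_marginals_rejected(self, probs):
        with pytest.raises(InvalidMarginalError):
            thresholds_from_marginals(probs)


# ---------------------------------------------------------------------------
# marginal_to_categories
# ---------------------------------------------------------------------------

class TestMarginalCalibration:
    def test_all_zero_item(self):
        np.testing.assert_allclose(
            marginal_to_categories(MarginalTarget(0.0, 0.0)), [1, 0, 0, 0]
        )

    def test_saturated_item(self):
        np.testing.assert_allclose(
            marginal_to_categories(MarginalTarget(100.0, 3.0)), [0, 0, 0, 1]
        )

    def test_published_target_satisfies_both_moments(self):
        # prevalence 64.0%, mean severity 1.07
        p = marginal_to_categories(MarginalTarget(64.0, 1.07))
        assert np.all(p >= 0) and np.isclose(p.sum(), 1.0, atol=1e-12)
        assert np.isclose(100.0 * (1.0 - p[0]), 64.0, atol=1e-9)
        assert np.isclose(p[1] + 2 * p[2] + 3 * p[3], 1.07, atol=1e-9)
        # documented allocation rule: geometric positive-mass split
        assert np.isclose(p[2] ** 2, p[1] * p[3], atol=1e-12)

    def test_grid_search_oracle_confirms_feasibility_region(self):
        # brute-force enumeration over a probability grid: solutions matching
        # both moments exist for the published target and the implementation's
        # answer lies inside the enumerated feasible hull
        target = MarginalTarget(64.0, 1.07)
        s = 0.64
        feasible = []
        grid = np.linspace(0.0, s, 321)
        for p1 in grid:
            for p2 in grid:
                p3 = s - p1 - p2
                if p3 < -1e-12:
                    continue
                p3 = max(p3, 0.0)
                if abs(p1 + 2 * p2 + 3 * p3 - 1.07) < 2e-3:
                    feasible.append((p1, p2, p3))
        assert feasible, "grid oracle found no solution for a feasible target"
        p = marginal_to_categories(target)
        dists = [abs(p[1] - a) + abs(p[2] - b) + abs(p[3] - c)
                 for a, b, c in feasible]
        assert min(dists) < 1e-2

    @pytest.mark.parametrize("prev,mean", [(50.0, 2.0), (50.0, 0.2), (0.0, 1.0)])
    def test_infeasible_pairs_rejected(self, prev, mean):
        with pytest.raises(InfeasibleMarginalError):
            marginal_to_categories(MarginalTarget(prev, mean))

    @pytest.mark.parametrize("prev,mean", [(30.0, 0.3), (30.0, 0.9), (71.2, 1.02),
                                           (59.2, 0.92), (90.0, 2.69)])
    def test_moment_constraints_always_hold(self, prev, mean):
        p = marginal_to_categories(MarginalTarget(prev, mean))
        assert np.isclose(100.0 * (1.0 - p[0]), prev, atol=1e-8)
        assert np.isclose(p[1] + 2 * p[2] + 3 * p[3], mean, atol=1e-8)


# ---------------------------------------------------------------------------
# generate_responses
# ---------------------------------------------------------------------------

class TestGeneration:
    def test_deterministic_given_seed(self):
        spec = calibrated_spec(n_participants=200, seed=11)
        a = generate_responses(spec)
        b = generate_responses(spec)
        assert a.to_csv() == b.to_csv()  # byte-for-byte

    def test_scores_in_range_and_columns_named(self, instrument):
        df = generate_responses(calibrated_spec(n_participants=50, seed=2))
        assert list(df.columns) == list(instrument.item_ids)
        assert df.isin([0, 1, 2, 3]).all().all()

    def test_independent_items_uncorrelated(self):
        df = generate_responses(_uniform_spec(10000, 5, seed=4))
        rho = stats.spearmanr(df).statistic
        off = rho[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_strong_latent_pair_has_largest_rho(self):
        R = np.eye(6)
        R[1, 4] = R[4, 1] = 0.95
        df = generate_responses(_uniform_spec(10000, 6, corr=R, seed=5))
        rho = np.abs(np.asarray(stats.spearmanr(df).statistic))
        np.fill_diagonal(rho, 0.0)
        assert np.unravel_index(rho.argmax(), rho.shape) in [(1, 4), (4, 1)]

    def test_marginal_recovery_at_large_n(self):
        # empirical category frequencies within +-0.01 of the target marginals
        spec = calibrated_spec(n_participants=50_000, seed=6)
        df = generate_responses(spec)
        for j, item in enumerate(df.columns):
            freq = (
                df[item].value_counts(normalize=True)
                .reindex([0, 1, 2, 3], fill_value=0.0)
                .to_numpy()
            )
            np.testing.assert_allclose(
                freq, spec.category_probs[j], atol=0.01,
                err_msg=f"marginal drift for {item}",
            )

    def test_association_monotone_in_latent_correlation(self):
        rhos = []
        for latent in (0.0, 0.2, 0.4, 0.6, 0.8):
            R = np.array([[1.0, latent], [latent, 1.0]])
            df = generate_responses(_uniform_spec(20_000, 2, corr=R, seed=8))
            rhos.append(stats.spearmanr(df.iloc[:, 0], df.iloc[:, 1]).statistic)
        assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_empirical_spearman_matches_monte_carlo_oracle(self):
        # independent MC oracle: fresh bivariate-normal sampler, 1e6 draws,
        # mid-rank Spearman computed longhand on a 50k subsample of it
        latent = 0.8
        cuts = np.array([-0.6744897502, 0.0, 0.6744897502])
        rng = np.random.default_rng(987654321)
        z1 = rng.standard_normal(1_000_000)
        z2 = latent * z1 + np.sqrt(1 - latent**2) * rng.standard_normal(1_000_000)
        x = (z1[:, None] > cuts).sum(axis=1)
        y = (z2[:, None] > cuts).sum(axis=1)
        oracle = stats.spearmanr(x, y).statistic
        assert abs(oracle - spearman_oracle(x[:50_000], y[:50_000])) < 0.02

        R = np.array([[1.0, latent], [latent, 1.0]])
        df = generate_responses(_uniform_spec(50_000, 2, corr=R, seed=9))
        emp = stats.spearmanr(df.iloc[:, 0], df.iloc[:, 1]).statistic
        assert abs(emp - oracle) < 0.03

    def test_non_psd_spec_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(NotPositiveSemidefiniteError):
            CopulaSpec(10, R, np.full((3, 4), 0.25))

    def test_serialization_round_trip(self, tmp_path):
        spec = calibrated_spec(n_participants=100, seed=3)
        spec.to_yaml(tmp_path / "spec.yaml")
        spec.to_json(tmp_path / "spec.json")
        for name in ("spec.yaml", "spec.json"):
            back = CopulaSpec.from_file(tmp_path / name)
            np.testing.assert_array_equal(back.latent_corr, spec.latent_corr)
            np.testing.assert_array_equal(back.category_probs, spec.category_probs)
            assert back.item_ids == spec.item_ids and back.seed == spec.seed
            assert generate_responses(back).equals(generate_responses(spec))


# ---------------------------------------------------------------------------
# plant_hub
# ---------------------------------------------------------------------------

class TestPlantHub:
    def test_structure_when_design_is_psd(self):
        # 3 items, mild hub: no repair needed, exact structure preserved
        spec = _uniform_spec(10, 3)
        planted = plant_hub(spec, 0, hub_corr=0.5, background_corr=0.2)
        expected = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.2], [0.5, 0.2, 1.0]])
        np.testing.assert_allclose(planted.latent_corr, expected, atol=1e-12)

    def test_equal_correlations_rejected(self):
        with pytest.raises(InvalidDesignError):
            plant_hub(_uniform_spec(10, 5), 0, hub_corr=0.3, background_corr=0.3)

    def test_unknown_hub_item_rejected(self):
        with pytest.raises(MissingItemError):
            plant_hub(_uniform_spec(10, 5), "nonexistent", 0.7, 0.2)

    def test_indefinite_design_repaired_to_psd(self):
        spec = _uniform_spec(10, 10)
        with pytest.warns(UserWarning, match="nearest PSD"):
            planted = plant_hub(spec, 3, hub_corr=0.7, background_corr=0.2)
        w = np.linalg.eigvalsh(planted.latent_corr)
        assert w.min() >= -1e-10
        # hub row still dominates after shrinkage
        R = planted.latent_corr.copy()
        np.fill_diagonal(R, 0.0)
        assert R.sum(axis=1).argmax() == 3

    def test_hub_recovered_as_top_strength_node(self):
        # planted hub is the top-strength node in >= 18 of 20 replicates
        hits = 0
        for seed in range(20):
            spec = _uniform_spec(2000, 10, seed=seed)
            with pytest.warns(UserWarning):
                planted = plant_hub(spec, 0, 0.7, 0.2)
            df = generate_responses(planted)
            rho = np.abs(np.asarray(stats.spearmanr(df).statistic))
            np.fill_diagonal(rho, 0.0)
            hits += int(rho.sum(axis=1).argmax() == 0)
        assert hits >= 18

    def test_strength_ratio_matches_closed_form_at_zero_background(self):
        # background 0, hub 0.5, 5 items: hub strength ~ 4x non-hub strength,
        # because each spoke shares the same latent correlation with the hub
        # and non-hub pairs are independent
        spec = _uniform_spec(200_000, 5, seed=10)
        planted = plant_hub(spec, 0, hub_corr=0.5, background_corr=0.0)
        df = generate_responses(planted)
        rho = np.abs(np.asarray(stats.spearmanr(df).statistic))
        np.fill_diagonal(rho, 0.0)
        s = rho.sum(axis=1)
        ratio = s[0] / s[1:].mean()
        assert 3.6 < ratio < 4.4


def test_clustered_latent_corr_is_psd_without_repair(instrument):
    R = clustered_latent_corr(instrument, within=0.6, between=0.3)
    assert np.linalg.eigvalsh(R).min() >= -1e-10
    ids = list(instrument.item_ids)
    i, j = ids.index("nervous"), ids.index("jittery")  # same cluster
    k = ids.index("weakness")  # different cluster
    assert R[i, j] == 0.6 and R[i, k] == 0.3


def test_nearest_psd_is_identity_on_psd_input():
    R = clustered_latent_corr(default_instrument())
    np.testing.assert_array_equal(nearest_psd(R), R)
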