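"""Synthetic-data generators: determinism, noise structure, type invariants."""

import numpy as np
import pytest

from fiscalfood import (DimensionError, ModelDimensions, aids_elasticities,
                        generate_luc_matrix, generate_population,
                        generate_synthetic_economy)


class TestDimensions:
    def test_defaults_are_valid(self):
        d = ModelDimensions()
        assert d.n_commodities == 10 and d.n_households == 4
        assert len(d.periods) == 20

    def test_paper_scale(self):
        d = ModelDimensions.paper_scale()
        assert d.n_commodities == 49 and d.n_households == 9

    @pytest.mark.parametrize("kwargs", [
        {"commodities": ["oil_palm_crop", "rice_crop", "maize_crop",
                         "palm_oil", "other_oils"]},              # too few
        {"households": ["only_one_rural"]},
        {"periods": [2016]},
        {"strata_count": 1},
        {"crops": ["oil_palm_crop", "rice_crop"]},                # 1 other crop
    ])
    def test_degenerate_dimensions_rejected(self, kwargs):
        with pytest.raises(DimensionError):
            ModelDimensions(**kwargs)


class TestEconomyGenerator:
    def test_same_seed_is_bit_identical(self, dims):
        a = generate_synthetic_economy(dims, seed=7, noise_level=0.05)
        b = generate_synthetic_economy(dims, seed=7, noise_level=0.05)
        assert np.array_equal(a[0].balanced_sam.values, b[0].balanced_sam.values)
        assert np.array_equal(a[1].values, b[1].values)
        assert np.array_equal(a[2].epsilon, b[2].epsilon)
        assert np.array_equal(a[0].population.counts, b[0].population.counts)

    def test_zero_noise_prior_is_exactly_balanced(self, dims):
        truth, unbalanced, _ = generate_synthetic_economy(dims, 3, 0.0)
        assert np.array_equal(unbalanced.values, truth.balanced_sam.values)
        assert unbalanced.max_imbalance() < 1e-9

    def test_noise_level_matches_log_ratio_sd(self):
        """With 5% lognormal noise the empirical sd of cell log-ratios over
        nonzero cells must sit in [0.02, 0.10] (direct recomputation)."""
        dims = ModelDimensions(commodities=[
            "oil_palm_crop", "rice_crop", "maize_crop", "palm_oil",
            "other_oils", "other_food", "manufactures", "services"])
        truth, unbalanced, _ = generate_synthetic_economy(dims, 5, 0.05)
        t, v = truth.balanced_sam.values, unbalanced.values
        nz = t > 0
        sd = np.std(np.log(v[nz] / t[nz]))
        assert 0.02 <= sd <= 0.10

    def test_priors_violate_regularity_only_under_noise(self, dims):
        truth, _, noisy = generate_synthetic_economy(dims, 11, 0.05)
        _, _, clean = generate_synthetic_economy(dims, 11, 0.0)
        # clean priors are the true, symmetric-gamma-implied elasticities
        eps_t, eta_t = aids_elasticities(truth.aids_parameters, clean.shares)
        assert np.allclose(clean.epsilon, eps_t)
        assert not np.allclose(noisy.epsilon, eps_t)
        # own-price signs preserved under noise
        diag = np.diagonal(noisy.epsilon, axis1=1, axis2=2)
        assert (diag < 0).all()
        # Engel aggregation broken by the noise
        assert np.max(np.abs((noisy.shares * noisy.eta).sum(axis=1) - 1.0)) > 1e-4

    def test_invariants_hold_across_many_seeds(self, dims):
        """Every generated table satisfies its type invariants (100 seeds)."""
        oils = [dims.palm_oil, dims.other_oils]
        pidx = dims.commodities.index(dims.palm_oil)
        oidx = dims.commodities.index(dims.other_oils)
        for seed in range(100):
            truth, unb, priors = generate_synthetic_economy(dims, seed, 0.05)
            assert truth.balanced_sam.max_imbalance() < 1e-8
            assert truth.aids_parameters.is_regular(1e-8)
            assert (priors.shares > 0).all() and (priors.shares < 1).all()
            nut = truth.nutrient_coefficients
            assert (nut.energy_density >= 0).all()
            assert (nut.sfa_frac + nut.mufa_frac + nut.pufa_frac <= 1 + 1e-12).all()
            assert (nut.sfa_frac[:, pidx] > nut.sfa_frac[:, oidx]).all()
            bio = truth.biomarker_distributions
            assert (bio.mean >= 2.0).all() and (bio.mean <= 7.0).all()
            assert (bio.sd > 0).all()
            assert (truth.population.counts > 0).all()
            m = truth.luc_matrix.coefficients
            assert np.allclose(m + m.T, 0, atol=1e-10)
            st = truth.strata
            assert (np.diff(st.support, axis=1) > 0).all()
            assert np.allclose(st.frequency.sum(axis=1), 1.0)


class TestPopulationGenerator:
    def test_counts_positive_and_total_consistent(self, dims):
        pop = generate_population(dims, seed=4)
        assert (pop.counts > 0).all()
        assert np.isclose(pop.national_total, pop.household_totals().sum())

    def test_mortality_non_decreasing_in_oldest_bands(self, dims):
        for seed in range(20):
            pop = generate_population(dims, seed)
            tail = pop.mortality[-3:, :]
            assert (np.diff(tail, axis=0) >= -1e-15).all()

    def test_migration_sums_to_zero_nationally(self, dims):
        pop = generate_population(dims, seed=9)
        assert abs(pop.migration.sum()) < 1e-6


class TestLucGenerator:
    def test_diagonal_zero_and_antisymmetric(self, dims):
        m = generate_luc_matrix(dims, seed=2)
        assert np.allclose(np.diag(m.coefficients), 0.0)
        assert np.allclose(m.coefficients + m.coefficients.T, 0.0)

    def test_converting_annual_crop_to_oil_palm_sequesters(self, dims):
        """Oil palm carries the largest carbon stock, so annual-crop ->
        oil-palm conversion coefficients are negative."""
        m = generate_luc_matrix(dims, seed=2)
        j = m.crops.index(dims.oil_palm_crop)
        for i, crop in enumerate(m.crops):
            if i != j:
                assert m.coefficients[i, j] < 0
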