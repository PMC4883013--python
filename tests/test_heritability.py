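"""AE variance-components model: kinship, likelihood, LRT, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subfieldstats.datatypes import InsufficientDataError, Pedigree
from subfieldstats.heritability import (
    PolygenicAE,
    bonferroni_threshold,
    build_kinship,
    falconer_h2,
    heritability_table,
    lrt_pvalue,
    twin_design_matrix,
)
from subfieldstats.simulate import CohortSpec, simulate_twin_cohort

from conftest import make_pedigree_frame


class TestKinship:
    def test_mz_pair_block(self, small_pedigree):
        kin = build_kinship(small_pedigree)
        ids, block = kin.families["famA"]
        np.testing.assert_array_equal(block, [[1.0, 1.0], [1.0, 1.0]])

    def test_dz_pair_block_half(self, small_pedigree):
        _, block = build_kinship(small_pedigree).families["famC"]
        np.testing.assert_array_equal(block, [[1.0, 0.5], [0.5, 1.0]])

    def test_cross_family_multipliers_zero(self, small_pedigree):
        dense = build_kinship(small_pedigree).dense_two_phi()
        assert dense.shape == (6, 6)
        # zero outside the 2x2 family blocks
        assert dense[0, 2] == 0.0 and dense[4, 1] == 0.0
        np.testing.assert_array_equal(np.diag(dense), np.ones(6))


def _cohort(h2, n_mz=132, n_dz=232, seed=0, **kw):
    vols, ped = simulate_twin_cohort(
        CohortSpec(n_mz_pairs=n_mz, n_dz_pairs=n_dz,
                   region_params={"r": (0.0, 1.0, h2)}, seed=seed, **kw)
    )
    return vols["r"], ped


class TestLikelihoodOracle:
    def test_blockwise_equals_dense_mvn(self):
        """Blockwise likelihood equals an independent dense MVN evaluation
        (scipy) on a 20-family cohort, to 1e-8."""
        y, ped = _cohort(0.6, n_mz=10, n_dz=10, seed=5)
        model = PolygenicAE.from_pedigree(y, ped)
        kin = build_kinship(ped)
        X = twin_design_matrix(ped).to_numpy()
        yv = y.loc[kin.individual_ids].to_numpy()
        for sg2, se2 in [(0.0, 1.0), (0.3, 0.7), (0.9, 0.2), (1.5, 0.05)]:
            omega = sg2 * kin.dense_two_phi() + se2 * np.eye(len(yv))
            W = np.linalg.inv(omega)
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ yv)
            oracle = stats.multivariate_normal.logpdf(yv, mean=X @ beta, cov=omega)
            assert model.profile_loglike(sg2, se2) == pytest.approx(oracle, abs=1e-8)
            assert model.loglike_dense(sg2, se2) == pytest.approx(oracle, abs=1e-8)


class TestFit:
    def test_pure_noise_gives_null_h2(self):
        y, ped = _cohort(0.0, seed=11)
        model = PolygenicAE.from_pedigree(y, ped)
        res = model.fit()
        null = model.fit(constrain_g_to_zero=True)
        assert res.h2 < 0.15
        assert res.loglik >= null.loglik - 1e-8
        # under the null the two models nearly coincide
        assert res.loglik - null.loglik < 3.0

    def test_noise_free_limit_h2_one(self):
        y, ped = _cohort(1.0, n_mz=30, n_dz=30, seed=2)
        res = PolygenicAE.from_pedigree(y, ped).fit()
        assert res.h2 > 0.995

    def test_mz_pairs_identical_when_h2_is_one(self):
        y, ped = _cohort(1.0, seed=3)
        df = ped.table
        mz = df[df.zygosity == "MZ"]
        v = y.loc[mz.individual_id].to_numpy().reshape(-1, 2)
        np.testing.assert_allclose(v[:, 0], v[:, 1], rtol=1e-10)

    def test_recovery_and_falconer_agreement(self):
        """At the 132 MZ + 232 DZ design, mean ML h2-hat over 100 seeds is
        within 0.02 of truth and tracks the Falconer moment estimate
        (which carries a small O(1/n) downward bias)."""
        for true_h2 in (0.2, 0.8):
            ml, falc = [], []
            for seed in range(100):
                y, ped = _cohort(true_h2, seed=seed)
                ml.append(PolygenicAE.from_pedigree(y, ped).fit().h2)
                falc.append(falconer_h2(y, ped))
            assert abs(np.mean(ml) - true_h2) <= 0.02
            assert abs(np.mean(ml) - np.mean(falc)) <= 0.05

    def test_covariate_invariance(self):
        """A strong age effect in the generative model leaves the
        covariate-adjusted h2 estimate unbiased."""
        ests = []
        for seed in range(30):
            vols, ped = simulate_twin_cohort(
                CohortSpec(region_params={"r": (100.0, 1.0, 0.5)},
                           covariate_effects=(2.0, 5.0, -0.5), seed=seed)
            )
            ests.append(PolygenicAE.from_pedigree(vols["r"], ped).fit().h2)
        assert abs(np.mean(ests) - 0.5) < 0.04

    def test_h2_se_plausible(self):
        y, ped = _cohort(0.8, seed=21)
        res = PolygenicAE.from_pedigree(y, ped).fit()
        assert 0.0 < res.h2_se < 0.15

    def test_summary_mentions_key_quantities(self):
        y, ped = _cohort(0.5, n_mz=20, n_dz=20, seed=4)
        text = PolygenicAE.from_pedigree(y, ped).fit().summary()
        for token in ("h^2", "sigma_g^2", "log-likelihood", "p-value", "age_x_sex"):
            assert token in text

    def test_too_few_families_rejected(self):
        y, ped = _cohort(0.5, n_mz=5, n_dz=5, seed=1)
        with pytest.raises(InsufficientDataError):
            PolygenicAE.from_pedigree(y, ped).fit()

    def test_zero_variance_phenotype_rejected(self, small_pedigree):
        with pytest.raises(ValueError, match="variance"):
            PolygenicAE.from_pedigree(
                np.ones(6), small_pedigree
            )


class TestLRT:
    def test_boundary_mass_at_zero(self):
        assert lrt_pvalue(-100.0, -100.0) == 0.5

    def test_half_chi2_quantile(self):
        # Lambda = 2.706 is the chi2_1 upper 0.10 point; halved tail = 0.05
        p = lrt_pvalue(-99.0 + 2.706 / 2, -99.0)
        assert p == pytest.approx(0.5 * stats.chi2.sf(2.706, 1), rel=1e-12)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_null_better_than_full_raises(self):
        with pytest.raises(ValueError, match="optimiser"):
            lrt_pvalue(-105.0, -100.0)


class TestBonferroni:
    def test_thirteen_regions_threshold(self):
        t = bonferroni_threshold(0.05, 13)
        assert t == pytest.approx(0.05 / 13, rel=1e-15)
        assert abs(t - 3.84e-3) < 1e-5  # printed precision

    def test_identity_and_halving(self):
        assert bonferroni_threshold(0.3, 1) == 0.3
        assert bonferroni_threshold(0.05, 2) == 0.025

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


class TestHeritabilityTable:
    def test_ordering_tracks_generative_h2(self):
        params = {f"r{i}": (0.0, 1.0, h2)
                  for i, h2 in enumerate([0.1, 0.45, 0.85])}
        vols, ped = simulate_twin_cohort(
            CohortSpec(region_params=params, seed=9)
        )
        tbl = heritability_table(vols, ped)
        assert list(tbl.index) == ["r0", "r1", "r2"]  # ascending h2
        assert tbl["significant"].loc["r2"]

    def test_single_region_matches_direct_fit(self):
        y, ped = _cohort(0.6, n_mz=40, n_dz=40, seed=13)
        vols = y.to_frame("r")
        tbl = heritability_table(vols, ped)
        direct = PolygenicAE.from_pedigree(y, ped).fit()
        assert tbl.loc["r", "h2"] == pytest.approx(direct.h2, abs=1e-8)
        assert tbl.loc["r", "p"] == pytest.approx(direct.p_value, rel=1e-6)
        assert tbl.attrs["threshold"] == pytest.approx(0.05)

    def test_failing_region_is_isolated(self):
        y, ped = _cohort(0.6, n_mz=40, n_dz=40, seed=14)
        vols = y.to_frame("good")
        vols["bad"] = 1.0  # zero variance -> per-region failure
        tbl = heritability_table(vols, ped)
        assert np.isnan(tbl.loc["bad", "h2"])
        assert tbl.loc["bad", "error"] != ""
        assert np.isfinite(tbl.loc["good", "h2"])


def test_falconer_closed_form_on_constructed_pairs():
    """Falconer's 2(r_MZ - r_DZ) on hand-built data with known double-entry
    correlations."""
    df = make_pedigree_frame(3, 3)
    ped = Pedigree(df)
    # MZ pairs perfectly concordant, DZ pairs exchangeable with lower
    # similarity
    values = {
        "f001_1": 1.0, "f001_2": 1.0,
        "f002_1": 2.0, "f002_2": 2.0,
        "f003_1": 3.0, "f003_2": 3.0,
        "f004_1": 1.0, "f004_2": 2.0,
        "f005_1": 2.0, "f005_2": 3.0,
        "f006_1": 3.0, "f006_2": 1.0,
    }
    y = pd.Series(values)
    r_mz = 1.0
    # independent double-entry computation for the DZ trio
    a = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 1.0])
    b = np.array([2.0, 3.0, 1.0, 1.0, 2.0, 3.0])
    r_dz = np.corrcoef(a, b)[0, 1]
    assert falconer_h2(y, ped) == pytest.approx(2 * (r_mz - r_dz), rel=1e-12)
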