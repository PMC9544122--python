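"""Tests for the pedigree algebra, Gibbs sampler and posterior summaries."""

import numpy as np
import pandas as pd
import pytest

from patternherit import animal_model as am
from patternherit import simulate as sim


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


# ---------------------------------------------------------------------------
# independent oracle: additive relationship by the recursive definition
# ---------------------------------------------------------------------------

def recursive_A(pedigree):
    """Relationship matrix straight from the recursive definition.

    a(i, i) = 1 + a(s_i, d_i) / 2 ; a(i, j) = (a(s_i, j) + a(d_i, j)) / 2
    for i not an ancestor of j, with unknown parents contributing 0.
    Written independently of the package's tabular construction.
    """
    ids = pedigree["id"].tolist()
    parents = {
        r["id"]: (r["sire"] or None, r["dam"] or None)
        for _, r in pedigree.iterrows()
    }
    order = {v: i for i, v in enumerate(ids)}  # assumes parents listed first
    memo = {}

    def a(i, j):
        if i is None or j is None:
            return 0.0
        key = (i, j) if order[i] <= order[j] else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            s, d = parents[i]
            val = 1.0 + 0.5 * a(s, d)
        else:
            x, y = (i, j) if order[i] >= order[j] else (j, i)
            s, d = parents[x]
            val = 0.5 * (a(s, y) + a(d, y))
        memo[key] = val
        return val

    n = len(ids)
    return np.array([[a(ids[i], ids[j]) for j in range(n)] for i in range(n)])


class TestRelationshipMatrix:
    def test_parent_offspring_relationship(self, fixture_pedigrees):
        A, ids = am.build_A(fixture_pedigrees["parent_offspring"])
        assert A[ids.index("s"), ids.index("o")] == pytest.approx(0.5)

    def test_full_and_half_sibs(self, fixture_pedigrees):
        A, ids = am.build_A(fixture_pedigrees["full_sibs"])
        assert A[ids.index("o1"), ids.index("o2")] == pytest.approx(0.5)
        A, ids = am.build_A(fixture_pedigrees["half_sibs"])
        assert A[ids.index("o1"), ids.index("o2")] == pytest.approx(0.25)

    def test_full_sib_mating_diagonal(self, fixture_pedigrees):
        A, ids = am.build_A(fixture_pedigrees["full_sib_mating"])
        assert A[ids.index("i"), ids.index("i")] == pytest.approx(1.25)

    def test_matches_recursive_oracle_on_all_fixtures(self, fixture_pedigrees):
        for name, ped in fixture_pedigrees.items():
            A, _ = am.build_A(ped)
            np.testing.assert_allclose(A, recursive_A(ped), atol=1e-12,
                                       err_msg=name)

    def test_symmetric_psd_with_unit_plus_F_diagonal(self, fixture_pedigrees):
        for ped in fixture_pedigrees.values():
            A, _ = am.build_A(ped)
            np.testing.assert_allclose(A, A.T)
            assert np.linalg.eigvalsh(A).min() > -1e-10
            assert (np.diag(A) >= 1.0 - 1e-12).all()

    def test_inverse_matches_dense_inverse(self, fixture_pedigrees):
        for name, ped in fixture_pedigrees.items():
            A, _ = am.build_A(ped)
            Ainv, _ = am.build_A_inverse(ped)
            np.testing.assert_allclose(
                Ainv @ A, np.eye(len(A)), atol=1e-10, err_msg=name
            )

    def test_inbreeding_matches_tabular_diagonal(self, fixture_pedigrees):
        for ped in fixture_pedigrees.values():
            A, ids = am.build_A(ped)
            F = am.inbreeding_coefficients(ped)
            np.testing.assert_allclose(F.loc[ids].to_numpy(), np.diag(A) - 1.0,
                                       atol=1e-12)

    def test_cycle_is_reported_with_individuals(self):
        ped = ped_frame([("a", "b", ""), ("b", "a", "")])
        with pytest.raises(ValueError, match="cycle"):
            am.build_A(ped)

    def test_unknown_parent_reference_rejected(self):
        ped = ped_frame([("a", "ghost", "")])
        with pytest.raises(ValueError, match="ghost"):
            am.build_A(ped)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def one_record(**overrides):
    base = dict(
        id="o1", sex="female", year=2015, age_days=30,
        offspring_treatment="long-bask", parental_treatment="long-bask",
        dam="d", parental_cage="pc", offspring_cage="oc", brightness=0.3,
    )
    base.update(overrides)
    return pd.DataFrame([base])


class TestBuildDesign:
    pedigree = ped_frame([("s", "", ""), ("d", "", ""), ("o1", "s", "d")])

    def test_reference_level_row_is_intercept_and_age_only(self):
        spec = am.ModelSpec(response="brightness", n_iter=10, thin=1, burnin=1)
        d = am.build_design(one_record(), self.pedigree, spec)
        np.testing.assert_allclose(
            d.X[0], [1, 0, 30, 0, 0, 0, 0, 0, 0, 0]
        )
        assert d.X.shape[1] == len(am.FIXED_EFFECTS) == 10

    def test_triple_short_bask_male_sets_all_interactions(self):
        rec = one_record(
            sex="male", offspring_treatment="short-bask",
            parental_treatment="short-bask",
        )
        spec = am.ModelSpec(response="brightness", n_iter=10, thin=1, burnin=1)
        d = am.build_design(rec, self.pedigree, spec)
        np.testing.assert_allclose(
            d.X[0], [1, 0, 30, 1, 1, 1, 1, 1, 1, 1]
        )

    def test_missing_covariates_are_dropped_complete_case(self):
        rec = pd.concat([one_record(), one_record(id="o2", age_days=np.nan)])
        ped = ped_frame(
            [("s", "", ""), ("d", "", ""), ("o1", "s", "d"), ("o2", "s", "d")]
        )
        spec = am.ModelSpec(response="brightness", n_iter=10, thin=1, burnin=1)
        d = am.build_design(rec, ped, spec)
        assert d.record_ids == ["o1"]
        assert d.n_dropped == 1

    def test_missing_response_column_is_named(self):
        spec = am.ModelSpec(response="contrast", n_iter=10, thin=1, burnin=1)
        with pytest.raises(KeyError, match="contrast"):
            am.build_design(one_record(), self.pedigree, spec)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

class TestPosteriorSummaries:
    def test_mode_of_constant_chain(self):
        assert am.posterior_mode(np.full(50, 3.25)) == 3.25

    def test_mode_of_normal_sample(self):
        x = np.random.default_rng(1).normal(5.0, 1.0, 50_000)
        assert am.posterior_mode(x) == pytest.approx(5.0, abs=0.1)

    def test_mode_of_exponential_sample_near_zero(self):
        # boundary bias of the Gaussian kernel keeps the estimated mode
        # slightly above the true mode at 0; it shrinks with n^(−1/5)
        x = np.random.default_rng(2).exponential(1.0, 500_000)
        assert am.posterior_mode(x) < 0.15

    def test_hpd_width_of_uniform_sample(self):
        x = np.random.default_rng(3).uniform(0, 1, 100_000)
        lo, hi = am.hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_hpd_symmetric_for_normal_sample(self):
        x = np.random.default_rng(4).normal(0, 1, 100_000)
        lo, hi = am.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-hi, abs=0.05)

    def test_hpd_of_constant_chain_has_zero_width(self):
        lo, hi = am.hpd_interval(np.full(100, 2.0))
        assert lo == hi == 2.0

    def test_hpd_needs_enough_draws(self):
        with pytest.raises(ValueError, match="at least 20"):
            am.hpd_interval(np.arange(10))

    @pytest.mark.parametrize(
        "chain, expected",
        [
            (np.abs(np.random.default_rng(5).normal(size=200)) + 0.1, 1 / 200),
            (np.r_[np.ones(100), -np.ones(100)], 1.0),
            (np.r_[np.ones(975), -np.ones(25)], 0.05),
        ],
    )
    def test_pmcmc_sign_probability(self, chain, expected):
        assert am.pmcmc(chain) == pytest.approx(expected)


class TestDiagnostics:
    def test_iid_chain_passes_in_most_replicates(self):
        ok = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=5000)
            d = am.diagnostics(x)
            ok += abs(d["lag1_autocorr"]) < 0.05 and abs(d["geweke_z"]) < 3
        assert ok >= 19

    def test_random_walk_has_high_autocorrelation(self):
        x = np.cumsum(np.random.default_rng(6).normal(size=2000))
        assert am.diagnostics(x)["lag1_autocorr"] > 0.9

    def test_mean_shift_gives_large_geweke_z(self):
        rng = np.random.default_rng(7)
        x = np.r_[rng.normal(0, 1, 1000), rng.normal(3, 1, 1000)]
        assert abs(am.diagnostics(x)["geweke_z"]) > 5

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            am.diagnostics(np.arange(50))


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def samples_from(variances: dict) -> am.PosteriorSamples:
    v = pd.DataFrame(variances)
    beta = pd.DataFrame(
        np.zeros((len(v), len(am.FIXED_EFFECTS))), columns=list(am.FIXED_EFFECTS)
    )
    return am.PosteriorSamples(beta=beta, variances=v)


class TestHeritability:
    def test_equal_components_give_one_fifth(self):
        s = samples_from({k: np.ones(100) for k in am.VARIANCE_COMPONENTS})
        h2 = am.heritability(s)
        np.testing.assert_allclose(h2.chain, 0.2)
        assert h2.mode == pytest.approx(0.2)

    def test_vanishing_additive_variance(self):
        v = {k: np.ones(100) for k in am.VARIANCE_COMPONENTS}
        v["sigma2_A"] = np.full(100, 1e-8)
        h2 = am.heritability(samples_from(v))
        assert h2.mode < 0.01

    def test_scale_invariance_of_the_ratio(self):
        rng = np.random.default_rng(8)
        v = {k: rng.gamma(2.0, 1.0, 500) for k in am.VARIANCE_COMPONENTS}
        h2 = am.heritability(samples_from(v))
        h2s = am.heritability(samples_from({k: 10.0 * x for k, x in v.items()}))
        np.testing.assert_allclose(h2.chain, h2s.chain)

    def test_mismatched_chain_lengths_rejected(self):
        v = {k: np.ones(100) for k in am.VARIANCE_COMPONENTS}
        v["sigma2_R"] = np.r_[np.ones(90), np.full(10, np.nan)]
        with pytest.raises(ValueError, match="mismatched"):
            am.heritability(samples_from(v))


# ---------------------------------------------------------------------------
# Gibbs sampler behaviour
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_fit(study_dataset):
    pedigree, records, truth = study_dataset
    spec = am.ModelSpec(
        response="brightness", n_iter=4000, thin=4, burnin=400, seed=13
    )
    design = am.build_design(records, pedigree, spec)
    A_inv, _ = am.build_A_inverse(pedigree)
    return design, A_inv, spec


class TestGibbsSampler:
    def test_identical_seeds_give_identical_chains(self, small_fit):
        design, A_inv, spec = small_fit
        a = am.gibbs_sample(design, A_inv, spec)
        b = am.gibbs_sample(design, A_inv, spec)
        pd.testing.assert_frame_equal(a.variances, b.variances)
        pd.testing.assert_frame_equal(a.beta, b.beta)

    def test_retained_draw_count_and_positivity(self, small_fit):
        design, A_inv, spec = small_fit
        s = am.gibbs_sample(design, A_inv, spec)
        assert len(s.variances) == spec.n_retained == 900
        assert (s.variances.to_numpy() > 0).all()
        h2 = am.heritability(s)
        assert ((h2.chain > 0) & (h2.chain < 1)).all()

    def test_phenotype_rescaling_equivariance(self, small_fit):
        # scaling y by c and the prior scale by c**2 leaves the h2
        # posterior unchanged (variance ratios are scale-free); chains
        # agree distributionally, not bit-for-bit, because last-ulp
        # rounding differences compound over iterations
        design, A_inv, spec = small_fit
        import copy
        scaled = copy.copy(design)
        scaled.y = 10.0 * design.y
        spec_scaled = am.ModelSpec(
            response=spec.response, prior_V=100.0 * spec.prior_V,
            prior_nu=spec.prior_nu, n_iter=spec.n_iter, thin=spec.thin,
            burnin=spec.burnin, seed=spec.seed,
        )
        h2_a = am.heritability(am.gibbs_sample(design, A_inv, spec)).chain
        h2_b = am.heritability(am.gibbs_sample(scaled, A_inv, spec_scaled)).chain
        assert ((h2_b > 0) & (h2_b < 1)).all()
        assert abs(h2_a.mean() - h2_b.mean()) < 0.05
        assert abs(np.median(h2_a) - np.median(h2_b)) < 0.05


# ---------------------------------------------------------------------------
# REML oracle
# ---------------------------------------------------------------------------

class TestReml:
    def test_balanced_one_way_matches_anova_estimator(self):
        # classical identity: for a balanced one-way layout REML equals
        # the ANOVA moment estimator (when it is interior)
        rng = np.random.default_rng(20)
        g, r = 30, 6
        effects = rng.normal(0, np.sqrt(2.0), g)
        y = np.repeat(effects, r) + rng.normal(0, 1.0, g * r)
        X = np.ones((g * r, 1))
        Z = np.kron(np.eye(g), np.ones((r, 1)))
        est, ll, ok = am.reml_fit(y, X, [Z @ Z.T, np.eye(g * r)])
        ybar_g = y.reshape(g, r).mean(axis=1)
        msb = r * ((ybar_g - y.mean()) ** 2).sum() / (g - 1)
        msw = ((y.reshape(g, r) - ybar_g[:, None]) ** 2).sum() / (g * (r - 1))
        assert est[1] == pytest.approx(msw, rel=1e-3)
        assert est[0] == pytest.approx((msb - msw) / r, rel=1e-3)

    def test_optimum_beats_truth(self, study_dataset):
        pedigree, records, truth = study_dataset
        spec = am.ModelSpec(response="brightness", n_iter=10, thin=1, burnin=1)
        design = am.build_design(records, pedigree, spec)
        A, _ = am.build_A(pedigree)
        res = am.reml_oracle(design, A)
        covs = [
            design.Z_animal @ A @ design.Z_animal.T,
            design.Z_dam @ design.Z_dam.T,
            design.Z_pcage @ design.Z_pcage.T,
            design.Z_ocage @ design.Z_ocage.T,
            np.eye(len(design.y)),
        ]
        tt = truth.traits["brightness"]
        ll_truth = am.reml_restricted_loglik(
            np.array([tt.sigma2_A, tt.sigma2_dam, tt.sigma2_pcage,
                      tt.sigma2_ocage, tt.sigma2_R]),
            design.y, design.X, covs,
        )
        assert res.loglik >= ll_truth - 1e-6

    def test_component_recovery_within_loose_bound(self):
        # half-sib layout, all five true components 1.0; REML should
        # land within 50% of each at n = 1000 (loose Monte-Carlo bound)
        rng = np.random.default_rng(40)
        ped_rows, cov_rows = [], []
        for s in range(100):
            sire = f"S{s:03d}"
            ped_rows.append((sire, "", ""))
            for d in range(2):
                dam = f"D{s:03d}_{d}"
                ped_rows.append((dam, "", ""))
                for o in range(5):
                    oid = f"O{s:03d}_{d}_{o}"
                    ped_rows.append((oid, sire, dam))
                    cov_rows.append(
                        dict(
                            id=oid,
                            sex="male" if rng.random() < 0.5 else "female",
                            year=2015 + d, age_days=int(rng.integers(6, 63)),
                            offspring_treatment=["long-bask", "short-bask"][o % 2],
                            parental_treatment=["long-bask", "short-bask"][s % 2],
                            dam=dam, parental_cage=f"PC{s:03d}",
                            offspring_cage=f"OC{rng.integers(120):03d}",
                        )
                    )
        pedigree = ped_frame(ped_rows)
        covariates = pd.DataFrame(cov_rows)
        truth = sim.SimulationTruth(
            traits={
                t: sim.TraitTruth(
                    beta={"intercept": 1.0}, sigma2_A=1.0, sigma2_dam=1.0,
                    sigma2_pcage=1.0, sigma2_ocage=1.0, sigma2_R=1.0,
                )
                for t in sim.TRAITS
            }
        )
        records = sim.simulate_records(pedigree, covariates, truth, seed=41)
        spec = am.ModelSpec(response="brightness", n_iter=10, thin=1, burnin=1)
        design = am.build_design(records, pedigree, spec)
        A, _ = am.build_A(pedigree)
        res = am.reml_oracle(design, A)
        for name, est in res.estimates.items():
            assert 0.5 <= est <= 1.5, (name, est)
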