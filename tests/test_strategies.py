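import numpy as np
import pytest

from beefq.bayesr import BayesRConfig, fit_bayesr
from beefq.simulate import PhenotypeDesign, simulate_cohort
from beefq.strategies import (
    StrategyUsageError,
    TrainingData,
    model1_design,
    model5_design,
    predict,
    project_pcs,
    train_model1,
    train_model5,
)
from beefq.structure import heterozygosity


def make_training_data(cohort, trait="tender"):
    Z = cohort.geno.codes.astype(float)
    pcs, _ = project_pcs(Z, Z, k=4)
    df = cohort.phenotypes.data
    return TrainingData(
        y=cohort.phenotypes.trait(trait),
        cg=df["cg"].to_numpy(),
        days_aged=df["days_aged"].to_numpy(float),
        carcass_weight=df["carcass_weight"].to_numpy(float),
        pcs=pcs,
        het=heterozygosity(cohort.geno),
        Z=Z,
    )


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(n_per_group=(150, 150, 60), m=400, seed=31)


@pytest.fixture(scope="module")
def small_fits(small_cohort):
    data = make_training_data(small_cohort)
    cfg = BayesRConfig(n_iter=1_500, burn_in=500, thin=2, seed=13)
    return data, train_model1(data, cfg), train_model5(data, cfg)


class TestDesigns:
    def test_model1_column_count(self, small_cohort):
        data = make_training_data(small_cohort)
        X, names, levels = model1_design(data)
        n_cg = len(np.unique(data.cg))
        assert X.shape[1] == 1 + (n_cg - 1) + 2 + 4 + 1
        assert names[0] == "intercept" and names[-1] == "het"

    def test_model5_column_count(self, small_cohort):
        data = make_training_data(small_cohort)
        X, names, _ = model5_design(data)
        n_cg = len(np.unique(data.cg))
        assert X.shape[1] == 1 + (n_cg - 1) + 2
        assert "pc1" not in names


class TestPredictAssembly:
    def _posterior_with(self, small_fits, g, coefs=None):
        _, post_m1, _ = small_fits
        post = post_m1
        post = type(post)(**{**post.__dict__})
        post.mean_g = np.asarray(g, float)
        if coefs is not None:
            post.mean_beta = post.mean_beta.copy()
            for name, val in coefs.items():
                post.mean_beta[post.fixed_names.index(name)] = val
        return post

    def test_strategy1_is_dot_product(self, small_fits):
        post = self._posterior_with(small_fits, np.zeros(400))
        post.mean_g = np.array([1.0, -1.0])
        Z = np.array([[2.0, 0.0]])
        pred = predict(1, post, Z)
        assert pred.y_hat[0] == pytest.approx(2.0)
        assert pred.terms == ("Zg",)

    def test_zero_fixed_effects_collapse_strategies(self, small_fits):
        data, post_m1, _ = small_fits
        post = self._posterior_with(
            small_fits, post_m1.mean_g,
            coefs={n: 0.0 for n in
                   ("days_aged", "carcass_weight", "pc1", "pc2", "pc3", "pc4", "het")},
        )
        kw = dict(days_aged=data.days_aged[:10], carcass_weight=data.carcass_weight[:10],
                  pcs=data.pcs[:10], het=data.het[:10])
        y1 = predict(1, post, data.Z[:10], **kw).y_hat
        y2 = predict(2, post, data.Z[:10], **kw).y_hat
        y3 = predict(3, post, data.Z[:10], **kw).y_hat
        np.testing.assert_allclose(y1, y2)
        np.testing.assert_allclose(y1, y3)

    def test_strategy2_minus_strategy3_is_covariate_terms(self, small_fits):
        data, post_m1, _ = small_fits
        kw = dict(days_aged=data.days_aged[:25], carcass_weight=data.carcass_weight[:25],
                  pcs=data.pcs[:25], het=data.het[:25])
        y2 = predict(2, post_m1, data.Z[:25], **kw).y_hat
        y3 = predict(3, post_m1, data.Z[:25], **kw).y_hat
        expected = (
            data.days_aged[:25] * post_m1.fixed_effect("days_aged")
            + data.carcass_weight[:25] * post_m1.fixed_effect("carcass_weight")
        )
        np.testing.assert_allclose(y2 - y3, expected, rtol=1e-12)

    def test_strategy_posterior_mismatch(self, small_fits):
        data, post_m1, post_m5 = small_fits
        with pytest.raises(StrategyUsageError):
            predict(4, post_m1, data.Z[:5])
        with pytest.raises(StrategyUsageError):
            predict(1, post_m5, data.Z[:5])
        with pytest.raises(StrategyUsageError):
            predict(7, post_m1, data.Z[:5])

    def test_cg_and_intercept_never_predicted(self, small_fits):
        data, post_m1, _ = small_fits
        for s in (1, 2, 3):
            terms = predict(
                s, post_m1, data.Z[:5], days_aged=data.days_aged[:5],
                carcass_weight=data.carcass_weight[:5], pcs=data.pcs[:5],
                het=data.het[:5],
            ).terms
            assert "intercept" not in terms
            assert not any(t.startswith("cg") for t in terms)


class TestModelBehaviour:
    def test_single_breed_gebvs_agree_across_models(self):
        c = simulate_cohort(
            n_per_group=(500, 0, 0), m=800,
            design=PhenotypeDesign(breed_shift=0.0), seed=33,
        )
        data = make_training_data(c)
        cfg = BayesRConfig(n_iter=1_500, burn_in=500, thin=2, seed=14)
        g1 = train_model1(data, cfg).mean_g
        g5 = train_model5(data, cfg).mean_g
        gebv1, gebv5 = data.Z @ g1, data.Z @ g5
        assert np.corrcoef(gebv1, gebv5)[0, 1] > 0.95

    def test_model5_absorbs_breed_signal(self, small_cohort, small_fits):
        data, post_m1, post_m5 = small_fits
        var1 = np.var(data.Z @ post_m1.mean_g)
        var5 = np.var(data.Z @ post_m5.mean_g)
        assert var5 > var1

    def test_zero_pc_effect_estimates_near_zero(self):
        c = simulate_cohort(
            n_per_group=(400, 0, 0), m=600,
            design=PhenotypeDesign(breed_shift=0.0, heterosis_slope=0.0), seed=35,
        )
        data = make_training_data(c)
        cfg = BayesRConfig(n_iter=2_000, burn_in=500, thin=3, seed=15)
        post = train_model1(data, cfg)
        for pc in ("pc1", "pc2", "pc3", "pc4"):
            j = post.fixed_names.index(pc)
            sd = post.beta_samples[:, j].std()
            assert abs(post.mean_beta[j]) < 2.5 * sd

    def test_omitting_cg_inflates_residual_variance(self, small_cohort):
        data = make_training_data(small_cohort)
        cfg = BayesRConfig(n_iter=1_200, burn_in=400, thin=2, seed=16)
        X_full, names, _ = model5_design(data)
        full = fit_bayesr(data.y, X_full, data.Z, cfg, fixed_names=names)
        no_cg = np.column_stack([np.ones(len(data.y)), data.days_aged,
                                 data.carcass_weight])
        reduced = fit_bayesr(data.y, no_cg, data.Z, cfg,
                             fixed_names=["intercept", "days_aged", "carcass_weight"])
        assert reduced.sigma_e2_samples.mean() > full.sigma_e2_samples.mean()


class TestPcProjection:
    def test_projection_matches_training_scores(self):
        c = simulate_cohort(n_per_group=(120, 120, 0), m=600, seed=36)
        Z = c.geno.codes.astype(float)
        train_scores, val_scores = project_pcs(Z, Z, k=4)
        # projecting the training animals themselves reproduces their scores
        np.testing.assert_allclose(val_scores, train_scores, atol=1e-8)

    def test_projected_pc1_separates_held_out_breeds(self):
        c = simulate_cohort(n_per_group=(200, 200, 0), m=2000, seed=37)
        Z = c.geno.codes.astype(float)
        rng = np.random.default_rng(0)
        val = np.zeros(400, dtype=bool)
        val[rng.choice(400, 80, replace=False)] = True
        _, val_scores = project_pcs(Z[~val], Z[val], k=4)
        breed = (c.truth.group_labels[val] == "A").astype(float)
        assert abs(np.corrcoef(val_scores[:, 0], breed)[0, 1]) > 0.95
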