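import numpy as np
import pandas as pd
import pytest

from wkgs import (BackgroundMatrix, MEFit, PhenotypeTable, SimConfig,
                  additive_kernel, assemble_kernel_set, build_background,
                  estimate_h2, fit_me, fit_se, predict_cv2, predict_se,
                  simulate_dataset)
from wkgs.bayes import Chain
from wkgs.kernels import KernelSet


def _phenos_df(ids, envs, values):
    return PhenotypeTable(pd.DataFrame({
        "individual_id": ids, "environment": envs,
        "trait": "t", "value": values}))


class TestBuildBackground:
    def test_identity_mode(self):
        phenos = _phenos_df(["a", "b", "c"], ["E1"] * 3, [1.0, 2.0, 3.0])
        bg = build_background(phenos, "t")
        np.testing.assert_array_equal(bg.full, np.eye(3))

    def test_half_sib_quarter_for_same_family_pairs(self):
        ids = ["a1", "a2", "b1", "b2"]
        envs = ["E1", "E2", "E1", "E2"]
        fams = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        phenos = _phenos_df(ids, envs, [1.0, 2.0, 3.0, 4.0])
        bg = build_background(phenos, "t", families=fams, mode="half_sib")
        # record order is environment-major: a1, b1 (E1), a2, b2 (E2)
        order = bg.record_ids
        n_quarter = 0
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert bg.full[i, j] == 1.0
                elif fams[order[i]] == fams[order[j]]:
                    assert bg.full[i, j] == 0.25
                    n_quarter += 1
                else:
                    assert bg.full[i, j] == 0.0
        assert n_quarter == 4

    def test_record_permutation_conjugates_matrix(self):
        ids = ["c", "a", "b", "d"]
        fams = {x: ("F1" if x in "ab" else "F2") for x in ids}
        ph1 = _phenos_df(ids, ["E1"] * 4, [1.0, 2, 3, 4])
        ph2 = _phenos_df(sorted(ids), ["E1"] * 4, [2.0, 3, 1, 4])
        b1 = build_background(ph1, "t", families=fams, mode="half_sib")
        b2 = build_background(ph2, "t", families=fams, mode="half_sib")
        perm = [b1.record_ids.index(i) for i in b2.record_ids]
        np.testing.assert_array_equal(b2.full, b1.full[np.ix_(perm, perm)])

    def test_missing_family_label_is_an_error(self):
        phenos = _phenos_df(["a", "b"], ["E1", "E1"], [1.0, 2.0])
        with pytest.raises(ValueError, match="family"):
            build_background(phenos, "t", families={"a": "F"}, mode="half_sib")


def _se_sim(rng, n=250, h2=0.5, p=120):
    """Marker-effect simulation with p < n so genetic and background
    variance are identifiable (the genetic term lives in marker space)."""
    X = rng.integers(0, 3, size=(n, p)).astype(float)
    K = additive_kernel(X)
    beta = rng.standard_normal(p)
    g = (X - X.mean(axis=0)) @ beta
    g = g / g.std() * np.sqrt(h2)
    y = 1.0 + g + rng.standard_normal(n) * np.sqrt(1 - h2)
    return y, K, g


class TestFitSE:
    def test_equal_seeds_give_identical_chains(self, rng):
        y, K, _ = _se_sim(rng, n=60)
        a = fit_se(y, K, iters=400, burnin=200, seed=3)
        b = fit_se(y, K, iters=400, burnin=200, seed=3)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.sig2_g, b.sig2_g)
        np.testing.assert_array_equal(a.g_draws, b.g_draws)

    def test_heritability_recovery(self, rng):
        errs = []
        for rep in range(6):
            y, K, _ = _se_sim(np.random.default_rng(100 + rep), n=250, h2=0.6)
            fit = fit_se(y, K, iters=1500, burnin=500, seed=rep)
            errs.append(estimate_h2(fit)[0] - 0.6)
        assert abs(np.mean(errs)) < 0.1

    def test_pure_noise_trait_has_low_heritability(self, rng):
        y = rng.standard_normal(300)
        X = rng.integers(0, 3, size=(300, 120)).astype(float)
        fit = fit_se(y, additive_kernel(X), iters=1500, burnin=500, seed=0)
        # the proper variance prior keeps a small floor under sigma2_g, so
        # the posterior null heritability sits near 0.15, far below any signal
        assert estimate_h2(fit)[0] < 0.2
        # fitted genetic values should not track the noise
        assert abs(np.corrcoef(fit.g_mean, y)[0, 1]) < 0.9

    def test_vanishing_noise_drives_h2_to_one(self):
        y, K, _ = _se_sim(np.random.default_rng(5), h2=0.999)
        fit = fit_se(y, K, iters=1500, burnin=500, seed=1)
        assert estimate_h2(fit)[0] > 0.9

    def test_iters_must_exceed_burnin(self, rng):
        y, K, _ = _se_sim(rng, n=30)
        with pytest.raises(ValueError, match="burnin"):
            fit_se(y, K, iters=100, burnin=100)

    def test_non_psd_kernel_is_an_error(self, rng):
        K = -np.eye(20)
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_se(rng.standard_normal(20), K, iters=10, burnin=5)

    def test_predict_interpolates_training_data(self, rng):
        y, K, _ = _se_sim(rng, n=80, h2=0.9)
        tr = np.arange(60)
        te = np.arange(60, 80)
        fit = fit_se(y[tr], K[np.ix_(tr, tr)], iters=1000, burnin=500, seed=2)
        pred_tr = predict_se(fit, K, np.eye(80), tr, tr[:10])
        # conditioning on training data reproduces it closely at high h2
        assert np.corrcoef(pred_tr, y[:10])[0, 1] > 0.8


def _shared_lines_fixture(seed=11, n=80, h2=0.5, rho=0.8, p=300, n_qtl=60,
                          kernel="gaussian"):
    cfg = SimConfig(design="dh_shared_lines", n=n, m=2, p=p, n_qtl=n_qtl,
                    h2=h2, genetic_corr=rho, seed=seed)
    panel, phenos, truth = simulate_dataset(cfg)
    recs = phenos.for_trait("trait")
    if kernel == "gaussian":
        kset = assemble_kernel_set(
            panel, {}, record_ids=list(zip(recs["individual_id"],
                                           recs["environment"])))
    else:
        order = panel.row_index(recs[recs["environment"] == "E1"]
                                ["individual_id"])
        K = additive_kernel(panel.calls[order])
        kset = KernelSet(environments=["E1", "E2"],
                         full=np.tile(K, (2, 2)),
                         record_envs=recs["environment"].to_numpy(),
                         record_ids=list(recs["individual_id"]))
    bg = build_background(phenos, "trait")
    return panel, phenos, truth, kset, bg


def _post_corr(fit):
    G = fit.G_env.mean(axis=0)
    return G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])


class TestFitME:
    def test_regimes_agree_on_shared_lines(self):
        # additive kernel with p < n keeps the variance split identifiable,
        # so the two samplers' differing covariance priors wash out
        _, phenos, truth, kset, bg = _shared_lines_fixture(
            n=120, p=80, n_qtl=80, kernel="additive")
        kron = fit_me(phenos, kset, bg, iters=3000, burnin=1500, seed=1,
                      regime="kronecker")
        gen = fit_me(phenos, kset, bg, iters=3000, burnin=1500, seed=1,
                     regime="general")
        assert abs(_post_corr(kron) - _post_corr(gen)) < 0.15
        np.testing.assert_allclose(estimate_h2(kron), estimate_h2(gen),
                                   atol=0.12)
        np.testing.assert_allclose(kron.mu.mean(axis=0), gen.mu.mean(axis=0),
                                   atol=0.25)

    def test_every_stored_G_env_draw_is_positive_definite(self):
        _, phenos, _, kset, bg = _shared_lines_fixture(seed=5, n=50, p=150)
        for regime in ("kronecker", "general"):
            fit = fit_me(phenos, kset, bg, iters=600, burnin=300, seed=2,
                         regime=regime)
            for G in fit.G_env[::25]:
                np.linalg.cholesky(G)

    def test_chains_reproducible_for_fixed_seed(self):
        _, phenos, _, kset, bg = _shared_lines_fixture(seed=6, n=40, p=120)
        a = fit_me(phenos, kset, bg, iters=400, burnin=200, seed=9,
                   regime="general")
        b = fit_me(phenos, kset, bg, iters=400, burnin=200, seed=9,
                   regime="general")
        np.testing.assert_array_equal(a.G_env, b.G_env)
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_single_environment_general_fit_matches_se(self, rng):
        y, K, _ = _se_sim(rng, n=120, h2=0.5)
        ids = [f"i{k}" for k in range(120)]
        phenos = _phenos_df(ids, ["E1"] * 120, y)
        # order by id to match the phenotype table's canonical record order
        order = np.argsort(ids)
        kset = KernelSet(environments=["E1"], full=K[np.ix_(order, order)],
                         record_envs=np.array(["E1"] * 120),
                         record_ids=[ids[i] for i in order])
        bg = build_background(phenos, "t")
        me = fit_me(phenos, kset, bg, iters=4000, burnin=2000, seed=3,
                    regime="general", trait="t")
        se = fit_se(y[order], kset.full, iters=4000, burnin=2000, seed=3)
        assert abs(me.G_env[:, 0, 0].mean() - se.sig2_g.mean()) < 0.15
        assert abs(me.sig2_e[:, 0].mean() - se.sig2_e.mean()) < 0.15
        assert abs(me.mu[:, 0].mean() - se.mu.mean()) < 0.15

    def test_half_sib_background_fits_disjoint_design(self, halfsib_dataset):
        """The general sampler with half-sib background runs end to end on a
        disjoint multi-family design and keeps its covariance draws PD."""
        panel, phenos, _ = halfsib_dataset
        recs = phenos.for_trait("trait")
        kset = assemble_kernel_set(
            panel, {}, record_ids=list(zip(recs["individual_id"],
                                           recs["environment"])))
        bg = build_background(phenos, "trait", families=panel.family_of,
                              mode="half_sib")
        fit = fit_me(phenos, kset, bg, iters=800, burnin=400, seed=4,
                     regime="general")
        assert fit.background_mode == "half_sib"
        for M in np.concatenate([fit.G_env[::40], fit.B_env[::40]]):
            np.linalg.cholesky(M)
        # predictions for a held-out tail of records are finite and sane
        mask = np.ones(len(recs), dtype=bool)
        mask[::7] = False
        fit2 = fit_me(phenos, kset, bg, iters=800, burnin=400, seed=4,
                      regime="general", train_mask=mask)
        pred = predict_cv2(fit2, kset, bg, mask, ~mask)
        assert np.all(np.isfinite(pred))
        assert pred.std() > 0

    def test_kronecker_requires_matching_lines(self):
        ids = ["a", "b", "c"]
        phenos = _phenos_df(ids + ["a", "b"], ["E1"] * 3 + ["E2"] * 2,
                            [1.0, 2, 3, 4, 5])
        K = np.eye(5)
        kset = KernelSet(environments=["E1", "E2"], full=K,
                         record_envs=np.array(["E1"] * 3 + ["E2"] * 2),
                         record_ids=["a", "b", "c", "a", "b"])
        bg = build_background(phenos, "t")
        with pytest.raises(ValueError, match="identical lines"):
            fit_me(phenos, kset, bg, iters=20, burnin=10, regime="kronecker",
                   trait="t")


def _manual_fit(mu, G, Bv, sig2_e, y_tr, envs, train_mask, n_draws=4):
    m = len(mu)
    S = n_draws
    chain = Chain(traces={"mu": np.tile(mu, (S, 1))}, iters=S, burnin=0, seed=0)
    return MEFit(environments=[f"E{j+1}" for j in range(m)],
                 mu=np.tile(mu, (S, 1)),
                 G_env=np.tile(G, (S, 1, 1)),
                 B_env=np.tile(Bv, (S, 1, 1)),
                 sig2_e=np.tile(sig2_e, (S, 1)),
                 g_mean=np.zeros(train_mask.sum()),
                 b_mean=np.zeros(train_mask.sum()),
                 y=y_tr, record_envs=envs[train_mask], train_mask=train_mask,
                 background_mode="identity", regime="general", chain=chain)


class TestPredictCV2:
    def test_no_cross_covariance_predicts_environment_means(self):
        """Diagonal G_env, identity kernel and background: conditional mean
        collapses to the per-environment intercept."""
        envs = np.array(["E1"] * 3 + ["E2"] * 3)
        ids = [f"i{k}" for k in range(6)]
        kset = KernelSet(environments=["E1", "E2"], full=np.eye(6),
                         record_envs=envs, record_ids=ids)
        bg = BackgroundMatrix(full=np.eye(6), mode="identity",
                              record_envs=envs, record_ids=ids)
        train = np.array([True, True, False, True, True, False])
        fit = _manual_fit(np.array([1.0, 2.0]), np.diag([1.0, 1.0]),
                          np.diag([0.5, 0.5]), np.array([0.3, 0.3]),
                          y_tr=np.array([9.0, -3.0, 5.0, 0.0]),
                          envs=envs, train_mask=train)
        pred = predict_cv2(fit, kset, bg, train, ~train, thin=1)
        np.testing.assert_allclose(pred, [1.0, 2.0])

    def test_duplicate_of_training_record_interpolates_as_noise_vanishes(self):
        envs = np.array(["E1"] * 3)
        ids = ["a", "b", "test"]
        K = np.eye(3)
        K[1, 2] = K[2, 1] = 1.0  # test record genetically identical to 'b'
        kset = KernelSet(environments=["E1"], full=K, record_envs=envs,
                         record_ids=ids)
        bg = BackgroundMatrix(full=np.eye(3), mode="identity",
                              record_envs=envs, record_ids=ids)
        train = np.array([True, True, False])
        fit = _manual_fit(np.array([0.0]), np.array([[1.0]]),
                          np.array([[1e-12]]), np.array([1e-8]),
                          y_tr=np.array([4.0, 7.5]), envs=envs,
                          train_mask=train)
        pred = predict_cv2(fit, kset, bg, train, ~train, thin=1)
        assert pred[0] == pytest.approx(7.5, abs=1e-4)

    def test_overlapping_masks_rejected(self):
        envs = np.array(["E1"] * 3)
        kset = KernelSet(environments=["E1"], full=np.eye(3),
                         record_envs=envs, record_ids=["a", "b", "c"])
        bg = BackgroundMatrix(full=np.eye(3), mode="identity",
                              record_envs=envs, record_ids=["a", "b", "c"])
        train = np.array([True, True, False])
        fit = _manual_fit(np.array([0.0]), np.array([[1.0]]),
                          np.array([[0.1]]), np.array([0.1]),
                          y_tr=np.array([1.0, 2.0]), envs=envs,
                          train_mask=train)
        with pytest.raises(ValueError, match="overlap"):
            predict_cv2(fit, kset, bg, train, train)


class TestChainDiagnostics:
    def test_iid_trace_diagnostics(self, rng):
        chain = Chain(traces={"x": rng.standard_normal(2000)},
                      iters=2000, burnin=0, seed=0)
        d = chain.diagnostics()
        assert d.loc[0, "ess"] > 500
        assert abs(d.loc[0, "rhat"] - 1.0) < 0.05

    def test_long_format_round_trip(self, rng):
        chain = Chain(traces={"mu": rng.standard_normal((10, 2))},
                      iters=10, burnin=0, seed=0)
        df = chain.to_frame()
        assert set(df.columns) == {"draw", "parameter", "value"}
        assert len(df) == 20

    def test_mismatched_trace_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            Chain(traces={"a": np.zeros(5), "b": np.zeros(6)},
                  iters=5, burnin=0, seed=0)
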