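"""QTL factors, DSM inference against enumeration oracles, and training."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsmlink.dsm import (
    DSMParams,
    EQTLMap,
    ExpressionProfile,
    GenotypeProfile,
    QTLFactorParams,
    TrainConfig,
    conditional_loglik,
    dosage_matrix,
    dsm_exact_diploid_logscore,
    dsm_haplotype_logmarginal,
    dsm_logscore,
    dsm_score_matrix,
    evidence_from_expression,
    factor_probs,
    predict_dosage,
    qtl_factor,
    train_dsm,
    windowed_training,
    _objective_and_grad,
    _prepare_training,
)
from dsmlink.hmm import (
    HaplotypePanel,
    HMMParams,
    Haplotype,
    brute_force_marginal,
    build_hmm_params,
    hmm_loglik,
)
from dsmlink.simulate import SimConfig, make_linking_fixture


def _random_dsm(fx, rng):
    params = DSMParams.flat(fx.panel, fx.eqtl_map, build_hmm_params(fx.panel, 1.0, 0.05))
    params.qtl = QTLFactorParams(
        rng.normal(0, 1, fx.eqtl_map.n_eqtls),
        [rng.normal(0, 1, len(g)) for g in fx.eqtl_map.egene_sets],
    )
    return params


class TestQTLFactor:
    def test_flat_factor_is_half(self):
        e = np.array([1.3, -2.0])
        assert qtl_factor(1, e, 0.0, np.zeros(2)) == 0.5
        assert qtl_factor(0, e, 0.0, np.zeros(2)) == 0.5

    def test_logit_ln3_gives_three_quarters(self):
        assert qtl_factor(1, np.array([np.log(3)]), 0.0, np.array([1.0])) == pytest.approx(0.75)
        assert qtl_factor(0, np.array([np.log(3)]), 0.0, np.array([1.0])) == pytest.approx(0.25)

    def test_saturates_toward_one(self):
        assert qtl_factor(1, np.array([50.0]), 0.0, np.array([1.0])) > 1 - 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qtl_factor(1, np.zeros(3), 0.0, np.zeros(2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5),
        st.lists(st.floats(-3, 3), min_size=1, max_size=4),
        st.integers(0, 10**6),
    )
    def test_factor_normalization(self, alpha, beta, seed):
        """phi(0,.) + phi(1,.) = 1 for any parameters and expression."""
        beta = np.array(beta)
        e = np.random.default_rng(seed).normal(size=beta.shape[0])
        total = qtl_factor(0, e, alpha, beta) + qtl_factor(1, e, alpha, beta)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestHaplotypeMarginal:
    def test_flat_factors_shift_hmm_by_half_per_site(self, tiny_fixture):
        fx = tiny_fixture
        params = DSMParams.flat(fx.panel, fx.eqtl_map)
        h = fx.test_genotypes[0].maternal
        e = fx.test_expressions[0]
        expected = hmm_loglik(h, fx.panel, params.hmm) + fx.eqtl_map.n_eqtls * np.log(0.5)
        assert dsm_haplotype_logmarginal(h, e, params) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_evidence_weighted_enumeration(self, tiny_fixture):
        fx = tiny_fixture
        rng = np.random.default_rng(9)
        for _ in range(25):
            params = _random_dsm(fx, rng)
            e = fx.test_expressions[int(rng.integers(len(fx.test_expressions)))]
            h = fx.test_genotypes[int(rng.integers(len(fx.test_genotypes)))].maternal
            ev = evidence_from_expression(params, e)
            assert dsm_haplotype_logmarginal(h, e, params) == pytest.approx(
                brute_force_marginal(h, fx.panel, params.hmm, ev), abs=1e-10
            )

    def test_strengthening_correct_factor_increases_marginal(self, tiny_fixture):
        """Pushing a factor further toward the carried allele cannot hurt."""
        fx = tiny_fixture
        rng = np.random.default_rng(10)
        params = _random_dsm(fx, rng)
        h = fx.test_genotypes[0].maternal
        e = fx.test_expressions[0]
        base = dsm_haplotype_logmarginal(h, e, params)
        probs = factor_probs(params, [e])[0]
        for s in range(fx.eqtl_map.n_eqtls):
            carried = h.alleles[fx.eqtl_map.site_indices[s]]
            # move alpha toward the carried allele's direction
            shift = 0.5 if carried == 1 else -0.5
            stronger = _random_dsm(fx, np.random.default_rng(10))
            stronger.qtl.alphas[s] += shift
            new_p = factor_probs(stronger, [e])[0][s]
            moved_toward = (new_p > probs[s]) if carried == 1 else (new_p < probs[s])
            assert moved_toward
            assert dsm_haplotype_logmarginal(h, e, stronger) >= base - 1e-12


class TestMatchScore:
    def test_flat_factors_tie_all_candidates(self, tiny_fixture):
        fx = tiny_fixture
        params = DSMParams.flat(fx.panel, fx.eqtl_map)
        e = fx.test_expressions[0]
        scores = [dsm_logscore(g, e, params) for g in fx.test_genotypes]
        expected = 2 * fx.eqtl_map.n_eqtls * np.log(0.5)
        assert np.allclose(scores, expected, atol=1e-9)

    def test_single_eqtl_hmm_terms_cancel(self):
        # K=1 panel: the chain contributes identically to p~ and p_HMM
        panel = HaplotypePanel(
            np.ones((1, 3), dtype=int), ["a", "b", "c"], [1, 2, 3], np.zeros(3)
        )
        emap = EQTLMap([1], [["g1"]])
        params = DSMParams.flat(panel, emap, HMMParams(np.zeros(2), 0.1, np.ones(1)))
        params.qtl = QTLFactorParams(np.array([0.4]), [np.array([0.8])])
        params.__post_init__()
        e = ExpressionProfile(np.array([1.5]), ["g1"])
        x = GenotypeProfile(Haplotype([1, 1, 0]), Haplotype([1, 0, 1]))
        p = factor_probs(params, [e])[0, 0]
        expected = np.log(p) + np.log(1 - p)  # h_m = 1, h_p = 0 at the eQTL site
        assert dsm_logscore(x, e, params) == pytest.approx(expected, abs=1e-9)

    def test_matrix_route_matches_definitional_route(self, tiny_fixture):
        fx = tiny_fixture
        params = _random_dsm(fx, np.random.default_rng(11))
        mat = dsm_score_matrix(fx.test_expressions, fx.test_genotypes, params)
        for j, e in enumerate(fx.test_expressions):
            for i, g in enumerate(fx.test_genotypes):
                assert mat[j, i] == pytest.approx(dsm_logscore(g, e, params), abs=1e-9)


class TestExactDiploid:
    def test_product_factor_equals_decoupled_sum(self, tiny_fixture):
        fx = tiny_fixture
        params = _random_dsm(fx, np.random.default_rng(12))
        g, e = fx.test_genotypes[0], fx.test_expressions[0]
        exact = dsm_exact_diploid_logscore(g, e, params, factor="product")
        decoupled = dsm_haplotype_logmarginal(g.maternal, e, params) + dsm_haplotype_logmarginal(
            g.paternal, e, params
        )
        assert exact == pytest.approx(decoupled, abs=1e-10)

    def test_ordinal_factor_matches_joint_path_enumeration(self):
        rng = np.random.default_rng(13)
        K, V = 2, 4
        cfg = SimConfig(
            K_panel=K, V_sites=V, n_eqtls=2, genes_per_eqtl=1, n_noise_genes=1,
            ld_block_size=2, seed=21,
        )
        fx = make_linking_fixture(cfg, n_train=4, n_test=1, n_decoys=0)
        params = _random_dsm(fx, rng)
        g, e = fx.test_genotypes[0], fx.test_expressions[0]
        got = dsm_exact_diploid_logscore(g, e, params, factor="ordinal")

        # independent enumeration over all (K*K)^V joint hidden paths
        from dsmlink.dsm import _genotype_factor, _logits, _standardized, expression_matrix

        logits = _logits(params, _standardized(params, expression_matrix([e], params.gene_ids)))[0]
        site_logit = dict(zip(map(int, fx.eqtl_map.site_indices), logits))
        eps = params.hmm.emission_error
        rho = params.hmm.switch_prob
        dose = g.dosage
        total = 0.0
        for zm in itertools.product(range(K), repeat=V):
            for zp in itertools.product(range(K), repeat=V):
                p = (1 / K) ** 2
                for s in range(V):
                    if s > 0:
                        for prev, cur in ((zm[s - 1], zm[s]), (zp[s - 1], zp[s])):
                            p *= (1 - rho[s - 1]) * (prev == cur) + rho[s - 1] / K
                    p *= (1 - eps) if fx.panel.alleles[zm[s], s] == g.maternal.alleles[s] else eps
                    p *= (1 - eps) if fx.panel.alleles[zp[s], s] == g.paternal.alleles[s] else eps
                    if s in site_logit:
                        p *= _genotype_factor(int(dose[s]), site_logit[s], "ordinal", 1.0)
                total += p
        assert got == pytest.approx(np.log(total), abs=1e-10)

    def test_symmetric_input_invariant_to_haplotype_swap(self, tiny_fixture):
        fx = tiny_fixture
        params = _random_dsm(fx, np.random.default_rng(14))
        g, e = fx.test_genotypes[1], fx.test_expressions[1]
        swapped = GenotypeProfile(g.paternal, g.maternal, g.sample_id)
        for kind in ("product", "ordinal"):
            assert dsm_exact_diploid_logscore(g, e, params, factor=kind) == pytest.approx(
                dsm_exact_diploid_logscore(swapped, e, params, factor=kind), abs=1e-12
            )


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(20)
        for trial in range(20):
            cfg = SimConfig(
                K_panel=int(rng.integers(2, 5)),
                V_sites=int(rng.integers(4, 8)),
                n_eqtls=3,
                genes_per_eqtl=int(rng.integers(1, 3)),
                n_noise_genes=2,
                ld_block_size=2,
                seed=100 + trial,
            )
            fx = make_linking_fixture(cfg, n_train=6, n_test=1, n_decoys=0)
            data, _ = _prepare_training(
                fx.train_pairs, fx.panel, fx.eqtl_map, TrainConfig()
            )
            alphas = rng.normal(0, 0.5, 3)
            betas = [rng.normal(0, 0.5, len(g)) for g in fx.eqtl_map.egene_sets]
            _, g_a, g_b = _objective_and_grad(alphas, betas, data)
            eps = 1e-6

            def value(a, b):
                v, _, _ = _objective_and_grad(a, b, data, want_grad=False)
                return v

            for s in range(3):
                a2 = alphas.copy()
                a2[s] += eps
                up = value(a2, betas)
                a2[s] -= 2 * eps
                dn = value(a2, betas)
                fd = (up - dn) / (2 * eps)
                assert abs(fd - g_a[s]) / max(abs(fd), 1e-8) < 1e-4
                for j in range(betas[s].shape[0]):
                    b2 = [b.copy() for b in betas]
                    b2[s][j] += eps
                    up = value(alphas, b2)
                    b2[s][j] -= 2 * eps
                    dn = value(alphas, b2)
                    fd = (up - dn) / (2 * eps)
                    assert abs(fd - g_b[s][j]) / max(abs(fd), 1e-8) < 1e-4


def _recovery_config(seed):
    """Independent common-variant eQTLs with one strongly coupled eGene each."""
    return SimConfig(
        K_panel=40, V_sites=40, n_eqtls=20, genes_per_eqtl=1,
        effect_low=3.0, effect_high=3.0, noise_sd=0.5,
        ld_block_size=1, n_founders=40, n_noise_genes=5,
        founder_freq_low=0.35, founder_freq_high=0.65, seed=seed,
    )


class TestTraining:
    def test_loss_trace_decreases(self, trained_dsm):
        loss = trained_dsm.train_loss
        assert loss[-1] < loss[0]
        # allow small optimizer noise but require near-monotone descent
        increases = np.diff(loss)
        assert (increases > 1e-3).sum() <= len(loss) // 10

    def test_requires_two_pairs(self, tiny_fixture):
        fx = tiny_fixture
        with pytest.raises(ValueError):
            train_dsm(fx.train_pairs[:1], fx.panel, fx.eqtl_map)

    def test_recovers_effect_signs_and_predicts_heldout_dosage(self):
        cfg = _recovery_config(11)
        fx = make_linking_fixture(cfg, n_train=500, n_test=100, n_decoys=0)
        tc = TrainConfig(recomb_scale=cfg.recomb_scale, emission_error=cfg.copy_error)
        params = train_dsm(fx.train_pairs, fx.panel, fx.eqtl_map, tc)
        true_signs = np.array(
            [
                np.sign(fx.effects[(int(s), genes[0])])
                for s, genes in zip(fx.eqtl_map.site_indices, fx.eqtl_map.egene_sets)
            ]
        )
        fitted_signs = np.array([np.sign(b[0]) for b in params.qtl.betas])
        assert (true_signs == fitted_signs).mean() >= 0.95
        P = factor_probs(params, fx.test_expressions)
        D = dosage_matrix(fx.test_genotypes, fx.eqtl_map.site_indices)
        assert (predict_dosage(P) == D).mean() > 0.9

    def test_permuted_labels_learn_nothing(self):
        cfg = _recovery_config(12)
        fx = make_linking_fixture(cfg, n_train=500, n_test=100, n_decoys=0)
        tc = TrainConfig(recomb_scale=cfg.recomb_scale, emission_error=cfg.copy_error)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(fx.train_pairs))
        shuffled = [
            (fx.train_pairs[i][0], fx.train_pairs[perm[i]][1])
            for i in range(len(perm))
        ]
        params = train_dsm(shuffled, fx.panel, fx.eqtl_map, tc)
        P = factor_probs(params, fx.test_expressions)
        assert abs(P.mean() - 0.5) < 0.1

    def test_duplicated_egene_calibration(self):
        """Two copies of the same eGene must fit the same combined logit as
        the single-gene model (redundancy absorbed, not double-counted)."""
        cfg = _recovery_config(13)
        fx = make_linking_fixture(cfg, n_train=400, n_test=60, n_decoys=0)
        # compare converged optima: the equality is a property of the
        # objective's maximizer, not of a fixed-budget optimization state
        tc = TrainConfig(
            epochs=600, recomb_scale=cfg.recomb_scale, emission_error=cfg.copy_error
        )
        single = train_dsm(fx.train_pairs, fx.panel, fx.eqtl_map, tc)

        def duplicate(e):
            return ExpressionProfile(
                np.concatenate([e.values, e.values]),
                e.gene_ids + [g + "_copy" for g in e.gene_ids],
                e.sample_id,
            )

        dup_map = EQTLMap(
            fx.eqtl_map.site_indices,
            [[g, g + "_copy"] for genes in fx.eqtl_map.egene_sets for g in genes[:1]],
            significance=fx.eqtl_map.significance,
        )
        dup_pairs = [(g, duplicate(e)) for g, e in fx.train_pairs]
        dup = train_dsm(dup_pairs, fx.panel, dup_map, tc)
        L1 = np.log(factor_probs(single, fx.test_expressions)) - np.log1p(
            -factor_probs(single, fx.test_expressions)
        )
        L2p = factor_probs(dup, [duplicate(e) for e in fx.test_expressions])
        L2 = np.log(L2p) - np.log1p(-L2p)
        # combined logits agree on held-out samples up to optimization noise
        assert np.median(np.abs(L1 - L2)) < 0.2
        assert np.corrcoef(L1.ravel(), L2.ravel())[0, 1] > 0.995

    def test_linked_sites_no_worse_than_independent_product(self):
        """Held-out log-loss of the jointly trained DSM is at least as good
        as a product of independently fitted per-site logistic factors when
        eQTLs sit in perfect LD and duplicate the same signal."""
        from sklearn.linear_model import LogisticRegression

        cfg = SimConfig(
            K_panel=30, V_sites=20, n_eqtls=10, genes_per_eqtl=1,
            effect_low=1.5, effect_high=2.0, noise_sd=1.0,
            ld_block_size=10, n_founders=3, n_noise_genes=2, seed=17,
        )
        fx = make_linking_fixture(cfg, n_train=300, n_test=80, n_decoys=0)
        tc = TrainConfig(recomb_scale=cfg.recomb_scale, emission_error=cfg.copy_error)
        params = train_dsm(fx.train_pairs, fx.panel, fx.eqtl_map, tc)
        test_pairs = list(zip(fx.test_genotypes, fx.test_expressions))
        dsm_ll = conditional_loglik(test_pairs, params)

        # naive factors: independent per-site logistic regressions of the
        # allele on expression (the two-stage approach joint training replaces),
        # plugged into the identical normalized sequence likelihood
        from dsmlink.dsm import expression_matrix, _standardized

        E_tr = _standardized(params, expression_matrix([e for _, e in fx.train_pairs], params.gene_ids))
        D_tr = dosage_matrix([g for g, _ in fx.train_pairs], fx.eqtl_map.site_indices)
        naive = DSMParams.flat(fx.panel, fx.eqtl_map, params.hmm)
        naive.gene_ids = params.gene_ids
        naive.gene_means, naive.gene_sds = params.gene_means, params.gene_sds
        naive.__post_init__()
        for s, idx in enumerate(naive._gene_idx):
            y = np.concatenate([(D_tr[:, s] >= 1), (D_tr[:, s] == 2)]).astype(int)
            X = np.vstack([E_tr[:, idx], E_tr[:, idx]])
            clf = LogisticRegression(C=10.0).fit(X, y)
            naive.qtl.alphas[s] = clf.intercept_[0]
            naive.qtl.betas[s] = clf.coef_[0]
        naive_ll = conditional_loglik(test_pairs, naive)
        assert dsm_ll >= naive_ll


class TestWindowedTraining:
    def test_partition_sizes(self, tiny_fixture):
        fx = tiny_fixture
        cfg = SimConfig(
            K_panel=4, V_sites=10, n_eqtls=10, genes_per_eqtl=1, n_noise_genes=0,
            ld_block_size=2, seed=30,
        )
        f2 = make_linking_fixture(cfg, n_train=6, n_test=1, n_decoys=0)
        tc = TrainConfig(epochs=2)
        wm = windowed_training(f2.train_pairs, f2.panel, f2.eqtl_map, window_size=3, cfg=tc)
        assert [m.eqtl_map.n_eqtls for m in wm.models] == [3, 3, 3, 1]

    def test_single_window_equals_plain_training(self, tiny_fixture):
        fx = tiny_fixture
        tc = TrainConfig(epochs=5)
        wm = windowed_training(fx.train_pairs, fx.panel, fx.eqtl_map, window_size=1000, cfg=tc)
        assert len(wm.models) == 1
        plain = train_dsm(fx.train_pairs, fx.panel, fx.eqtl_map, tc)
        g, e = fx.test_genotypes[0], fx.test_expressions[0]
        assert wm.logscore(g, e) == pytest.approx(
            dsm_score_matrix([e], [g], plain)[0, 0], abs=1e-9
        )

    def test_empty_map_rejected(self, tiny_fixture):
        fx = tiny_fixture
        with pytest.raises(ValueError):
            windowed_training(fx.train_pairs, fx.panel, EQTLMap([], []), 3)
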