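"""Cox loss oracles, attention mechanics and MIL training behaviour."""

import numpy as np
import pytest

from milsurv._coxloss import cox_nll_grad
from milsurv.features import PhenotypeBag, bags_from_cohort, cluster_phenotypes
from milsurv.model import (MILSurvivalModel, ModelConfig, _FlatBags, _backward,
                           _forward, _init_params, attention_aggregate,
                           cox_partial_nll, cross_validate, embed_cluster,
                           predict_risk, train, train_ensemble)
from milsurv.survival import concordance_index
from milsurv.synthetic import generate_cohort, phenotype_effect_pattern


def _bag(slot_sizes, d=4, seed=0, pid="p"):
    rng = np.random.default_rng(seed)
    slots = [rng.normal(size=(s, d)) if s else np.zeros((0, d))
             for s in slot_sizes]
    return PhenotypeBag(pid, len(slot_sizes), slots)


class TestCoxLoss:
    def test_closed_form_at_zero_risks(self):
        # 3 subjects, all events, distinct times: ln 3 + ln 2 + ln 1
        val = cox_partial_nll([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert val == pytest.approx(np.log(6), abs=1e-12)

    def test_location_invariance(self, rng):
        r = rng.normal(size=12)
        t = rng.exponential(size=12)
        e = rng.integers(0, 2, 12)
        e[0] = 1
        a = cox_partial_nll(r, t, e)
        b = cox_partial_nll(r + 7.3, t, e)
        assert a == pytest.approx(b, rel=1e-10)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="without events"):
            cox_partial_nll([0.0, 1.0], [1.0, 2.0], [0, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        r = rng.normal(size=n)
        t = np.round(rng.exponential(size=n), 1)  # induces ties
        e = rng.integers(0, 2, n)
        e[:3] = 1
        _, grad = cox_nll_grad(r, t, e)
        eps = 1e-6
        for j in range(n):
            rp, rm = r.copy(), r.copy()
            rp[j] += eps
            rm[j] -= eps
            fd = (cox_partial_nll(rp, t, e) - cox_partial_nll(rm, t, e)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestNetworkMechanics:
    def _model(self, k=3, d=4, seed=0):
        cfg = ModelConfig(k=k, d=d, embed_dims=(8, 6), attention_dim=5, seed=seed)
        params = _init_params(cfg, np.random.default_rng(seed))
        return MILSurvivalModel(cfg, params)

    def test_singleton_embedding_is_network_output(self, rng):
        model = self._model()
        x = rng.normal(size=(1, 4))
        single = embed_cluster(x, model)
        triple = embed_cluster(np.tile(x, (3, 1)), model)
        assert np.allclose(single, triple)

    def test_embedding_permutation_invariant(self, rng):
        model = self._model()
        X = rng.normal(size=(7, 4))
        a = embed_cluster(X, model)
        b = embed_cluster(X[rng.permutation(7)], model)
        assert np.array_equal(a, b)

    def test_singleton_attention_weight_is_one(self, rng):
        model = self._model()
        E = rng.normal(size=(3, 6))
        mask = np.array([False, True, False])
        _, att = attention_aggregate(E, mask, model)
        assert att[1] == 1.0
        assert att[0] == att[2] == 0.0

    def test_identical_embeddings_share_weight(self, rng):
        model = self._model(k=2)
        e = rng.normal(size=6)
        _, att = attention_aggregate(np.stack([e, e]), np.array([True, True]),
                                     model)
        assert np.allclose(att, 0.5)

    def test_attention_sums_to_one(self, rng):
        model = self._model(k=5)
        for _ in range(5):
            E = rng.normal(size=(5, 6))
            mask = rng.integers(0, 2, 5).astype(bool)
            if not mask.any():
                continue
            _, att = attention_aggregate(E, mask, model)
            assert att.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(att >= 0)

    def test_all_empty_rejected(self, rng):
        model = self._model()
        with pytest.raises(ValueError, match="empty"):
            attention_aggregate(rng.normal(size=(3, 6)), np.zeros(3, bool), model)

    def test_predict_deterministic_and_order_invariant(self, rng):
        model = self._model()
        bag = _bag([3, 0, 5], seed=1)
        out1 = predict_risk(model, bag)
        out2 = predict_risk(model, bag)
        assert out1.risk == out2.risk
        # permute tiles within a cluster
        perm_slots = [s[::-1].copy() for s in bag.slots]
        out3 = predict_risk(model, PhenotypeBag("p", 3, perm_slots))
        assert out3.risk == pytest.approx(out1.risk, rel=1e-12)
        assert np.allclose(out3.attention, out1.attention)
        assert out1.attention.sum() == pytest.approx(1.0)
        assert out1.attention[1] == 0.0            # empty cluster masked

    def test_cluster_relabeling_leaves_risk_unchanged(self):
        """Phenotype indices are nominal: permuting cluster slots (and
        nothing else) must not change the risk."""
        model = self._model()
        bag = _bag([2, 3, 4], seed=5)
        perm = [2, 0, 1]
        out1 = predict_risk(model, bag)
        out2 = predict_risk(model, PhenotypeBag("p", 3,
                                                [bag.slots[i] for i in perm]))
        assert out2.risk == pytest.approx(out1.risk, rel=1e-12)
        assert np.allclose(out2.attention, out1.attention[perm])

    def test_k_mismatch_rejected(self):
        model = self._model(k=3)
        with pytest.raises(ValueError, match="k="):
            model.predict(_bag([1, 2]))

    def test_full_network_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        bags = [_bag([2, 1, 0], seed=i, pid=f"p{i}") for i in range(6)]
        t = rng.exponential(size=6) + 0.1
        e = np.array([1, 1, 0, 1, 0, 1])
        cfg = ModelConfig(k=3, d=4, embed_dims=(5, 4), attention_dim=3, seed=0)
        params = _init_params(cfg, rng)
        flat = _FlatBags(bags)

        def loss(p):
            r, _ = _forward(p, flat)
            return cox_partial_nll(r, t, e)

        r, cache = _forward(params, flat)
        _, dr = cox_nll_grad(r, t, e)
        grads = _backward(params, flat, cache, dr)
        eps = 1e-6
        for key, g in grads.items():
            flat_g = np.ravel(g)
            idx = rng.choice(flat_g.size, size=min(6, flat_g.size), replace=False)
            for j in idx:
                pp = {k: v.copy() for k, v in params.items()}
                np.ravel(pp[key])[j] += eps
                pm = {k: v.copy() for k, v in params.items()}
                np.ravel(pm[key])[j] -= eps
                fd = (loss(pp) - loss(pm)) / (2 * eps)
                assert flat_g[j] == pytest.approx(fd, rel=1e-4, abs=1e-7), key


class TestTraining:
    def _cohort_bags(self, seed, n=120, effect=2.0, bag=(30, 80)):
        K = 6
        co = generate_cohort(n, K_true=K, d=8,
                             bag_size_range=bag,
                             beta_phenotype=phenotype_effect_pattern(K, effect),
                             censor_rate=0.3, seed=seed)
        X = np.concatenate([co.features[p] for p in co.patients])
        _, clus = cluster_phenotypes(X, k=K, seed=0)
        return co, bags_from_cohort(co, clus)

    def test_loss_non_increasing_on_smooth_run(self):
        co, bags = self._cohort_bags(0, n=60)
        cfg = ModelConfig(k=6, d=8, epochs=40, seed=0, learning_rate=2e-3,
                          instance_jitter=0.0, weight_decay=0.0)
        model = train(bags, co.times, co.events, cfg)
        h = np.array(model.loss_history)
        upticks = np.sum(np.diff(h) > 1e-6)
        assert upticks <= 0.05 * len(h)
        assert h[-1] < h[0]

    def test_needs_two_events(self):
        bags = [_bag([2, 1], seed=i, pid=f"p{i}") for i in range(3)]
        with pytest.raises(ValueError, match="2 patients with events"):
            train(bags, [1.0, 2.0, 3.0], [1, 0, 0], ModelConfig(k=2, d=4))

    def test_training_deterministic_under_seed(self):
        co, bags = self._cohort_bags(1, n=40)
        cfg = ModelConfig(k=6, d=8, epochs=5, seed=3)
        m1 = train(bags, co.times, co.events, cfg)
        m2 = train(bags, co.times, co.events, cfg)
        for key in m1.params:
            assert np.array_equal(m1.params[key], m2.params[key])

    def test_recovers_planted_signal_on_heldout(self):
        co, bags = self._cohort_bags(6, n=200, bag=(100, 300))
        rng = np.random.default_rng(0)
        idx = rng.permutation(200)
        tr, te = idx[:150], idx[150:]
        cfg = ModelConfig(k=6, d=8, epochs=30, seed=0)
        ens = train_ensemble([bags[i] for i in tr], co.times[tr],
                             co.events[tr], cfg, n_members=3)
        risks = ens.predict_many([bags[i] for i in te])
        c = concordance_index(risks, co.times[te], co.events[te])
        assert c >= 0.70
        # predicted risks track the generating log-hazard
        from scipy.stats import spearmanr
        rho = spearmanr(risks, co.log_hazard[te]).statistic
        assert rho > 0.6

    def test_save_load_roundtrip(self, tmp_path):
        co, bags = self._cohort_bags(2, n=40)
        cfg = ModelConfig(k=6, d=8, epochs=3, seed=1)
        model = train(bags, co.times, co.events, cfg)
        model.save(tmp_path / "ckpt")
        back = MILSurvivalModel.load(tmp_path / "ckpt")
        assert np.allclose(back.predict_many(bags), model.predict_many(bags))
        assert back.config == model.config


class TestCrossValidation:
    def test_single_config_grid_returns_it(self):
        K = 4
        co = generate_cohort(60, K_true=K, d=6, bag_size_range=(10, 20),
                             beta_phenotype=phenotype_effect_pattern(K, 1.0),
                             censor_rate=0.2, seed=3)
        X = np.concatenate([co.features[p] for p in co.patients])
        _, clus = cluster_phenotypes(X, k=K, seed=0)
        bags = bags_from_cohort(co, clus)
        cfg = ModelConfig(k=K, d=6, seed=0)
        res = cross_validate(bags, co.times, co.events, [cfg], folds=3,
                             epoch_grid=(5, 10), seed=1)
        assert res.best_config.k == K
        assert res.best_epochs in (5, 10)
        # bookkeeping: folds x configs x epoch-grid entries
        assert len(res.metrics) == 3 * 1 * 2
        assert 0.0 <= res.test_concordance <= 1.0
        # internal test patients never appear in the CV portion
        assert not set(res.test_indices) & set(res.train_indices)
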