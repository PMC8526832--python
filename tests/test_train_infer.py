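"""Variant assembly, joint objective, training dynamics, and MC inference."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression

from bgpseq.encoder import desk_config, pack_batch
from bgpseq.synthetic_ehr import CohortSpec, generate_cohort
from bgpseq.train_infer import (
    HeadConfig,
    ModelVariant,
    TrainingConfig,
    build_model,
    deterministic_twin,
    load_checkpoint,
    mc_predict,
    save_checkpoint,
    split_cohort,
    summaries_from_frame,
    summaries_to_frame,
    train,
    train_two_stage,
    training_loss,
)


def _tiny_model(variant, vocab_size=40, pooled=4, seed=0, grid=8):
    enc = desk_config(vocab_size=vocab_size, pooled_size=pooled, hidden_size=16,
                      n_layers=1, n_heads=2, intermediate_size=32,
                      max_seq_len=32, max_positions=16)
    return build_model(variant, enc, HeadConfig(n_inducing=8, grid_size=grid),
                       seed=seed)


class TestBuildModel:
    def test_sparse_gp_has_no_stochastic_groups(self):
        model = _tiny_model("SPARSE_GP")
        assert model.stochastic_groups() == set()
        report = model.parameter_group_report()
        assert not any(g["stochastic"] for g in report.values())
        assert report["classifier"]["kind"] == "sparse_gp"

    def test_be_bo_stochastic_groups(self):
        model = _tiny_model("BE_BO")
        assert model.stochastic_groups() == {"embeddings", "classifier"}
        report = model.parameter_group_report()
        assert report["embeddings"]["stochastic"]
        assert report["classifier"]["stochastic"]
        assert report["classifier"]["kind"] == "linear"

    def test_dbgp_is_stochastic_embeddings_plus_kiss(self):
        model = _tiny_model("DBGP")
        assert model.stochastic_groups() == {"embeddings"}
        assert model.parameter_group_report()["classifier"]["kind"] == "kiss_gp"

    def test_inconsistent_pooled_size_raises(self):
        enc = desk_config(vocab_size=40, pooled_size=8)
        head = HeadConfig(expected_pooled_size=24)
        with pytest.raises(ValueError, match="pooled_size"):
            build_model("DBGP", enc, head)

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_every_variant_builds_and_forwards(self, variant, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model(variant)
        batch = pack_batch(records[:8], model.enc_config)
        probs = model.predict_probabilities(
            batch, np.random.default_rng(0) if model.stochastic_groups() else None
        )
        assert probs.shape == (8,)
        assert np.all((probs > 0) & (probs < 1))


class TestTrainingLoss:
    def test_deterministic_zero_logits_give_log_two(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("BE")
        model.clamp_embedding_variance(True)   # deterministic special case
        model.head.w.data[:] = 0.0
        model.head.b.data[:] = 0.0
        # zero the pooling layer so logits are exactly zero for every patient
        model.transformer.pool_w.data[:] = 0.0
        model.transformer.pool_b.data[:] = 0.0
        batch = pack_batch(records[:16], model.enc_config)
        loss = training_loss(model, batch, 16, 1, 1,
                             np.random.default_rng(0), train_mode=False)
        assert abs(loss.item() - np.log(2.0)) < 1e-12

    def test_gradient_matches_finite_differences(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("BO")
        batch = pack_batch(records[:8], model.enc_config)

        def f():
            return training_loss(model, batch, 8, 1, 1,
                                 np.random.default_rng(3), train_mode=False)

        loss = f()
        loss.backward()
        checked = 0
        for p in [model.head.weight.mean, model.head.bias.rho,
                  model.transformer.pool_w]:
            g = p.grad.copy().ravel()
            p.grad = None
            flat = p.data.ravel()
            for j in np.argsort(-np.abs(g))[:3]:
                old = flat[j]
                flat[j] = old + 1e-5
                fp = f().item()
                flat[j] = old - 1e-5
                fm = f().item()
                flat[j] = old
                fd = (fp - fm) / 2e-5
                assert abs(g[j] - fd) < 1e-4 * (abs(fd) + 1.0)
                checked += 1
        assert checked >= 7

    def test_nan_loss_aborts_with_diagnostics(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("BE")
        model.head.w.data[:] = np.nan
        batch = pack_batch(records[:8], model.enc_config)
        with pytest.raises(FloatingPointError, match="sd range"):
            training_loss(model, batch, 8, 1, 1, np.random.default_rng(0))


class TestTrain:
    def test_zero_epochs_leaves_model_unchanged(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("KISS_GP")
        before = [p.data.copy() for p in model.parameters()]
        trace = train(model, records, TrainingConfig(epochs=0, seed=0))
        assert trace == []
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_same_seed_gives_identical_traces(self, small_cohort):
        _, records, _, _ = small_cohort
        cfg = TrainingConfig(epochs=2, learning_rate=1e-3, batch_size=64, seed=5)
        traces = []
        for _ in range(2):
            model = _tiny_model("BO", seed=1)
            traces.append(train(model, records[:128], cfg))
        assert traces[0] == traces[1]

    def test_separable_toy_reaches_high_accuracy(self):
        """One token decides the label almost deterministically; a
        deterministic-embedding linear model should fit it, as logistic
        regression on token presence does."""
        spec = CohortSpec(n_patients=200, positive_rate=0.4, vocab_size=30,
                          risk_tokens={5: 60.0}, nuisance_noise_sd=0.0,
                          baseline_log_odds=-30.0,
                          n_visits_range=(1, 3), codes_per_visit_range=(1, 3),
                          seed=21)
        records, _, vocab = generate_cohort(spec)
        y = np.array([r.label for r in records])
        bow = np.zeros((len(records), vocab.size))
        for i, r in enumerate(records):
            bow[i, r.codes] = 1.0
        oracle_acc = LogisticRegression(max_iter=1000).fit(bow, y).score(bow, y)
        assert oracle_acc >= 0.95

        enc = desk_config(vocab_size=30, pooled_size=8, hidden_size=16,
                          n_layers=1, n_heads=2, intermediate_size=32,
                          max_seq_len=32, max_positions=16, dropout=0.0)
        model = build_model("BE", enc, HeadConfig(n_inducing=8, grid_size=8),
                            seed=0)
        model.clamp_embedding_variance(True)
        cfg = TrainingConfig(epochs=30, learning_rate=1.5e-2, batch_size=64,
                             weight_decay=0.0, seed=0)
        train(model, records, cfg)
        preds = mc_predict(model, records, n_draws=1, seed=0)
        acc = np.mean([(p.mean_probability > 0.5) == p.label for p in preds])
        assert acc >= 0.95

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_loss_decreases_over_first_epochs(self, variant, small_cohort):
        _, records, _, _ = small_cohort
        drops = 0
        for seed in (0, 1, 2):
            model = _tiny_model(variant, seed=seed)
            cfg = TrainingConfig(epochs=5, learning_rate=5e-3, batch_size=64,
                                 seed=seed)
            trace = train(model, records, cfg)
            if trace[-1] < trace[0]:
                drops += 1
        assert drops == 3

    def test_divergence_aborts(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("BO")
        cfg = TrainingConfig(epochs=50, learning_rate=30.0, batch_size=64,
                             seed=0)
        with pytest.raises(FloatingPointError):
            train(model, records, cfg)

    def test_split_cohort_partitions(self, small_cohort):
        _, records, _, _ = small_cohort
        tr, tu, va = split_cohort(records, (0.5, 0.2, 0.3), seed=4)
        all_idx = sorted(tr + tu + va)
        assert all_idx == list(range(len(records)))
        assert len(tr) == round(0.5 * len(records))
        with pytest.raises(ValueError):
            split_cohort(records, (0.5, 0.2, 0.2), seed=0)


class TestMCPredict:
    def test_deterministic_variants_have_zero_std(self, small_cohort):
        _, records, _, _ = small_cohort
        for variant in ("SPARSE_GP", "KISS_GP"):
            model = _tiny_model(variant)
            preds = mc_predict(model, records[:20], n_draws=30, seed=3)
            assert all(p.std_probability == 0.0 for p in preds)
            assert all(np.ptp(p.mc_probabilities) == 0.0 for p in preds)

    def test_probabilities_valid_and_std_nonnegative(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("BE_BO")
        preds = mc_predict(model, records[:20], n_draws=10, seed=3)
        for p in preds:
            assert np.all((p.mc_probabilities >= 0) & (p.mc_probabilities <= 1))
            assert p.std_probability >= 0
            assert p.mean_probability == pytest.approx(p.mc_probabilities.mean())

    def test_requires_at_least_one_draw(self, small_cohort):
        _, records, _, _ = small_cohort
        with pytest.raises(ValueError):
            mc_predict(_tiny_model("BE"), records[:2], n_draws=0)

    def test_mc_sample_size_robustness(self, small_cohort):
        """Means from 30 vs 60 draws agree within Monte-Carlo standard error
        for nearly every patient."""
        _, records, _, _ = small_cohort
        model = _tiny_model("BE", seed=3)
        p30 = mc_predict(model, records[:60], n_draws=30, seed=7)
        p60 = mc_predict(model, records[:60], n_draws=60, seed=8)
        ok = 0
        for a, b in zip(p30, p60):
            se = a.mc_probabilities.std(ddof=1) / np.sqrt(30)
            if abs(a.mean_probability - b.mean_probability) < 3 * se + 1e-12:
                ok += 1
        assert ok / len(p30) >= 0.95


class TestVariantReduction:
    def test_clamped_dbgp_equals_kiss_twin(self, small_cohort):
        """With embedding variances clamped to zero, the hybrid model is
        exactly its deterministic-kernel-learning special case."""
        _, records, _, _ = small_cohort
        model = _tiny_model("DBGP", seed=9)
        cfg = TrainingConfig(epochs=2, learning_rate=3e-3, batch_size=64, seed=9)
        train(model, records[:128], cfg)
        model.clamp_embedding_variance(True)
        twin = deterministic_twin(model)
        p_dbgp = mc_predict(model, records[:40], n_draws=5, seed=1)
        p_twin = mc_predict(twin, records[:40], n_draws=5, seed=2)
        for a, b in zip(p_dbgp, p_twin):
            assert abs(a.mean_probability - b.mean_probability) < 1e-6
            assert a.std_probability == 0.0 and b.std_probability == 0.0

    def test_twin_requires_dbgp(self):
        with pytest.raises(ValueError):
            deterministic_twin(_tiny_model("BE"))


class TestParameterRecovery:
    def test_risk_token_carriers_score_higher(self):
        """A single strong planted token should raise the model's predicted
        risk for its carriers (Mann-Whitney on carrier vs non-carrier mean
        probabilities)."""
        spec = CohortSpec(n_patients=600, positive_rate=0.25, vocab_size=30,
                          risk_tokens={5: 4.0}, nuisance_noise_sd=0.25,
                          n_visits_range=(1, 3), codes_per_visit_range=(1, 3),
                          seed=13)
        records, _, _ = generate_cohort(spec)
        model = _tiny_model("BE", vocab_size=30, pooled=8, seed=4)
        warm = TrainingConfig(epochs=15, learning_rate=3e-3, batch_size=128,
                              seed=4)
        fine = TrainingConfig(epochs=3, learning_rate=3e-5, batch_size=128,
                              seed=54)
        train_two_stage(model, records, warm, fine)
        preds = mc_predict(model, records, n_draws=10, seed=5)
        mp = np.array([p.mean_probability for p in preds])
        carrier = np.array([5 in r.codes for r in records])
        stat = mannwhitneyu(mp[carrier], mp[~carrier], alternative="greater")
        assert stat.pvalue < 0.01


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, small_cohort):
        _, records, _, _ = small_cohort
        for variant in ("DBGP", "BE_BO", "SPARSE_GP"):
            model = _tiny_model(variant, seed=6)
            path = tmp_path / f"{variant}.npz"
            save_checkpoint(model, path)
            back = load_checkpoint(path)
            assert back.variant == model.variant
            p1 = mc_predict(model, records[:10], n_draws=4, seed=2)
            p2 = mc_predict(back, records[:10], n_draws=4, seed=2)
            for a, b in zip(p1, p2):
                assert a.mc_probabilities == pytest.approx(b.mc_probabilities)

    def test_predictions_frame_roundtrip(self, small_cohort):
        _, records, _, _ = small_cohort
        model = _tiny_model("BO")
        preds = mc_predict(model, records[:12], n_draws=5, seed=1)
        frame = summaries_to_frame(preds)
        back = summaries_from_frame(frame)
        for a, b in zip(preds, back):
            assert a.mean_probability == pytest.approx(b.mean_probability)
            assert a.mc_probabilities == pytest.approx(b.mc_probabilities)

    def test_missing_std_column_named(self, small_cohort):
        import pandas as pd
        frame = pd.DataFrame({"patient_id": [0], "label": [1],
                              "mean_prob": [0.5]})
        with pytest.raises(ValueError, match="std_prob"):
            summaries_from_frame(frame)
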