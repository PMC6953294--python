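import numpy as np
import pytest

from coevonet import features as F
from coevonet import training as T
from coevonet.labels import SS_MASKED, LabelBundle
from coevonet.model import ContactNetwork, ModelConfig, PredictionBundle
from coevonet.msa import EncodedAlignment
from coevonet.nn.autodiff import Tensor
from coevonet.weighting import WeightMLP

from conftest import random_alignment


class TestContactLoss:
    def test_single_pair_closed_form(self):
        y = np.full((8, 8), np.nan)
        y[0, 7] = y[7, 0] = 1.0
        p = np.full((8, 8), 0.5)
        assert T.contact_loss(y, p) == pytest.approx(np.log(2))

    def test_all_masked_gives_zero(self):
        y = np.full((8, 8), np.nan)
        assert T.contact_loss(y, np.random.default_rng(0).random((8, 8))) == 0.0

    def test_masked_entries_do_not_influence(self):
        rng = np.random.default_rng(1)
        y = (rng.random((10, 10)) < 0.3).astype(float)
        y = np.maximum(y, y.T)
        y[2, 9] = y[9, 2] = np.nan
        p = rng.random((10, 10))
        base = T.contact_loss(y, p)
        p2 = p.copy()
        p2[2, 9] = p2[9, 2] = 0.999
        assert T.contact_loss(y, p2) == base

    def test_short_separation_pairs_excluded(self):
        y = np.zeros((8, 8))
        y[0, 3] = y[3, 0] = 1.0  # separation 3 < 6: carries no signal
        p = np.full((8, 8), 1e-6)
        assert T.contact_loss(y, p) == pytest.approx(0.0, abs=1e-3)

    def test_tensor_and_array_paths_agree(self):
        rng = np.random.default_rng(2)
        y = (rng.random((12, 12)) < 0.2).astype(float)
        y = np.maximum(y, y.T)
        p = rng.random((12, 12))
        assert float(T.contact_loss(y, Tensor(p)).data) == pytest.approx(
            T.contact_loss(y, p)
        )


class TestSSLoss:
    def test_certain_correct_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert T.ss_loss(np.array([0]), probs) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_gives_ln3(self):
        probs = np.full((1, 3), 1 / 3)
        assert T.ss_loss(np.array([0]), probs) == pytest.approx(np.log(3))

    def test_masked_residues_contribute_nothing(self):
        probs = np.array([[1 / 3] * 3, [0.01, 0.01, 0.98]])
        labels = np.array([0, SS_MASKED])
        assert T.ss_loss(labels, probs) == pytest.approx(np.log(3))


class TestAsaLoss:
    def test_perfect_prediction(self):
        asa = np.array([50.0, 80.0])
        assert T.asa_loss(asa, asa) == 0.0

    def test_rmse_closed_form(self):
        true = np.array([100.0, 50.0])
        pred = np.array([110.0, 40.0])
        assert T.asa_loss(true, pred) == pytest.approx(10.0)

    def test_single_residue_absolute_error(self):
        assert T.asa_loss(np.array([30.0]), np.array([30.0 + 7.5])) == pytest.approx(7.5)

    def test_masked_excluded_from_n(self):
        true = np.array([100.0, np.nan])
        pred = np.array([110.0, 999.0])
        assert T.asa_loss(true, pred) == pytest.approx(10.0)


def micro_sample(rng, L=15, n=8):
    enc = random_alignment(rng, n, L)
    y = (rng.random((L, L)) < 0.2).astype(float)
    y = np.maximum(y, y.T)
    np.fill_diagonal(y, 0)
    return T.ProteinSample(
        enc=enc,
        labels=LabelBundle(
            contact_map=y,
            ss3=rng.integers(0, 3, L).astype(np.int8),
            asa=rng.random(L) * 100,
        ),
        identifier="micro",
    )


def micro_model(variant="baseline", seed=0, **kw):
    cfg = ModelConfig(
        variant=variant, trunk_channels=kw.pop("channels", 16),
        n_blocks=kw.pop("blocks", 2), n_shared_blocks=kw.pop("shared", 1),
    )
    return ContactNetwork(cfg, seed=seed)


class TestTrainLoop:
    def test_overfits_single_protein(self):
        """Optimization sanity: a micro-model drives the summed contact loss
        below 0.05 on one protein within 300 steps."""
        rng = np.random.default_rng(3)
        sample = micro_sample(rng)
        model = micro_model(seed=1)
        config = T.TrainConfig(epochs=300, learning_rate=0.01, seed=0)
        result = T.train(model, [sample], config)
        assert result.train_trace[-1].contact_loss < 0.05

    def test_identical_seeds_give_bitwise_identical_traces(self):
        rng = np.random.default_rng(4)
        samples = [micro_sample(rng, L=12, n=6) for _ in range(3)]
        traces = []
        for _ in range(2):
            model = micro_model(seed=2)
            config = T.TrainConfig(epochs=2, seed=7)
            result = T.train(model, samples, config)
            traces.append([b.total for b in result.train_trace])
        assert traces[0] == traces[1]

    def test_weighted_variant_propagates_gradient_to_weight_mlp(self):
        rng = np.random.default_rng(5)
        sample = micro_sample(rng)
        model = micro_model("weighted", seed=3)
        mlp = WeightMLP(seed=3)
        out, w = T.forward_sample(model, sample.enc, mlp)
        loss, _ = T.total_loss(sample.labels, out, T.TrainConfig())
        loss.backward()
        norms = [np.linalg.norm(p.grad) for p in mlp.parameters() if p.grad is not None]
        assert norms and max(norms) > 0

    def test_best_epoch_tracked_per_task(self):
        rng = np.random.default_rng(6)
        samples = [micro_sample(rng, L=10, n=5) for _ in range(2)]
        model = micro_model("multitask", seed=4)
        config = T.TrainConfig(variant="multitask", epochs=2, seed=1)
        result = T.train(model, samples, config, val_dataset=samples[:1])
        assert set(result.best_epoch) == {"contact", "ss", "asa"}
        assert all(len(state) == 2 for state in result.best_state.values())

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        rng = np.random.default_rng(7)
        sample = micro_sample(rng)
        model = micro_model(seed=5)
        model.contact_out.bias.data[:] = np.nan
        with pytest.raises(FloatingPointError, match="micro"):
            T.train(model, [sample], T.TrainConfig(epochs=1, seed=0))


class TestEnsemble:
    def test_k_copies_equal_single_model(self):
        rng = np.random.default_rng(8)
        model = micro_model(seed=6)
        x = rng.normal(size=(441, 10, 10)).astype(np.float32)
        single = model.predict(x).contact_prob
        avg = T.ensemble_predict([model] * 5, x).contact_prob
        np.testing.assert_allclose(avg, single, atol=1e-7)

    def test_two_model_average(self):
        b1 = PredictionBundle(contact_prob=np.full((4, 4), 0.2))
        b2 = PredictionBundle(contact_prob=np.full((4, 4), 0.8))

        class Stub:
            def __init__(self, b):
                self.b = b

            def predict(self, x):
                return self.b

        avg = T.ensemble_predict([Stub(b1), Stub(b2)], np.zeros((1, 4, 4)))
        np.testing.assert_allclose(avg.contact_prob, 0.5)

    def test_five_fold_output_symmetric_in_unit_interval(self):
        rng = np.random.default_rng(9)
        models = [micro_model(seed=10 + k) for k in range(5)]
        x = rng.normal(size=(441, 9, 9)).astype(np.float32)
        avg = T.ensemble_predict(models, x).contact_prob
        np.testing.assert_allclose(avg, avg.T, atol=1e-7)
        assert np.all((avg > 0) & (avg < 1))
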