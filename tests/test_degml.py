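import json

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from degronkit import degml, io
from degronkit.degml import (
    DegronCall,
    PhysicochemicalProvider,
    TrainingError,
    extract_window,
    load_ensemble,
    predict,
    rank_high_priority,
    save_ensemble,
    train_embedding_fallback,
    train_ensemble,
)
from degronkit.features import FEATURE_REGISTRY


def synthetic_features(n, disorder_mean, seed):
    """Feature table where only disorder is informative."""
    rng = np.random.default_rng(seed)
    data = {}
    for feat in FEATURE_REGISTRY:
        if feat == "disorder":
            data[feat] = np.clip(rng.normal(disorder_mean, 0.05, n), 0, 1)
        elif feat in ("n_phospho", "n_ubiq", "flank_lysine_count"):
            data[feat] = rng.integers(0, 4, n).astype(float)
        else:
            data[feat] = rng.normal(0.5, 0.2, n)
    return pd.DataFrame(data)


@pytest.fixture(scope="module")
def separable_model():
    pos = synthetic_features(100, 0.9, seed=1)
    bg = synthetic_features(100, 0.1, seed=2)
    small_grid = {"max_depth": [2], "learning_rate": [0.3],
                  "n_estimators": [50], "subsample": [1.0]}
    model = train_ensemble(pos, bg, config={"grid": small_grid}, seed=1)
    return model, pos, bg


class TestEnsembleTraining:
    def test_separable_features_high_holdout_auc(self, separable_model):
        model, _, _ = separable_model
        pos_test = synthetic_features(50, 0.9, seed=3)
        bg_test = synthetic_features(50, 0.1, seed=4)
        probs = [c.probability for c in predict(model, pos_test)]
        probs += [c.probability for c in predict(model, bg_test)]
        auc = roc_auc_score([1] * 50 + [0] * 50, probs)
        assert auc >= 0.95

    def test_same_seed_reproduces_scores(self):
        pos = synthetic_features(30, 0.9, seed=5)
        bg = synthetic_features(30, 0.1, seed=6)
        probe = synthetic_features(10, 0.5, seed=7)
        grid = {"max_depth": [2], "learning_rate": [0.3],
                "n_estimators": [50], "subsample": [1.0]}
        a = train_ensemble(pos, bg, config={"grid": grid}, seed=9)
        b = train_ensemble(pos, bg, config={"grid": grid}, seed=9)
        assert [c.per_model_scores for c in predict(a, probe)] == [
            c.per_model_scores for c in predict(b, probe)
        ]

    def test_too_few_positives_rejected(self):
        with pytest.raises(TrainingError, match="at least 20"):
            train_ensemble(synthetic_features(5, 0.9, 1), synthetic_features(50, 0.1, 2))

    def test_extreme_imbalance_rejected(self):
        with pytest.raises(TrainingError, match="imbalance"):
            train_ensemble(
                synthetic_features(20, 0.9, 1), synthetic_features(2500, 0.1, 2)
            )

    def test_constant_feature_rejected(self):
        pos = synthetic_features(30, 0.9, 1)
        bg = synthetic_features(30, 0.1, 2)
        pos["rigidity"] = 0.5
        bg["rigidity"] = 0.5
        with pytest.raises(TrainingError, match="rigidity"):
            train_ensemble(pos, bg)

    def test_manifest_records_training_recipe(self, separable_model):
        model, pos, bg = separable_model
        m = model.manifest
        assert len(m["bootstrap_indices"]) == 10
        assert all(len(idx) == len(pos) + len(bg) for idx in m["bootstrap_indices"])
        assert len(m["member_seeds"]) == 10
        assert m["feature_names"] == list(FEATURE_REGISTRY)


class TestPrediction:
    def test_probability_is_mean_and_threshold_strict(self):
        call = DegronCall(
            candidate_ref=("P", 1, 5, "M"),
            probability=0.5,
            passed_threshold=False,
            high_priority=False,
            model_version="t",
            per_model_scores=tuple([0.4] * 5 + [0.6] * 5),
        )
        assert call.probability == 0.5 and not call.passed_threshold
        with pytest.raises(ValueError):
            DegronCall(("P", 1, 5, "M"), 0.6, True, False, "t", (0.5,) * 10)

    def test_probability_invariant_under_member_permutation(self, separable_model):
        model, pos, _ = separable_model
        probe = pos.head(5)
        before = [c.probability for c in predict(model, probe)]
        model.members = model.members[::-1]
        after = [c.probability for c in predict(model, probe)]
        model.members = model.members[::-1]
        assert before == pytest.approx(after)

    def test_unknown_feature_column_rejected(self, separable_model):
        model, pos, _ = separable_model
        bad = pos.head(3).assign(mystery=1.0)
        with pytest.raises(KeyError, match="mystery"):
            predict(model, bad)

    def test_positive_probe_scores_above_threshold(self, separable_model):
        model, _, _ = separable_model
        probe = synthetic_features(5, 0.9, seed=11)
        assert all(c.probability > 0.5 for c in predict(model, probe))


class TestHighPriority:
    def _call(self, prob, motif="classA"):
        return DegronCall(
            ("P", 1, 5, motif), prob, prob > 0.5, False, "t", (prob,) * 10
        )

    def test_above_class_minimum_is_priority(self):
        calls = rank_high_priority([self._call(0.70)], {"classA": [0.62, 0.8]})
        assert calls[0].high_priority

    def test_below_class_minimum_is_not(self):
        calls = rank_high_priority([self._call(0.55)], {"classA": [0.62]})
        assert calls[0].passed_threshold and not calls[0].high_priority

    def test_class_without_verified_calls_warns(self):
        with pytest.warns(UserWarning, match="no verified"):
            calls = rank_high_priority([self._call(0.99, "classB")], {"classA": [0.6]})
        assert not calls[0].high_priority


class TestWindow:
    def test_centering_near_n_terminus(self):
        protein = io.ProteinRecord("P", "A" * 30)
        w = extract_window(protein, (5, 8))
        # centre 6: window [-18, 31] -> 19 left pads, 30 residues, 1 right pad
        assert w == "X" * 19 + "A" * 30 + "X"

    def test_interior_span_unpadded(self):
        protein = io.ProteinRecord("P", "A" * 200)
        assert extract_window(protein, (100, 103)) == "A" * 50

    @pytest.mark.parametrize("span", [(1, 1), (1, 10), (195, 200), (50, 120)])
    def test_window_always_fifty(self, span):
        protein = io.ProteinRecord("P", "A" * 200)
        assert len(extract_window(protein, span)) == 50


class TestEmbeddingFallback:
    @staticmethod
    def _windows(n, with_motif, seed):
        """50-mers; positives carry a literal LPETGG block at the centre."""
        rng = np.random.default_rng(seed)
        letters = list("ACDEFGHIKMNQRSVWY")
        out = []
        for _ in range(n):
            chars = rng.choice(letters, size=50).tolist()
            if with_motif:
                chars[22:28] = list("LPETGG")
            out.append("".join(chars))
        return out

    def test_implanted_motif_separable(self):
        pos = self._windows(120, True, 1)
        neg = self._windows(120, False, 2)
        model = train_embedding_fallback(pos + neg, [1] * 120 + [0] * 120, seed=3)
        pos_t = self._windows(40, True, 4)
        neg_t = self._windows(40, False, 5)
        preds = model.predict_proba(pos_t + neg_t) > 0.5
        accuracy = np.mean(preds == np.array([1] * 40 + [0] * 40))
        assert accuracy >= 0.9

    def test_same_seed_identical_predictions(self):
        pos = self._windows(40, True, 1)
        neg = self._windows(40, False, 2)
        probe = self._windows(10, True, 9)
        a = train_embedding_fallback(pos + neg, [1] * 40 + [0] * 40, seed=7)
        b = train_embedding_fallback(pos + neg, [1] * 40 + [0] * 40, seed=7)
        assert np.array_equal(a.predict_proba(probe), b.predict_proba(probe))

    def test_single_class_labels_rejected(self):
        pos = self._windows(30, True, 1)
        with pytest.raises(TrainingError):
            train_embedding_fallback(pos, [1] * 30)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            train_embedding_fallback(["ACDEF"], [1])
        provider = PhysicochemicalProvider()
        with pytest.raises(ValueError):
            provider(["ACDEF"])

    def test_provider_is_deterministic(self):
        provider = PhysicochemicalProvider()
        w = self._windows(3, True, 1)
        assert np.array_equal(provider(w), provider(w))


class TestBundle:
    def test_round_trip_preserves_predictions(self, separable_model, tmp_path):
        model, pos, _ = separable_model
        save_ensemble(model, tmp_path / "bundle")
        loaded = load_ensemble(tmp_path / "bundle")
        probe = pos.head(8)
        a = [c.per_model_scores for c in predict(model, probe)]
        b = [c.per_model_scores for c in predict(loaded, probe)]
        assert np.allclose(a, b, atol=1e-6)

    def test_registry_mismatch_rejected(self, separable_model, tmp_path):
        model, _, _ = separable_model
        save_ensemble(model, tmp_path / "bundle")
        manifest_path = tmp_path / "bundle" / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["feature_names"][0] = "not_a_feature"
        manifest_path.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="registry"):
            load_ensemble(tmp_path / "bundle")
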