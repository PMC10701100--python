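"""Ensemble degron classifier and sequence-embedding fallback.

The primary predictor is a bag of 10 gradient-boosted tree classifiers, each
fit on an independent bootstrap resample (with replacement, size equal to
the full training set) of degron-positive versus length-matched background
feature vectors. Shared hyperparameters are selected once by stratified
5-fold cross-validation over a small declared grid. A candidate's degron
probability is the arithmetic mean of the 10 member scores; it passes the
call threshold when strictly greater than 0.5, and is flagged high-priority
when it additionally exceeds the lowest probability among verified degrons
of the same motif class.

Candidates without feature tracks fall back to a sequence-only model: a
50-residue window centred on the candidate is embedded by a pluggable
provider and scored by a dense head (128-ReLU → 64-ReLU → 1-sigmoid) trained
with binary cross-entropy and early stopping. The built-in provider is a
deterministic per-residue physicochemical encoding; a pretrained
protein-language-model provider (e.g. a 1,024-dimensional embedding) can be
injected through the same interface.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
import xgboost
from xgboost import XGBClassifier

from .alphabet import AA20, CHARGE_PH7, KYTE_DOOLITTLE, SIDE_CHAIN_VOLUME
from .features import FEATURE_REGISTRY
from .io import ProteinRecord

logger = logging.getLogger(__name__)

ENSEMBLE_SIZE = 10
CALL_THRESHOLD = 0.5
WINDOW_LENGTH = 50
MAX_CLASS_IMBALANCE = 100

DEFAULT_GRID = {
    "max_depth": [2, 3],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100],
    "subsample": [0.8, 1.0],
}

MODEL_VERSION = "degml-0.1"


@dataclass(frozen=True)
class DegronCall:
    candidate_ref: tuple[str, int, int, str]
    probability: float
    passed_threshold: bool
    high_priority: bool
    model_version: str
    per_model_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.probability - float(np.mean(self.per_model_scores))) > 1e-9:
            raise ValueError("probability must equal the mean of per-model scores")
        if self.high_priority and not self.passed_threshold:
            raise ValueError("high_priority implies passed_threshold")


@dataclass
class EnsembleModel:
    members: list[XGBClassifier]
    scaler: StandardScaler
    feature_names: tuple[str, ...]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != ENSEMBLE_SIZE:
            raise ValueError(f"ensemble must have exactly {ENSEMBLE_SIZE} members")


class TrainingError(ValueError):
    """Raised on degenerate or insufficient training input."""


def _as_matrix(df: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    missing = [f for f in feature_names if f not in df.columns]
    if missing:
        raise KeyError(f"feature table missing columns {missing}")
    return df.loc[:, list(feature_names)].to_numpy(dtype=float)


def train_ensemble(
    positive_features: pd.DataFrame,
    background_features: pd.DataFrame,
    config: Mapping | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the 10-member bootstrapped gradient-boosting ensemble.

    ``positive_features`` and ``background_features`` are feature tables
    (registry columns). Hyperparameters are chosen once on the full training
    set by stratified 5-fold CV over ``config['grid']`` (default grid above),
    then each member is fit on its own seeded bootstrap resample. The
    returned manifest records seeds, chosen hyperparameters, and bootstrap
    indices, which suffices to retrain the ensemble bit-compatibly.
    """
    config = dict(config or {})
    feature_names = tuple(config.get("features", FEATURE_REGISTRY))
    n_pos, n_bg = len(positive_features), len(background_features)
    if n_pos < 20 or n_bg < 20:
        raise TrainingError(
            f"need at least 20 rows per class, got {n_pos} positive / {n_bg} background"
        )
    if max(n_pos, n_bg) > MAX_CLASS_IMBALANCE * min(n_pos, n_bg):
        raise TrainingError(
            f"class imbalance {max(n_pos, n_bg)}:{min(n_pos, n_bg)} exceeds "
            f"{MAX_CLASS_IMBALANCE}:1 — re-sample the majority class"
        )
    X = np.vstack(
        [_as_matrix(positive_features, feature_names),
         _as_matrix(background_features, feature_names)]
    )
    y = np.concatenate([np.ones(n_pos), np.zeros(n_bg)])
    constant = [f for f, v in zip(feature_names, X.var(axis=0)) if v == 0.0]
    if constant:
        raise TrainingError(f"all-constant features in training data: {constant}")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    grid = config.get("grid", DEFAULT_GRID)
    base = XGBClassifier(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )
    search = GridSearchCV(
        base,
        grid,
        scoring="roc_auc",
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(Xs, y)
    best = search.best_params_
    logger.info("selected hyperparameters: %s (CV AUC %.3f)", best, search.best_score_)

    rng = np.random.default_rng(seed)
    n = len(y)
    members: list[XGBClassifier] = []
    bootstrap_indices: list[list[int]] = []
    member_seeds: list[int] = []
    for i in range(ENSEMBLE_SIZE):
        idx = rng.integers(0, n, size=n)  # classical bootstrap: size = full set
        if len(np.unique(y[idx])) < 2:  # resample until both classes present
            idx = rng.integers(0, n, size=n)
        member_seed = int(rng.integers(0, 2**31 - 1))
        model = XGBClassifier(
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=member_seed,
            **best,
        )
        model.fit(Xs[idx], y[idx])
        members.append(model)
        bootstrap_indices.append([int(j) for j in idx])
        member_seeds.append(member_seed)

    manifest = {
        "model_version": MODEL_VERSION,
        "seed": seed,
        "member_seeds": member_seeds,
        "hyperparameters": {k: (float(v) if isinstance(v, float) else v) for k, v in best.items()},
        "grid": {k: list(v) for k, v in grid.items()},
        "bootstrap_indices": bootstrap_indices,
        "n_positive": n_pos,
        "n_background": n_bg,
        "feature_names": list(feature_names),
    }
    return EnsembleModel(members, scaler, feature_names, manifest)


def predict(
    ensemble: EnsembleModel,
    features: pd.DataFrame,
    candidate_refs: Sequence[tuple[str, int, int, str]] | None = None,
) -> list[DegronCall]:
    """Score candidates: probability = mean of the 10 member scores,
    threshold strictly > 0.5; high_priority is set later by ranking."""
    extra = set(features.columns) - set(ensemble.feature_names) - {
        "candidate_ref", "imputed"
    }
    if extra:
        raise KeyError(f"unknown feature columns: {sorted(extra)}")
    X = ensemble.scaler.transform(_as_matrix(features, ensemble.feature_names))
    scores = np.column_stack(
        [m.predict_proba(X)[:, 1] for m in ensemble.members]
    ).astype(float)
    probs = scores.mean(axis=1)
    if candidate_refs is None:
        if "candidate_ref" in features.columns:
            candidate_refs = [
                _parse_candidate_ref(r) for r in features["candidate_ref"]
            ]
        else:
            candidate_refs = [("", i + 1, i + 1, "") for i in range(len(features))]
    calls = []
    for ref, p, row in zip(candidate_refs, probs, scores):
        calls.append(
            DegronCall(
                candidate_ref=tuple(ref),
                probability=float(p),
                passed_threshold=bool(p > CALL_THRESHOLD),
                high_priority=False,
                model_version=ensemble.manifest.get("model_version", MODEL_VERSION),
                per_model_scores=tuple(float(s) for s in row),
            )
        )
    return calls


def _parse_candidate_ref(text: str) -> tuple[str, int, int, str]:
    pid, start, end, motif = str(text).split("|")
    return (pid, int(start), int(end), motif)


def rank_high_priority(
    calls: Sequence[DegronCall],
    verified_calls_by_class: Mapping[str, Sequence[float]],
) -> list[DegronCall]:
    """Flag calls exceeding the lowest verified-degron probability of their
    motif class (and the 0.5 threshold). Classes with no verified degron
    cannot anchor the rule: their candidates stay non-priority, with a
    warning."""
    minima = {
        cls: min(probs)
        for cls, probs in verified_calls_by_class.items()
        if len(probs) > 0
    }
    out = []
    warned: set[str] = set()
    for call in calls:
        cls = call.candidate_ref[3]
        if cls not in minima:
            if cls not in warned:
                warnings.warn(
                    f"motif class {cls!r} has no verified degron; "
                    "high-priority ranking unavailable for it"
                )
                warned.add(cls)
            high = False
        else:
            high = call.passed_threshold and call.probability > minima[cls]
        out.append(
            DegronCall(
                candidate_ref=call.candidate_ref,
                probability=call.probability,
                passed_threshold=call.passed_threshold,
                high_priority=high,
                model_version=call.model_version,
                per_model_scores=call.per_model_scores,
            )
        )
    return out


def calls_table(calls: Sequence[DegronCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "protein_id": c.candidate_ref[0],
            "start": c.candidate_ref[1],
            "end": c.candidate_ref[2],
            "motif_name": c.candidate_ref[3],
        }
        for i, s in enumerate(c.per_model_scores, start=1):
            row[f"score_{i:02d}"] = s
        row["probability"] = c.probability
        row["passed_threshold"] = c.passed_threshold
        row["high_priority"] = c.high_priority
        row["model_version"] = c.model_version
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Window extraction and the embedding fallback
# ---------------------------------------------------------------------------

def extract_window(
    protein: ProteinRecord, span: tuple[int, int], length: int = WINDOW_LENGTH
) -> str:
    """Fixed-length sequence window centred on the span midpoint.

    The centre is floor((start+end)/2); the window covers
    [c − (length//2 − 1), c + length//2] and is 'X'-padded beyond the
    termini, so the output is always exactly ``length`` characters.
    """
    start, end = span
    if not (1 <= start <= end <= len(protein)):
        raise ValueError(f"invalid span {span} on protein {protein.protein_id}")
    centre = (start + end) // 2
    lo = centre - (length // 2 - 1)
    hi = centre + length // 2
    chars = [
        protein.sequence[p - 1] if 1 <= p <= len(protein) else "X"
        for p in range(lo, hi + 1)
    ]
    return "".join(chars)


class PhysicochemicalProvider:
    """Deterministic, dependency-free sequence-embedding provider.

    Encodes each residue as (normalised hydropathy, charge, normalised
    side-chain volume, helix/turn propensity proxy via hydropathy sign,
    known-residue indicator), concatenated over the window positions and
    augmented with mean- and max-pooled summaries. Position-resolved, so
    motif placement inside the window is learnable. The unknown residue 'X'
    encodes as zeros with the indicator off.
    """

    provider_id = "physicochemical-v1"
    RESIDUE_DIM = 5

    def __init__(self, window_length: int = WINDOW_LENGTH) -> None:
        self.window_length = window_length
        self._table = {}
        vols = np.array([SIDE_CHAIN_VOLUME[a] for a in AA20])
        vmin, vspan = vols.min(), np.ptp(vols)
        for aa in AA20:
            self._table[aa] = np.array(
                [
                    KYTE_DOOLITTLE[aa] / 4.5,
                    CHARGE_PH7[aa],
                    (SIDE_CHAIN_VOLUME[aa] - vmin) / vspan,
                    np.sign(KYTE_DOOLITTLE[aa]),
                    1.0,
                ]
            )
        self._table["X"] = np.zeros(self.RESIDUE_DIM)

    @property
    def dim(self) -> int:
        return self.window_length * self.RESIDUE_DIM + 2 * self.RESIDUE_DIM

    def __call__(self, windows: Sequence[str]) -> np.ndarray:
        out = np.empty((len(windows), self.dim))
        for i, w in enumerate(windows):
            if len(w) != self.window_length:
                raise ValueError(
                    f"window length {len(w)} != expected {self.window_length}"
                )
            per_res = np.stack([self._table[c] for c in w])
            out[i] = np.concatenate(
                [per_res.ravel(), per_res.mean(axis=0), per_res.max(axis=0)]
            )
        return out


@dataclass
class EmbeddingModel:
    provider: Callable[[Sequence[str]], np.ndarray]
    head: MLPClassifier
    window_length: int = WINDOW_LENGTH
    provider_id: str = "custom"

    def predict_proba(self, windows: Sequence[str]) -> np.ndarray:
        for w in windows:
            if len(w) != self.window_length:
                raise ValueError(f"window length {len(w)} != {self.window_length}")
        return self.head.predict_proba(self.provider(windows))[:, 1]


def train_embedding_fallback(
    windows: Sequence[str],
    labels: Sequence[int],
    provider: Callable[[Sequence[str]], np.ndarray] | None = None,
    config: Mapping | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Train the sequence-only fallback: embed 50-residue windows with the
    provider and fit the fixed 128→64→1 dense head (ReLU hidden layers,
    sigmoid output, binary cross-entropy, early stopping on a held-out
    split)."""
    config = dict(config or {})
    window_length = int(config.get("window_length", WINDOW_LENGTH))
    for w in windows:
        if len(w) != window_length:
            raise ValueError(f"window length {len(w)} != expected {window_length}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("degenerate single-class training labels")
    if provider is None:
        provider = PhysicochemicalProvider(window_length)
    X = provider(windows)
    head = MLPClassifier(
        hidden_layer_sizes=(128, 64),
        activation="relu",
        solver="adam",
        early_stopping=True,
        n_iter_no_change=10,
        validation_fraction=0.15,
        max_iter=500,
        random_state=seed,
    )
    head.fit(X, y)
    return EmbeddingModel(
        provider=provider,
        head=head,
        window_length=window_length,
        provider_id=getattr(provider, "provider_id", "custom"),
    )


# ---------------------------------------------------------------------------
# Model bundle on disk
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, directory: str | Path) -> None:
    """Persist the ensemble as a versioned bundle: a JSON manifest (seeds,
    bootstrap indices, hyperparameters, scaler statistics) plus one JSON
    booster file per member."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = dict(ensemble.manifest)
    manifest["scaler_mean"] = [float(v) for v in ensemble.scaler.mean_]
    manifest["scaler_scale"] = [float(v) for v in ensemble.scaler.scale_]
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for i, model in enumerate(ensemble.members):
        booster = model.get_booster() if hasattr(model, "get_booster") else model
        booster.save_model(directory / f"member_{i:02d}.json")


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    feature_names = tuple(manifest["feature_names"])
    unknown = set(feature_names) - set(FEATURE_REGISTRY)
    if unknown:
        raise ValueError(
            f"bundle feature registry mismatch: unknown features {sorted(unknown)}"
        )
    scaler = StandardScaler()
    scaler.mean_ = np.array(manifest.pop("scaler_mean"))
    scaler.scale_ = np.array(manifest.pop("scaler_scale"))
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = len(feature_names)
    members = []
    for i in range(ENSEMBLE_SIZE):
        booster = xgboost.Booster()
        booster.load_model(str(directory / f"member_{i:02d}.json"))
        members.append(_BoosterMember(booster))
    return EnsembleModel(members, scaler, feature_names, manifest)


class _BoosterMember:
    """Loaded ensemble member: a bare booster with a predict_proba surface."""

    def __init__(self, booster: "xgboost.Booster") -> None:
        self.booster = booster

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.booster.inplace_predict(X)
        return np.column_stack([1.0 - p, p])
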