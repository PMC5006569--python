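"""Per-feature base learners emitting positive-class probabilities.

One probabilistic classifier is trained per feature family on the training
fold; its score f_i(x) in [0, 1] is the estimated probability that x is a
real piRNA. The shipped engine is a random forest with a pinned tree count
(100) for reproducibility; any estimator with ``fit``/``predict_proba`` is
pluggable through the ``engine_factory`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence as TSequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ValidationError
from .features import FeatureSpec

N_TREES = 100

EngineFactory = Callable[[int], object]


def _default_engine(seed: int):
    return RandomForestClassifier(n_estimators=N_TREES, random_state=seed, n_jobs=1)


@dataclass
class BaseLearner:
    """A fitted per-feature scorer; score(X) is P(real piRNA) in [0, 1]."""

    spec: FeatureSpec
    engine: object
    engine_seed: int

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        proba = self.engine.predict_proba(features)
        pos_col = int(np.flatnonzero(self.engine.classes_ == 1)[0])
        return np.clip(proba[:, pos_col], 0.0, 1.0)


def train_base_learner(
    features: np.ndarray,
    labels: np.ndarray,
    engine_seed: int,
    spec: FeatureSpec | None = None,
    engine_factory: EngineFactory = _default_engine,
) -> BaseLearner:
    """Fit one base learner on one feature matrix (both classes required)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ValidationError("feature rows and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValidationError("training labels contain a single class")
    if spec is not None and features.shape[1] != spec.dimension:
        raise ValidationError(
            f"{spec.name}: {features.shape[1]} columns != dimension {spec.dimension}"
        )
    engine = engine_factory(engine_seed)
    engine.fit(features, labels)
    return BaseLearner(spec=spec, engine=engine, engine_seed=engine_seed)


def score_matrix(
    bank: TSequence[BaseLearner], matrices: dict[str, np.ndarray]
) -> np.ndarray:
    """Stack per-learner scores into an (n_instances x N) matrix, catalog order."""
    if not bank:
        raise ValidationError("empty learner bank")
    cols = []
    n = None
    for learner in bank:
        mat = matrices[learner.spec.name]
        if n is None:
            n = mat.shape[0]
        elif mat.shape[0] != n:
            raise ValidationError("feature matrices disagree on instance count")
        cols.append(learner.score(mat))
    return np.column_stack(cols)


def learner_seed(master_seed: int, fold: int, feature_index: int) -> int:
    """Deterministic per-(fold, feature) engine seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, fold, feature_index])
    return int(ss.generate_state(1)[0] % (2**31))
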