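"""Metrics and the 10-fold train/validation/test evaluation protocol.

Each cross-validation round uses 8 folds for training the base learners (and
the PSSM, which is rebuilt from the positive training sequences of that round
only), 1 fold for the GA weight search (validation), and 1 fold for testing;
the validation fold is the one cyclically following the test fold. AUC is the
primary metric; ACC/SN/SP are reported at a 0.5 threshold (predict positive
iff F(x) >= 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence as TSequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError
from .features import FeatureSpec, build_pssm, encode_dataset
from .gawe import GAConfig, ga_optimize, ensemble_score
from .learners import BaseLearner, learner_seed, score_matrix, train_base_learner
from .seqio import LabeledDataset

logger = logging.getLogger(__name__)

N_FOLDS = 10
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class MetricsReport:
    """AUC, accuracy, sensitivity and specificity for one evaluation."""

    auc: float
    acc: float
    sn: float
    sp: float
    threshold: float = DEFAULT_THRESHOLD

    def as_dict(self) -> dict[str, float]:
        return {"AUC": self.auc, "ACC": self.acc, "SN": self.sn, "SP": self.sp}


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC (tied scores count 1/2); needs both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> MetricsReport:
    """SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/all at the threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValidationError("cannot evaluate an empty score vector")
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    neg = ~pos
    if not pos.any():
        raise ValidationError("SN undefined: no positive instances")
    if not neg.any():
        raise ValidationError("SP undefined: no negative instances")
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & neg).sum())
    fp = int((pred & neg).sum())
    return MetricsReport(
        auc=roc_auc(scores, labels),
        acc=(tp + tn) / (tp + tn + fp + fn),
        sn=tp / (tp + fn),
        sp=tn / (tn + fp),
        threshold=threshold,
    )


@dataclass(frozen=True)
class CVPlan:
    """Stratified fold assignment plus the 8/1/1 role schedule."""

    fold_of: np.ndarray  # fold index (0..9) per instance

    def round_indices(self, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train, validation, test) instance indices for round r (0-based)."""
        test_fold = r
        val_fold = (r + 1) % N_FOLDS
        test = np.flatnonzero(self.fold_of == test_fold)
        val = np.flatnonzero(self.fold_of == val_fold)
        train = np.flatnonzero((self.fold_of != test_fold) & (self.fold_of != val_fold))
        return train, val, test


def make_cv_plan(n: int, labels: np.ndarray, rng_seed: int) -> CVPlan:
    """Seeded stratified assignment of n instances to 10 folds."""
    labels = np.asarray(labels)
    if n < N_FOLDS:
        raise ValidationError(f"need at least {N_FOLDS} instances, got {n}")
    if labels.shape[0] != n:
        raise ValidationError("labels length must equal n")
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=rng_seed)
    fold_of = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        fold_of[test_idx] = f
    return CVPlan(fold_of)


@dataclass
class CVRoundResult:
    round_index: int
    report: MetricsReport
    weights: np.ndarray
    ga_trace: np.ndarray
    test_indices: np.ndarray


@dataclass
class CVResult:
    rounds: list[CVRoundResult]
    mean_report: MetricsReport
    catalog: list[FeatureSpec]

    @property
    def weight_matrix(self) -> np.ndarray:
        """(rounds x features) optimal-weight heat-map data."""
        return np.vstack([r.weights for r in self.rounds])

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weight_matrix,
            index=[f"round{r.round_index + 1}" for r in self.rounds],
            columns=[s.name for s in self.catalog],
        )

    def metrics_frame(self) -> pd.DataFrame:
        rows = [r.report.as_dict() for r in self.rounds]
        frame = pd.DataFrame(rows, index=[f"round{r.round_index + 1}" for r in self.rounds])
        frame.loc["mean"] = frame.mean()
        return frame


def run_cv(
    dataset: LabeledDataset,
    catalog: TSequence[FeatureSpec],
    ga_cfg: GAConfig = GAConfig(),
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVResult:
    """Run the full 10-round 8/1/1 protocol on a labeled dataset.

    Sequence-only feature matrices are computed once; the PSSM feature is
    recomputed per round from that round's positive training sequences, so
    no validation or test information reaches training.
    """
    labels = dataset.labels
    plan = make_cv_plan(len(dataset), labels, seed)
    catalog = list(catalog)
    static_specs = [s for s in catalog if s.family != "pssm"]
    pssm_specs = [s for s in catalog if s.family == "pssm"]

    logger.info("encoding %d sequences for %d static feature families",
                len(dataset), len(static_specs))
    static_matrices = encode_dataset(dataset.sequences, static_specs)

    rounds: list[CVRoundResult] = []
    for r in range(N_FOLDS):
        train, val, test = plan.round_indices(r)
        matrices = dict(static_matrices)
        if pssm_specs:
            train_pos = [dataset.sequences[i] for i in train if labels[i] == 1]
            for spec in pssm_specs:
                model = build_pssm(train_pos, spec.d)
                matrices.update(encode_dataset(dataset.sequences, [spec], model))

        bank: list[BaseLearner] = []
        for fi, spec in enumerate(catalog):
            bank.append(
                train_base_learner(
                    matrices[spec.name][train], labels[train],
                    engine_seed=learner_seed(seed, r, fi), spec=spec,
                )
            )
        sub = lambda idx: {s.name: matrices[s.name][idx] for s in catalog}
        s_val = score_matrix(bank, sub(val))
        s_test = score_matrix(bank, sub(test))

        ga = ga_optimize(
            s_val, labels[val],
            GAConfig(
                population_size=ga_cfg.population_size,
                generations=ga_cfg.generations,
                k1=ga_cfg.k1, k2=ga_cfg.k2, k3=ga_cfg.k3, k4=ga_cfg.k4,
                elite_count=ga_cfg.elite_count,
                rng_seed=learner_seed(seed, r, 10_000),
            ),
        )
        test_scores = ensemble_score(ga.weights, s_test)
        report = confusion_metrics(test_scores, labels[test], threshold)
        logger.info("round %d: test AUC %.3f ACC %.3f", r + 1, report.auc, report.acc)
        rounds.append(CVRoundResult(r, report, ga.weights, ga.trace, test))

    mean = MetricsReport(
        auc=float(np.mean([x.report.auc for x in rounds])),
        acc=float(np.mean([x.report.acc for x in rounds])),
        sn=float(np.mean([x.report.sn for x in rounds])),
        sp=float(np.mean([x.report.sp for x in rounds])),
        threshold=threshold,
    )
    return CVResult(rounds, mean, catalog)
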