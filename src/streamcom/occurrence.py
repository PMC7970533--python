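"""Per-species probabilistic occurrence models.

Each commonly caught species gets a boosted-tree binary classifier of
presence/absence over five stream covariates (drainage area, catchment
elevation, slope, IWI, BMMI).  Training positives are survey sites
where the species was caught; negatives are sites inside HUC8s where
the species has a distribution record but was not caught — absences
outside the known range carry no information about habitat and are
never used.  Species caught in fewer than ``min_captures`` surveys
(default 25) are not modelled.

Two bespoke decision thresholds convert a predicted probability into
presence/absence, both computed from training-set predictions:

* mean rule: ``(P0 + P1)/2`` where P1/P0 are the mean predicted
  probabilities at presence/absence training sites;
* robust rule: ``max(P0, P1 − SD(P1))``, a lower cutoff that trades
  false positives for fewer false negatives.

Validation is summarised by a pooled confusion matrix with Cohen's
kappa, accuracy, sensitivity and specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .species import DistributionTable, StreamCovariates, SurveyRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_HYPERPARAMETERS",
    "DEFAULT_MIN_CAPTURES",
    "ThresholdStats",
    "OccurrenceModel",
    "TrainingTable",
    "TrainingSets",
    "ValidationSummary",
    "build_training_sets",
    "train_occurrence_model",
    "threshold_mean",
    "threshold_robust",
    "decision_threshold",
    "filter_assemblage",
    "validation_metrics",
    "split_surveys",
    "pooled_confusion",
]

COVARIATE_COLUMNS = list(StreamCovariates.FIELDS)

DEFAULT_MIN_CAPTURES = 25

#: Boosting hyperparameters under their published configuration names.
#: The list mixes two libraries' vocabularies; see
#: :data:`HYPERPARAMETER_NAME_MAP` for how each maps onto the XGBoost
#: native parameter actually set.
DEFAULT_HYPERPARAMETERS: dict[str, float | int] = {
    "n_estimators": 500,
    "learning_rate": 0.05,
    "subsample": 0.75,
    "min_samples_leaf": 3,
    "max_depth": 3,
    "n_iter_no_change": 10,
}

#: Config-name -> XGBoost-native-name.  ``min_samples_leaf`` (a
#: scikit-learn tree parameter) has no exact XGBoost equivalent; the
#: nearest is ``min_child_weight``, the minimum summed hessian in a
#: leaf, which for logistic loss approximates a minimum leaf size.
#: ``n_iter_no_change`` maps to ``early_stopping_rounds``.
HYPERPARAMETER_NAME_MAP: dict[str, str] = {
    "n_estimators": "n_estimators",
    "learning_rate": "learning_rate",
    "subsample": "subsample",
    "min_samples_leaf": "min_child_weight",
    "max_depth": "max_depth",
    "n_iter_no_change": "early_stopping_rounds",
}

#: Fraction of the training table carved off as the internal
#: early-stopping validation fold.
EARLY_STOPPING_FRACTION = 0.15


@dataclass(frozen=True)
class ThresholdStats:
    """Training-set prediction summaries used by the threshold rules.

    p1_mean : mean predicted probability at sites where the species
        was present (P1).
    p0_mean : mean at sites where it was absent (P0).
    p1_sd : standard deviation of predictions at presence sites.
    """

    p1_mean: float
    p0_mean: float
    p1_sd: float

    def __post_init__(self) -> None:
        for name in ("p1_mean", "p0_mean", "p1_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class TrainingTable:
    """Labelled covariate table for one species."""

    species_id: str
    X: pd.DataFrame
    y: np.ndarray
    n_present: int
    n_absent: int

    @property
    def degenerate(self) -> bool:
        """True when only one class is present (e.g. a species caught
        at every site in its range)."""
        return self.n_present == 0 or self.n_absent == 0


@dataclass
class TrainingSets:
    """Per-species training tables plus the species excluded by the
    minimum-capture rule (species_id -> capture count)."""

    tables: dict[str, TrainingTable]
    excluded: dict[str, int]


@dataclass
class OccurrenceModel:
    """A fitted boosted-tree occurrence classifier for one species."""

    species_id: str
    booster: XGBClassifier
    threshold_stats: ThresholdStats
    n_present: int
    n_absent: int
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def predict_probability(
        self, covariates: StreamCovariates | pd.DataFrame
    ) -> np.ndarray:
        if isinstance(covariates, StreamCovariates):
            frame = pd.DataFrame([covariates.as_tuple()], columns=COVARIATE_COLUMNS)
        else:
            frame = covariates[COVARIATE_COLUMNS]
        return self.booster.predict_proba(frame)[:, 1]


@dataclass(frozen=True)
class ValidationSummary:
    """Pooled confusion-matrix summary.

    Sensitivity/specificity are ``None`` (not 0) when their
    denominator is zero.
    """

    true_pos: int
    false_pos: int
    false_neg: int
    true_neg: int
    kappa: float
    accuracy: float
    sensitivity: float | None
    specificity: float | None


def build_training_sets(
    surveys: Sequence[SurveyRecord],
    db: DistributionTable,
    min_captures: int = DEFAULT_MIN_CAPTURES,
) -> TrainingSets:
    """Assemble per-species presence/absence training tables.

    Positives: surveys where the species was caught.  Negatives:
    surveys in HUC8s where the species has a distribution record but
    was not caught.  Species caught in fewer than ``min_captures``
    surveys are excluded and reported.
    """
    capture_counts: dict[str, int] = {}
    for survey in surveys:
        for sid in survey.caught:
            capture_counts[sid] = capture_counts.get(sid, 0) + 1

    cov = pd.DataFrame(
        [s.covariates.as_tuple() for s in surveys], columns=COVARIATE_COLUMNS
    )
    huc_ids = np.array([s.huc8_id for s in surveys])

    tables: dict[str, TrainingTable] = {}
    excluded: dict[str, int] = {}
    for sid, n_caught in sorted(capture_counts.items()):
        if n_caught < min_captures:
            excluded[sid] = n_caught
            continue
        in_range = np.isin(huc_ids, sorted(db.hucs_for_species(sid)))
        caught = np.array([sid in s.caught for s in surveys])
        keep = caught | in_range
        y = caught[keep].astype(int)
        tables[sid] = TrainingTable(
            species_id=sid,
            X=cov.loc[keep].reset_index(drop=True),
            y=y,
            n_present=int(y.sum()),
            n_absent=int((1 - y).sum()),
        )
        if tables[sid].degenerate:
            logger.warning(
                "species %s training set is degenerate "
                "(present=%d, absent=%d)",
                sid, tables[sid].n_present, tables[sid].n_absent,
            )
    return TrainingSets(tables=tables, excluded=excluded)


def _native_hyperparameters(hyperparameters: Mapping[str, float | int]) -> dict:
    native = {}
    for name, value in hyperparameters.items():
        mapped = HYPERPARAMETER_NAME_MAP.get(name, name)
        if mapped != name:
            logger.info("hyperparameter %s -> %s = %r", name, mapped, value)
        native[mapped] = value
    return native


def train_occurrence_model(
    table: TrainingTable,
    hyperparameters: Mapping[str, float | int] | None = None,
    seed: int = 0,
) -> OccurrenceModel:
    """Fit a boosted-tree occurrence classifier for one species.

    An internal stratified validation fold (15% of the table) drives
    early stopping: boosting halts once the fold's log-loss fails to
    improve for ``n_iter_no_change`` rounds.  Threshold statistics
    (P1, P0, SD(P1)) are computed from predictions over the full
    training table.  Fully deterministic for a fixed seed.
    """
    if table.degenerate:
        raise ValueError(
            f"species {table.species_id}: training set has a single class "
            f"(present={table.n_present}, absent={table.n_absent}); "
            "see build_training_sets degenerate flag"
        )
    params = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        params.update(hyperparameters)
    native = _native_hyperparameters(params)

    X_fit, X_val, y_fit, y_val = train_test_split(
        table.X,
        table.y,
        test_size=EARLY_STOPPING_FRACTION,
        random_state=seed,
        stratify=table.y,
    )
    clf = XGBClassifier(
        objective="binary:logistic",
        eval_metric="logloss",
        random_state=seed,
        n_jobs=1,
        **native,
    )
    clf.fit(X_fit, y_fit, eval_set=[(X_val, y_val)], verbose=False)

    prob = clf.predict_proba(table.X)[:, 1]
    present = table.y == 1
    stats = ThresholdStats(
        p1_mean=float(prob[present].mean()),
        p0_mean=float(prob[~present].mean()),
        p1_sd=float(prob[present].std(ddof=0)),
    )
    return OccurrenceModel(
        species_id=table.species_id,
        booster=clf,
        threshold_stats=stats,
        n_present=table.n_present,
        n_absent=table.n_absent,
        hyperparameters=dict(params),
        seed=seed,
    )


def threshold_mean(stats: ThresholdStats) -> float:
    """Mean-based decision threshold ``(P0 + P1)/2``."""
    return 0.5 * (stats.p0_mean + stats.p1_mean)


def threshold_robust(stats: ThresholdStats) -> float:
    """Robust decision threshold ``max(P0, P1 − SD(P1))``; lower than
    the mean rule whenever SD(P1) exceeds (P1 − P0)/2."""
    return max(stats.p0_mean, stats.p1_mean - stats.p1_sd)


def decision_threshold(
    stats: ThresholdStats, rule: str | float
) -> float:
    """Resolve a threshold rule ('mean', 'robust', or a fixed numeric
    cutoff) into a probability."""
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        if not 0.0 <= rule <= 1.0:
            raise ValueError(f"fixed threshold must lie in [0, 1], got {rule}")
        return float(rule)
    if rule == "mean":
        return threshold_mean(stats)
    if rule == "robust":
        return threshold_robust(stats)
    raise ValueError(f"unknown threshold rule: {rule!r}")


def filter_assemblage(
    assemblage: Sequence[str],
    covariates: StreamCovariates,
    models: Mapping[str, OccurrenceModel],
    threshold_rule: str | float = "mean",
    include: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> list[tuple[str, float | None]]:
    """Filter a HUC8 species pool into a plausible stream community.

    A modelled species is retained iff its predicted probability at
    ``covariates`` is >= its threshold (inclusive boundary).  Species
    without a model — the rarely caught ones — pass through with
    probability ``None``.  Manual ``include``/``exclude`` overrides are
    applied last and win over the model decision.
    """
    include, exclude = set(include), set(exclude)
    community: list[tuple[str, float | None]] = []
    for sid in assemblage:
        model = models.get(sid)
        if model is None:
            prob: float | None = None
            retained = True
        else:
            prob = float(model.predict_probability(covariates)[0])
            retained = prob >= decision_threshold(model.threshold_stats, threshold_rule)
        if sid in exclude:
            retained = False
        elif sid in include:
            retained = True
        if retained:
            community.append((sid, prob))
    return community


def validation_metrics(
    true_pos: int, false_pos: int, false_neg: int, true_neg: int
) -> ValidationSummary:
    """Confusion-matrix summary with Cohen's kappa.

    kappa = (p_o − p_e)/(1 − p_e), with expected agreement p_e from
    the marginal products.  Sensitivity = TP/(TP+FN) and specificity =
    TN/(TN+FP) are ``None`` when undefined.
    """
    counts = (true_pos, false_pos, false_neg, true_neg)
    if any(c < 0 for c in counts):
        raise ValueError(f"confusion counts must be non-negative: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("confusion matrix is empty")

    p_o = (true_pos + true_neg) / n
    pred_pos = true_pos + false_pos
    pred_neg = false_neg + true_neg
    act_pos = true_pos + false_neg
    act_neg = false_pos + true_neg
    p_e = (pred_pos * act_pos + pred_neg * act_neg) / (n * n)
    kappa = 0.0 if math.isclose(p_e, 1.0) else (p_o - p_e) / (1.0 - p_e)

    sensitivity = true_pos / act_pos if act_pos else None
    specificity = true_neg / act_neg if act_neg else None
    return ValidationSummary(
        true_pos=true_pos,
        false_pos=false_pos,
        false_neg=false_neg,
        true_neg=true_neg,
        kappa=float(kappa),
        accuracy=float(p_o),
        sensitivity=None if sensitivity is None else float(sensitivity),
        specificity=None if specificity is None else float(specificity),
    )


def split_surveys(
    surveys: Sequence[SurveyRecord],
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[SurveyRecord], list[SurveyRecord]]:
    """Random by-site train/test split (default 75/25)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(surveys))
    n_test = int(round(test_fraction * len(surveys)))
    test_idx = set(order[:n_test].tolist())
    train = [s for i, s in enumerate(surveys) if i not in test_idx]
    test = [s for i, s in enumerate(surveys) if i in test_idx]
    return train, test


def pooled_confusion(
    models: Mapping[str, OccurrenceModel],
    surveys: Sequence[SurveyRecord],
    db: DistributionTable,
    threshold_rule: str | float = "mean",
) -> tuple[int, int, int, int]:
    """Pooled (species x site) confusion counts on a survey set.

    For each modelled species, sites inside its recorded range are
    scored: actual presence is whether it was caught; predicted
    presence is probability >= threshold.  Counts are pooled over all
    species, matching a micro-averaged validation summary.
    Returns (TP, FP, FN, TN).
    """
    cov = pd.DataFrame(
        [s.covariates.as_tuple() for s in surveys], columns=COVARIATE_COLUMNS
    )
    huc_ids = np.array([s.huc8_id for s in surveys])
    tp = fp = fn = tn = 0
    for sid in sorted(models):
        model = models[sid]
        in_range = np.isin(huc_ids, sorted(db.hucs_for_species(sid)))
        caught = np.array([sid in s.caught for s in surveys])
        keep = caught | in_range
        if not keep.any():
            continue
        prob = model.predict_probability(cov.loc[keep])
        cutoff = decision_threshold(model.threshold_stats, threshold_rule)
        predicted = prob >= cutoff
        actual = caught[keep]
        tp += int((predicted & actual).sum())
        fp += int((predicted & ~actual).sum())
        fn += int((~predicted & actual).sum())
        tn += int((~predicted & ~actual).sum())
    return tp, fp, fn, tn
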