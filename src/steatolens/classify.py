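"""Patch-level classifiers with donor-level nested cross-validation.

Livers are labelled ``valid`` (HS <= threshold) or ``non_valid``
(HS > threshold) from biopsy; every patch inherits its case's label.
Because the classes are imbalanced (roughly 28 % non-valid at the 15 %
threshold), classifier losses are weighted inversely proportional to
class frequency, ``w_c = N / (2 * N_c)``.

Generalisation is estimated by nested cross-validation: an outer loop of
repeated stratified 70/30 donor splits, and for each outer repeat an
inner stratified 90/10 donor split of the outer-training donors used to
pick hyperparameters by grid search (inner liver-level AUC). All splits
are at the donor level so that no donor contributes patches to both
sides of any split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aggregate_eval import (
    NON_VALID,
    VALID,
    AggregationConfig,
    aggregate,
    metrics as eval_metrics,
    roc_auc,
)
from .cases import LiverCase
from .features import ClinicalScaler, FeatureConfig, feature_names as _feature_names


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# labels and class weights

def case_hs(values: Sequence[float], lobe_rule: str = "mean") -> float:
    """Combine per-lobe biopsy HS values into one case-level value."""
    if not values:
        raise ClassifyError("no biopsy values available")
    if lobe_rule == "mean":
        return float(np.mean(values))
    if lobe_rule == "max":
        return float(np.max(values))
    raise ClassifyError(f"unknown lobe rule {lobe_rule!r}")


def make_label(case: LiverCase, threshold: float, lobe_rule: str = "mean") -> int:
    """``non_valid`` iff the case HS exceeds the threshold (HS <= t is valid)."""
    return NON_VALID if case_hs(case.biopsy_values(), lobe_rule) > threshold else VALID


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Inverse-frequency weights ``w_c = N / (2 * N_c)``."""
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassifyError("both classes must be present to compute weights")
    n = y.size
    return {int(c): n / (2 * int(k)) for c, k in zip(classes, counts)}


# ---------------------------------------------------------------------------
# donor-level splits

def split_donors(
    donor_labels: dict[str, int],
    test_fraction: float = 0.30,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Stratified donor-disjoint split.

    Per class, ``round(test_fraction * N_c)`` donors (at least 1, at most
    ``N_c - 1``) go to the test side. Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for d, lab in donor_labels.items():
        by_class.setdefault(int(lab), []).append(d)
    train, test = [], []
    for lab in sorted(by_class):
        ids = sorted(by_class[lab])
        if len(ids) < 2:
            raise ClassifyError(f"class {lab} has fewer than 2 donors")
        rng.shuffle(ids)
        n_test = int(np.clip(round(test_fraction * len(ids)), 1, len(ids) - 1))
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return sorted(train), sorted(test)


@dataclass
class SplitManifest:
    outer_train: list[str]
    outer_test: list[str]
    inner_train: list[str]
    inner_val: list[str]


def plan_nested_splits(
    donor_labels: dict[str, int],
    outer_repeats: int,
    seed: int,
    test_fraction: float = 0.30,
    inner_fraction: float = 0.10,
) -> list[SplitManifest]:
    """Donor manifests for every outer repeat and its inner split."""
    rng = np.random.default_rng(seed)
    manifests = []
    for _ in range(outer_repeats):
        tr, te = split_donors(donor_labels, test_fraction, rng)
        inner_labels = {d: donor_labels[d] for d in tr}
        itr, iva = split_donors(inner_labels, inner_fraction, rng)
        manifests.append(
            SplitManifest(outer_train=tr, outer_test=te, inner_train=itr, inner_val=iva)
        )
    return manifests


# ---------------------------------------------------------------------------
# model configuration and training

FOREST_GRID: tuple[dict, ...] = tuple(
    {"n_estimators": n, "max_depth": d, "max_features": f}
    for n in (100, 300)
    for d in (None, 10)
    for f in ("sqrt", "log2")
)
#: RBF margin classifier: C grid and kernel-width multipliers around the
#: default scale heuristic.
SVM_GRID: tuple[dict, ...] = tuple(
    {"C": c, "gamma_mult": g} for c in (0.1, 1.0, 10.0) for g in (0.3, 1.0, 3.0)
)


@dataclass(frozen=True)
class ModelConfig:
    """Which classifier to train and under which labelling regime."""

    classifier: str = "random_forest"  # or "margin_svm"
    hs_threshold: float = 15.0
    use_clinical: bool = True
    lobe_rule: str = "mean"
    grid: Optional[tuple[dict, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hs_threshold < 100:
            raise ClassifyError("hs_threshold must be in (0, 100)")
        if self.classifier not in ("random_forest", "margin_svm"):
            raise ClassifyError(f"unknown classifier {self.classifier!r}")

    @property
    def effective_grid(self) -> tuple[dict, ...]:
        if self.grid is not None:
            return self.grid
        return FOREST_GRID if self.classifier == "random_forest" else SVM_GRID


@dataclass
class TrainedModel:
    """A fitted patch classifier plus everything needed to apply it."""

    kind: str
    estimator: object
    class_weights: dict[int, float]
    feature_cfg: FeatureConfig
    scaler: Optional[ClinicalScaler]
    hs_threshold: float
    lobe_rule: str
    grid_point: dict
    seed: int
    link: object = None  # logistic link mapping SVM margins to [0, 1]
    input_scaler: object = None  # feature standardizer for the SVM path

    @property
    def feature_names(self) -> list[str]:
        return _feature_names(self.feature_cfg)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Probability-like score for ``non_valid`` in [0, 1] per patch."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_cfg.n_features:
            raise ClassifyError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.feature_cfg.n_features})"
            )
        if self.kind == "random_forest":
            proba = self.estimator.predict_proba(X)
            idx = list(self.estimator.classes_).index(NON_VALID)
            return proba[:, idx]
        margins = self.estimator.decision_function(self.input_scaler.transform(X))
        return self.link.predict_proba(margins.reshape(-1, 1))[:, 1]


def predict_patch(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch (label, score); label is ``non_valid`` iff score >= 0.5."""
    scores = model.predict_scores(features)
    labels = np.where(scores >= 0.5, NON_VALID, VALID)
    return labels, scores


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ModelConfig,
    feature_cfg: FeatureConfig,
    scaler: Optional[ClinicalScaler] = None,
    grid_point: Optional[dict] = None,
    seed: Optional[int] = None,
) -> TrainedModel:
    """Fit one patch-level classifier with inverse-frequency class weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ClassifyError("training set must contain both classes")
    if np.all(X.std(axis=0) == 0):
        raise ClassifyError("all features have zero variance")
    seed = cfg.seed if seed is None else seed
    gp = dict(grid_point) if grid_point is not None else dict(cfg.effective_grid[0])
    weights = class_weights(y)
    link = None
    input_scaler = None
    if cfg.classifier == "random_forest":
        est = RandomForestClassifier(
            n_estimators=gp.get("n_estimators", 100),
            max_depth=gp.get("max_depth"),
            max_features=gp.get("max_features", "sqrt"),
            class_weight=weights,
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y)
    else:
        input_scaler = StandardScaler().fit(X)
        Xs = input_scaler.transform(X)
        gamma = gp.get("gamma_mult", 1.0) / (X.shape[1] * Xs.var())
        est = SVC(
            kernel="rbf",
            C=gp.get("C", 1.0),
            gamma=gamma,
            class_weight=weights,
            random_state=seed,
        )
        est.fit(Xs, y)
        margins = est.decision_function(Xs).reshape(-1, 1)
        link = LogisticRegression(random_state=seed).fit(margins, y)
    return TrainedModel(
        kind=cfg.classifier,
        estimator=est,
        class_weights=weights,
        feature_cfg=feature_cfg,
        scaler=scaler,
        hs_threshold=cfg.hs_threshold,
        lobe_rule=cfg.lobe_rule,
        grid_point=gp,
        seed=seed,
        link=link,
        input_scaler=input_scaler,
    )


# ---------------------------------------------------------------------------
# nested cross-validation over a patch table

@dataclass
class RepeatResult:
    metrics: dict[str, Optional[float]]
    grid_point: dict
    manifest: SplitManifest
    predictions: list = field(default_factory=list)


@dataclass
class CvResult:
    repeats: list[RepeatResult]

    def mean_metric(self, name: str) -> float:
        vals = [r.metrics[name] for r in self.repeats if r.metrics.get(name) is not None]
        return float(np.mean(vals))

    @property
    def mean_metrics(self) -> dict[str, float]:
        keys = self.repeats[0].metrics.keys()
        return {k: self.mean_metric(k) for k in keys}


def _evaluate_cases(
    model: TrainedModel,
    table,
    case_idx: Sequence[int],
    agg_cfg: AggregationConfig,
) -> tuple[list, np.ndarray, np.ndarray, np.ndarray]:
    """Liver-level predictions and metrics inputs for the given cases."""
    labels = table.case_labels(model.hs_threshold, model.lobe_rule)
    preds, fractions, decisions, truths = [], [], [], []
    for ci in case_idx:
        Xc = table.case_matrix(ci, model.feature_cfg.use_clinical, model.scaler)
        patch_labels, patch_scores = predict_patch(model, Xc)
        lp = aggregate(patch_labels, agg_cfg, case_id=table.case_ids[ci], patch_scores=patch_scores)
        preds.append(lp)
        fractions.append(lp.fraction)
        decisions.append(lp.decision)
        truths.append(labels[ci])
    return preds, np.array(fractions), np.array(decisions), np.array(truths)


def _liver_metrics(fractions, decisions, truths) -> dict[str, Optional[float]]:
    m = eval_metrics(decisions, truths)
    out = {
        "accuracy": m.accuracy,
        "precision": m.precision,
        "recall": m.recall,
    }
    if len(np.unique(truths)) >= 2:
        _, out["auc"] = roc_auc(fractions, truths)
    else:
        out["auc"] = None
    return out


def nested_cv(
    table,
    cfg: ModelConfig,
    outer_repeats: int = 10,
    agg_cfg: AggregationConfig = AggregationConfig(),
    test_fraction: float = 0.30,
    inner_fraction: float = 0.10,
) -> CvResult:
    """Repeated stratified 70/30 donor splits with inner 90/10 model selection.

    For each outer repeat, every grid point is fitted on the inner-train
    donors and scored by liver-level AUC on the inner-validation donors;
    the best point is refitted on the full outer-training set and
    evaluated on the held-out outer-test donors at the liver level. The
    average across repeats is the generalisation estimate.
    """
    donor_labels = table.donor_labels(cfg.hs_threshold, cfg.lobe_rule)
    manifests = plan_nested_splits(
        donor_labels, outer_repeats, cfg.seed, test_fraction, inner_fraction
    )
    repeats = []
    for rep, man in enumerate(manifests):
        rep_seed = (cfg.seed + 7919 * (rep + 1)) % (2**31 - 1)
        best_gp, best_score = None, -np.inf
        for gp in cfg.effective_grid:
            model = _fit_on_donors(table, man.inner_train, cfg, gp, rep_seed)
            idx = table.indices_for(man.inner_val)
            _, fr, de, tr = _evaluate_cases(model, table, idx, agg_cfg)
            if len(np.unique(tr)) >= 2:
                _, score = roc_auc(fr, tr)
            else:  # degenerate inner validation fold: fall back to accuracy
                score = eval_metrics(de, tr).accuracy
            if score > best_score:
                best_gp, best_score = gp, score
        model = _fit_on_donors(table, man.outer_train, cfg, best_gp, rep_seed)
        idx = table.indices_for(man.outer_test)
        preds, fr, de, tr = _evaluate_cases(model, table, idx, agg_cfg)
        repeats.append(
            RepeatResult(
                metrics=_liver_metrics(fr, de, tr),
                grid_point=dict(best_gp),
                manifest=man,
                predictions=preds,
            )
        )
    return CvResult(repeats=repeats)


def _fit_on_donors(
    table, donor_ids: Sequence[str], cfg: ModelConfig, grid_point: dict, seed: int
) -> TrainedModel:
    idx = table.indices_for(donor_ids)
    scaler = table.fit_clinical_scaler(idx) if cfg.use_clinical else None
    X, y = table.training_matrix(idx, cfg.hs_threshold, cfg.lobe_rule, cfg.use_clinical, scaler)
    feature_cfg = table.feature_cfg_with_clinical(cfg.use_clinical)
    return train(X, y, cfg, feature_cfg, scaler=scaler, grid_point=grid_point, seed=seed)
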