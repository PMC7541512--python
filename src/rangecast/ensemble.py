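"""Ensemble species distribution modelling.

Three presence/pseudo-absence base learners are fitted over independent
pseudo-absence replicates and stratified cross-validation folds:

* ``boosted_trees`` — stagewise boosted shallow regression trees with
  logistic loss (the GBM of the SDM literature);
* ``additive_model`` — a sum of smooth univariate spline terms through a
  logistic link (a GAM);
* ``maxent_like`` — presence-vs-background penalized logistic regression on
  the predictors plus their squares, the standard Maxent / infinitely
  weighted logistic regression correspondence.

Each fold-fit is scored on its held-out fold with the true skill statistic
(TSS = sensitivity + specificity - 1, at the TSS-maximizing cut point) and
AUROC.  Fits enter the ensemble iff TSS >= 0.4 (inclusive) and AUROC > 0.7
(strict); ensemble weights are proportional to TSS, and the ensemble's own
binarization cut point again maximizes TSS, on pooled holdout predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, SplineTransformer, StandardScaler

from .grids import EnvStack, Layer, extract_values
from .occurrences import CalibrationArea, OccurrenceSet
from .pseudoabsence import fit_profile, replicate_seeds, sample_pseudo_absences

logger = logging.getLogger(__name__)

LEARNERS = ("boosted_trees", "additive_model", "maxent_like")


class UndefinedMetricError(ValueError):
    """Metric requested with one class absent."""


class NoAdmissibleModelsError(ValueError):
    """Every candidate fit failed the TSS/AUROC gates."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class EnsembleConfig:
    """Workflow and hyperparameter settings with field-standard defaults.

    ``pa_counts`` maps learner -> pseudo-absence count; the additive model
    uses as many pseudo-absences as presences (the string ``"n_presence"``).
    """

    n_pa_replicates: int = 10
    folds: int = 5
    train_fraction: float = 0.8
    tss_min: float = 0.4
    auc_min: float = 0.7
    weight_metric: str = "tss"  # or "auroc"
    pa_counts: dict = field(
        default_factory=lambda: {
            "boosted_trees": 1000,
            "additive_model": "n_presence",
            "maxent_like": 1000,
        }
    )
    learners: tuple = LEARNERS
    profile_q: float = 0.025
    # base-learner hyperparameters; shallow stumps with strong shrinkage give
    # smoother, better-calibrated probability surfaces than deep fast trees
    gbm_stages: int = 300
    gbm_depth: int = 1
    gbm_learning_rate: float = 0.05
    spline_knots: int = 5
    spline_degree: int = 3
    additive_C: float = 1.0
    maxent_C: float = 1.0

    def pa_count(self, learner: str, n_presence: int) -> int:
        raw = self.pa_counts.get(learner, 1000)
        return n_presence if raw == "n_presence" else int(raw)


# ---------------------------------------------------------------------------
# Data splitting


@dataclass
class TrainingSet:
    """Feature table with labels, replicate id and 1-based fold assignment."""

    features: pd.DataFrame
    labels: np.ndarray
    folds: np.ndarray
    replicate_id: int = 0

    def fold_split(self, fold_id: int):
        """(train X, train y, val X, val y) for one CV fold."""
        val = self.folds == fold_id
        return (
            self.features[~val],
            self.labels[~val],
            self.features[val],
            self.labels[val],
        )


def _stratified_assign(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each record to one of k groups, balanced within each class."""
    out = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        out[idx] = np.arange(len(idx)) % k
    return out


def split_data(
    features: pd.DataFrame,
    labels: np.ndarray,
    train_fraction: float = 0.8,
    folds: int = 5,
    seed: int = 0,
    replicate_id: int = 0,
) -> tuple[TrainingSet, pd.DataFrame, np.ndarray]:
    """Stratified train/holdout split plus stratified CV folds.

    Class proportions are preserved within +-1 record in the holdout and in
    every fold.  Returns (training set, holdout features, holdout labels).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to stratify")
    rng = np.random.default_rng(seed)
    holdout_mask = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_hold = int(round(len(idx) * (1 - train_fraction)))
        rng.shuffle(idx)
        holdout_mask[idx[:n_hold]] = True
    train_idx = np.flatnonzero(~holdout_mask)
    y_train = labels[train_idx]
    if min(np.bincount(y_train, minlength=2)) < folds:
        raise ValueError(
            f"too few records per class ({np.bincount(y_train)}) for {folds} folds"
        )
    fold_assign = _stratified_assign(y_train, folds, rng) + 1
    train = TrainingSet(
        features=features.iloc[train_idx].reset_index(drop=True),
        labels=y_train,
        folds=fold_assign,
        replicate_id=replicate_id,
    )
    return train, features.iloc[holdout_mask].reset_index(drop=True), labels[holdout_mask]


# ---------------------------------------------------------------------------
# Base learners


def _add_squares(X):
    X = np.asarray(X, dtype=float)
    return np.hstack([X, X**2])


def _make_estimator(learner: str, config: EnsembleConfig, random_state: int):
    if learner == "boosted_trees":
        return GradientBoostingClassifier(
            n_estimators=config.gbm_stages,
            max_depth=config.gbm_depth,
            learning_rate=config.gbm_learning_rate,
            random_state=random_state,
        )
    if learner == "additive_model":
        return Pipeline(
            [
                (
                    "splines",
                    SplineTransformer(
                        n_knots=config.spline_knots, degree=config.spline_degree
                    ),
                ),
                (
                    "logit",
                    LogisticRegression(
                        C=config.additive_C, max_iter=1000, random_state=random_state
                    ),
                ),
            ]
        )
    if learner == "maxent_like":
        return Pipeline(
            [
                ("quadratic", FunctionTransformer(_add_squares)),
                ("scale", StandardScaler()),
                (
                    "logit",
                    LogisticRegression(
                        C=config.maxent_C, max_iter=1000, random_state=random_state
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown learner {learner!r}")


@dataclass
class BaseFit:
    """One fitted fold-level base model with its probability contract."""

    learner: str
    replicate_id: int
    fold_id: int
    predictors: list[str]
    model: object
    failed: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p = self.model.predict_proba(np.asarray(X[self.predictors], dtype=float))[:, 1]
        return np.clip(p, 0.0, 1.0)


def fit_base(
    learner: str,
    X: pd.DataFrame,
    y: np.ndarray,
    config: EnsembleConfig | None = None,
    random_state: int = 0,
    replicate_id: int = 0,
    fold_id: int = 0,
) -> BaseFit:
    """Fit one base learner; a non-converging fit is returned flagged failed."""
    config = config or EnsembleConfig()
    predictors = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    constant = Xa.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "constant feature(s) in training fold: %s",
            [p for p, c in zip(predictors, constant) if c],
        )
    est = _make_estimator(learner, config, random_state)
    fit = BaseFit(learner, replicate_id, fold_id, predictors, est)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xa, np.asarray(y, dtype=int))
    except Exception as exc:  # non-convergence or degenerate data
        logger.warning("fit failed (%s, rep %d, fold %d): %s", learner, replicate_id, fold_id, exc)
        fit.failed = True
    return fit


# ---------------------------------------------------------------------------
# Evaluation metrics


def auroc(scores, labels) -> float:
    """AUROC as the Mann-Whitney probability, ties counted half.

    Computed from midranks: AUROC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)
    where R_pos is the rank-sum of presence scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalResult:
    """Threshold metrics of one fit: TSS at the optimal cut point, AUROC."""

    tss: float
    auroc: float
    cutpoint: float
    sensitivity: float
    specificity: float


def tss(tp: int, fp: int, tn: int, fn: int) -> EvalResult:
    """TSS = sensitivity + specificity - 1 from a confusion matrix."""
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("TSS needs both observed classes")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalResult(
        tss=sens + spec - 1.0,
        auroc=float("nan"),
        cutpoint=float("nan"),
        sensitivity=sens,
        specificity=spec,
    )


def _tss_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> EvalResult:
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    res = tss(tp, fp, tn, fn)
    res.cutpoint = threshold
    return res


def optimize_cutpoint(scores, labels) -> EvalResult:
    """Scan every distinct score as a ``>=`` threshold; return the
    evaluation at the TSS-maximizing one (smallest such threshold on ties),
    with AUROC filled in."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best: EvalResult | None = None
    for t in np.unique(scores):
        res = _tss_at(scores, labels, float(t))
        if best is None or res.tss > best.tss:
            best = res
    assert best is not None
    best.auroc = auroc(scores, labels)
    return best


def evaluate_fit(fit: BaseFit, X_val: pd.DataFrame, y_val: np.ndarray) -> EvalResult:
    return optimize_cutpoint(fit.predict(X_val), y_val)


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsembleModel:
    """Gated, TSS-weighted ensemble of base fits with its own cut point."""

    fits: list[BaseFit]
    evals: list[EvalResult]
    weights: np.ndarray
    cutpoint: float
    predictors: list[str]
    tss_min: float = 0.4
    auc_min: float = 0.7
    rejected: list[tuple[str, int, int, EvalResult]] = field(default_factory=list)
    #: evaluation of the pooled member predictions on the 20% holdout records
    holdout_eval: EvalResult | None = None

    def predict_table(self, X: pd.DataFrame) -> np.ndarray:
        """Weighted-mean probability over retained fits for tabular input."""
        preds = np.stack([f.predict(X) for f in self.fits])
        return np.average(preds, axis=0, weights=self.weights)

    def model_card(self) -> dict:
        card = {
            "tss_min": self.tss_min,
            "auc_min": self.auc_min,
            "cutpoint": self.cutpoint,
            "predictors": self.predictors,
            "holdout": (
                {"tss": self.holdout_eval.tss, "auroc": self.holdout_eval.auroc}
                if self.holdout_eval is not None
                else None
            ),
            "retained": [
                {
                    "learner": f.learner,
                    "replicate": f.replicate_id,
                    "fold": f.fold_id,
                    "tss": e.tss,
                    "auroc": e.auroc,
                    "weight": float(w),
                }
                for f, e, w in zip(self.fits, self.evals, self.weights)
            ],
            "rejected": [
                {"learner": L, "replicate": r, "fold": k, "tss": e.tss, "auroc": e.auroc}
                for L, r, k, e in self.rejected
            ],
        }
        return card


def build_ensemble(
    fits: list[BaseFit],
    evals: list[EvalResult],
    holdout_scores: np.ndarray | None = None,
    holdout_labels: np.ndarray | None = None,
    tss_min: float = 0.4,
    auc_min: float = 0.7,
    weight_metric: str = "tss",
) -> EnsembleModel:
    """Gate fits (TSS >= tss_min AND AUROC > auc_min), weight by TSS.

    ``holdout_scores`` are the ensemble's pooled holdout predictions used to
    set the ensemble cut point; without them the weight-averaged member cut
    point is used.
    """
    retained, kept_evals, rejected = [], [], []
    for f, e in zip(fits, evals):
        if (not f.failed) and e.tss >= tss_min and e.auroc > auc_min:
            retained.append(f)
            kept_evals.append(e)
        else:
            rejected.append((f.learner, f.replicate_id, f.fold_id, e))
    if not retained:
        lines = ", ".join(
            f"{L}/rep{r}/fold{k}: tss={e.tss:.3f} auc={e.auroc:.3f}"
            for L, r, k, e in rejected
        )
        raise NoAdmissibleModelsError(f"no fit passed the gates ({lines})")
    metric = np.array(
        [e.tss if weight_metric == "tss" else e.auroc for e in kept_evals]
    )
    weights = metric / metric.sum() if metric.sum() > 0 else np.full(len(metric), 1 / len(metric))
    holdout_eval = None
    if holdout_scores is not None and holdout_labels is not None:
        holdout_eval = optimize_cutpoint(holdout_scores, holdout_labels)
        cut = holdout_eval.cutpoint
    else:
        cut = float(np.average([e.cutpoint for e in kept_evals], weights=weights))
    return EnsembleModel(
        fits=retained,
        evals=kept_evals,
        weights=weights,
        cutpoint=cut,
        predictors=list(retained[0].predictors),
        tss_min=tss_min,
        auc_min=auc_min,
        rejected=rejected,
        holdout_eval=holdout_eval,
    )


def predict_ensemble(model: EnsembleModel, stack: EnvStack) -> Layer:
    """Map the ensemble's weighted-mean probability over the grid.

    Nodata wherever any predictor is invalid.
    """
    missing = [p for p in model.predictors if p not in stack]
    if missing:
        raise KeyError(f"stack is missing predictor(s) {missing}")
    mask = stack.joint_mask(model.predictors)
    X = pd.DataFrame(
        {p: stack[p].values[mask] for p in model.predictors}
    )
    vals = np.full(stack.spec.shape, stack.spec.nodata)
    if len(X):
        vals[mask] = model.predict_table(X)
    return Layer(stack.spec, "ensemble_suitability", vals)


def binarize(suitability: Layer, cutpoint: float) -> Layer:
    """Presence iff suitability >= cutpoint; nodata preserved."""
    vals = np.where(
        suitability.mask,
        (suitability.values >= cutpoint).astype(float),
        suitability.spec.nodata,
    )
    return Layer(suitability.spec, suitability.name + "_binary", vals)


def variable_contribution(
    model: EnsembleModel,
    X: pd.DataFrame,
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: 1 - mean Pearson r between ensemble
    predictions on the original table and on the table with one predictor's
    column permuted (``reps`` permutations).  Also reported normalized to
    sum 1.  Constant predictions give score 0 with a warning."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = model.predict_table(X)
    scores = {}
    for p in model.predictors:
        rs = []
        for _ in range(reps):
            Xp = X.copy()
            Xp[p] = rng.permutation(Xp[p].to_numpy())
            perm = model.predict_table(Xp)
            if np.std(base) == 0 or np.std(perm) == 0:
                warnings.warn(f"constant predictions while permuting {p!r}; score 0")
                rs.append(1.0)
            else:
                rs.append(np.corrcoef(base, perm)[0, 1])
        scores[p] = 1.0 - float(np.mean(rs))
    total = sum(scores.values())
    return pd.DataFrame(
        {
            "predictor": list(scores),
            "contribution": list(scores.values()),
            "contribution_normalized": [
                v / total if total > 0 else 0.0 for v in scores.values()
            ],
        }
    )


# ---------------------------------------------------------------------------
# High-level workflow


def presence_features(
    occ: OccurrenceSet, stack: EnvStack, predictors: list[str]
) -> pd.DataFrame:
    """Predictor table at presence points, nodata rows dropped."""
    sub = stack.subset(predictors)
    tab = extract_values(sub, [tuple(p) for p in occ.xy])
    tab = tab[tab["valid_flag"] == "ok"]
    return tab[predictors].reset_index(drop=True)


def fit_sdm(
    presences: OccurrenceSet,
    stack: EnvStack,
    predictors: list[str],
    area: CalibrationArea,
    config: EnsembleConfig | None = None,
    master_seed: int = 0,
) -> EnsembleModel:
    """Full workflow: profile -> PA replicates -> CV fold fits -> gated ensemble.

    Per pseudo-absence replicate and learner, a fresh background sample of
    the learner's size is drawn outside the presence envelope; each of the
    ``folds`` fold-fits is evaluated on its held-out fold, and all candidate
    fits across replicates and learners are gated together.
    """
    config = config or EnsembleConfig()
    pres_X = presence_features(presences, stack, predictors)
    if len(pres_X) < 5:
        raise ValueError("too few presences with valid environment")
    profile = fit_profile(pres_X, q=config.profile_q)
    presence_cells = presences.cell_set()
    seeds = replicate_seeds(master_seed, config.n_pa_replicates)

    fits: list[BaseFit] = []
    evals: list[EvalResult] = []
    hold_scores: list[np.ndarray] = []
    hold_labels: list[np.ndarray] = []
    for rep, rep_seed in enumerate(seeds):
        for li, learner in enumerate(config.learners):
            n_pa = config.pa_count(learner, len(pres_X))
            pa_set, _ = sample_pseudo_absences(
                stack.subset(predictors),
                area,
                profile,
                n=n_pa,
                exclude_cells=presence_cells,
                seed=rep_seed + li,
                species=presences.species,
            )
            pa_X = presence_features(pa_set, stack, predictors)
            X = pd.concat([pres_X, pa_X], ignore_index=True)
            y = np.concatenate([np.ones(len(pres_X), int), np.zeros(len(pa_X), int)])
            train, hX, hy = split_data(
                X,
                y,
                train_fraction=config.train_fraction,
                folds=config.folds,
                seed=rep_seed + 7919 * li,
                replicate_id=rep,
            )
            for fold_id in range(1, config.folds + 1):
                tX, ty, vX, vy = train.fold_split(fold_id)
                fit = fit_base(
                    learner,
                    tX,
                    ty,
                    config,
                    random_state=(rep_seed + 31 * li + fold_id) % (2**31),
                    replicate_id=rep,
                    fold_id=fold_id,
                )
                if fit.failed:
                    continue
                ev = evaluate_fit(fit, vX, vy)
                fits.append(fit)
                evals.append(ev)
                if ev.tss >= config.tss_min and ev.auroc > config.auc_min:
                    hold_scores.append(fit.predict(hX))
                    hold_labels.append(hy)
    # pooled holdout predictions of the (to-be-)retained fits set the cut point
    hs = np.concatenate(hold_scores) if hold_scores else None
    hl = np.concatenate(hold_labels) if hold_labels else None
    return build_ensemble(
        fits,
        evals,
        holdout_scores=hs,
        holdout_labels=hl,
        tss_min=config.tss_min,
        auc_min=config.auc_min,
        weight_metric=config.weight_metric,
    )
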