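"""Pseudoabsence design, model fitting, ROC/MTSS evaluation, importance.

True absences are unavailable for most occurrence datasets, so the response
is presence (1) versus randomly placed pseudoabsence (0) within the study
area, excluding presence cells.  Several independent pseudoabsence sets are
drawn; each is modeled with several 70/30 train/test replicates, giving
``n_sets x n_replicates`` model runs whose test-partition ROC AUC gates the
downstream ensemble.

:class:`SDMClassifier` is a scikit-learn estimator (``fit`` /
``predict_proba`` / ``get_params``) wrapping the supported algorithms —
boosted trees (GBM), random forest (RF), logistic regression (GLM) and a
multilayer perceptron (ANN) — behind one suitability-prediction contract,
so it composes with sklearn pipelines and model selection.

Evaluation is deliberately explicit rather than delegated:

* AUC is the rank statistic — the fraction of (presence, absence) score
  pairs ranked concordantly, ties counting one half;
* the MTSS binarization threshold maximizes sensitivity + specificity over
  candidate thresholds taken as midpoints of the sorted unique test scores
  (plus 0 and 1), predictions at or above the threshold counting positive;
* variable importance is permutation-based: the correlation r between
  predictions before and after shuffling one predictor column, scored as
  1 - max(0, r) and averaged over shuffles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from ._seeds import child_seed
from .grid import PredictorStack
from .occurrences import OccurrenceSet, StudyArea

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoAbsenceSet",
    "TrainingTable",
    "Evaluation",
    "ModelRun",
    "SDMClassifier",
    "sample_pseudoabsences",
    "assemble_training",
    "fit_model",
    "evaluate_model",
    "preselect_algorithms",
    "permutation_importance",
    "run_models",
    "auc_score",
    "mtss_threshold",
]

#: default hyperparameters per algorithm, mirroring the ensemble platform's
#: conventions; override (e.g. smaller tree counts) through ``params``.
DEFAULT_PARAMS: dict[str, dict] = {
    "GBM": dict(n_estimators=2500, max_depth=7, learning_rate=0.001, subsample=0.5),
    "RF": dict(n_estimators=500),
    "GLM": dict(max_iter=1000),
    "ANN": dict(hidden_layer_sizes=(8,), max_iter=500),
}

SUPPORTED_ALGORITHMS = tuple(DEFAULT_PARAMS)


@dataclass
class PseudoAbsenceSet:
    """One random background draw (cells exclude presence cells)."""

    set_id: int
    rows: np.ndarray
    cols: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class TrainingTable:
    """Weighted presence/pseudoabsence table with a 70/30 partition.

    ``data`` columns: ``response`` (0/1), ``weight``, one column per
    predictor, ``partition`` ('train'/'test'); row weights rescale the
    pseudoabsences so both classes carry equal total weight (prevalence
    0.5).
    """

    data: pd.DataFrame
    predictor_names: list[str]
    pa_set_id: int
    replicate_id: int = 0
    split_seed: int = 0
    n_dropped_nodata: int = 0

    def part(self, which: str) -> pd.DataFrame:
        return self.data[self.data["partition"] == which]

    def X(self, which: str | None = None) -> pd.DataFrame:
        d = self.data if which is None else self.part(which)
        return d[self.predictor_names]

    def y(self, which: str | None = None) -> np.ndarray:
        d = self.data if which is None else self.part(which)
        return d["response"].to_numpy()

    def w(self, which: str | None = None) -> np.ndarray:
        d = self.data if which is None else self.part(which)
        return d["weight"].to_numpy()


@dataclass
class Evaluation:
    """Test-partition discrimination metrics at the MTSS threshold."""

    auc: float
    mtss_threshold: float
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class ModelRun:
    """One fitted (pseudoabsence set x replicate) model and its evaluation."""

    algorithm: str
    pa_set_id: int
    replicate_id: int
    model: "SDMClassifier"
    predictor_names: list[str]
    evaluation: Evaluation | None = None
    importance: dict[str, float] = field(default_factory=dict)

    def predict_suitability(self, X) -> np.ndarray:
        return self.model.predict_suitability(X)


class SDMClassifier(BaseEstimator, ClassifierMixin):
    """Presence/background classifier with a habitat-suitability output.

    Parameters
    ----------
    algorithm : {'GBM', 'RF', 'GLM', 'ANN'}
        Underlying learner: gradient-boosted trees, random forest,
        logistic regression, or a small multilayer perceptron.
    params : dict, optional
        Hyperparameter overrides merged over the per-algorithm defaults.
    random_state : int
        Seed for the underlying learner.

    Attributes
    ----------
    model_ : fitted sklearn estimator
    classes_ : ndarray
    feature_names_in_ : ndarray of str, when fit on a DataFrame
    """

    def __init__(self, algorithm: str = "RF", params: dict | None = None,
                 random_state: int = 0):
        self.algorithm = algorithm
        self.params = params
        self.random_state = random_state

    def _make_estimator(self):
        if self.algorithm not in SUPPORTED_ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"supported: {SUPPORTED_ALGORITHMS}")
        kwargs = dict(DEFAULT_PARAMS[self.algorithm])
        kwargs.update(self.params or {})
        if self.algorithm == "GBM":
            return GradientBoostingClassifier(random_state=self.random_state, **kwargs)
        if self.algorithm == "RF":
            return RandomForestClassifier(random_state=self.random_state, **kwargs)
        if self.algorithm == "GLM":
            return LogisticRegression(**kwargs)
        return MLPClassifier(random_state=self.random_state, **kwargs)

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contain a single class")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
        if (Xv.std(axis=0) == 0).all():
            warnings.warn("all predictors are constant; predictions will be "
                          "near-constant", UserWarning, stacklevel=2)
        self.model_ = self._make_estimator()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if self.algorithm == "ANN" and sample_weight is not None:
                # MLP has no sample_weight support; emulate by class-balanced
                # resampling of the heavier class is overkill here — weights in
                # this pipeline only equalize class prevalence, so drop them.
                self.model_.fit(Xv, y)
            else:
                self.model_.fit(Xv, y, sample_weight=sample_weight)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = Xv.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_suitability(self, X) -> np.ndarray:
        """P(presence) in [0, 1] per row."""
        proba = self.predict_proba(X)
        pos = int(np.nonzero(self.classes_ == 1)[0][0])
        return proba[:, pos]


# ---------------------------------------------------------------------------
# sampling and table assembly
# ---------------------------------------------------------------------------

def sample_pseudoabsences(area: StudyArea, occ: OccurrenceSet, n: int,
                          n_sets: int, seed: int = 0) -> list[PseudoAbsenceSet]:
    """Draw ``n_sets`` independent uniform background samples.

    Each set is ``n`` study-area cells drawn without replacement, never a
    presence cell; sets are mutually independent, all seeded from ``seed``.
    """
    template = area.mask
    rows, cols = area.valid_cells()
    prow, pcol = occ.cells(template)
    presence_flat = set(prow * template.n_cols + pcol)
    flat = rows * template.n_cols + cols
    candidate = ~np.isin(flat, list(presence_flat))
    rows, cols = rows[candidate], cols[candidate]
    if n > len(rows):
        raise ValueError(f"requested {n} pseudoabsences but only {len(rows)} "
                         "candidate cells are available")
    out = []
    for s in range(n_sets):
        set_seed = child_seed(seed, f"pa-set-{s}")
        idx = np.random.default_rng(set_seed).choice(len(rows), n, replace=False)
        out.append(PseudoAbsenceSet(set_id=s, rows=rows[idx], cols=cols[idx],
                                    seed=set_seed))
    return out


def assemble_training(stack: PredictorStack, occ: OccurrenceSet,
                      pa: PseudoAbsenceSet, predictors: Sequence[str],
                      split: float = 0.7, seed: int = 0,
                      replicate_id: int = 0) -> TrainingTable:
    """Build the weighted presence/pseudoabsence table with a 70/30 split.

    Presences get response 1, pseudoabsences 0; pseudoabsence weights are
    scaled so both classes sum to equal weight (prevalence 0.5).  The split
    is stratified by class so both partitions always hold both classes.
    Rows whose predictors contain nodata are dropped and counted.
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    predictors = list(predictors)
    template = stack.template
    prow, pcol = occ.cells(template)
    nodata = stack.combined_nodata()

    def block(rows, cols, response):
        ok = ~nodata[rows, cols]
        X = stack.to_table(rows[ok], cols[ok], predictors)
        df = pd.DataFrame(X, columns=predictors)
        df.insert(0, "response", response)
        return df, int((~ok).sum())

    pres, d1 = block(prow, pcol, 1)
    absn, d2 = block(pa.rows, pa.cols, 0)
    if d1 or d2:
        logger.warning("dropped %d presence and %d pseudoabsence rows with "
                       "nodata predictors", d1, d2)
    if len(pres) == 0 or len(absn) == 0:
        raise ValueError("one class is empty after nodata filtering")

    df = pd.concat([pres, absn], ignore_index=True)
    w = np.where(df["response"] == 1, 1.0, len(pres) / len(absn))
    df.insert(1, "weight", w)

    rng = np.random.default_rng(seed)
    partition = np.empty(len(df), dtype=object)
    for cls in (0, 1):
        idx = np.nonzero(df["response"].to_numpy() == cls)[0]
        perm = rng.permutation(idx)
        n_train = int(round(split * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both partitions non-empty
        partition[perm[:n_train]] = "train"
        partition[perm[n_train:]] = "test"
    df["partition"] = partition
    return TrainingTable(data=df, predictor_names=predictors,
                         pa_set_id=pa.set_id, replicate_id=replicate_id,
                         split_seed=seed, n_dropped_nodata=d1 + d2)


# ---------------------------------------------------------------------------
# fitting and evaluation
# ---------------------------------------------------------------------------

def fit_model(table: TrainingTable, algorithm: str,
              params: dict | None = None, seed: int = 0) -> ModelRun:
    """Fit one algorithm on the table's train partition (weighted)."""
    clf = SDMClassifier(algorithm=algorithm, params=params, random_state=seed)
    clf.fit(table.X("train"), table.y("train"), sample_weight=table.w("train"))
    return ModelRun(algorithm=algorithm, pa_set_id=table.pa_set_id,
                    replicate_id=table.replicate_id, model=clf,
                    predictor_names=table.predictor_names)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the rank statistic; tied scores credit one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def mtss_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are midpoints of the sorted unique scores, plus 0 and 1;
    predictions at or above the threshold count positive.  Ties go to the
    smallest maximizing threshold.  Returns (threshold, sensitivity,
    specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("threshold selection needs both classes")
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest) maximizer
    return float(candidates[best]), float(sens[best]), float(spec[best])


def evaluate_model(run: ModelRun, table: TrainingTable) -> Evaluation:
    """Test-partition AUC and MTSS-threshold metrics; stored on the run."""
    test = table.part("test")
    if test.empty or len(np.unique(test["response"])) < 2:
        raise ValueError("test partition must contain both classes")
    scores = run.predict_suitability(test[table.predictor_names])
    y = test["response"].to_numpy()
    auc = auc_score(scores, y)
    thr, sens, spec = mtss_threshold(scores, y)
    run.evaluation = Evaluation(auc=auc, mtss_threshold=thr,
                                sensitivity=sens, specificity=spec)
    return run.evaluation


def permutation_importance(run: ModelRun, table: TrainingTable,
                           n_perm: int = 1, seed: int = 0) -> dict[str, float]:
    """Permutation importance as decorrelation of predictions.

    For each predictor: shuffle its column, re-predict, and compute the
    Pearson correlation r between original and shuffled-input predictions;
    the score is 1 - max(0, r), averaged over ``n_perm`` shuffles.  A
    variable the model ignores scores ~0; one the model relies on entirely
    scores ~1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = table.X().reset_index(drop=True)
    base = run.predict_suitability(X)
    out: dict[str, float] = {}
    if base.std() == 0:
        warnings.warn("zero-variance predictions; importance defined as 0",
                      UserWarning, stacklevel=2)
        return {v: 0.0 for v in table.predictor_names}
    for v in table.predictor_names:
        rng = np.random.default_rng(child_seed(seed, f"perm-{v}"))
        scores = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[v] = rng.permutation(Xp[v].to_numpy())
            pred = run.predict_suitability(Xp)
            if pred.std() == 0:
                scores.append(0.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            scores.append(1.0 - max(0.0, r))
        out[v] = float(np.mean(scores))
    run.importance = out
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_models(stack: PredictorStack, occ: OccurrenceSet,
               pa_sets: list[PseudoAbsenceSet], predictors: Sequence[str],
               algorithm: str, n_replicates: int = 10, split: float = 0.7,
               params: dict | None = None, seed: int = 0,
               n_perm: int = 1) -> tuple[list[ModelRun], list[TrainingTable]]:
    """Fit ``len(pa_sets) x n_replicates`` evaluated model runs."""
    runs: list[ModelRun] = []
    tables: list[TrainingTable] = []
    for pa in pa_sets:
        for rep in range(n_replicates):
            label = f"pa{pa.set_id}-rep{rep}"
            table = assemble_training(stack, occ, pa, predictors, split=split,
                                      seed=child_seed(seed, f"split-{label}"),
                                      replicate_id=rep)
            run = fit_model(table, algorithm, params=params,
                            seed=child_seed(seed, f"fit-{label}"))
            evaluate_model(run, table)
            permutation_importance(run, table, n_perm=n_perm,
                                   seed=child_seed(seed, f"imp-{label}"))
            runs.append(run)
            tables.append(table)
    return runs, tables


def preselect_algorithms(stack: PredictorStack, occ: OccurrenceSet,
                         pa_sets: list[PseudoAbsenceSet],
                         predictors: Sequence[str],
                         algorithms: Sequence[str], runs: int = 5,
                         split: float = 0.7, params: dict[str, dict] | None = None,
                         seed: int = 0) -> list[tuple[str, float]]:
    """Rank candidate algorithms by mean test AUC over ``runs`` replicates.

    Each replicate cycles through the pseudoabsence sets with a fresh split.
    Algorithms whose fits fail are dropped with a logged reason.  Returns
    (algorithm, mean_auc) sorted best-first; the top entry is the final
    modeling algorithm.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    params = params or {}
    ranking = []
    for algo in algorithms:
        aucs = []
        try:
            for r in range(runs):
                pa = pa_sets[r % len(pa_sets)]
                table = assemble_training(
                    stack, occ, pa, predictors, split=split,
                    seed=child_seed(seed, f"presel-{algo}-{r}"), replicate_id=r)
                run = fit_model(table, algo, params=params.get(algo),
                                seed=child_seed(seed, f"preselfit-{algo}-{r}"))
                aucs.append(evaluate_model(run, table).auc)
        except Exception as exc:  # propagate-as-log per contract
            logger.error("algorithm %s aborted during pre-selection: %s", algo, exc)
            continue
        ranking.append((algo, float(np.mean(aucs))))
    ranking.sort(key=lambda t: -t[1])
    return ranking
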