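"""Random under-sampling ensemble: training, probability fusion, cutoff rule.

The predictor is a fusion of one classifier per (composition scheme,
balanced subset) pair — with the default five schemes and ten subsets,
50 members.  Each member is trained on a 1:1 balanced subset of the
benchmark data, with its own min-max normalizer and hyperparameters
selected by repeated 5-fold cross-validated grid search (median of the
per-repeat winners).  A peptide's ensemble score Y is the unweighted
mean of all member probabilities; the call is positive when Y >= the
fusion cutoff, itself chosen by scanning 0.00-1.00 in 0.01 steps for
maximal MCC on out-of-fold benchmark scores.  The published predictor
fixed this cutoff at 0.45.

Three interchangeable backends are supported: random forest (RF),
extremely randomized trees (ERT) and an RBF-kernel SVM with calibrated
probabilities.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .dataset_prep import BalancedSubset, make_balanced_subsets
from .encoders import (ALL_SCHEMES, NormalizationStats, apply_normalizer,
                       encode_matrix, fit_normalizer)
from .evaluation import labels_to_binary
from .io_core import LABEL_NONPIP, LABEL_PIP, PeptideDataset, PipelError

logger = logging.getLogger("pipel")

DEFAULT_CUTOFF = 0.45  # published fusion cutoff

BACKEND_RF = "RF"
BACKEND_ERT = "ERT"
BACKEND_SVM = "SVM"

# ntree / mtry / nsplit analogues; conventional candidate values.  For the
# categorical mtry rule the list order encodes the "less complex first"
# tie-break preference.
DEFAULT_TREE_GRID = {
    "n_estimators": [100, 200, 500],
    "max_features": ["sqrt", "log2", 1.0 / 3.0],
    "min_samples_split": [2, 5, 10],
}
DEFAULT_SVM_GRID = {
    "C": [2.0 ** e for e in range(-15, 11)],
    "gamma": [2.0 ** e for e in range(-10, 11)],
}


class TrainingError(PipelError):
    pass


@dataclass(frozen=True)
class BackendSpec:
    algorithm: str = BACKEND_RF
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in (BACKEND_RF, BACKEND_ERT, BACKEND_SVM):
            raise ValueError(f"unknown backend {self.algorithm!r}")
        if not self.grid:
            default = DEFAULT_SVM_GRID if self.algorithm == BACKEND_SVM else DEFAULT_TREE_GRID
            object.__setattr__(self, "grid", {k: list(v) for k, v in default.items()})
        for name, cands in self.grid.items():
            if not cands:
                raise ValueError(f"empty candidate list for parameter {name!r}")


def make_estimator(backend: BackendSpec, params: dict, seed: int):
    if backend.algorithm == BACKEND_RF:
        return RandomForestClassifier(random_state=seed, **params)
    if backend.algorithm == BACKEND_ERT:
        return ExtraTreesClassifier(random_state=seed, **params)
    return SVC(kernel="rbf", probability=True, random_state=seed, **params)


@dataclass
class Member:
    composition: str
    subset_id: int
    estimator: object
    normalizer: NormalizationStats
    params: dict

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        Xn = apply_normalizer(self.normalizer, X)
        proba = self.estimator.predict_proba(Xn)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


@dataclass(frozen=True)
class Prediction:
    peptide_id: str
    score: float
    call: str

    def __post_init__(self) -> None:
        expected = LABEL_PIP if self.score >= self._cutoff else LABEL_NONPIP
        if self.call != expected:
            raise ValueError("call inconsistent with score and cutoff")

    # cutoff injected at construction via make(); stored for the invariant
    _cutoff: float = DEFAULT_CUTOFF

    @classmethod
    def make(cls, peptide_id: str, score: float, cutoff: float) -> "Prediction":
        call = LABEL_PIP if score >= cutoff else LABEL_NONPIP
        return cls(peptide_id, float(score), call, cutoff)


# --------------------------------------------------------------------------
# hyperparameter tuning
# --------------------------------------------------------------------------

def _grid_combinations(grid: dict) -> list[dict]:
    combos: list[dict] = [{}]
    for name, cands in grid.items():
        combos = [{**c, name: v} for c in combos for v in cands]
    return combos


def _lower_median(values: Sequence[float]) -> float:
    """Median with even-count ties resolved toward the smaller value."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _mode_first(values: Sequence, candidates: Sequence):
    """Most frequent value; ties broken by earliest position in the
    grid's candidate list (the less complex option by convention)."""
    counts = Counter(values)
    best = max(counts.values())
    for cand in candidates:
        if counts.get(cand, 0) == best:
            return cand
    raise RuntimeError("mode not among candidates")


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    backend: BackendSpec,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated cross-validated grid search; element-wise median winner.

    For each repeat, every grid combination is scored by mean stratified
    k-fold CV MCC and the best is recorded; the returned parameters take,
    per numeric parameter, the (lower) median over repeats and, per
    categorical parameter, the mode with ties toward the candidate listed
    first.  A singleton grid is returned immediately.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("cannot tune on single-class labels")
    combos = _grid_combinations(backend.grid)
    if len(combos) == 1:
        return dict(combos[0])

    X = np.asarray(X, dtype=float)
    winners: list[dict] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        splits = list(skf.split(X, y))
        best_score, best_combo = -np.inf, None
        for combo in combos:
            fold_scores = []
            for train_idx, test_idx in splits:
                est = make_estimator(backend, combo, seed=seed + r)
                est.fit(X[train_idx], y[train_idx])
                fold_scores.append(matthews_corrcoef(y[test_idx], est.predict(X[test_idx])))
            score = float(np.mean(fold_scores))
            if score > best_score:
                best_score, best_combo = score, combo
        winners.append(best_combo)

    selected: dict = {}
    for name, cands in backend.grid.items():
        picked = [w[name] for w in winners]
        if all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in cands):
            med = _lower_median(picked)
            selected[name] = type(cands[0])(med) if med in cands else med
        else:
            selected[name] = _mode_first(picked, cands)
    return selected


# --------------------------------------------------------------------------
# cutoff optimization
# --------------------------------------------------------------------------

def optimize_cutoff(scores: Sequence[float], y: Sequence[int]) -> float:
    """MCC-maximizing probability cutoff over 0.00-1.00 in 0.01 steps.

    Ties are broken toward the cutoff nearest 0.5, then the smaller one.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0,1]")
    if len(np.unique(y)) < 2:
        raise TrainingError("cutoff optimization needs both classes")
    cutoffs = np.round(np.arange(0, 101) * 0.01, 2)
    mccs = np.array([
        matthews_corrcoef(y, (scores >= c).astype(int)) for c in cutoffs
    ])
    best = mccs.max()
    tied = cutoffs[mccs >= best - 1e-12]
    order = sorted(tied, key=lambda c: (abs(c - 0.5), c))
    return float(order[0])


# --------------------------------------------------------------------------
# the ensemble
# --------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    members: list[Member]
    cutoff: float
    backend: BackendSpec
    compositions: tuple[str, ...]
    subsets: list[BalancedSubset]
    seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)

    def score_dataset(self, ds: PeptideDataset) -> tuple[np.ndarray, list[str]]:
        """Mean member probability per peptide.  Peptides failing an
        encoder precondition are dropped with a logged diagnostic; returns
        (scores, scored peptide ids)."""
        ok_peptides, ok_ids = [], []
        for p in ds:
            if len(p) < 2 and any(s in ("DPC", "HYBRID") for s in self.compositions):
                logger.warning("skipping %s: too short for DPC encoding", p.id)
                continue
            ok_peptides.append(p)
            ok_ids.append(p.id)
        if not ok_peptides:
            return np.zeros(0), []
        matrices = {s: encode_matrix(ok_peptides, s)[0] for s in self.compositions}
        probs = np.vstack([
            m.probabilities(matrices[m.composition]) for m in self.members
        ])
        return probs.mean(axis=0), ok_ids

    def predict(self, ds: PeptideDataset) -> list[Prediction]:
        scores, ids = self.score_dataset(ds)
        return [Prediction.make(pid, s, self.cutoff) for pid, s in zip(ids, scores)]


def _train_member(
    subset_ds: PeptideDataset,
    composition: str,
    subset_id: int,
    backend: BackendSpec,
    folds: int,
    repeats: int,
    seed: int,
) -> Member:
    X_raw, _ = encode_matrix(subset_ds.peptides, composition)
    y = labels_to_binary(subset_ds)
    normalizer = fit_normalizer(X_raw, composition)
    X = apply_normalizer(normalizer, X_raw)
    params = tune_hyperparameters(X, y, backend, folds=folds, repeats=repeats, seed=seed)
    est = make_estimator(backend, params, seed=seed)
    est.fit(X, y)
    return Member(composition, subset_id, est, normalizer, params)


def train_ensemble(
    benchmark: PeptideDataset,
    backend: BackendSpec | None = None,
    compositions: Sequence[str] = ALL_SCHEMES,
    k: int = 10,
    seed: int = 0,
    folds: int = 5,
    repeats: int = 10,
    cutoff: Optional[float] = None,
    oof_folds: int = 5,
) -> EnsembleModel:
    """Train the full under-sampling ensemble on a benchmark dataset.

    Builds k balanced subsets; for each (composition, subset) pair fits a
    normalizer, tunes hyperparameters and fits a member on the whole
    subset.  Unless ``cutoff`` is given explicitly, the fusion cutoff is
    optimized on out-of-fold ensemble scores: members score their own
    training peptides via ``oof_folds``-fold cross-val-predict and all
    other benchmark peptides directly.
    """
    backend = backend or BackendSpec()
    compositions = tuple(compositions)
    if not compositions:
        raise ValueError("at least one composition scheme required")
    subsets = make_balanced_subsets(benchmark, k=k, seed=seed)
    bench_ids = benchmark.ids()
    pos_of = {pid: i for i, pid in enumerate(bench_ids)}
    y_bench = labels_to_binary(benchmark)

    full_matrices = {s: encode_matrix(benchmark.peptides, s)[0] for s in compositions}

    members: list[Member] = []
    oof_scores = np.zeros((len(benchmark), 0))
    member_cols: list[np.ndarray] = []
    for ci, comp in enumerate(compositions):
        for subset in subsets:
            member_seed = seed + 1000 * ci + subset.subset_id
            sub_ds = benchmark.subset(subset.all_ids(), f"B{subset.subset_id}")
            member = _train_member(sub_ds, comp, subset.subset_id, backend,
                                   folds, repeats, member_seed)
            members.append(member)

            if cutoff is None:
                col = np.empty(len(benchmark))
                sub_idx = np.array([pos_of[pid] for pid in sub_ds.ids()])
                out_mask = np.ones(len(benchmark), dtype=bool)
                out_mask[sub_idx] = False
                # out-of-fold probabilities inside the training subset,
                # with per-fold normalization to avoid leakage
                pipe = Pipeline([
                    ("scale", MinMaxScaler(clip=True)),
                    ("clf", clone(member.estimator)),
                ])
                X_sub = full_matrices[comp][sub_idx]
                y_sub = y_bench[sub_idx]
                skf = StratifiedKFold(n_splits=oof_folds, shuffle=True,
                                      random_state=member_seed)
                proba = cross_val_predict(pipe, X_sub, y_sub, cv=skf,
                                          method="predict_proba")
                col[sub_idx] = proba[:, 1]
                if out_mask.any():
                    col[out_mask] = member.probabilities(full_matrices[comp][out_mask])
                member_cols.append(col)

    if cutoff is None:
        oof_scores = np.vstack(member_cols).mean(axis=0)
        cutoff = optimize_cutoff(oof_scores, y_bench)
        logger.info("optimized fusion cutoff: %.2f", cutoff)

    return EnsembleModel(members, float(cutoff), backend, compositions, subsets, seed)


def ensemble_oof_scores(model: EnsembleModel, benchmark: PeptideDataset,
                        oof_folds: int = 5) -> np.ndarray:
    """Recompute out-of-fold mean probabilities for a trained ensemble."""
    bench_ids = benchmark.ids()
    pos_of = {pid: i for i, pid in enumerate(bench_ids)}
    y_bench = labels_to_binary(benchmark)
    matrices = {s: encode_matrix(benchmark.peptides, s)[0] for s in model.compositions}
    cols = []
    subset_of = {s.subset_id: s for s in model.subsets}
    for member in model.members:
        subset = subset_of[member.subset_id]
        sub_idx = np.array([pos_of[pid] for pid in subset.all_ids()])
        out_mask = np.ones(len(benchmark), dtype=bool)
        out_mask[sub_idx] = False
        pipe = Pipeline([("scale", MinMaxScaler(clip=True)),
                         ("clf", clone(member.estimator))])
        skf = StratifiedKFold(n_splits=oof_folds, shuffle=True,
                              random_state=model.seed + member.subset_id)
        proba = cross_val_predict(pipe, matrices[member.composition][sub_idx],
                                  y_bench[sub_idx], cv=skf, method="predict_proba")
        col = np.empty(len(benchmark))
        col[sub_idx] = proba[:, 1]
        if out_mask.any():
            col[out_mask] = member.probabilities(matrices[member.composition][out_mask])
        cols.append(col)
    return np.vstack(cols).mean(axis=0)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_ensemble(model: EnsembleModel, path: str) -> None:
    joblib.dump({"format": "pipel-ensemble", "version": _ARCHIVE_VERSION,
                 "model": model}, path)


def load_ensemble(path: str) -> EnsembleModel:
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("format") != "pipel-ensemble":
        raise PipelError(f"{path} is not a serialized ensemble archive")
    if blob.get("version") != _ARCHIVE_VERSION:
        raise PipelError(f"unsupported archive version {blob.get('version')}")
    return blob["model"]


def predictions_to_tsv(preds: list[Prediction], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tscore\tcall\n")
        for p in preds:
            fh.write(f"{p.peptide_id}\t{p.score:.6f}\t{p.call}\n")
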