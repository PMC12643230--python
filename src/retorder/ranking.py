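"""Pairwise learning-to-rank of retention order.

A ranking SVM never sees absolute retention times. Training examples are
*pairs* of compounds from the same subset: the feature is the PCF difference
vector ``δ = x_a − x_b`` and the label is +1 when compound ``a`` elutes
before ``b`` ("correct" order under the storage convention) and −1 otherwise
("reverse"). The linear model solves

    minimize  ½‖w‖² + C · Σ hinge(1 − y ⟨w, δ⟩)

which is an intercept-free soft-margin SVM on difference vectors; the learned
score ``⟨w, x⟩`` acts as a surrogate elution coordinate, and
``sign(⟨w, x_a − x_b⟩)`` predicts the order of any pair. Antisymmetry
(``predict(a,b) = −predict(b,a)``) holds by construction because there is no
intercept; exact score ties resolve to +1 ("a before b").

Model selection uses leave-one-subset-out cross-validation over a C grid,
scored by held-out pairwise accuracy. A RandomForest RT-regression baseline
is included: it predicts absolute RTs and derives pair orders from them,
evaluated with the same harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVC

__all__ = [
    "PairSample",
    "PairSet",
    "RankingModel",
    "make_pairs",
    "train_ranksvm",
    "predict_order",
    "pairwise_accuracy",
    "pairwise_accuracy_items",
    "ConvergenceError",
    "cross_validate",
    "CVResult",
    "RFOrderBaseline",
    "rf_baseline",
]

# PCF scores of counting fingerprints carry variances of order 1e2-1e4, so
# difference vectors are large and useful soft-margin C values are small; the
# grid spans the regularization path from strongly to weakly regularized.
DEFAULT_C_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 0.1)


@dataclass(frozen=True)
class PairSample:
    """One labeled pair: delta = x_a − x_b, label +1 iff rt_a < rt_b."""

    delta: np.ndarray
    label: int
    ids: tuple[str, str]
    subset: str = ""

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"pair label must be ±1, got {self.label}")
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=float))


@dataclass
class PairSet:
    """Pairs generated from one subset plus the tie count dropped."""

    pairs: list[PairSample]
    n_ties: int = 0

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def make_pairs(
    items: Sequence[tuple[str, np.ndarray, float | None]],
    subset_label: str = "",
    min_delta_rt: float = 0.0,
) -> PairSet:
    """Enumerate all unordered within-subset pairs with order labels.

    ``items`` is a list of ``(id, pcf_vector, rt)``. Pairs are stored in
    canonical orientation ``id_a < id_b`` (lexicographic) and labeled +1 iff
    ``rt_a < rt_b``. Pairs with ``|rt_a − rt_b| <= min_delta_rt`` (exact ties
    at the default 0) carry no order information and are dropped and counted.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 compounds to form pairs")
    for iid, _, rt in items:
        if rt is None:
            raise ValueError(f"compound {iid!r} has no retention time")
    ordered = sorted(items, key=lambda t: t[0])
    out = PairSet(pairs=[])
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            id_a, x_a, rt_a = ordered[i]
            id_b, x_b, rt_b = ordered[j]
            if abs(rt_a - rt_b) <= min_delta_rt:
                out.n_ties += 1
                continue
            label = 1 if rt_a < rt_b else -1
            out.pairs.append(
                PairSample(
                    delta=np.asarray(x_a, float) - np.asarray(x_b, float),
                    label=label,
                    ids=(id_a, id_b),
                    subset=subset_label,
                )
            )
    return out


class ConvergenceError(RuntimeError):
    pass


@dataclass
class RankingModel:
    """Trained pairwise ranking function over PCF space."""

    kernel: str
    C: float
    weights: np.ndarray | None = None       # linear kernel
    _svc: SVC | None = None                 # rbf kernel (symmetrized dual form)
    cv_record: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        if self.kernel == "linear":
            return int(self.weights.shape[0])
        return int(self._svc.support_vectors_.shape[1])

    def decision(self, delta: np.ndarray) -> float:
        """Antisymmetric ranking score for a difference vector."""
        delta = np.asarray(delta, dtype=float)
        if delta.shape[-1] != self.n_features:
            raise ValueError(
                f"vector length {delta.shape[-1]} does not match model "
                f"dimension {self.n_features}"
            )
        if self.kernel == "linear":
            return float(self.weights @ delta)
        f = self._svc.decision_function
        return (f(delta.reshape(1, -1))[0] - f(-delta.reshape(1, -1))[0]) / 2.0

    def predict_order(self, pcf_a: np.ndarray, pcf_b: np.ndarray) -> int:
        """+1 if a is predicted to elute before b, else −1 (score tie → +1)."""
        score = self.decision(np.asarray(pcf_a, float) - np.asarray(pcf_b, float))
        return 1 if score >= 0 else -1

    def to_json(self, path: str | Path | None = None) -> str:
        if self.kernel != "linear":
            raise ValueError("only linear models serialize to JSON")
        payload = json.dumps(
            {"kernel": self.kernel, "C": self.C, "weights": self.weights.tolist()}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "RankingModel":
        text = str(source)
        if not text.lstrip().startswith("{"):  # a path, not JSON text
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            kernel=d["kernel"], C=float(d["C"]),
            weights=np.asarray(d["weights"], dtype=float),
        )


def _symmetrize(pairs: Sequence[PairSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([p.delta for p in pairs])
    y = np.array([p.label for p in pairs], dtype=int)
    return np.vstack([X, -X]), np.concatenate([y, -y])


def _fit_linear_primal(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    smoothing: float,
    max_iter: int,
    w0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize ½‖w‖² + C·Σ hinge(1 − y⟨w,δ⟩) in the primal with L-BFGS.

    The hinge is quadratically smoothed over a margin band of width
    ``smoothing`` (exact hinge in the limit smoothing → 0), which makes the
    objective differentiable and the deterministic quasi-Newton solve
    reliable at any C. The problem is solved in globally rescaled
    coordinates δ/s (s = median pair norm, C·s² compensating) — an exactly
    equivalent objective that conditions the quasi-Newton iteration.
    ``w0`` warm-starts the solve (e.g. from a smaller C on the same data).
    """
    scale = float(np.median(np.linalg.norm(X, axis=1))) or 1.0
    Z = (X / scale) * y[:, None]
    C_eff = C * scale * scale
    gamma = smoothing
    # Divide through by C_eff·n: the argmin is unchanged but the objective
    # and gradient are O(1) per pair, so the stopping tolerances are
    # meaningful at every C.
    norm = C_eff * Z.shape[0]

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        u = 1.0 - Z @ w  # margin shortfall per pair
        loss = np.where(u <= 0, 0.0, np.where(u >= gamma, u - gamma / 2, u**2 / (2 * gamma)))
        dz = np.where(u <= 0, 0.0, np.where(u >= gamma, -1.0, -u / gamma))
        value = (0.5 * (w @ w) + C_eff * float(loss.sum())) / norm
        grad = (w + C_eff * (Z.T @ dz)) / norm
        return value, grad

    start = np.zeros(X.shape[1]) if w0 is None else np.asarray(w0, float) * scale
    result = minimize(
        objective,
        start,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 2 * max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    # L-BFGS stops on ftol near flat optima; accept any stop whose per-pair
    # gradient is small, else surface diagnostics.
    grad_norm = float(np.max(np.abs(result.jac)))
    if not result.success and grad_norm > 1e-3:
        raise ConvergenceError(
            f"RankSVM primal solve did not converge (C={C}): {result.message}; "
            f"iterations={result.nit}, per-pair max|grad|={grad_norm:.3e}"
        )
    return result.x / scale


def train_ranksvm(
    pairs: Sequence[PairSample],
    C: float = 1.0,
    kernel: str = "linear",
    smoothing: float = 0.01,
    max_iter: int = 20_000,
    warm_start: np.ndarray | None = None,
) -> RankingModel:
    """Fit the soft-margin pairwise ranking SVM.

    The linear kernel is solved in the primal (intercept-free, so the decision
    function is exactly antisymmetric) with a quadratically smoothed hinge;
    see :func:`_fit_linear_primal`. The RBF kernel trains an SVC on the
    symmetrized pair set (each (δ, y) also contributing (−δ, −y)) with C
    halved to keep the objective equal to ½‖w‖² + C·Σ hinge over the original
    pairs, and predicts through the antisymmetrized score (f(δ) − f(−δ))/2.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no training pairs")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if kernel == "linear":
        X = np.vstack([p.delta for p in pairs])
        y = np.array([p.label for p in pairs], dtype=float)
        weights = _fit_linear_primal(X, y, C, smoothing, max_iter, w0=warm_start)
        return RankingModel(kernel="linear", C=C, weights=weights)
    if kernel == "rbf":
        X, y = _symmetrize(pairs)
        svc = SVC(C=C / 2.0, kernel="rbf", random_state=0)
        svc.fit(X, y)
        return RankingModel(kernel="rbf", C=C, _svc=svc)
    raise ValueError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")


def predict_order(model: RankingModel, pcf_a: np.ndarray, pcf_b: np.ndarray) -> int:
    """Functional alias for :meth:`RankingModel.predict_order`."""
    return model.predict_order(pcf_a, pcf_b)


def pairwise_accuracy(model: RankingModel, pairs: Sequence[PairSample]) -> float:
    """Fraction of pairs whose predicted order matches the label."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to score")
    labels = np.array([p.label for p in pairs])
    if model.kernel == "linear":
        scores = np.vstack([p.delta for p in pairs]) @ model.weights
    else:
        scores = np.array([model.decision(p.delta) for p in pairs])
    predicted = np.where(scores >= 0, 1, -1)
    return float(np.mean(predicted == labels))


def pairwise_accuracy_items(
    order_model,
    items: Sequence[tuple[str, np.ndarray, float]],
    min_delta_rt: float = 0.0,
) -> float:
    """Pairwise accuracy of any order predictor on raw (id, x, rt) items.

    Enumerates the same canonical non-tied pairs as :func:`make_pairs` and
    scores ``order_model.predict_order(x_a, x_b)`` against the measured RT
    order — a shared harness for the ranking SVM and the RF baseline.
    """
    ordered = sorted(items, key=lambda t: t[0])
    # Batch the expensive model calls: RT regressors predict all compounds
    # once; difference-vector models get one matrix product per compound.
    if hasattr(order_model, "predict_rt"):
        pred = order_model.predict_rt(np.vstack([x for _, x, _ in ordered]))

        def predicted(i: int, j: int) -> int:
            return 1 if pred[i] <= pred[j] else -1

    else:

        def predicted(i: int, j: int) -> int:
            return order_model.predict_order(ordered[i][1], ordered[j][1])

    total = correct = 0
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            rt_a, rt_b = ordered[i][2], ordered[j][2]
            if abs(rt_a - rt_b) <= min_delta_rt:
                continue
            truth = 1 if rt_a < rt_b else -1
            total += 1
            if predicted(i, j) == truth:
                correct += 1
    if total == 0:
        raise ValueError("no non-tied pairs to score")
    return correct / total


@dataclass
class CVResult:
    model: RankingModel
    best_C: float
    table: pd.DataFrame  # columns: C, fold, n_train_pairs, n_test_pairs, accuracy

    @property
    def best_mean_accuracy(self) -> float:
        means = self.table.groupby("C")["accuracy"].mean()
        return float(means.loc[self.best_C])


def cross_validate(
    subset_pairs: Sequence[PairSet | Sequence[PairSample]],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    kernel: str = "linear",
    shared_pairs: Sequence[PairSample] = (),
) -> CVResult:
    """Leave-one-subset-out CV over a C grid; refit on everything at best C.

    ``shared_pairs`` (e.g. reference-panel pairs) are added to the training
    side of every fold but never scored. Ties in mean held-out accuracy go to
    the smallest C (strongest regularization).
    """
    folds = [list(ps) for ps in subset_pairs]
    if len(folds) < 2:
        raise ValueError("cross-validation needs at least 2 subsets")
    shared = list(shared_pairs)
    rows = []
    for i, heldout in enumerate(folds):
        train = [p for j, f in enumerate(folds) if j != i for p in f] + shared
        warm = None  # warm-start along the ascending C path within a fold
        for C in sorted(C_grid):
            model = train_ranksvm(train, C=C, kernel=kernel, warm_start=warm)
            if kernel == "linear":
                warm = model.weights
            rows.append(
                {
                    "C": C,
                    "fold": i,
                    "n_train_pairs": len(train),
                    "n_test_pairs": len(heldout),
                    "accuracy": pairwise_accuracy(model, heldout),
                }
            )
    table = pd.DataFrame(rows)
    means = table.groupby("C")["accuracy"].mean()
    best_C = float(min(means.index[means == means.max()]))
    all_pairs = [p for f in folds for p in f] + shared
    final = train_ranksvm(all_pairs, C=best_C, kernel=kernel)
    final.cv_record = table
    return CVResult(model=final, best_C=best_C, table=table)


@dataclass
class RFOrderBaseline:
    """RT-regression forest exposed through the pairwise-order interface.

    Predicts absolute retention times and derives pair orders by comparing
    them, so it plugs into the same scoring harness as the ranking SVM
    (predicted-RT tie → +1, "a before b").
    """

    forest: RandomForestRegressor

    def predict_rt(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def decision(self, delta: np.ndarray) -> float:
        raise NotImplementedError(
            "the RF baseline scores compounds, not difference vectors"
        )

    def predict_order(self, pcf_a: np.ndarray, pcf_b: np.ndarray) -> int:
        rt_a = self.predict_rt(pcf_a)[0]
        rt_b = self.predict_rt(pcf_b)[0]
        return 1 if rt_a <= rt_b else -1


def rf_baseline(
    train_X: np.ndarray,
    train_rt: Sequence[float],
    n_trees: int = 500,
    seed: int = 0,
) -> RFOrderBaseline:
    """Fit the RandomForest RT-regression baseline on PCF features."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(train_X, np.asarray(train_rt, dtype=float))
    return RFOrderBaseline(forest=forest)
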