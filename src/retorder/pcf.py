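"""Principal component fingerprints (PCF): PCA over counting fingerprints.

Counting fingerprints are highly multicollinear — many substructure slots
rise and fall together — which inflates the variance of any model fit on
them. The remedy used here is covariance PCA: constant slots are dropped, the
remaining slots mean-centered, and the eigenvectors of the covariance matrix
define a linear map into decorrelated "principal component fingerprint"
scores. The transform fitted on training data is *reused verbatim* on any
test data; it is never refit, so train and test live in the same coordinate
system.

The module also provides the variance inflation factor (VIF) diagnostic
(``VIF_j = 1/(1 - R²_j)`` from regressing slot j on all other slots), the
filter-style component selection (keep the top-k components by explained
variance) and loading inspection for connecting components back to
substructure patterns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PCFTransform",
    "fit_pcf",
    "apply_pcf",
    "vif",
    "select_components",
    "top_loadings",
]


@dataclass(frozen=True)
class PCFTransform:
    """Fitted centering vector + orthonormal component matrix.

    ``components`` has one row per component (ordered by decreasing explained
    variance) over the ``kept_features`` columns of the input space. The sign
    of each row is fixed so its largest-|loading| entry is positive, making
    scores reproducible across linear-algebra backends.
    """

    center: np.ndarray            # mean over kept features
    components: np.ndarray        # (n_components, n_kept)
    explained_variance: np.ndarray
    n_features_in: int
    kept_features: np.ndarray     # indices of non-constant input slots

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Project fingerprints into PCF scores; never refits."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in:
            raise ValueError(
                f"fingerprint length {X.shape[1]} does not match the "
                f"transform's expected length {self.n_features_in}"
            )
        return (X[:, self.kept_features] - self.center) @ self.components.T

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "center": self.center.tolist(),
                "components": self.components.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "n_features_in": self.n_features_in,
                "kept_features": self.kept_features.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "PCFTransform":
        text = str(source)
        if not text.lstrip().startswith("{"):  # a path, not JSON text
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            center=np.asarray(d["center"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            n_features_in=int(d["n_features_in"]),
            kept_features=np.asarray(d["kept_features"], dtype=int),
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pcf(X: np.ndarray, n_components: int | None = None) -> PCFTransform:
    """Fit the PCF transform on a (n_samples, n_features) counting matrix.

    Zero-variance columns are removed (and recorded in ``kept_features``);
    the rest are mean-centered and decomposed. With ``n_components=None`` all
    ``min(n_samples - 1, n_kept)`` components are kept; use
    :func:`select_components` to truncate afterwards.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("fingerprint matrix contains non-finite values")
    variable = np.ptp(X, axis=0) > 0
    kept = np.flatnonzero(variable)
    if kept.size == 0:
        raise ValueError("no variance: every fingerprint column is constant")
    Xk = X[:, kept]
    max_rank = min(X.shape[0] - 1, kept.size)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(Xk)
    return PCFTransform(
        center=pca.mean_,
        components=_fix_signs(pca.components_),
        explained_variance=pca.explained_variance_.copy(),
        n_features_in=X.shape[1],
        kept_features=kept,
    )


def apply_pcf(transform: PCFTransform, X: np.ndarray) -> np.ndarray:
    """Project fingerprints with a fitted transform (see PCFTransform.apply)."""
    return transform.apply(X)


def vif(
    X: np.ndarray,
    max_features: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Variance inflation factor per column: ``1 / (1 - R²_j)``.

    ``R²_j`` comes from an intercept-included least-squares regression of
    column j on all other columns. Perfectly collinear columns get ``inf``.
    Exact VIF requires more samples than features; if that fails, a random
    column subsample of size ``max_features`` (default ``n_samples - 2``) is
    scored instead, with a warning, and columns outside the subsample get NaN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if (np.ptp(X, axis=0) == 0).any():
        raise ValueError("VIF is undefined for constant columns; remove them first")
    selected = np.arange(p)
    if n <= p:
        limit = max_features if max_features is not None else n - 2
        if limit < 2:
            raise ValueError(f"too few samples (n={n}) for a VIF estimate")
        warnings.warn(
            f"n_features={p} >= n_samples={n}: VIF computed on a random "
            f"subsample of {limit} columns",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        selected = np.sort(rng.choice(p, size=limit, replace=False))
    Xs = X[:, selected]
    out = np.full(p, np.nan)
    for pos, j in enumerate(selected):
        y = Xs[:, pos]
        others = np.delete(Xs, pos, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if 1.0 - r2 <= 1e-12 else 1.0 / (1.0 - r2)
    return out


def select_components(transform: PCFTransform, k: int) -> PCFTransform:
    """Filter-style truncation: keep the first k components by variance."""
    if not 1 <= k <= transform.n_components:
        raise ValueError(
            f"k must be in [1, {transform.n_components}], got {k}"
        )
    return PCFTransform(
        center=transform.center,
        components=transform.components[:k],
        explained_variance=transform.explained_variance[:k],
        n_features_in=transform.n_features_in,
        kept_features=transform.kept_features,
    )


def top_loadings(
    transform: PCFTransform,
    component_index: int,
    n: int,
    feature_labels: Sequence[str],
    restrict_to: slice | Sequence[int] | None = None,
) -> list[tuple[str, float]]:
    """Top-n features of one component by |loading|, ties by feature index.

    ``restrict_to`` limits the ranking to a slice of the input feature space
    (e.g. the MACCS block of a MIX fingerprint, whose SMARTS labels are the
    interpretable ones).
    """
    if not 0 <= component_index < transform.n_components:
        raise ValueError(
            f"component {component_index} out of range "
            f"[0, {transform.n_components})"
        )
    if len(feature_labels) != transform.n_features_in:
        raise ValueError(
            f"{len(feature_labels)} labels for {transform.n_features_in} features"
        )
    full = np.zeros(transform.n_features_in)
    full[transform.kept_features] = transform.components[component_index]
    if restrict_to is None:
        indices = np.arange(transform.n_features_in)
    elif isinstance(restrict_to, slice):
        indices = np.arange(transform.n_features_in)[restrict_to]
    else:
        indices = np.asarray(restrict_to, dtype=int)
    order = sorted(indices, key=lambda j: (-abs(full[j]), j))
    return [(feature_labels[j], float(full[j])) for j in order[:n]]
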