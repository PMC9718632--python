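"""Multivariate key-component screening: PCA and PLS-DA with VIP scores.

PCA is run on the correlation matrix of the batches-by-peaks area matrix
(the factor-analysis convention: loadings are eigenvector * sqrt(eigenvalue)
and lie in [-1, 1]); with n batches and p >> n peaks at most n - 1
eigenvalues are nonzero, so the cumulative variance contribution reaches
100% after n - 1 components.

PLS-DA is fitted by NIPALS with a centered dummy-coded class response.
Variable importance in projection,

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ),

with unit-norm weight vectors w_a and SS_a the response sum of squares
explained by component a, satisfies mean(VIP^2) = 1; variables with
VIP > 1 are conventionally screened as key components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "PLSModel",
    "ConvergenceError",
    "pca",
    "scree_table",
    "nipals_plsda",
    "vip",
    "screen_key_components",
]

#: eigenvalues below this fraction of the trace count as zero
EIGENVALUE_REL_TOL = 1e-10


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # descending
    contribution_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: np.ndarray  # variables x components, eigenvector * sqrt(eigenvalue)
    scores: np.ndarray  # samples x components
    mode: str

    @property
    def n_nonzero(self) -> int:
        tol = EIGENVALUE_REL_TOL * float(np.sum(self.eigenvalues))
        return int(np.sum(self.eigenvalues > tol))


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance column(s) {bad}")
    return (X - mean) / sd


def pca(X, mode: str = "correlation") -> PCAResult:
    """Eigendecomposition of the correlation (or covariance) matrix of ``X``.

    ``X`` is samples x variables with at least 2 samples.  Components are
    ordered by descending eigenvalue; tiny negative eigenvalues from
    round-off are clipped to zero.  Eigenvector signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with n >= 2 samples and p >= 1 variables")
    if mode == "correlation":
        Z = _standardize(X)
        C = (Z.T @ Z) / (X.shape[0] - 1)
    elif mode == "covariance":
        Z = X - X.mean(axis=0)
        C = np.cov(X, rowvar=False, ddof=1)
        C = np.atleast_2d(C)
    else:
        raise ValueError(f"mode must be 'correlation' or 'covariance', got {mode!r}")

    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest |loading| per component positive
    flips = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flips[flips == 0] = 1.0
    eigvec = eigvec * flips

    total = float(np.sum(eigval))
    contribution = 100.0 * eigval / total
    loadings = eigvec * np.sqrt(eigval)
    scores = Z @ eigvec
    return PCAResult(
        eigenvalues=eigval,
        contribution_pct=contribution,
        cumulative_pct=np.cumsum(contribution),
        loadings=loadings,
        scores=scores,
        mode=mode,
    )


def scree_table(result: PCAResult) -> pd.DataFrame:
    """Scree data: component index, eigenvalue, contribution, cumulative %."""
    k = result.eigenvalues.size
    return pd.DataFrame(
        {
            "component": np.arange(1, k + 1),
            "eigenvalue": result.eigenvalues,
            "contribution_pct": result.contribution_pct,
            "cumulative_pct": result.cumulative_pct,
        }
    )


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    weights: np.ndarray  # variables x components, unit-norm columns
    x_scores: np.ndarray  # samples x components
    x_loadings: np.ndarray  # variables x components
    y_loadings: np.ndarray  # classes x components
    ss_y: np.ndarray  # explained response sum of squares per component
    classes: tuple

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]


def _dummy_code(y) -> tuple[np.ndarray, tuple]:
    labels = list(y)
    classes = tuple(sorted(set(labels), key=repr))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y - Y.mean(axis=0), classes


def nipals_plsda(
    X,
    y,
    n_components: int = 2,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> PLSModel:
    """Fit PLS-DA by NIPALS on column-standardized X and centered dummy Y.

    Components are extracted sequentially with X deflation; weight
    vectors are stored with unit norm.  Raises :class:`ConvergenceError`
    (reporting the component index) if the weight vector has not
    stabilized after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Y, classes = _dummy_code(y)
    if Y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")

    Xd = _standardize(X)
    Yd = Y.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((len(classes), n_components))
    ss = np.zeros(n_components)

    for a in range(n_components):
        u = Yd[:, int(np.argmax(np.sum(Yd**2, axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ConvergenceError(f"component {a + 1}: degenerate weight vector")
            w_new /= norm
            t = Xd @ w_new
            tt = float(t @ t)
            if tt == 0:
                raise ConvergenceError(f"component {a + 1}: zero score vector")
            q = Yd.T @ t / tt
            qq = float(q @ q)
            u = Yd @ q / qq if qq > 0 else t
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise ConvergenceError(
                f"component {a + 1}: NIPALS did not converge in {max_iter} iterations"
            )
        t = Xd @ w
        tt = float(t @ t)
        p_a = Xd.T @ t / tt
        q_a = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p_a)
        Yd = Yd - np.outer(t, q_a)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_a, q_a
        ss[a] = tt * float(q_a @ q_a)  # response SS explained by component a

    return PLSModel(
        n_components=n_components,
        weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        ss_y=ss,
        classes=classes,
    )


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection, one score per variable."""
    total = float(np.sum(model.ss_y))
    if total <= 0:
        raise ValueError("degenerate model: no explained response variance")
    p = model.n_variables
    weighted = (model.weights**2) @ model.ss_y
    return np.sqrt(p * weighted / total)


def screen_key_components(
    vip_scores, peak_ids=None, threshold: float = 1.0
) -> list[tuple[int, float]]:
    """Peak ids with VIP strictly above ``threshold``, sorted by descending VIP."""
    v = np.asarray(vip_scores, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("VIP scores must be finite")
    ids = list(peak_ids) if peak_ids is not None else list(range(1, v.size + 1))
    if len(ids) != v.size:
        raise ValueError("peak_ids length mismatch")
    hits = [(ids[j], float(v[j])) for j in np.flatnonzero(v > threshold)]
    return sorted(hits, key=lambda kv: -kv[1])
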