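"""Two-block partial least squares, RV coefficient and permutation tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PLSError(ValueError):
    pass


def _as_matrix(block) -> np.ndarray:
    X = np.asarray(block, dtype=float)
    if X.ndim == 3:  # (n, k, 3) configurations
        X = X.reshape(len(X), -1)
    if X.ndim != 2:
        raise PLSError("block must be an (n, p) matrix or (n, k, 3) array")
    return X


@dataclass
class PLSResult:
    """Paired singular axes of the between-block cross-covariance."""

    u: np.ndarray                # (p1, r) block-1 singular vectors (columns)
    v: np.ndarray                # (p2, r)
    singular_values: np.ndarray  # (r,)
    scores1: np.ndarray          # (n, r)
    scores2: np.ndarray          # (n, r)
    correlations: np.ndarray     # (r,)
    pct_covariance: np.ndarray   # (r,) percentages summing to 100
    rv: float                    # RV over full centered blocks
    rv_axes: float | None = None     # RV over a leading-axes score truncation
    p_values: dict = field(default_factory=dict)

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def rv_coefficient(X, Y) -> float:
    """Escoufier's RV between column-centered matrices; in [0, 1]."""
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if len(X) != len(Y):
        raise PLSError("blocks must have the same number of rows")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = float(np.sum((Xc.T @ Xc) ** 2))
    syy = float(np.sum((Yc.T @ Yc) ** 2))
    if sxx <= 0 or syy <= 0:
        raise PLSError("zero-variance block: RV undefined")
    sxy = Xc.T @ Yc
    num = float(np.sum(sxy * sxy))  # tr(S_XY S_YX)
    return num / np.sqrt(sxx * syy)


def two_block_pls(block1, block2, n_axes: int | None = None,
                  rv_axes: int | None = None) -> PLSResult:
    """SVD of the between-block cross-covariance of centered data.

    Axis signs are fixed so each block-1 vector's largest-magnitude loading
    is positive. ``rv_axes`` additionally reports RV over score matrices
    truncated to that many leading axes.
    """
    X = _as_matrix(block1)
    Y = _as_matrix(block2)
    n = len(X)
    if len(Y) != n:
        raise PLSError("blocks must cover the same specimens")
    if n < 3:
        raise PLSError("need at least 3 specimens")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    C = Xc.T @ Yc / (n - 1)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    r = int(np.sum(s > 1e-12 * (s[0] if len(s) else 1.0)))
    if n_axes is not None:
        r = min(r, n_axes)
    U, s, V = U[:, :r], s[:r], Vt[:r].T
    # deterministic sign convention
    for j in range(r):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    S1 = Xc @ U
    S2 = Yc @ V
    corr = np.empty(r)
    for j in range(r):
        s1, s2 = S1[:, j], S2[:, j]
        denom = np.linalg.norm(s1 - s1.mean()) * np.linalg.norm(s2 - s2.mean())
        corr[j] = float((s1 - s1.mean()) @ (s2 - s2.mean()) / denom) if denom > 0 else 0.0
    total_sq = float(np.sum(np.linalg.svd(C, compute_uv=False) ** 2))
    pct = 100.0 * s ** 2 / total_sq if total_sq > 0 else np.zeros(r)
    rv = rv_coefficient(Xc, Yc)
    rv_ax = rv_coefficient(S1[:, :rv_axes], S2[:, :rv_axes]) if rv_axes else None
    return PLSResult(
        u=U, v=V, singular_values=s, scores1=S1, scores2=S2,
        correlations=corr, pct_covariance=pct, rv=rv, rv_axes=rv_ax,
    )


def pls_permutation_test(block1, block2, n_perm: int = 1000, seed: int = 0,
                         n_axes: int | None = None,
                         per_axis: str = "singular_value") -> dict:
    """Permutation test for PLS covariation, permuting block-2 specimen rows.

    Returns add-one p-values: ``rv_p`` for the RV coefficient, ``axis_p``
    per retained axis (statistic = that axis's singular value by default,
    or its score correlation with ``per_axis='correlation'``), and
    ``covariance_p`` for the total squared covariance. Minimum attainable
    p is ``1 / (n_perm + 1)``; deterministic given ``seed``.
    """
    if n_perm < 1:
        raise PLSError("n_perm must be >= 1")
    if per_axis not in ("singular_value", "correlation"):
        raise PLSError("per_axis must be 'singular_value' or 'correlation'")
    X = _as_matrix(block1)
    Y = _as_matrix(block2)
    obs = two_block_pls(X, Y, n_axes=n_axes)
    r = obs.n_axes
    obs_axis = obs.singular_values if per_axis == "singular_value" else np.abs(obs.correlations)
    obs_total = float(np.sum(obs.singular_values ** 2))
    rng = np.random.default_rng(seed)
    n = len(X)
    ge_rv = 0
    ge_axis = np.zeros(r, dtype=int)
    ge_total = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Y[perm]
        res = two_block_pls(X, Yp, n_axes=r)
        if res.rv >= obs.rv:
            ge_rv += 1
        stat = res.singular_values if per_axis == "singular_value" else np.abs(res.correlations)
        m = min(len(stat), r)
        ge_axis[:m] += stat[:m] >= obs_axis[:m]
        if float(np.sum(res.singular_values ** 2)) >= obs_total:
            ge_total += 1
    denom = n_perm + 1
    return {
        "rv_p": (1 + ge_rv) / denom,
        "axis_p": (1 + ge_axis) / denom,
        "covariance_p": (1 + ge_total) / denom,
        "observed": obs,
        "n_perm": n_perm,
    }


@dataclass
class ExtremeShapes:
    """Fitted block shapes at +/- ``multiple`` x score range along one axis."""

    plus: tuple[np.ndarray, np.ndarray]
    minus: tuple[np.ndarray, np.ndarray]
    displacement: tuple[np.ndarray, np.ndarray]  # plus - minus per block, (k, 3)


def pls_extreme_shapes(pls: PLSResult, axis: int, multiple: float,
                       mean_shape1: np.ndarray,
                       mean_shape2: np.ndarray) -> ExtremeShapes:
    """Shapes at the +/- limits of one PLS axis.

    The step along the axis is ``multiple`` times the observed score
    half-range of each block; outputs are symmetric about the mean shapes.
    """
    if not 0 <= axis < pls.n_axes:
        raise PLSError(f"axis {axis} out of range (have {pls.n_axes})")
    m1 = np.asarray(mean_shape1, dtype=float).reshape(-1, 3)
    m2 = np.asarray(mean_shape2, dtype=float).reshape(-1, 3)
    half1 = 0.5 * float(pls.scores1[:, axis].max() - pls.scores1[:, axis].min())
    half2 = 0.5 * float(pls.scores2[:, axis].max() - pls.scores2[:, axis].min())
    d1 = (multiple * half1 * pls.u[:, axis]).reshape(-1, 3)
    d2 = (multiple * half2 * pls.v[:, axis]).reshape(-1, 3)
    plus = (m1 + d1, m2 + d2)
    minus = (m1 - d1, m2 - d2)
    return ExtremeShapes(plus=plus, minus=minus, displacement=(2 * d1, 2 * d2))
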