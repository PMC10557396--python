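"""Ridge regression from hard-tissue PC scores to soft-tissue PC scores.

The learned coefficient matrix maps an organ's (nose or mouth) hard-tissue
shape-space scores to the corresponding soft-tissue scores; predicted
shapes are the soft mean plus the scored linear combination of soft PCs,
emitted in shape space (unit centroid size, alignment-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..meshkit.landmarks import Configuration
from ..morphometrics.gpa import (
    _optimal_rotation,
    centroid_size,
    gpa,
    procrustes_distance,
)
from ..morphometrics.pca import ShapeSpace, pca_shapes


class RegressionError(ValueError):
    pass


@dataclass
class RegressionModel:
    hard_space: ShapeSpace
    soft_space: ShapeSpace
    M: np.ndarray          # (d_soft, d_hard): soft = M @ hard
    eta: float

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (self.soft_space.d, self.hard_space.d):
            raise RegressionError(
                f"M must be (d_soft, d_hard) = "
                f"({self.soft_space.d}, {self.hard_space.d}), got {self.M.shape}"
            )
        if self.eta < 0:
            raise RegressionError("eta must be >= 0")


def fit_scores_map(hard_scores: np.ndarray, soft_scores: np.ndarray,
                   eta: float = 0.0) -> np.ndarray:
    """Closed-form ridge solution of min ||H M^T - S||^2 + eta^2 ||M||^2.

    Rows of ``hard_scores``/``soft_scores`` are specimens. With ``eta=0``
    and more specimens than hard dimensions this is ordinary least squares;
    a singular unregularized system raises, advising ``eta > 0``.
    """
    H = np.asarray(hard_scores, dtype=float)
    S = np.asarray(soft_scores, dtype=float)
    if H.ndim != 2 or S.ndim != 2 or len(H) != len(S):
        raise RegressionError("score matrices must share the specimen axis")
    d_hard = H.shape[1]
    A = H.T @ H + (eta ** 2) * np.eye(d_hard)
    if eta == 0.0:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise RegressionError(
                "singular normal equations with eta=0; use eta > 0"
            )
    Mt = np.linalg.solve(A, H.T @ S)  # (d_hard, d_soft)
    return Mt.T


def fit_organ_regression(hard_scores: np.ndarray, soft_scores: np.ndarray,
                         hard_space: ShapeSpace, soft_space: ShapeSpace,
                         eta: float = 0.0) -> RegressionModel:
    M = fit_scores_map(hard_scores, soft_scores, eta)
    return RegressionModel(hard_space=hard_space, soft_space=soft_space, M=M, eta=eta)


def project_to_shape_space(space: ShapeSpace, config) -> np.ndarray:
    """Scores of a raw configuration after centering/scaling/rotating to the mean."""
    pts = config.points if isinstance(config, Configuration) else \
        np.asarray(config, dtype=float).reshape(-1, 3)
    if len(pts) != space.k:
        raise RegressionError(
            f"configuration has {len(pts)} points, model expects {space.k}"
        )
    pts = pts - pts.mean(axis=0)
    size = centroid_size(pts)
    if size < 1e-12:
        raise RegressionError("degenerate configuration")
    pts = pts / size
    R = _optimal_rotation(pts, space.mean_shape)
    rotated = pts @ R.T
    # full OPA: optimal scale onto the mean, so the mean itself projects to
    # zero scores exactly
    s = float(np.sum(rotated * space.mean_shape) / np.sum(rotated * rotated))
    return space.project(s * rotated)


def predict_organ(model: RegressionModel, hard_config) -> Configuration:
    """Predicted soft-tissue shape (unit centroid size, model frame)."""
    h_scores = project_to_shape_space(model.hard_space, hard_config)
    s_scores = model.M @ h_scores
    shape = model.soft_space.reconstruct(s_scores)
    if isinstance(hard_config, Configuration):
        nl = 0
        if model.soft_space.k == hard_config.k:
            nl = hard_config.n_landmarks
        return Configuration(shape, n_landmarks=nl)
    return Configuration(shape)


def choose_eta(hard_scores: np.ndarray, soft_scores: np.ndarray,
               grid: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0, 10.0)) -> float:
    """Pick eta by leave-one-out error over a small grid (ties -> smaller eta)."""
    H = np.asarray(hard_scores, dtype=float)
    S = np.asarray(soft_scores, dtype=float)
    n = len(H)
    best_eta, best_err = grid[0], np.inf
    for eta in grid:
        err = 0.0
        ok = True
        for i in range(n):
            mask = np.arange(n) != i
            try:
                M = fit_scores_map(H[mask], S[mask], eta)
            except RegressionError:
                ok = False
                break
            err += float(np.sum((M @ H[i] - S[i]) ** 2))
        if ok and err < best_err - 1e-12:
            best_err = err
            best_eta = eta
    return best_eta


def organ_loocv(hard_configs: list, soft_configs: list,
                configuration_choice: str = "landmarks_plus_semilandmarks",
                eta: float | None = None,
                cumulative_threshold: float = 0.95) -> dict:
    """Leave-one-out organ prediction accuracy with ratio statistics.

    For each held-out specimen the shape spaces and regression are refit on
    the remainder, the soft shape predicted, and the Procrustes distance to
    the true shape recorded. ``ratio_i = d_i / mean_j d(specimen_j, mean)``
    uses the training soft shapes' mean distance to their mean shape.
    """
    n = len(hard_configs)
    if n < 3 or len(soft_configs) != n:
        raise RegressionError("need >= 3 paired specimens")
    if configuration_choice not in ("landmarks_only", "landmarks_plus_semilandmarks"):
        raise RegressionError(f"unknown configuration choice {configuration_choice!r}")

    def hard_points(c: Configuration) -> np.ndarray:
        if configuration_choice == "landmarks_only":
            if c.n_landmarks == 0:
                raise RegressionError("configuration has no named landmarks")
            return c.points[: c.n_landmarks]
        return c.points

    distances = np.empty(n)
    ratios = np.empty(n)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        hard_train = [hard_points(hard_configs[j]) for j in train_idx]
        soft_train = [soft_configs[j].points for j in train_idx]
        g_hard = gpa(hard_train, with_scaling=True)
        g_soft = gpa(soft_train, with_scaling=True)
        hs = pca_shapes(g_hard, cumulative_threshold)
        ss = pca_shapes(g_soft, cumulative_threshold)
        H = np.stack([project_to_shape_space(hs, x) for x in hard_train])
        S = np.stack([project_to_shape_space(ss, x) for x in soft_train])
        eta_i = choose_eta(H, S) if eta is None else eta
        try:
            model = fit_organ_regression(H, S, hs, ss, eta_i)
        except RegressionError:
            model = fit_organ_regression(H, S, hs, ss, max(eta_i, 1e-6))
        pred = predict_organ(model, Configuration(hard_points(hard_configs[i])))
        distances[i] = procrustes_distance(pred.points, soft_configs[i].points,
                                           with_scaling=True)
        baseline = float(g_soft.distances.mean())
        ratios[i] = distances[i] / baseline if baseline > 0 else np.inf
    return {
        "distances": distances,
        "ratios": ratios,
        "mean": float(distances.mean()),
        "sd": float(distances.std(ddof=1)) if n > 1 else 0.0,
        "max_ratio": float(ratios.max()),
        "min_ratio": float(ratios.min()),
        "configuration": configuration_choice,
    }
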