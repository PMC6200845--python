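"""Landmark-driven dual-Kriging mesh morphing.

The morph maps source-frame points to target-frame points as the sum of an
affine *drift* and a radial *fluctuation*::

    y(x) = a0 + a1 x + a2 y + a3 z  +  sum_s b_s K(||x - x_s||)

fitted independently per output coordinate so that every source control
point lands exactly on its matched target control point.  The generalized
covariance kernel defaults to the logarithmic form ``K(h) = h^2 log h``
(with the continuity convention ``K(0) = 0``); linear, cubic, Gaussian and
(inverse) multiquadric kernels are available as options.

Well-posedness requires the standard side conditions on the fluctuation
coefficients (``sum b_s = 0`` and first-moment orthogonality), imposed by
bordering the covariance matrix with the affine design block.  The module
also provides morph-quality metrics (nearest-neighbour node discrepancy
``q`` and control-point RMSE) and greedy backward elimination of control
points driven by a leave-one-out cross-validation RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .mesh import LandmarkSet, MeshError


class KrigingError(ValueError):
    """Kriging system could not be solved (rank deficiency, duplicates)."""


# ---------------------------------------------------------------------------
# Covariance kernels


def covariance(h, kind: str = "log", scale: float = 1.0):
    """Generalized covariance K(h) for distance(s) ``h >= 0``.

    ``log``: h^2 log h (0 at h = 0); ``linear``: h; ``cubic``: h^3;
    ``gaussian``: exp(-(h/scale)^2); ``multiquadric``: sqrt(h^2 + scale^2);
    ``inverse_multiquadric``: 1/sqrt(h^2 + scale^2).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("covariance distance must be non-negative")
    if kind == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(h > 0, h * h * np.log(np.where(h > 0, h, 1.0)), 0.0)
        return out if out.ndim else float(out)
    if kind == "linear":
        return h if h.ndim else float(h)
    if kind == "cubic":
        return h**3 if h.ndim else float(h**3)
    if kind == "gaussian":
        out = np.exp(-((h / scale) ** 2))
    elif kind == "multiquadric":
        out = np.sqrt(h * h + scale * scale)
    elif kind == "inverse_multiquadric":
        out = 1.0 / np.sqrt(h * h + scale * scale)
    else:
        raise ValueError(f"unknown covariance kind {kind!r}")
    return out if out.ndim else float(out)


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)


# ---------------------------------------------------------------------------
# Model


@dataclass
class KrigingModel:
    """Fitted dual-Kriging morph (drift + fluctuation per output axis)."""

    source_points: np.ndarray          # (n, 3) control points, source frame
    drift: np.ndarray                  # (4, 3): rows a0, a1, a2, a3 per axis
    fluctuation: np.ndarray            # (n, 3): b_s per axis
    kind: str = "log"
    scale: float = 1.0
    normalized: bool = False
    _center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    _span: float = 1.0
    _out_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_points(self) -> int:
        return self.source_points.shape[0]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_kriging(self, points)

    def side_condition_residuals(self) -> dict[str, float]:
        """Max abs residual of sum(b) = 0 and sum(b * coords) = 0."""
        b = self.fluctuation
        x = self.source_points
        return {
            "sum_b": float(np.abs(b.sum(axis=0)).max()),
            "sum_bx": float(np.abs(x.T @ b).max()),
        }

    @classmethod
    def fit(
        cls,
        source: LandmarkSet | np.ndarray,
        target: LandmarkSet | np.ndarray,
        kind: str = "log",
        scale: float = 1.0,
        normalize: bool = False,
    ) -> "KrigingModel":
        return fit_kriging(source, target, kind=kind, scale=scale, normalize=normalize)


def _as_coords(lm) -> np.ndarray:
    if isinstance(lm, LandmarkSet):
        return lm.coords
    return np.asarray(lm, dtype=float)


def fit_kriging(
    source,
    target,
    kind: str = "log",
    scale: float = 1.0,
    normalize: bool = False,
) -> KrigingModel:
    """Fit the dual-Kriging morph from matched control points.

    Solves, for all three output coordinates at once, the bordered
    symmetric system ``[[K, P], [P^T, 0]] [b; a] = [Y; 0]`` with
    ``P = [1 | x | y | z]``, which enforces exact interpolation and the
    fluctuation side conditions.

    ``normalize=True`` rescales coordinates to a unit bounding-box
    diagonal before solving (a pure conditioning device; results agree
    with the raw solve to high precision and are mapped back).
    """
    if isinstance(source, LandmarkSet) and isinstance(target, LandmarkSet):
        source.require_matched(target)
    xs = _as_coords(source)
    yt = _as_coords(target)
    if xs.shape != yt.shape or xs.ndim != 2 or xs.shape[1] != 3:
        raise KrigingError("source and target control points must both be (n, 3)")
    n = xs.shape[0]
    if n < 5:
        raise KrigingError(f"need at least 5 control points, got {n}")

    center = np.zeros(3)
    span = 1.0
    out_center = np.zeros(3)
    if normalize:
        lo, hi = xs.min(axis=0), xs.max(axis=0)
        center = (lo + hi) / 2.0
        span = float(np.linalg.norm(hi - lo)) or 1.0
        out_center = yt.mean(axis=0)
        xs = (xs - center) / span
        yt = (yt - out_center) / span

    d = _pairwise_dist(xs, xs)
    if np.any(d[~np.eye(n, dtype=bool)] == 0.0):
        dup = np.argwhere((d == 0.0) & ~np.eye(n, dtype=bool))
        raise KrigingError(f"duplicated source control points at indices {dup[0].tolist()}")
    K = covariance(d, kind=kind, scale=scale)
    P = np.column_stack([np.ones(n), xs])
    if np.linalg.matrix_rank(P) < 4:
        raise KrigingError(
            "source control points are coplanar (affine drift block rank "
            f"{np.linalg.matrix_rank(P)} < 4)"
        )
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = yt
    try:
        sol = scipy.linalg.solve(A, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise KrigingError(f"singular Kriging system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise KrigingError("Kriging solve produced non-finite coefficients")
    b = sol[:n]
    a = sol[n:]
    return KrigingModel(
        xs, a, b, kind=kind, scale=scale, normalized=normalize,
        _center=center, _span=span, _out_center=out_center,
    )


def apply_kriging(model: KrigingModel, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted morph at arbitrary points (m, 3) -> (m, 3)."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if model.normalized:
        pts = (pts - model._center) / model._span
    d = _pairwise_dist(pts, model.source_points)
    K = covariance(d, kind=model.kind, scale=model.scale)
    P = np.column_stack([np.ones(pts.shape[0]), pts])
    out = P @ model.drift + K @ model.fluctuation
    if model.normalized:
        out = out * model._span + model._out_center
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Morph quality


@dataclass
class MorphQuality:
    """Nearest-neighbour discrepancy between target and morphed source."""

    q_values: np.ndarray   # per-target-node distance to nearest morphed node (mm)
    mean: float
    sd: float
    max: float
    rmse: float            # RMS distance over matched landmark pairs (mm)

    def to_dict(self) -> dict:
        return {
            "q_mean": self.mean,
            "q_sd": self.sd,
            "q_max": self.max,
            "landmark_rmse": self.rmse,
            "n_target_nodes": int(self.q_values.size),
        }


def morph_quality(
    morphed_source_nodes: np.ndarray,
    target_nodes: np.ndarray,
    landmarks_source_morphed: np.ndarray | LandmarkSet,
    landmarks_target: np.ndarray | LandmarkSet,
) -> MorphQuality:
    """Score a morph: per-target-node nearest-neighbour distance ``q`` to
    the morphed source nodes, plus the control-point RMSE (mm)."""
    ms = np.asarray(morphed_source_nodes, dtype=float)
    tg = np.asarray(target_nodes, dtype=float)
    if ms.size == 0 or tg.size == 0:
        raise MeshError("morph_quality requires non-empty node sets")
    q, _ = cKDTree(ms).query(tg)
    lm_s = _as_coords(landmarks_source_morphed)
    lm_t = _as_coords(landmarks_target)
    rmse = float(np.sqrt(np.mean(np.sum((lm_s - lm_t) ** 2, axis=1))))
    sd = float(np.std(q, ddof=1)) if q.size > 1 else 0.0
    return MorphQuality(q, float(q.mean()), sd, float(q.max()), rmse)


# ---------------------------------------------------------------------------
# Control-point optimization


def _cv_rmse(
    xs: np.ndarray,
    yt: np.ndarray,
    retained: list[int],
    kind: str,
    scale: float,
) -> float:
    """Cross-validation RMSE over ALL original landmark pairs.

    Retained points are scored by leave-one-out refits; removed points are
    scored as probes of the fit on the retained set.  Exact interpolation
    makes the naive all-retained residual identically zero, so this CV
    form is what actually exposes an inconsistent (outlier) control point.
    """
    n = xs.shape[0]
    errs = np.zeros(n)
    retained_set = set(retained)
    model_R = fit_kriging(xs[retained], yt[retained], kind=kind, scale=scale)
    for r in range(n):
        if r in retained_set:
            sub = [i for i in retained if i != r]
            try:
                m = fit_kriging(xs[sub], yt[sub], kind=kind, scale=scale)
            except KrigingError:
                return np.inf
            pred = apply_kriging(m, xs[r])
        else:
            pred = apply_kriging(model_R, xs[r])
        errs[r] = np.linalg.norm(pred - yt[r])
    return float(np.sqrt(np.mean(errs**2)))


@dataclass
class EliminationRound:
    removed_label: str
    removed_index: int
    rmse: float


@dataclass
class OptimizationReport:
    initial_rmse: float
    rounds: list[EliminationRound]
    final_rmse: float
    retained_labels: list[str]

    def to_dict(self) -> dict:
        return {
            "initial_rmse": self.initial_rmse,
            "final_rmse": self.final_rmse,
            "rounds": [
                {"removed": r.removed_label, "rmse": r.rmse} for r in self.rounds
            ],
            "retained": self.retained_labels,
        }


def optimize_control_points(
    source: LandmarkSet,
    target: LandmarkSet,
    kind: str = "log",
    scale: float = 1.0,
    min_points: int = 5,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-8,
) -> tuple[LandmarkSet, LandmarkSet, OptimizationReport]:
    """Greedy backward elimination of control points.

    Each round refits the morph without each remaining point in turn and
    scores the candidate configurations by the cross-validation RMSE over
    all original landmark pairs (removed points act as probes); the point
    whose removal lowers the RMSE the most is discarded.  Elimination
    stops when no removal lowers the RMSE by more than the numerical
    tolerance ``max(abs_tol, rel_tol * current)`` (mm; ties broken by
    lowest landmark index) or when ``min_points`` would be violated.
    """
    source.require_matched(target)
    xs, yt = source.coords, target.coords
    n = xs.shape[0]
    if n < 6:
        raise KrigingError("optimization needs at least 6 control points")
    retained = list(range(n))
    current = _cv_rmse(xs, yt, retained, kind, scale)
    report = OptimizationReport(current, [], current, list(source.labels))
    while len(retained) > min_points:
        best_idx, best_rmse = None, current
        for r in retained:
            cand = [i for i in retained if i != r]
            rmse = _cv_rmse(xs, yt, cand, kind, scale)
            if rmse < best_rmse - max(abs_tol, rel_tol * best_rmse):
                best_idx, best_rmse = r, rmse
        if best_idx is None:
            break
        retained = [i for i in retained if i != best_idx]
        current = best_rmse
        report.rounds.append(
            EliminationRound(source.labels[best_idx], best_idx, best_rmse)
        )
    report.final_rmse = current
    report.retained_labels = [source.labels[i] for i in retained]
    return source.subset(retained), target.subset(retained), report
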