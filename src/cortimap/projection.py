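"""Inverse-distance-power thickness projection and its quality metrics.

Every target node ``i`` receives the weighted average of all source nodal
thicknesses ``t_j``::

    t_i(beta) = sum_j t_j q_ij^-beta / sum_j q_ij^-beta

where ``q_ij`` is the Euclidean distance from target node ``i`` to source
node ``j`` and ``beta >= 0`` controls the locality of the transfer:
``beta = 0`` spreads the plain source mean uniformly, large ``beta``
approaches the nearest-neighbour map.  Weights are evaluated in log space
and shifted by the per-node maximum before exponentiation, so arbitrarily
large exponents cannot overflow; a target node coincident with a source
node takes that source value exactly (the analytic zero-distance limit).

Two scalar metrics score a projection against the anchor exponent
``beta_max`` (default 50, the nearest-neighbour surrogate):

* accuracy ``A(beta) = 1 - sum_i (t_i(beta_max) - t_i(beta))^2 /
  sum_i (t_i(beta_max) - t_i(0))^2`` — 0 at the uniform projection, 1 at
  the anchor;
* smoothness, from the per-node residual ``E_i`` of a first-order
  (multivariate linear) regression of the thicknesses of the nodes
  edge-connected to ``i`` on their coordinates.  The reported
  ``S(beta) = 1 - sum_i (E_i(beta_max) - E_i(beta))^2 /
  sum_i (E_i(beta_max) - E_i(0))^2`` is 0 for the perfectly smooth
  ``beta = 0`` field and 1 at the noisy nearest-neighbour anchor, i.e. it
  measures how much of the anchor's roughness a projection retains.

The sweep selects the exponent where the rising accuracy curve crosses
the falling smoothness curve ``1 - S`` (the accuracy/smoothness tradeoff
point), by piecewise-linear interpolation on the beta grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .mesh import MeshError, NodalScalarField, SurfaceMesh, node_adjacency

DEFAULT_BETAS = (0.0, 1.0, 2.0, 3.0, 4.0, 10.0, 25.0, 50.0)


@dataclass
class ProjectionResult:
    """A projected thickness field on the target nodes."""

    beta: float
    field: NodalScalarField
    contributing_counts: np.ndarray  # per-target-node count of sources with
                                     # non-negligible weight (QC)

    @property
    def values(self) -> np.ndarray:
        return self.field.values


def project_thickness(
    target_nodes,
    source_nodes,
    source_field: NodalScalarField | np.ndarray,
    beta: float,
    target_ids: np.ndarray | None = None,
) -> ProjectionResult:
    """Project source nodal thicknesses onto target nodes.

    Parameters
    ----------
    target_nodes : (P, 3) target coordinates, or a :class:`SurfaceMesh`.
    source_nodes : (N, 3) source coordinates (typically the morphed source
        outer-surface nodes).
    source_field : thickness per source node; a :class:`NodalScalarField`
        must cover the source nodes in order, a plain array is taken as
        already aligned.
    beta : non-negative weighting exponent.
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if isinstance(target_nodes, SurfaceMesh):
        if target_ids is None:
            target_ids = target_nodes.node_ids
        target_nodes = target_nodes.coords
    tgt = np.asarray(target_nodes, dtype=float)
    src = np.asarray(source_nodes, dtype=float)
    t = source_field.values if isinstance(source_field, NodalScalarField) else np.asarray(
        source_field, dtype=float
    )
    if src.shape[0] == 0:
        raise MeshError("empty source node set")
    if t.shape[0] != src.shape[0]:
        raise MeshError("source field length does not match source nodes")
    P, N = tgt.shape[0], src.shape[0]
    if target_ids is None:
        target_ids = np.arange(1, P + 1)

    if beta == 0.0:
        vals = np.full(P, float(t.mean()))
        counts = np.full(P, N)
        return ProjectionResult(0.0, NodalScalarField(target_ids, vals), counts)

    q = cdist(tgt, src)
    vals = np.empty(P)
    counts = np.empty(P, dtype=np.int64)
    zero_rows = q.min(axis=1) == 0.0
    with np.errstate(divide="ignore"):
        logw = -beta * np.log(q, where=q > 0, out=np.full_like(q, -np.inf))
    m = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - m)
    w[np.isnan(w)] = 0.0
    denom = w.sum(axis=1)
    vals = (w @ t) / np.where(denom > 0, denom, 1.0)
    counts = (w > 1e-12).sum(axis=1)
    if np.any(zero_rows):
        # exact zero-distance limit: the coincident source value (mean if
        # several sources coincide with the node)
        for i in np.nonzero(zero_rows)[0]:
            hit = q[i] == 0.0
            vals[i] = float(t[hit].mean())
            counts[i] = int(hit.sum())
    return ProjectionResult(float(beta), NodalScalarField(target_ids, vals), counts)


def accuracy(field_beta, field_0, field_betamax) -> float:
    """Accuracy ``A`` of a projection relative to the anchor projection.

    ``A = 1 - sum (t_max - t_beta)^2 / sum (t_max - t_0)^2``; 0 when the
    field equals the uniform (beta = 0) projection, 1 at the anchor.  A
    constant source field makes the denominator vanish; A is then defined
    as 1 (every projection equals the anchor) with a warning.
    """
    tb = _field_values(field_beta)
    t0 = _field_values(field_0)
    tm = _field_values(field_betamax)
    if not (tb.shape == t0.shape == tm.shape):
        raise MeshError("accuracy requires fields on identical node sets")
    denom = float(np.sum((tm - t0) ** 2))
    if denom == 0.0:
        warnings.warn(
            "accuracy denominator is zero (constant source field); A := 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - float(np.sum((tm - tb) ** 2)) / denom


def _field_values(f) -> np.ndarray:
    if isinstance(f, ProjectionResult):
        return f.field.values
    if isinstance(f, NodalScalarField):
        return f.values
    return np.asarray(f, dtype=float)


def local_regression_errors(
    mesh: SurfaceMesh,
    field: NodalScalarField,
    adjacency: dict[int, list[int]] | None = None,
) -> NodalScalarField:
    """Per-node first-order regression error ``E_i``.

    For each node ``i``, the thicknesses of its ``m`` edge-connected
    neighbours are regressed on their coordinates
    (``t_hat = C1 x + C2 y + C3 z + C4``) and ``E_i`` is the squared
    Euclidean norm of the residual.  A constant field yields ``E_i = 0``
    everywhere; so does any field exactly linear in the coordinates.
    Rank-deficient neighbourhoods (``m < 4`` or degenerate positions) use
    the minimum-norm least-squares solution; an isolated node gets
    ``E_i = 0`` with a warning.
    """
    if adjacency is None:
        adjacency = node_adjacency(mesh)
    ids = mesh.node_ids
    E = np.empty(ids.size)
    for k, nid in enumerate(ids):
        nbrs = adjacency[int(nid)]
        if not nbrs:
            warnings.warn(f"isolated node {int(nid)}: E set to 0", stacklevel=2)
            E[k] = 0.0
            continue
        idx = mesh.index_of(nbrs)
        X = np.column_stack([mesh.coords[idx], np.ones(len(nbrs))])
        tm = field.reindex(nbrs)
        coef, *_ = np.linalg.lstsq(X, tm, rcond=None)
        resid = X @ coef - tm
        E[k] = float(resid @ resid)
    return NodalScalarField(ids, E)


def local_regression_error(
    mesh: SurfaceMesh, field: NodalScalarField, node_id: int
) -> float:
    """``E_i`` for a single node (see :func:`local_regression_errors`)."""
    adjacency = node_adjacency(mesh)
    nbrs = adjacency[int(node_id)]
    if not nbrs:
        warnings.warn(f"isolated node {int(node_id)}: E set to 0", stacklevel=2)
        return 0.0
    idx = mesh.index_of(nbrs)
    X = np.column_stack([mesh.coords[idx], np.ones(len(nbrs))])
    tm = field.reindex(nbrs)
    coef, *_ = np.linalg.lstsq(X, tm, rcond=None)
    resid = X @ coef - tm
    return float(resid @ resid)


def smoothness(E_beta, E_0, E_betamax) -> float:
    """Reported smoothness ``S`` of a projection.

    Computed from the squared-difference ratio of the per-node regression
    errors against the anchor, oriented so that ``S(0) = 0`` (perfectly
    smooth uniform field) and ``S(beta_max) = 1`` (the anchor's own
    roughness): ``S = 1 - sum (E_max - E_beta)^2 / sum (E_max - E_0)^2``.
    A zero denominator (anchor as smooth as the uniform field) gives
    ``S = 1`` with a warning.
    """
    eb = _field_values(E_beta)
    e0 = _field_values(E_0)
    em = _field_values(E_betamax)
    if not (eb.shape == e0.shape == em.shape):
        raise MeshError("smoothness requires error vectors on identical node sets")
    denom = float(np.sum((em - e0) ** 2))
    if denom == 0.0:
        warnings.warn(
            "smoothness denominator is zero (anchor field already smooth); S := 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - float(np.sum((em - eb) ** 2)) / denom


@dataclass
class BetaSweep:
    """Projections over a beta grid with the accuracy/smoothness tradeoff."""

    betas: np.ndarray
    projections: list[ProjectionResult]
    A: np.ndarray
    S: np.ndarray
    selected_beta: float

    def table(self) -> list[dict]:
        return [
            {"beta": float(b), "A": float(a), "S": float(s)}
            for b, a, s in zip(self.betas, self.A, self.S)
        ]

    def to_dict(self) -> dict:
        return {"selected_beta": self.selected_beta, "curve": self.table()}

    def projection_at(self, beta: float) -> ProjectionResult:
        for p in self.projections:
            if p.beta == beta:
                return p
        raise KeyError(f"beta {beta} not in sweep grid")

    def plot(self, path=None):
        """Accuracy and smoothness-tradeoff curves vs beta."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.betas, self.A, "o-", label="accuracy A")
        ax.plot(self.betas, 1.0 - self.S, "s-", label="smoothness 1 - S")
        ax.axvline(self.selected_beta, ls="--", c="k",
                   label=f"crossing beta = {self.selected_beta:.2f}")
        ax.set_xlabel("beta")
        ax.set_ylabel("metric")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _crossing(betas: np.ndarray, A: np.ndarray, S: np.ndarray) -> float:
    """Smallest abscissa where A crosses the falling curve 1 - S."""
    g = A - (1.0 - S)
    for k in range(len(betas)):
        if g[k] == 0.0:
            return float(betas[k])
        if k + 1 < len(betas) and g[k] < 0.0 <= g[k + 1]:
            frac = -g[k] / (g[k + 1] - g[k])
            return float(betas[k] + frac * (betas[k + 1] - betas[k]))
    # no sign change (degenerate curves): fall back to the grid point
    # minimising |g|
    return float(betas[int(np.argmin(np.abs(g)))])


def beta_sweep(
    target_mesh: SurfaceMesh,
    source_nodes,
    source_field,
    betas=DEFAULT_BETAS,
    beta_max: float = 50.0,
) -> BetaSweep:
    """Sweep the weighting exponent and locate the tradeoff point.

    Computes the projection, accuracy ``A`` and reported smoothness ``S``
    for every exponent in ``betas`` (which must contain 0 and
    ``beta_max``), then selects the abscissa where the rising accuracy
    curve meets the falling smoothness curve ``1 - S``, by
    piecewise-linear interpolation; with several crossings the smallest
    is returned.
    """
    betas = np.asarray(sorted(float(b) for b in betas))
    if betas[0] != 0.0:
        raise ValueError("beta grid must contain 0 (the uniform projection)")
    if beta_max not in betas:
        raise ValueError(f"beta grid must contain the anchor beta_max = {beta_max}")
    adjacency = node_adjacency(target_mesh)
    projections = [
        project_thickness(target_mesh, source_nodes, source_field, b) for b in betas
    ]
    by_beta = {p.beta: p for p in projections}
    p0, pmax = by_beta[0.0], by_beta[float(beta_max)]
    E = {
        p.beta: local_regression_errors(target_mesh, p.field, adjacency)
        for p in projections
    }
    A = np.array([accuracy(p, p0, pmax) for p in projections])
    S = np.array([smoothness(E[b], E[0.0], E[float(beta_max)]) for b in betas])
    return BetaSweep(betas, projections, A, S, _crossing(betas, A, S))
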