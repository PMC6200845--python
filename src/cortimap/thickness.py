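"""Per-node cortical thickness of a one-element-thick solid layer.

For every node on the outer skin the matching inner-skin node is found
topologically (the opposite corner of a shared solid element), giving a
direction vector ``d`` from inner to outer.  ``d`` is generally oblique to
the surface, so it is projected onto the outward unit normal ``n_hat``:
the correction factor ``alpha = (d . n_hat)/|d|`` scales ``d`` into the
perpendicular thickness vector ``t = alpha * d``, and the nodal thickness
is ``|t| = |d . n_hat|``.  This is never larger than ``|d|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (
    MeshError,
    MeshStructureError,
    NodalScalarField,
    SolidShellLayer,
    vertex_normals,
)


@dataclass
class ThicknessVectorRecord:
    """Geometry of one outer-node thickness measurement."""

    outer_node: int
    inner_node: int
    d: np.ndarray            # inner -> outer direction vector (mm)
    n_hat: np.ndarray        # outward unit normal at the outer node
    alpha: float             # (d . n_hat) / |d|
    thickness: float         # |d . n_hat| (mm)

    @property
    def t(self) -> np.ndarray:
        """Perpendicular thickness vector ``alpha * d``."""
        return self.alpha * self.d


@dataclass
class ThicknessExtraction:
    """Result of a thickness extraction: the field plus per-node QC."""

    field: NodalScalarField
    records: list[ThicknessVectorRecord]
    flagged_thin: list[int] = field(default_factory=list)
    flagged_tangent: list[int] = field(default_factory=list)

    def qc_report(self) -> dict:
        return {
            "n_nodes": len(self.field),
            "flagged_thin": self.flagged_thin,
            "flagged_tangent": self.flagged_tangent,
            "summary": thickness_summary(self.field),
        }


def pair_inner_outer(
    layer: SolidShellLayer, method: str = "topological"
) -> dict[int, int]:
    """Map every outer-skin node to its matching inner-skin node.

    ``topological`` (default) pairs the opposite corners within each solid
    element — hexa column ``i <-> i+4``, wedge vertex ``i <-> i+3`` after
    identifying which face lies on the outer skin — and requires the
    pairing to agree across every element sharing the node.
    ``nearest`` pairs each outer node with the closest inner node.
    """
    outer, inner = layer.outer_surface_nodes, layer.inner_surface_nodes
    if method == "nearest":
        in_ids = np.asarray(sorted(inner))
        tree = cKDTree(layer.coords[layer.index_of(in_ids)])
        out_ids = sorted(outer)
        _, j = tree.query(layer.coords[layer.index_of(out_ids)])
        return {int(o): int(in_ids[k]) for o, k in zip(out_ids, j)}
    if method != "topological":
        raise ValueError(f"unknown pairing method {method!r}")

    pairing: dict[int, int] = {}
    conflicts: set[int] = set()
    for e in layer.elements:
        if len(e) == 8:
            bottom, top, stride = e[:4], e[4:], 4
        else:
            bottom, top, stride = e[:3], e[3:], 3
        if set(top) <= outer and set(bottom) <= inner:
            pairs = zip(top, bottom)
        elif set(bottom) <= outer and set(top) <= inner:
            pairs = zip(bottom, top)
        else:
            raise MeshStructureError(
                f"element {e} has no pure outer/inner opposite-face pair"
            )
        for o, i in pairs:
            if pairing.setdefault(o, i) != i:
                conflicts.add(o)
    if conflicts:
        raise MeshStructureError(
            f"contradictory inner/outer pairing at outer node(s) "
            f"{sorted(conflicts)[:10]}"
        )
    unpaired = outer - set(pairing)
    if unpaired:
        raise MeshStructureError(
            f"outer node(s) {sorted(unpaired)[:10]} belong to no solid element"
        )
    return pairing


def nodal_thickness(
    layer: SolidShellLayer,
    *,
    pairing_method: str = "topological",
    normal_weighting: str = "area",
    floor: float = 1e-6,
    tangent_alpha: float = 0.2,
) -> ThicknessExtraction:
    """Extract the per-outer-node thickness field of a solid layer.

    Parameters
    ----------
    floor : thickness (mm) below which a node is flagged in the QC report.
    tangent_alpha : nodes with ``|alpha|`` below this (direction vector
        nearly tangent to the surface) are flagged rather than rejected.
    """
    pairing = pair_inner_outer(layer, method=pairing_method)
    surf, hints = layer.outer_surface_mesh()
    normals = vertex_normals(surf, weighting=normal_weighting, outward_hints=hints)

    out_ids = sorted(layer.outer_surface_nodes)
    records: list[ThicknessVectorRecord] = []
    flagged_thin: list[int] = []
    flagged_tangent: list[int] = []
    values = np.empty(len(out_ids))
    for k, o in enumerate(out_ids):
        i = pairing[o]
        d = layer.coords[layer.index_of([o])[0]] - layer.coords[layer.index_of([i])[0]]
        dn = float(np.linalg.norm(d))
        if dn == 0.0:
            raise MeshError(f"zero-length inner/outer direction at node {o}")
        n_hat = normals[o]
        alpha = float(d @ n_hat) / dn
        t = abs(float(d @ n_hat))
        if t <= floor:
            flagged_thin.append(o)
            warnings.warn(f"near-zero thickness {t:g} mm at node {o}", stacklevel=2)
        if abs(alpha) < tangent_alpha:
            flagged_tangent.append(o)
        values[k] = t
        records.append(ThicknessVectorRecord(o, i, d, np.asarray(n_hat), alpha, t))
    fld = NodalScalarField(np.asarray(out_ids), values)
    return ThicknessExtraction(fld, records, flagged_thin, flagged_tangent)


def thickness_summary(field: NodalScalarField) -> dict[str, float]:
    """Sample mean, standard deviation (ddof=1), min and max of a field."""
    v = field.values
    if v.size == 0:
        raise MeshError("empty thickness field")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return {
        "mean": float(np.mean(v)),
        "sd": sd,
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }
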