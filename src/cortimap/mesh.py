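"""Mesh data model and geometric utilities.

Containers for the two mesh kinds handled by the pipeline — a triangulated
(or mixed tri/quad) surface, and a one-element-thick solid layer with paired
inner/outer skins representing a cortical bone shell — plus per-node scalar
fields, matched landmark sets, vertex normals and edge adjacency.

All coordinates are millimetres.  Node ids are positive integers and carry
no ordering assumption; internally everything is addressed by row index and
translated through an id -> index map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np


class MeshError(ValueError):
    """Invalid mesh content (bad references, degenerate geometry)."""


class MeshStructureError(MeshError):
    """Mesh violates a structural invariant (e.g. not one element thick)."""


# ---------------------------------------------------------------------------
# Surface mesh


@dataclass
class SurfaceMesh:
    """Triangulated surface with optional quads.

    Parameters
    ----------
    node_ids : (N,) int array of unique positive labels.
    coords : (N, 3) float array, millimetres.
    faces : sequence of 3- or 4-tuples of node ids.
    """

    node_ids: np.ndarray
    coords: np.ndarray
    faces: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.faces = [tuple(int(n) for n in f) for f in self.faces]
        if self.node_ids.ndim != 1:
            raise MeshError("node_ids must be one-dimensional")
        if self.coords.shape != (self.node_ids.size, 3):
            raise MeshError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.node_ids.size} node ids"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MeshError("non-finite node coordinates")
        if np.unique(self.node_ids).size != self.node_ids.size:
            raise MeshError("duplicate node ids")
        if np.any(self.node_ids <= 0):
            raise MeshError("node ids must be positive")
        self._index = {int(i): k for k, i in enumerate(self.node_ids)}
        for f in self.faces:
            if len(f) not in (3, 4):
                raise MeshError(f"face {f} is neither a triangle nor a quad")
            if len(set(f)) != len(f):
                raise MeshError(f"face {f} repeats a node")
            for n in f:
                if n not in self._index:
                    raise MeshError(f"face {f} references unknown node {n}")

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def index_of(self, ids: Iterable[int]) -> np.ndarray:
        """Row indices of the given node ids."""
        return np.asarray([self._index[int(i)] for i in ids], dtype=np.intp)

    def has_node(self, nid: int) -> bool:
        return int(nid) in self._index

    def triangles(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangulated faces as row-index triples.

        Quads (a, b, c, d) are split along the a-c diagonal into
        (a, b, c) and (a, c, d).  Returns ``(tris, parent)`` where
        ``parent[k]`` is the index of the originating face.
        """
        tris: list[tuple[int, int, int]] = []
        parent: list[int] = []
        for fi, f in enumerate(self.faces):
            idx = [self._index[n] for n in f]
            if len(idx) == 3:
                tris.append((idx[0], idx[1], idx[2]))
                parent.append(fi)
            else:
                tris.append((idx[0], idx[1], idx[2]))
                tris.append((idx[0], idx[2], idx[3]))
                parent.extend((fi, fi))
        return (
            np.asarray(tris, dtype=np.intp).reshape(-1, 3),
            np.asarray(parent, dtype=np.intp),
        )

    def validate_closed(self) -> None:
        """Raise unless every (triangulated) edge is shared by two faces."""
        tris, _ = self.triangles()
        edges, counts = _edge_counts(tris)
        bad = counts != 2
        if np.any(bad):
            raise MeshStructureError(
                f"surface not closed: {int(bad.sum())} boundary/non-manifold edges"
            )


# ---------------------------------------------------------------------------
# Solid shell layer

# Local face connectivity of the supported solid elements, in the keyword
# ordering: hexa nodes 1-4 / 5-8 are opposite faces with i <-> i+4 columns;
# wedge nodes 1-3 / 4-6 are the opposite triangles with i <-> i+3 columns.
_HEXA_FACES = ((0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4), (1, 2, 6, 5),
               (2, 3, 7, 6), (3, 0, 4, 7))
_WEDGE_FACES = ((0, 1, 2), (3, 4, 5), (0, 1, 4, 3), (1, 2, 5, 4), (2, 0, 3, 5))


def element_faces(elem: Sequence[int]) -> tuple[tuple[int, ...], ...]:
    """Faces of a solid element as tuples of node ids."""
    local = _HEXA_FACES if len(elem) == 8 else _WEDGE_FACES
    if len(elem) not in (6, 8):
        raise MeshError(f"solid element must have 6 or 8 nodes, got {len(elem)}")
    return tuple(tuple(elem[i] for i in f) for f in local)


@dataclass
class SolidShellLayer:
    """One-element-thick solid layer with labelled inner and outer skins.

    Elements are 8-node hexahedra or 6-node pentahedra (wedges), stored as
    node-id tuples in the keyword ordering.  ``outer_surface_nodes`` and
    ``inner_surface_nodes`` partition the node set; if omitted they are
    derived from the element topology (see :func:`classify_skins`).
    """

    node_ids: np.ndarray
    coords: np.ndarray
    elements: list[tuple[int, ...]]
    outer_surface_nodes: frozenset[int] = field(default=frozenset())
    inner_surface_nodes: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = [tuple(int(n) for n in e) for e in self.elements]
        if self.coords.shape != (self.node_ids.size, 3):
            raise MeshError("coords shape does not match node ids")
        if not np.all(np.isfinite(self.coords)):
            raise MeshError("non-finite node coordinates")
        if np.unique(self.node_ids).size != self.node_ids.size:
            raise MeshError("duplicate node ids")
        self._index = {int(i): k for k, i in enumerate(self.node_ids)}
        known = set(self._index)
        for e in self.elements:
            if len(e) not in (6, 8):
                raise MeshError(f"element {e} must have 6 or 8 nodes")
            if len(set(e)) != len(e):
                raise MeshError(f"element {e} repeats a node")
            missing = set(e) - known
            if missing:
                raise MeshError(f"element {e} references unknown nodes {missing}")
        if not self.outer_surface_nodes or not self.inner_surface_nodes:
            outer, inner = classify_skins(self)
            self.outer_surface_nodes = outer
            self.inner_surface_nodes = inner
        else:
            self.outer_surface_nodes = frozenset(int(n) for n in self.outer_surface_nodes)
            self.inner_surface_nodes = frozenset(int(n) for n in self.inner_surface_nodes)
        self.validate_layer()

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size

    def index_of(self, ids: Iterable[int]) -> np.ndarray:
        return np.asarray([self._index[int(i)] for i in ids], dtype=np.intp)

    def validate_layer(self) -> None:
        """Enforce the one-element-thick structural invariant."""
        outer, inner = self.outer_surface_nodes, self.inner_surface_nodes
        if outer & inner:
            raise MeshStructureError(
                f"inner and outer node sets overlap: {sorted(outer & inner)[:5]} ..."
            )
        interior = set(int(n) for n in self.node_ids) - outer - inner
        if interior:
            raise MeshStructureError(
                f"layer is not one element thick: interior nodes {sorted(interior)[:5]} ..."
            )
        face_count: dict[frozenset[int], int] = {}
        for e in self.elements:
            for f in element_faces(e):
                key = frozenset(f)
                face_count[key] = face_count.get(key, 0) + 1
        for e in self.elements:
            skin = []
            n_out = n_in = 0
            for f in element_faces(e):
                if set(f) <= outer:
                    n_out += 1
                    skin.append(f)
                elif set(f) <= inner:
                    n_in += 1
                    skin.append(f)
            if n_out != 1 or n_in != 1:
                raise MeshStructureError(
                    f"element {e} has {n_out} outer and {n_in} inner faces "
                    "(expected exactly one of each)"
                )
            for f in skin:
                if face_count[frozenset(f)] != 1:
                    raise MeshStructureError(
                        f"skin face {f} is shared between elements; layer is "
                        "more than one element thick"
                    )

    def skin_faces(self, which: str = "outer") -> tuple[list[tuple[int, ...]], list[int]]:
        """Faces lying entirely on one skin, with owning element indices."""
        target = self.outer_surface_nodes if which == "outer" else self.inner_surface_nodes
        faces: list[tuple[int, ...]] = []
        owners: list[int] = []
        for ei, e in enumerate(self.elements):
            for f in element_faces(e):
                if set(f) <= target:
                    faces.append(f)
                    owners.append(ei)
                    break
        return faces, owners

    def outer_surface_mesh(self) -> tuple["SurfaceMesh", np.ndarray]:
        """Outer skin as a SurfaceMesh plus per-face outward hint vectors.

        The hint for each face is the direction from the owning solid
        element's centroid to the face centroid, which by construction
        points away from the solid.
        """
        faces, owners = self.skin_faces("outer")
        used = sorted({n for f in faces for n in f})
        idx = self.index_of(used)
        mesh = SurfaceMesh(np.asarray(used), self.coords[idx], faces)
        hints = np.empty((len(faces), 3))
        for k, (f, ei) in enumerate(zip(faces, owners)):
            fc = self.coords[self.index_of(f)].mean(axis=0)
            ec = self.coords[self.index_of(self.elements[ei])].mean(axis=0)
            hints[k] = fc - ec
        return mesh, hints


def classify_skins(layer: SolidShellLayer) -> tuple[frozenset[int], frozenset[int]]:
    """Derive the outer and inner node sets from element topology.

    Uses the through-thickness column structure of the keyword element
    ordering (hexa corner ``i`` opposite ``i+4``, wedge vertex ``i``
    opposite ``i+3``): nodes sharing a skin face must take the same label,
    column mates the opposite one.  Two-colouring this constraint graph
    splits the nodes into the two skins; within each connected group the
    skin lying farther from the layer centroid on average is the outer
    one.  An odd cycle means the layer is not a consistent one-element
    -thick sheet.
    """
    color: dict[int, int] = {}
    # adjacency with parity: 0 = same skin, 1 = opposite skin
    edges: dict[int, list[tuple[int, int]]] = {int(n): [] for n in layer.node_ids}
    for e in layer.elements:
        k = 4 if len(e) == 8 else 3
        bottom, top = e[:k], e[k:]
        for side in (bottom, top):
            for a, b in zip(side, side[1:]):
                edges[a].append((b, 0))
                edges[b].append((a, 0))
        for a, b in zip(bottom, top):
            edges[a].append((b, 1))
            edges[b].append((a, 1))

    groups: list[set[int]] = []
    for start in sorted(edges):
        if start in color or not edges[start]:
            continue
        color[start] = 0
        group = {start}
        stack = [start]
        while stack:
            a = stack.pop()
            for b, parity in edges[a]:
                want = color[a] ^ parity
                if b not in color:
                    color[b] = want
                    group.add(b)
                    stack.append(b)
                elif color[b] != want:
                    raise MeshStructureError(
                        f"inconsistent inner/outer structure at node {b}; "
                        "layer is not one element thick"
                    )
        groups.append(group)

    uncolored = set(int(n) for n in layer.node_ids) - set(color)
    if uncolored:
        raise MeshStructureError(
            f"node(s) {sorted(uncolored)[:5]} belong to no solid element"
        )

    centroid = layer.coords.mean(axis=0)
    outer: set[int] = set()
    inner: set[int] = set()
    for group in groups:
        side0 = sorted(n for n in group if color[n] == 0)
        side1 = sorted(n for n in group if color[n] == 1)
        d0 = float(np.linalg.norm(
            layer.coords[layer.index_of(side0)] - centroid, axis=1).mean())
        d1 = float(np.linalg.norm(
            layer.coords[layer.index_of(side1)] - centroid, axis=1).mean())
        if d0 > d1 or (d0 == d1 and side0[0] < side1[0]):
            outer.update(side0)
            inner.update(side1)
        else:
            outer.update(side1)
            inner.update(side0)
    return frozenset(outer), frozenset(inner)


# ---------------------------------------------------------------------------
# Scalar fields and landmarks


@dataclass
class NodalScalarField:
    """One scalar (mm) per node on a stated node subset."""

    node_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.node_ids.shape != self.values.shape:
            raise MeshError("field node_ids and values differ in length")
        if np.unique(self.node_ids).size != self.node_ids.size:
            raise MeshError("field has duplicate node ids")
        if not np.all(np.isfinite(self.values)):
            raise MeshError("field has non-finite values")
        self._map = {int(i): float(v) for i, v in zip(self.node_ids, self.values)}

    def __len__(self) -> int:
        return self.node_ids.size

    def __getitem__(self, nid: int) -> float:
        return self._map[int(nid)]

    def __contains__(self, nid: int) -> bool:
        return int(nid) in self._map

    def get(self, nid: int, default: float | None = None) -> float | None:
        return self._map.get(int(nid), default)

    def reindex(self, ids: Iterable[int]) -> np.ndarray:
        """Values in the order of the given ids; KeyError names missing ids."""
        ids = list(ids)
        out = np.empty(len(ids))
        for k, n in enumerate(ids):
            if int(n) not in self._map:
                raise KeyError(f"node {int(n)} has no field value")
            out[k] = self._map[int(n)]
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "NodalScalarField":
        ids = np.asarray(sorted(mapping), dtype=np.int64)
        return cls(ids, np.asarray([mapping[int(i)] for i in ids]))


@dataclass
class LandmarkSet:
    """Ordered, labelled 3D control points (mm)."""

    labels: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(s) for s in self.labels]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise MeshError("landmark coords must be (n, 3) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise MeshError("landmark labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise MeshError("non-finite landmark coordinates")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, keep: Sequence[int]) -> "LandmarkSet":
        return LandmarkSet([self.labels[i] for i in keep], self.coords[list(keep)])

    def require_matched(self, other: "LandmarkSet") -> None:
        if self.labels != other.labels:
            raise MeshError("landmark sets are not matched label-for-label")


# ---------------------------------------------------------------------------
# Geometry


def _edge_counts(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0, return_counts=True)


def _orient_consistently(tris: np.ndarray) -> np.ndarray:
    """Flip triangle windings so neighbours traverse shared edges oppositely."""
    tris = tris.copy()
    edge_map: dict[tuple[int, int], list[int]] = {}
    for t, (a, b, c) in enumerate(tris):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_map.setdefault((min(u, v), max(u, v)), []).append(t)
    n = len(tris)
    seen = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        while stack:
            t = stack.pop()
            a, b, c = tris[t]
            for u, v in ((a, b), (b, c), (c, a)):
                for t2 in edge_map[(min(u, v), max(u, v))]:
                    if t2 == t or seen[t2]:
                        continue
                    a2, b2, c2 = tris[t2]
                    # consistent if t2 contains the directed edge (v, u)
                    directed = ((a2, b2), (b2, c2), (c2, a2))
                    if (u, v) in directed:
                        tris[t2] = tris[t2][::-1]
                    seen[t2] = True
                    stack.append(t2)
    return tris


def _signed_volume(coords: np.ndarray, tris: np.ndarray) -> float:
    v0, v1, v2 = coords[tris[:, 0]], coords[tris[:, 1]], coords[tris[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def vertex_normals(
    mesh: SurfaceMesh,
    weighting: str = "area",
    outward_hints: np.ndarray | None = None,
) -> NodalVectorField:
    """Outward unit normal at every node lying on a face.

    Each normal is the weighted average of incident face normals
    (area-weighted by default, ``weighting="angle"`` for incident-angle
    weights), normalised to unit length.  Faces are re-oriented outward
    first: against per-face ``outward_hints`` when given (e.g. the
    element-centroid-to-face-centroid directions of a solid layer), else by
    propagating a consistent winding and fixing the global sign with the
    signed volume (closed surfaces) or the mean outward projection.
    """
    if weighting not in ("area", "angle"):
        raise ValueError(f"unknown weighting {weighting!r}")
    tris, parent = mesh.triangles()
    if len(tris) == 0:
        raise MeshError("mesh has no faces")
    if outward_hints is not None:
        hints = np.asarray(outward_hints, dtype=float)
        fn = np.cross(
            mesh.coords[tris[:, 1]] - mesh.coords[tris[:, 0]],
            mesh.coords[tris[:, 2]] - mesh.coords[tris[:, 0]],
        )
        flip = np.einsum("ij,ij->i", fn, hints[parent]) < 0
        tris[flip] = tris[flip][:, ::-1]
    else:
        tris = _orient_consistently(tris)
        vol = _signed_volume(mesh.coords, tris)
        scale = float(np.abs(mesh.coords - mesh.coords.mean(0)).max()) or 1.0
        if abs(vol) > 1e-9 * scale**3:
            if vol < 0:
                tris = tris[:, ::-1]
        else:
            # open surface: fix sign by mean outward projection (no-op when
            # the projection is itself zero, e.g. a flat sheet)
            fn = np.cross(
                mesh.coords[tris[:, 1]] - mesh.coords[tris[:, 0]],
                mesh.coords[tris[:, 2]] - mesh.coords[tris[:, 0]],
            )
            fc = mesh.coords[tris].mean(axis=1)
            s = float(np.einsum("ij,ij->i", fn, fc - mesh.coords.mean(0)).sum())
            if s < 0:
                tris = tris[:, ::-1]

    v0, v1, v2 = mesh.coords[tris[:, 0]], mesh.coords[tris[:, 1]], mesh.coords[tris[:, 2]]
    face_cross = np.cross(v1 - v0, v2 - v0)  # |.| = 2 * area

    acc = np.zeros_like(mesh.coords)
    if weighting == "area":
        np.add.at(acc, tris[:, 0], face_cross)
        np.add.at(acc, tris[:, 1], face_cross)
        np.add.at(acc, tris[:, 2], face_cross)
    else:
        norms = np.linalg.norm(face_cross, axis=1, keepdims=True)
        unit = np.divide(face_cross, norms, out=np.zeros_like(face_cross), where=norms > 0)
        for corner in range(3):
            p = mesh.coords[tris[:, corner]]
            q = mesh.coords[tris[:, (corner + 1) % 3]]
            r = mesh.coords[tris[:, (corner + 2) % 3]]
            u, w = q - p, r - p
            cosang = np.einsum("ij,ij->i", u, w) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(acc, tris[:, corner], unit * ang[:, None])

    on_face = np.zeros(mesh.n_nodes, dtype=bool)
    on_face[tris.ravel()] = True
    norms = np.linalg.norm(acc, axis=1)
    bad = on_face & (norms <= 1e-300)
    if np.any(bad):
        raise MeshError(
            f"degenerate (zero-area) vertex star at node(s) "
            f"{mesh.node_ids[bad][:5].tolist()}"
        )
    normals = np.full_like(acc, np.nan)
    normals[on_face] = acc[on_face] / norms[on_face, None]
    return NodalVectorField(mesh.node_ids[on_face], normals[on_face])


@dataclass
class NodalVectorField:
    """One 3-vector per node on a stated node subset."""

    node_ids: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (self.node_ids.size, 3):
            raise MeshError("vector field shape mismatch")
        self._map = {int(i): k for k, i in enumerate(self.node_ids)}

    def __getitem__(self, nid: int) -> np.ndarray:
        return self.vectors[self._map[int(nid)]]

    def __contains__(self, nid: int) -> bool:
        return int(nid) in self._map


def node_adjacency(mesh: SurfaceMesh) -> dict[int, list[int]]:
    """Edge neighbours of every node, as sorted node-id lists.

    Quads are split into two triangles first, so the split diagonal counts
    as an edge.  The relation is symmetric and self-loop free.
    """
    tris, _ = mesh.triangles()
    adj: dict[int, set[int]] = {int(i): set() for i in mesh.node_ids}
    ids = mesh.node_ids
    for a, b, c in tris:
        ia, ib, ic = int(ids[a]), int(ids[b]), int(ids[c])
        adj[ia].update((ib, ic))
        adj[ib].update((ia, ic))
        adj[ic].update((ia, ib))
    return {n: sorted(s) for n, s in adj.items()}
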