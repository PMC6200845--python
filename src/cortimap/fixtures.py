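"""Synthetic two-surface shells with known ground truth.

The real application transfers cortical thickness between proprietary
anatomical meshes; these generators stand in for them with closed
ellipsoidal shells whose thickness field, tessellation and source-target
deformation are all analytic, so every pipeline stage can be checked
against exact answers.

A fixture is an icosphere-tessellated sphere or ellipsoid carrying a
strictly positive analytic thickness field; the solid layer is built by
offsetting each outer node inward along the analytic surface normal and
extruding one pentahedral (wedge) element per triangle.  The matched
target is a differently tessellated copy of the same surface (seeded
random rotation of the icosphere and/or different refinement) pushed
through a known smooth deformation — affine, or a localized radial bulge
— which also supplies the matched landmark sets (farthest-point sampled)
and the ground-truth deformed coordinates.  Optional landmark noise and a
single injected outlier emulate imperfect hand-picked anatomical points.

All randomness is driven by the spec seed; identical specs produce
byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .mesh import LandmarkSet, MeshError, SolidShellLayer, SurfaceMesh


# ---------------------------------------------------------------------------
# Icosphere


def icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: (vertices, faces) with 10*4^level + 2 vertices and
    20*4^level triangles."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.intp,
    )
    for _ in range(level):
        verts_list = [tuple(v) for v in verts]
        cache: dict[tuple[int, int], int] = {}
        new_faces = []

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (verts[a] + verts[b]) / 2.0
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(tuple(m))
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.asarray(verts_list, dtype=float)
        faces = np.asarray(new_faces, dtype=np.intp)
    return verts, faces


# ---------------------------------------------------------------------------
# Fixture spec


@dataclass
class FixtureSpec:
    """Recipe for a synthetic source shell and matched target surface.

    Defaults model a thin anatomical shell at roughly hip-bone scale: a
    100 x 80 x 120 mm ellipsoid whose wall thickness varies smoothly
    between 1 and 2 mm with latitude, a target of different tessellation
    related to the source by a gentle localized bulge, and 24 well-spread
    landmarks.
    """

    kind: str = "ellipsoid"                 # "sphere" | "ellipsoid"
    semi_axes: tuple[float, float, float] = (50.0, 40.0, 60.0)  # mm
    level: int = 2                          # icosphere subdivisions (source)
    thickness: str = "latitudinal"          # "constant" | "latitudinal" | "bumps"
    thickness_params: dict = dc_field(
        default_factory=lambda: {"t0": 1.5, "t1": 0.5}
    )
    deformation: str = "bulge"              # "identity" | "affine" | "bulge"
    deformation_params: dict = dc_field(
        default_factory=lambda: {"amplitude": 0.2, "width": 0.8, "scale": 0.9}
    )
    target_level: int | None = None         # None -> same as source level
    target_rotate: bool = True              # seeded rotation of target tessellation
    n_landmarks: int = 24
    noise_sd: float = 0.0                   # mm, on target landmarks
    outlier: tuple[int, float] | None = None  # (landmark index, offset mm)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.kind == "sphere":
            r = float(self.semi_axes[0])
            self.semi_axes = (r, r, r)
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.n_landmarks < 5:
            raise ValueError("need at least 5 landmarks")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# thickness fields, defined on the unit sphere direction u --------------------


def thickness_function(spec: FixtureSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Strictly positive analytic thickness field t(u) on unit directions."""
    p = spec.thickness_params
    if spec.thickness == "constant":
        t0 = float(p.get("t0", 1.5))

        def f(u: np.ndarray) -> np.ndarray:
            u = np.atleast_2d(u)
            return np.full(u.shape[0], t0)

    elif spec.thickness == "latitudinal":
        t0, t1 = float(p.get("t0", 1.5)), float(p.get("t1", 0.5))

        def f(u: np.ndarray) -> np.ndarray:
            u = np.atleast_2d(u)
            return t0 + t1 * u[:, 2]  # cos(theta) on the unit sphere

    elif spec.thickness == "bumps":
        t0 = float(p.get("t0", 1.5))
        amp = float(p.get("amplitude", 0.6))
        width = float(p.get("width", 0.5))
        n_bumps = int(p.get("n_bumps", 3))
        rng = np.random.default_rng(spec.seed + 101)
        centers = rng.normal(size=(n_bumps, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)

        def f(u: np.ndarray) -> np.ndarray:
            u = np.atleast_2d(u)
            ang = np.arccos(np.clip(u @ centers.T, -1.0, 1.0))
            return t0 + amp * np.exp(-(ang**2) / (2 * width**2)).sum(axis=1)

    else:
        raise ValueError(f"unknown thickness function {spec.thickness!r}")

    def positive(u: np.ndarray) -> np.ndarray:
        t = f(u)
        if np.any(t <= 0):
            raise MeshError("thickness function is not strictly positive")
        return t

    return positive


def surface_points(spec: FixtureSpec, u: np.ndarray) -> np.ndarray:
    """Map unit directions to the fixture surface."""
    return np.atleast_2d(u) * np.asarray(spec.semi_axes)


def surface_normals(spec: FixtureSpec, u: np.ndarray) -> np.ndarray:
    """Analytic outward unit normals at surface points with direction u."""
    a, b, c = spec.semi_axes
    x = surface_points(spec, u)
    n = x / np.square([a, b, c])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def analytic_thickness_at(spec: FixtureSpec, points: np.ndarray) -> np.ndarray:
    """Analytic thickness at arbitrary points on (or near) the surface."""
    u = np.atleast_2d(points) / np.asarray(spec.semi_axes)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    return thickness_function(spec)(u)


# ---------------------------------------------------------------------------
# Solid shell


def make_solid_shell(
    spec: FixtureSpec,
) -> tuple[SolidShellLayer, Callable[[np.ndarray], np.ndarray]]:
    """Build the source solid layer and return it with the analytic field.

    Outer nodes get ids 1..N, their paired inner nodes N+1..2N; one wedge
    element is extruded per surface triangle, inner triangle first (so the
    wedge column ``i <-> i+3`` is the inner/outer pairing).
    """
    u, faces = icosphere(spec.level)
    tfun = thickness_function(spec)
    t = tfun(u)
    min_curv_radius = min(spec.semi_axes) ** 2 / max(spec.semi_axes)
    if t.max() >= min_curv_radius:
        raise MeshError(
            f"thickness {t.max():g} mm exceeds the minimum radius of "
            f"curvature {min_curv_radius:g} mm; inner surface would self-intersect"
        )
    outer = surface_points(spec, u)
    inner = outer - surface_normals(spec, u) * t[:, None]
    n = u.shape[0]
    node_ids = np.arange(1, 2 * n + 1)
    coords = np.vstack([outer, inner])
    elements = []
    for a, b, c in faces:
        elements.append(
            (int(a) + n + 1, int(b) + n + 1, int(c) + n + 1,
             int(a) + 1, int(b) + 1, int(c) + 1)
        )
    layer = SolidShellLayer(
        node_ids,
        coords,
        elements,
        outer_surface_nodes=frozenset(range(1, n + 1)),
        inner_surface_nodes=frozenset(range(n + 1, 2 * n + 1)),
    )

    def analytic(points: np.ndarray) -> np.ndarray:
        return analytic_thickness_at(spec, points)

    return layer, analytic


# ---------------------------------------------------------------------------
# Deformations


def deformation_function(spec: FixtureSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Seeded smooth deformation of the fixture surface (mm -> mm)."""
    p = spec.deformation_params
    if spec.deformation == "identity":
        return lambda x: np.atleast_2d(np.asarray(x, dtype=float)).copy()
    if spec.deformation == "affine":
        rng = np.random.default_rng(spec.seed + 202)
        A = np.eye(3) + rng.normal(scale=float(p.get("shear", 0.08)), size=(3, 3))
        A *= float(p.get("scale", 0.9))
        c = rng.normal(scale=float(p.get("translation", 15.0)), size=3)

        def affine(x: np.ndarray) -> np.ndarray:
            return np.atleast_2d(np.asarray(x, dtype=float)) @ A.T + c

        return affine
    if spec.deformation == "bulge":
        amp = float(p.get("amplitude", 0.2))
        width = float(p.get("width", 0.8))
        scale = float(p.get("scale", 0.9))
        rng = np.random.default_rng(spec.seed + 203)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)

        def bulge(x: np.ndarray) -> np.ndarray:
            x = np.atleast_2d(np.asarray(x, dtype=float))
            r = np.linalg.norm(x, axis=1, keepdims=True)
            xhat = np.divide(x, r, out=np.zeros_like(x), where=r > 0)
            ang = np.arccos(np.clip(xhat @ d, -1.0, 1.0))[:, None]
            factor = scale * (1.0 + amp * np.exp(-(ang**2) / (2 * width**2)))
            return x * factor

        return bulge
    raise ValueError(f"unknown deformation {spec.deformation!r}")


# ---------------------------------------------------------------------------
# Target pair and landmarks


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def farthest_point_indices(points: np.ndarray, k: int) -> list[int]:
    """Deterministic farthest-point sampling, seeded at the max-z point."""
    pts = np.asarray(points, dtype=float)
    chosen = [int(np.argmax(pts[:, 2]))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return chosen


@dataclass
class TargetPair:
    """Target surface plus matched landmarks and ground truth."""

    target_mesh: SurfaceMesh              # deformed, differently tessellated
    landmarks_source: LandmarkSet
    landmarks_target: LandmarkSet
    gt_target_preimage: np.ndarray        # target nodes before deformation
    deform: Callable[[np.ndarray], np.ndarray]

    def gt_morphed_source(self, source_points: np.ndarray) -> np.ndarray:
        """Ground-truth images of source points under the true deformation."""
        return self.deform(source_points)


def make_target_pair(spec: FixtureSpec) -> TargetPair:
    """Build the deformed, re-tessellated target and matched landmark sets.

    The target tessellation is an icosphere at ``target_level`` (default:
    the source level), optionally rotated by a seeded random rotation so
    its nodes do not coincide with the source's, mapped to the fixture
    surface and pushed through the spec deformation.  Landmarks are
    farthest-point-sampled source outer nodes; their target-frame
    positions are the true deformation images, optionally perturbed by
    Gaussian noise and a single large outlier offset.
    """
    rng = spec.rng()
    level = spec.target_level if spec.target_level is not None else spec.level
    u, faces = icosphere(level)
    if spec.target_rotate:
        u = u @ _rotation_matrix(np.random.default_rng(spec.seed + 304)).T
    pre = surface_points(spec, u)
    deform = deformation_function(spec)
    tgt_coords = deform(pre)
    target_mesh = SurfaceMesh(
        np.arange(1, u.shape[0] + 1),
        tgt_coords,
        [tuple(int(i) + 1 for i in f) for f in faces],
    )

    us, _ = icosphere(spec.level)
    src_pts = surface_points(spec, us)
    lm_idx = farthest_point_indices(src_pts, spec.n_landmarks)
    labels = [f"L{k:03d}" for k in range(spec.n_landmarks)]
    lm_src = src_pts[lm_idx]
    lm_tgt = deform(lm_src)
    if spec.noise_sd > 0:
        lm_tgt = lm_tgt + np.random.default_rng(spec.seed + 405).normal(
            scale=spec.noise_sd, size=lm_tgt.shape
        )
    if spec.outlier is not None:
        idx, offset = spec.outlier
        direction = np.random.default_rng(spec.seed + 506).normal(size=3)
        direction /= np.linalg.norm(direction)
        lm_tgt = lm_tgt.copy()
        lm_tgt[int(idx)] += float(offset) * direction
    return TargetPair(
        target_mesh,
        LandmarkSet(labels, lm_src),
        LandmarkSet(labels, lm_tgt),
        pre,
        deform,
    )


# ---------------------------------------------------------------------------
# File emission (CLI)


def write_fixture_files(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Emit the fixture as keyword meshes, landmark CSVs and a manifest."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layer, analytic = make_solid_shell(spec)
    pair = make_target_pair(spec)
    cio.write_lsdyna(layer, outdir / "source_shell.k")
    cio.write_lsdyna(pair.target_mesh, outdir / "target_surface.k")
    cio.write_landmarks(pair.landmarks_source, outdir / "landmarks_source.csv")
    cio.write_landmarks(pair.landmarks_target, outdir / "landmarks_target.csv")
    out_ids = sorted(layer.outer_surface_nodes)
    out_xyz = layer.coords[layer.index_of(out_ids)]
    from .mesh import NodalScalarField

    cio.write_thickness_csv(
        NodalScalarField(np.asarray(out_ids), analytic(out_xyz)),
        outdir / "analytic_thickness.csv",
    )
    manifest = {"spec": _spec_dict(spec), "files": [
        "source_shell.k", "target_surface.k", "landmarks_source.csv",
        "landmarks_target.csv", "analytic_thickness.csv",
    ]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _spec_dict(spec: FixtureSpec) -> dict:
    d = asdict(spec)
    d["semi_axes"] = list(d["semi_axes"])
    if d["outlier"] is not None:
        d["outlier"] = list(d["outlier"])
    return d
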