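"""Readers and writers for the supported mesh and table formats.

LS-Dyna keyword files (``*NODE``, ``*ELEMENT_SOLID``, ``*ELEMENT_SHELL``,
``*ELEMENT_SHELL_THICKNESS``) are parsed natively, accepting both the
8/16-column fixed-width layout and free-format comma-separated cards;
output is written comma-separated with shortest-round-trip floats so a
write/read cycle is lossless.  Legacy-ASCII VTK POLYDATA and Wavefront OBJ
cover surface interchange; landmark tables are CSV with a
``label,x,y,z`` header.

Pentahedral (wedge) solids follow the keyword convention of a degenerate
hexahedron ``n1 n2 n3 n3 n4 n5 n6 n6``; they are canonicalised to 6-node
tuples on read.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import (
    MeshError,
    NodalScalarField,
    LandmarkSet,
    SolidShellLayer,
    SurfaceMesh,
)


class ParseError(MeshError):
    """Malformed input file; message carries the path and line number."""


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the double exactly."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# LS-Dyna keyword


def _card_fields(line: str, widths: tuple[int, ...]) -> list[str]:
    """Split a card into tokens: comma-separated if a comma is present,
    otherwise by the given fixed column widths."""
    if "," in line:
        return [t.strip() for t in line.rstrip("\n").split(",")]
    out, pos = [], 0
    line = line.rstrip("\n")
    for w in widths:
        if pos >= len(line):
            break
        out.append(line[pos:pos + w].strip())
        pos += w
    return out


def _iter_cards(path: Path):
    """Yield (lineno, stripped_line) for data/keyword lines, skipping
    ``$`` comments and blanks."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("$"):
                continue
            yield lineno, line


def _canonical_solid(nodes: list[int], path: Path, lineno: int) -> tuple[int, ...]:
    nodes = [n for n in nodes if n != 0]
    if len(nodes) == 8:
        if nodes[2] == nodes[3] and nodes[6] == nodes[7]:
            # degenerate hexa -> wedge (n1 n2 n3 | n5 n6 n7)
            return (nodes[0], nodes[1], nodes[2], nodes[4], nodes[5], nodes[6])
        if len(set(nodes)) != 8:
            raise ParseError(
                f"{path}:{lineno}: unsupported degenerate solid element {nodes}"
            )
        return tuple(nodes)
    if len(nodes) == 6:
        return tuple(nodes)
    raise ParseError(
        f"{path}:{lineno}: solid element with {len(nodes)} nodes unsupported"
    )


def read_lsdyna(path: str | Path) -> SurfaceMesh | SolidShellLayer:
    """Read a keyword file into a surface mesh or a solid shell layer.

    A file containing ``*ELEMENT_SOLID`` cards yields a
    :class:`SolidShellLayer` (inner/outer skins derived from topology);
    one containing only shell cards yields a :class:`SurfaceMesh`.
    """
    path = Path(path)
    node_ids: list[int] = []
    coords: list[tuple[float, float, float]] = []
    solids: list[tuple[int, ...]] = []
    shells: list[tuple[int, ...]] = []
    section = None
    pending_thickness = None  # state within *ELEMENT_SHELL_THICKNESS
    for lineno, line in _iter_cards(path):
        if line.startswith("*"):
            section = line.strip().upper()
            pending_thickness = None
            if section == "*END":
                break
            continue
        try:
            if section == "*NODE":
                f = _card_fields(line, (8, 16, 16, 16))
                node_ids.append(int(f[0]))
                coords.append((float(f[1]), float(f[2]), float(f[3])))
            elif section == "*ELEMENT_SOLID":
                f = _card_fields(line, (8,) * 10)
                nodes = [int(t) for t in f[2:10] if t]
                solids.append(_canonical_solid(nodes, path, lineno))
            elif section in ("*ELEMENT_SHELL", "*ELEMENT_SHELL_THICKNESS"):
                if section == "*ELEMENT_SHELL_THICKNESS" and pending_thickness:
                    pending_thickness = None  # thickness card, consumed elsewhere
                    continue
                f = _card_fields(line, (8,) * 6)
                nodes = [int(t) for t in f[2:6] if t]
                nodes = [n for n in nodes if n != 0]
                if len(nodes) == 4 and nodes[3] == nodes[2]:
                    nodes = nodes[:3]
                shells.append(tuple(nodes))
                if section == "*ELEMENT_SHELL_THICKNESS":
                    pending_thickness = True
            elif section is None:
                raise ValueError("data before any keyword card")
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed card ({exc})") from exc
    if not node_ids:
        raise ParseError(f"{path}: no *NODE card found")
    ids = np.asarray(node_ids)
    xyz = np.asarray(coords)
    if solids:
        if shells:
            raise ParseError(f"{path}: mixed solid and shell elements unsupported")
        return SolidShellLayer(ids, xyz, solids)
    return SurfaceMesh(ids, xyz, shells)


def write_lsdyna(mesh: SurfaceMesh | SolidShellLayer, path: str | Path) -> None:
    """Write a mesh as comma-separated keyword cards (part id 1)."""
    path = Path(path)
    lines = ["*KEYWORD", "*NODE"]
    for nid, (x, y, z) in zip(mesh.node_ids, mesh.coords):
        lines.append(f"{int(nid)},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    if isinstance(mesh, SolidShellLayer):
        lines.append("*ELEMENT_SOLID")
        for eid, e in enumerate(mesh.elements, start=1):
            if len(e) == 6:
                n = (e[0], e[1], e[2], e[2], e[3], e[4], e[5], e[5])
            else:
                n = e
            lines.append(f"{eid},1," + ",".join(str(i) for i in n))
    else:
        lines.append("*ELEMENT_SHELL")
        for eid, f in enumerate(mesh.faces, start=1):
            n = list(f) + [f[2]] * (4 - len(f))
            lines.append(f"{eid},1," + ",".join(str(i) for i in n))
    lines.append("*END")
    path.write_text("\n".join(lines) + "\n")


def write_shell_thickness(
    mesh: SurfaceMesh, field: NodalScalarField, path: str | Path
) -> None:
    """Write ``*ELEMENT_SHELL_THICKNESS`` cards carrying per-node thickness.

    Each element gets two cards: connectivity, then the nodal thickness at
    each of its corners.  Values are written with full precision (well
    beyond 6 significant digits).  A node referenced by a face but missing
    from the field raises a :class:`MeshError` naming the node.
    """
    path = Path(path)
    for f in mesh.faces:
        for n in f:
            if n not in field:
                raise MeshError(f"node {n} has no thickness value")
    lines = ["*KEYWORD", "*NODE"]
    for nid, (x, y, z) in zip(mesh.node_ids, mesh.coords):
        lines.append(f"{int(nid)},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    lines.append("*ELEMENT_SHELL_THICKNESS")
    for eid, f in enumerate(mesh.faces, start=1):
        n = list(f) + [f[2]] * (4 - len(f))
        t = [field[i] for i in n]
        lines.append(f"{eid},1," + ",".join(str(i) for i in n))
        lines.append(",".join(_fmt(v) for v in t))
    lines.append("*END")
    path.write_text("\n".join(lines) + "\n")


def read_shell_thickness(path: str | Path) -> tuple[SurfaceMesh, NodalScalarField]:
    """Read back a shell mesh with per-node thickness cards."""
    path = Path(path)
    node_ids: list[int] = []
    coords: list[tuple[float, float, float]] = []
    faces: list[tuple[int, ...]] = []
    thick: dict[int, float] = {}
    section = None
    pending: list[int] | None = None
    for lineno, line in _iter_cards(path):
        if line.startswith("*"):
            section = line.strip().upper()
            pending = None
            if section == "*END":
                break
            continue
        try:
            if section == "*NODE":
                f = _card_fields(line, (8, 16, 16, 16))
                node_ids.append(int(f[0]))
                coords.append((float(f[1]), float(f[2]), float(f[3])))
            elif section == "*ELEMENT_SHELL_THICKNESS":
                if pending is None:
                    f = _card_fields(line, (8,) * 6)
                    nodes = [int(t) for t in f[2:6] if t and int(t) != 0]
                    pending = nodes
                else:
                    f = _card_fields(line, (16,) * 4)
                    vals = [float(t) for t in f if t]
                    for n, v in zip(pending, vals):
                        if n in thick and abs(thick[n] - v) > 1e-12 * max(1.0, abs(v)):
                            raise ValueError(
                                f"conflicting thickness at node {n}: {thick[n]} vs {v}"
                            )
                        thick[n] = v
                    nodes = pending
                    if len(nodes) == 4 and nodes[3] == nodes[2]:
                        nodes = nodes[:3]
                    faces.append(tuple(nodes))
                    pending = None
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed card ({exc})") from exc
    mesh = SurfaceMesh(np.asarray(node_ids), np.asarray(coords), faces)
    return mesh, NodalScalarField.from_mapping(thick)


# ---------------------------------------------------------------------------
# VTK legacy ASCII (POLYDATA) and OBJ


def read_vtk(path: str | Path) -> SurfaceMesh:
    """Minimal legacy-ASCII VTK POLYDATA surface reader."""
    path = Path(path)
    tokens: list[str] = []
    lines = path.read_text().splitlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise ParseError(f"{path}: not a legacy VTK file")
    for line in lines[2:]:
        tokens.extend(line.split())
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        while i < len(tokens) and tokens[i].upper() != word:
            i += 1
        if i >= len(tokens):
            raise ParseError(f"{path}: missing {word} section")
        i += 1

    expect("POINTS")
    npts = int(tokens[i]); i += 2  # skip dtype
    coords = np.asarray(tokens[i:i + 3 * npts], dtype=float).reshape(npts, 3)
    i += 3 * npts
    expect("POLYGONS")
    ncell = int(tokens[i]); i += 2  # skip size field
    faces = []
    for _ in range(ncell):
        k = int(tokens[i]); i += 1
        faces.append(tuple(int(tokens[i + j]) + 1 for j in range(k)))
        i += k
    ids = np.arange(1, npts + 1)
    return SurfaceMesh(ids, coords, faces)


def write_vtk(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    idx = {int(n): k for k, n in enumerate(mesh.node_ids)}
    lines = [
        "# vtk DataFile Version 3.0",
        "cortimap surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y, z in mesh.coords:
        lines.append(f"{_fmt(x)} {_fmt(y)} {_fmt(z)}")
    size = sum(len(f) + 1 for f in mesh.faces)
    lines.append(f"POLYGONS {mesh.n_faces} {size}")
    for f in mesh.faces:
        lines.append(f"{len(f)} " + " ".join(str(idx[n]) for n in f))
    path.write_text("\n".join(lines) + "\n")


def read_obj(path: str | Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="obj", process=False, force="mesh")
    ids = np.arange(1, len(tm.vertices) + 1)
    faces = [tuple(int(v) + 1 for v in f) for f in tm.faces]
    return SurfaceMesh(ids, np.asarray(tm.vertices, dtype=float), faces)


def write_obj(mesh: SurfaceMesh, path: str | Path) -> None:
    idx = {int(n): k + 1 for k, n in enumerate(mesh.node_ids)}
    lines = [f"v {_fmt(x)} {_fmt(y)} {_fmt(z)}" for x, y, z in mesh.coords]
    for f in mesh.faces:
        lines.append("f " + " ".join(str(idx[n]) for n in f))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dispatch


_EXT = {".k": "lsdyna_keyword", ".key": "lsdyna_keyword", ".dyn": "lsdyna_keyword",
        ".vtk": "vtk", ".obj": "obj"}


def read_mesh(path: str | Path, format: str | None = None):
    """Read a mesh, dispatching on ``format`` or the file extension."""
    path = Path(path)
    fmt = format or _EXT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer mesh format from {path.name!r}")
    if fmt == "lsdyna_keyword":
        return read_lsdyna(path)
    if fmt == "vtk":
        return read_vtk(path)
    if fmt == "obj":
        return read_obj(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def write_mesh(mesh, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _EXT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer mesh format from {path.name!r}")
    if fmt == "lsdyna_keyword":
        write_lsdyna(mesh, path)
    elif fmt == "vtk":
        write_vtk(mesh, path)
    elif fmt == "obj":
        write_obj(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# Tables


def read_landmarks(path: str | Path) -> LandmarkSet:
    """CSV with header ``label,x,y,z``."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"label", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: landmark CSV must have columns label,x,y,z")
    return LandmarkSet(df["label"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy(float))


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "x", "y", "z"])
        for lab, (x, y, z) in zip(lm.labels, lm.coords):
            w.writerow([lab, _fmt(x), _fmt(y), _fmt(z)])


def read_thickness_csv(path: str | Path) -> NodalScalarField:
    df = pd.read_csv(path, float_precision="round_trip")
    return NodalScalarField(df["node_id"].to_numpy(np.int64),
                            df["thickness_mm"].to_numpy(float))


def write_thickness_csv(field: NodalScalarField, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "thickness_mm"])
        for nid, v in zip(field.node_ids, field.values):
            w.writerow([int(nid), _fmt(v)])
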