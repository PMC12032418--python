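"""Minimal Gmsh ``.msh`` reader/writer for triangulated surfaces.

Supports the ASCII MSH 2.2 and 4.1 formats with three-noded triangles
(element type 2).  The region label travels as a physical-group name where
the format allows.  Anything non-triangular (e.g. quads, type 3) is
rejected, as are binary files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_msh", "write_msh"]


def _section(lines: list[str], name: str) -> list[str]:
    try:
        start = lines.index(f"${name}") + 1
        end = lines.index(f"$End{name}")
    except ValueError as exc:
        raise _err(f"missing ${name} section") from exc
    return lines[start:end]


def _err(msg: str):
    from uteroacoustics.phantom import MeshFormatError

    return MeshFormatError(f"Gmsh: {msg}")


def read_msh(path):
    """Read a triangle surface mesh from an ASCII .msh file (v2.2 or v4.1)."""
    from uteroacoustics.phantom import SurfaceMesh

    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    fmt = _section(lines, "MeshFormat")[0].split()
    version, is_binary = fmt[0], int(fmt[1])
    if is_binary:
        raise _err("binary files are not supported")

    label = ""
    if "$PhysicalNames" in lines:
        rows = _section(lines, "PhysicalNames")[1:]
        for row in rows:
            parts = row.split(maxsplit=2)
            if len(parts) == 3 and int(parts[0]) == 2:
                label = parts[2].strip().strip('"')
                break

    if version.startswith("2"):
        verts, tris = _read_v2(lines)
    elif version.startswith("4"):
        verts, tris = _read_v4(lines)
    else:
        raise _err(f"unsupported MSH version {version}")
    return SurfaceMesh(verts, tris, region_label=label)


def _read_v2(lines):
    node_rows = _section(lines, "Nodes")
    n = int(node_rows[0])
    ids = np.empty(n, dtype=np.int64)
    verts = np.empty((n, 3))
    for i, row in enumerate(node_rows[1:1 + n]):
        p = row.split()
        ids[i] = int(p[0])
        verts[i] = [float(p[1]), float(p[2]), float(p[3])]
    remap = {int(t): i for i, t in enumerate(ids)}

    elem_rows = _section(lines, "Elements")
    m = int(elem_rows[0])
    tris = []
    for row in elem_rows[1:1 + m]:
        p = row.split()
        etype = int(p[1])
        if etype in (15, 1):  # points / lines: ignore
            continue
        if etype != 2:
            raise _err(f"non-triangular element type {etype}")
        ntags = int(p[2])
        conn = [remap[int(t)] for t in p[3 + ntags:6 + ntags]]
        tris.append(conn)
    if not tris:
        raise _err("no triangles found")
    return verts, np.asarray(tris, dtype=np.int64)


def _read_v4(lines):
    node_rows = _section(lines, "Nodes")
    header = node_rows[0].split()
    nblocks, nnodes = int(header[0]), int(header[1])
    ids = []
    coords = []
    i = 1
    for _ in range(nblocks):
        _, _, parametric, count = (int(v) for v in node_rows[i].split())
        i += 1
        block_ids = [int(node_rows[i + j]) for j in range(count)]
        i += count
        for j in range(count):
            coords.append([float(v) for v in node_rows[i + j].split()[:3]])
        i += count
        ids.extend(block_ids)
    if len(ids) != nnodes:
        raise _err("node count mismatch")
    remap = {t: i for i, t in enumerate(ids)}
    verts = np.asarray(coords)

    elem_rows = _section(lines, "Elements")
    header = elem_rows[0].split()
    nblocks = int(header[0])
    tris = []
    i = 1
    for _ in range(nblocks):
        _, _, etype, count = (int(v) for v in elem_rows[i].split())
        i += 1
        if etype in (15, 1):
            i += count
            continue
        if etype != 2:
            raise _err(f"non-triangular element type {etype}")
        for j in range(count):
            p = elem_rows[i + j].split()
            tris.append([remap[int(t)] for t in p[1:4]])
        i += count
    if not tris:
        raise _err("no triangles found")
    return verts, np.asarray(tris, dtype=np.int64)


def write_msh(mesh, path) -> None:
    """Write MSH 2.2 ASCII with the region label as a physical-group name."""
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    if mesh.region_label:
        out += ["$PhysicalNames", "1", f'2 1 "{mesh.region_label}"', "$EndPhysicalNames"]
    out += ["$Nodes", str(len(mesh.vertices))]
    out += [
        f"{i + 1} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
        for i, v in enumerate(mesh.vertices)
    ]
    out += ["$EndNodes", "$Elements", str(len(mesh.triangles))]
    out += [
        f"{i + 1} 2 2 1 1 {t[0] + 1} {t[1] + 1} {t[2] + 1}"
        for i, t in enumerate(mesh.triangles)
    ]
    out += ["$EndElements", ""]
    Path(path).write_text("\n".join(out))
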