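"""Readers and writers for the trajectory and table formats the pipeline uses.

Two trajectory formats are supported:

* **Extended multi-frame XYZ.**  Plain XYZ carries no box or time record, so
  the comment line of every frame holds them:
  ``box=Lx,Ly,Lz t=<fs> wrapped=<0|1>`` (the ``wrapped`` token is optional on
  read and defaults to 0).  Coordinates are written with 6 decimals.
* **LAMMPS text dump**, dialect ``ITEM: ATOMS id type x y z`` with an
  orthorhombic ``ITEM: BOX BOUNDS``.  Numeric atom types are mapped to
  species labels by a caller-supplied mapping, and atoms are re-ordered by id
  so particle identity is stable across frames.

Thermo tables travel as CSV with headers
``temperature_K, dG_solv_kJ_mol, density_g_cm3``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .core import (
    Frame,
    ParseError,
    PeriodicBox,
    ThermoTable,
    Trajectory,
    UnsupportedFormatError,
    ValidationError,
)

PathLike = Union[str, Path]

_COMMENT_RE = re.compile(
    r"box=(?P<bx>[-\d.eE+]+),(?P<by>[-\d.eE+]+),(?P<bz>[-\d.eE+]+)"
    r"\s+t=(?P<t>[-\d.eE+]+)"
    r"(?:\s+wrapped=(?P<w>[01]))?"
)


def read_xyz(path: PathLike) -> Trajectory:
    """Read a multi-frame extended XYZ file into a Trajectory."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    box: PeriodicBox | None = None
    n_expected: int | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected particle count, got {lines[i]!r}")
        if n_atoms < 1:
            raise ParseError(f"line {i + 1}: particle count must be >= 1")
        if n_expected is None:
            n_expected = n_atoms
        elif n_atoms != n_expected:
            raise ParseError(
                f"line {i + 1}: frame has {n_atoms} particles, previous frames had {n_expected}"
            )
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 2}: missing comment line")
        m = _COMMENT_RE.search(lines[i + 1])
        if m is None:
            raise ParseError(
                f"line {i + 2}: comment line must carry 'box=Lx,Ly,Lz t=<fs>', got {lines[i + 1]!r}"
            )
        frame_box = PeriodicBox((float(m["bx"]), float(m["by"]), float(m["bz"])))
        if box is None:
            box = frame_box
        elif not np.allclose(box.lengths, frame_box.lengths):
            raise ParseError(f"line {i + 2}: box changed between frames")
        time = float(m["t"])
        wrapped = m["w"] == "1"
        species: list[str] = []
        coords = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(f"line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'species x y z'")
            species.append(parts[0])
            try:
                coords[k] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"line {ln + 1}: non-numeric coordinate")
        frames.append(Frame(time=time, species=tuple(species), coordinates=coords, wrapped=wrapped))
        i += 2 + n_atoms
    if not frames or box is None:
        raise ParseError("file contains no frames")
    if len(frames) > 1:
        timestep = frames[1].time - frames[0].time
    else:
        timestep = 1.0
    return Trajectory(box=box, frames=frames, timestep=timestep)


def write_xyz(trajectory: Trajectory, path: PathLike) -> None:
    """Write a Trajectory as extended XYZ (6-decimal coordinates)."""
    bx, by, bz = trajectory.box.edge_lengths
    out: list[str] = []
    for fr in trajectory.frames:
        out.append(str(fr.n_particles))
        out.append(
            f"box={bx:.6f},{by:.6f},{bz:.6f} t={fr.time:.6f} wrapped={int(fr.wrapped)}"
        )
        for sp, (x, y, z) in zip(fr.species, fr.coordinates):
            out.append(f"{sp} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_lammps_dump(
    path: PathLike,
    type_map: Mapping[int, str],
    timestep_fs: float = 1.0,
    wrapped: bool = True,
) -> Trajectory:
    """Read a LAMMPS text dump (``id type x y z``) into a Trajectory.

    Parameters
    ----------
    type_map
        Numeric atom type -> species label; an unmapped type is an error.
    timestep_fs
        Physical time per dump TIMESTEP unit; frame times are step*timestep_fs.
    wrapped
        Whether dump coordinates are wrapped into the box (LAMMPS default).
    """
    lines = Path(path).read_text().splitlines()
    raw_frames: list[tuple[int, PeriodicBox, np.ndarray, np.ndarray, np.ndarray]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError(f"line {i + 1}: expected 'ITEM: TIMESTEP', got {lines[i]!r}")
        step = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(f"line {i + 3}: expected 'ITEM: NUMBER OF ATOMS'")
        n_atoms = int(lines[i + 3])
        bounds_header = lines[i + 4]
        if not bounds_header.startswith("ITEM: BOX BOUNDS"):
            raise ParseError(f"line {i + 5}: expected 'ITEM: BOX BOUNDS'")
        if any(t in bounds_header for t in ("xy", "xz", "yz")):
            raise UnsupportedFormatError(
                f"line {i + 5}: triclinic box bounds are not supported"
            )
        edges = []
        for k in range(3):
            lo, hi = (float(v) for v in lines[i + 5 + k].split()[:2])
            edges.append(hi - lo)
        box = PeriodicBox(tuple(edges))
        atoms_header = lines[i + 8]
        if not atoms_header.startswith("ITEM: ATOMS"):
            raise ParseError(f"line {i + 9}: expected 'ITEM: ATOMS'")
        cols = atoms_header.split()[2:]
        try:
            ci, ct = cols.index("id"), cols.index("type")
            cx, cy, cz = cols.index("x"), cols.index("y"), cols.index("z")
        except ValueError:
            raise UnsupportedFormatError(
                f"line {i + 9}: dump must provide columns id type x y z, got {cols}"
            )
        ids = np.empty(n_atoms, dtype=int)
        types = np.empty(n_atoms, dtype=int)
        coords = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            parts = lines[i + 9 + k].split()
            ids[k] = int(parts[ci])
            types[k] = int(parts[ct])
            coords[k] = [float(parts[cx]), float(parts[cy]), float(parts[cz])]
        raw_frames.append((step, box, ids, types, coords))
        i += 9 + n_atoms
    if not raw_frames:
        raise ParseError("dump contains no frames")

    raw_frames.sort(key=lambda f: f[0])
    frames: list[Frame] = []
    box0 = raw_frames[0][1]
    for step, box, ids, types, coords in raw_frames:
        order = np.argsort(ids, kind="stable")
        ids, types, coords = ids[order], types[order], coords[order]
        species = []
        for t in types:
            if int(t) not in type_map:
                raise ParseError(f"atom type {t} has no species mapping")
            species.append(type_map[int(t)])
        frames.append(
            Frame(
                time=step * timestep_fs,
                species=tuple(species),
                coordinates=coords,
                wrapped=wrapped,
            )
        )
    steps = [f[0] for f in raw_frames]
    dt = (steps[1] - steps[0]) * timestep_fs if len(steps) > 1 else timestep_fs
    return Trajectory(box=box0, frames=frames, timestep=dt)


def read_thermo_table(path: PathLike) -> ThermoTable:
    """Read a per-temperature ΔG_solv / density CSV into a validated ThermoTable."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty thermo table")
    if len(df) == 0:
        raise ValidationError(f"{path}: thermo table has headers but no rows")
    return ThermoTable(df)


def write_thermo_table(table: ThermoTable, path: PathLike) -> None:
    table.data.to_csv(path, index=False)
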