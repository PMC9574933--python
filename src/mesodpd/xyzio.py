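"""Extended-XYZ trajectory reader/writer.

Each frame is::

    <n_beads>
    box_edge=<L> shear_offset=<x> shear_rate=<g> time=<t> columns=species:x:y:z:vx:vy:vz:mol
    W 1.0 2.0 3.0 0.1 -0.2 0.0 17
    ...

Mandatory columns are species and x, y, z; velocity columns and the
molecule id are optional on read (zeros / fresh ids are substituted).
Floats are written with round-trip-exact shortest representations, so
a write/read cycle is bitwise lossless.  Frames are streamed, never
materialised all at once; paths ending in ``.gz`` are transparently
gzip-compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .system import Configuration

_FULL_COLUMNS = "species:x:y:z:vx:vy:vz:mol"


class TrajectoryFormatError(ValueError):
    pass


def write_trajectory(frames, path) -> None:
    """Write configurations as extended-XYZ (single frame or iterable)."""
    if isinstance(frames, Configuration):
        frames = [frames]
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for cfg in frames:
            fh.write(f"{len(cfg)}\n")
            fh.write(f"box_edge={float(cfg.box_edge)!r} "
                     f"shear_offset={float(cfg.shear_offset)!r} "
                     f"shear_rate={float(cfg.shear_rate)!r} "
                     f"time={float(cfg.time)!r} columns={_FULL_COLUMNS}\n")
            for s, p, v, m in zip(cfg.species, cfg.positions,
                                  cfg.velocities, cfg.molecule_id):
                fh.write(f"{s} {float(p[0])!r} {float(p[1])!r} "
                         f"{float(p[2])!r} {float(v[0])!r} {float(v[1])!r} "
                         f"{float(v[2])!r} {int(m)}\n")


def read_trajectory(path) -> Iterator[Configuration]:
    """Stream configurations from an extended-XYZ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lineno = 0
        frame = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                return
            header = header.strip()
            if not header:
                continue
            try:
                n = int(header)
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: expected bead count, got "
                    f"{header!r}") from exc
            comment = fh.readline()
            lineno += 1
            meta = {}
            for tok in comment.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            if "box_edge" not in meta:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: frame {frame} is missing the "
                    "box_edge metadata")
            columns = meta.get("columns", _FULL_COLUMNS).split(":")
            species = np.empty(n, dtype="<U8")
            pos = np.zeros((n, 3))
            vel = np.zeros((n, 3))
            mol = np.arange(n, dtype=np.int64)
            has_mol = "mol" in columns
            has_vel = "vx" in columns
            ncols = 4 + (3 if has_vel else 0) + (1 if has_mol else 0)
            for i in range(n):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise TrajectoryFormatError(
                        f"{path}:{lineno}: truncated frame {frame}")
                parts = line.split()
                if len(parts) < ncols:
                    raise TrajectoryFormatError(
                        f"{path}:{lineno}: truncated row in frame {frame}: "
                        f"expected {ncols} columns, got {len(parts)}")
                species[i] = parts[0]
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                k = 4
                if has_vel:
                    vel[i] = [float(parts[k]), float(parts[k + 1]),
                              float(parts[k + 2])]
                    k += 3
                if has_mol:
                    mol[i] = int(parts[k])
            yield Configuration(
                positions=pos, velocities=vel, species=species,
                molecule_id=mol, box_edge=float(meta["box_edge"]),
                shear_offset=float(meta.get("shear_offset", 0.0)),
                shear_rate=float(meta.get("shear_rate", 0.0)),
                time=float(meta.get("time", 0.0)))
            frame += 1
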