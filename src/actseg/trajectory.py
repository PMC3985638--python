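"""Text-first trajectory I/O: extended-XYZ frames plus CSV sidecars.

One frame per sample; the comment line carries the simulation time and the
confinement geometry; atom lines are ``<chromosome> x y z <monomer id>``.
Coordinates are written with 17 significant digits so a write/read round
trip reproduces them exactly.  The monomer table and loop set travel as CSV
sidecars next to the trajectory (``<stem>.monomers.csv``,
``<stem>.loops.csv``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genome_model import MonomerTable
from .loops import LoopSet
from .potentials import Geometry

__all__ = ["write_trajectory", "read_trajectory", "sidecar_paths"]


def sidecar_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    return p.with_suffix(".monomers.csv"), p.with_suffix(".loops.csv")


def _geometry_comment(geometry: Geometry | None) -> str:
    if geometry is None:
        return ""
    a, b, c = geometry.axes
    return (
        f" geometry={geometry.kind} R0={float(geometry.R0)!r}"
        f" axes={float(a)!r},{float(b)!r},{float(c)!r}"
    )


def write_trajectory(
    frames,
    table: MonomerTable,
    path: str | Path,
    times=None,
    geometry: Geometry | None = None,
    loops: LoopSet | None = None,
) -> None:
    """Write frames as extended-XYZ with the monomer-table CSV sidecar."""
    n = len(table)
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    for k, f in enumerate(frames):
        if f.shape != (n, 3):
            raise ValueError(
                f"frame {k} has shape {f.shape}, expected ({n}, 3) for this table"
            )
    if times is None:
        times = [float(k) for k in range(len(frames))]
    if len(times) != len(frames):
        raise ValueError("times and frames must have equal length")

    path = Path(path)
    geo = _geometry_comment(geometry)
    with open(path, "w") as fh:
        for t, f in zip(times, frames):
            fh.write(f"{n}\n")
            fh.write(f"time={float(t)!r}{geo}\n")
            for i in range(n):
                fh.write(
                    f"{table.chrom[i]} {float(f[i, 0])!r} {float(f[i, 1])!r} "
                    f"{float(f[i, 2])!r} {i}\n"
                )
    mono_csv, loops_csv = sidecar_paths(path)
    table.to_csv(mono_csv)
    if loops is not None:
        loops.to_csv(loops_csv)


def read_trajectory(path: str | Path):
    """Read an extended-XYZ trajectory back.

    Returns ``(frames, times, table)``; ``table`` is None when the CSV
    sidecar is absent.  A truncated file raises with the offending frame
    index.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    frame_idx = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k])
        except ValueError as exc:
            raise ValueError(f"frame {frame_idx}: bad atom-count line {lines[k]!r}") from exc
        if k + 1 + n >= len(lines) + 1 and k + 1 + n > len(lines):
            raise ValueError(f"truncated trajectory at frame {frame_idx}")
        comment = lines[k + 1]
        t = 0.0
        for tok in comment.split():
            if tok.startswith("time="):
                t = float(tok[5:])
        body = lines[k + 2 : k + 2 + n]
        if len(body) < n:
            raise ValueError(f"truncated trajectory at frame {frame_idx}")
        coords = np.empty((n, 3))
        for row, line in enumerate(body):
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(
                    f"frame {frame_idx}: malformed atom line {row}: {line!r}"
                )
            coords[int(parts[4])] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        frame_idx += 1
        k += 2 + n

    mono_csv, _ = sidecar_paths(path)
    table = MonomerTable.from_csv(mono_csv) if mono_csv.exists() else None
    return frames, times, table
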