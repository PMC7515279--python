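"""Streaming of coordinate + force trajectory frames.

Internal units are Å for coordinates and box edges and kJ mol⁻¹ Å⁻¹ for
forces.  Three formats are supported:

* ``plain`` — a self-describing text dialect: a header line
  ``natoms nframes bx by bz`` followed, frame by frame, by one line per
  atom ``x y z fx fy fz`` (Å, kJ mol⁻¹ Å⁻¹).  Box is constant.
* ``amber-netcdf`` — AMBER NetCDF trajectory with forces (read through
  MDAnalysis, which converts kcal mol⁻¹ Å⁻¹ to internal units).
* ``gromacs-trr`` — GROMACS TRR with forces (read through MDAnalysis,
  which converts nm / kJ mol⁻¹ nm⁻¹ to internal units).

Only orthorhombic boxes are supported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import FormatError, UnusableInputError

PLAIN = "plain"
AMBER_NETCDF = "amber-netcdf"
GROMACS_TRR = "gromacs-trr"


@dataclass
class Frame:
    """One snapshot: per-atom coordinates and forces plus the periodic box."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    forces: np.ndarray  # (n_atoms, 3), kJ mol^-1 Å^-1
    box: np.ndarray  # (3,) orthorhombic edge lengths, Å
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.shape != self.forces.shape:
            raise FormatError(
                f"coordinates {self.coordinates.shape} and forces "
                f"{self.forces.shape} shapes differ"
            )
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise FormatError(f"box must be 3 positive edge lengths, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)


def wrap_minimum_image(vector: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention: each component mapped into [−box/2, box/2)."""
    v = np.asarray(vector, dtype=float)
    box = np.asarray(box, dtype=float)
    return (v + box / 2.0) % box - box / 2.0


def read_frames(path, format_tag: str, n_atoms: int | None = None) -> Iterator[Frame]:
    """Yield frames from ``path`` in file order, converted to internal units.

    ``n_atoms``, when given (normally the topology's total atom count),
    is validated against the file.
    """
    if not os.path.exists(path):
        raise FormatError(f"trajectory file not found: {path}")
    if format_tag == PLAIN:
        yield from _read_plain(path, n_atoms)
    elif format_tag in (AMBER_NETCDF, GROMACS_TRR):
        yield from _read_mdanalysis(path, format_tag, n_atoms)
    else:
        raise FormatError(f"unknown trajectory format {format_tag!r}")


def _read_plain(path, n_atoms: int | None) -> Iterator[Frame]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 5:
            raise FormatError(
                "plain trajectory header must be 'natoms nframes bx by bz'"
            )
        na, nf = int(header[0]), int(header[1])
        box = np.array([float(x) for x in header[2:5]])
        if n_atoms is not None and na != n_atoms:
            raise FormatError(f"file has {na} atoms, topology expects {n_atoms}")
        for f in range(nf):
            data = np.empty((na, 6))
            for a in range(na):
                line = fh.readline()
                if not line:
                    raise FormatError(
                        f"truncated file: frame {f}, atom {a} missing"
                    )
                vals = line.split()
                if len(vals) != 6:
                    raise UnusableInputError(
                        f"frame {f}: atom line has {len(vals)} columns, "
                        "expected x y z fx fy fz"
                    )
                data[a] = [float(v) for v in vals]
            yield Frame(
                coordinates=data[:, :3], forces=data[:, 3:], box=box.copy(), time=float(f)
            )


def _read_mdanalysis(path, format_tag: str, n_atoms: int | None) -> Iterator[Frame]:
    if format_tag == AMBER_NETCDF:
        from MDAnalysis.coordinates.TRJ import NCDFReader as Reader
    else:
        from MDAnalysis.coordinates.TRR import TRRReader as Reader

    reader = Reader(str(path))
    if n_atoms is not None and reader.n_atoms != n_atoms:
        raise FormatError(
            f"file has {reader.n_atoms} atoms, topology expects {n_atoms}"
        )
    for i, ts in enumerate(reader):
        if not ts.has_forces:
            raise UnusableInputError(f"frame {i} carries no forces")
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise FormatError(f"frame {i}: missing periodic box")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise FormatError(
                f"frame {i}: triclinic box (angles {dims[3:6]}); only "
                "orthorhombic boxes are supported"
            )
        yield Frame(
            coordinates=ts.positions.astype(float),
            forces=ts.forces.astype(float),
            box=dims[:3].astype(float),
            time=float(ts.time) if ts.time is not None else float(i),
        )


def write_plain(path, frames: Iterable[Frame]) -> int:
    """Write frames in the plain dialect; returns the frame count.

    The frame list is materialised first because the header carries the
    count; the box of the first frame is used throughout.
    """
    frames = list(frames)
    if not frames:
        raise UnusableInputError("cannot write an empty trajectory")
    na = frames[0].n_atoms
    box = frames[0].box
    with open(path, "w") as fh:
        fh.write(f"{na} {len(frames)} {box[0]:.8g} {box[1]:.8g} {box[2]:.8g}\n")
        for fr in frames:
            if fr.n_atoms != na:
                raise FormatError("variable atom counts are not supported")
            block = np.hstack([fr.coordinates, fr.forces])
            np.savetxt(fh, block, fmt="%.10g")
    return len(frames)
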