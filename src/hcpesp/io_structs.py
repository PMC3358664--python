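"""Readers and writers for the plain-text formats the tool touches.

Three formats are handled:

* **PQR** — PDB-like whitespace-delimited records carrying per-atom partial
  charge (e) and radius (Å) instead of occupancy/B-factor.  Two common
  dialects exist, with and without the chain-id column; they are
  disambiguated purely by token count (10 tokens = no chain id, 11 = chain
  id present), since PQR has no authoritative column standard.
* **vertex files** — one ``x y z`` triple per line (Å), ``#`` comments
  allowed; the evaluation points on or near the molecular surface.
* **result tables** — CSV of per-vertex potentials plus a JSON summary with
  the evaluation accounting.

Coordinates are Å throughout; no unit conversion happens on input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np


class PQRParseError(ValueError):
    """A PQR record could not be parsed; the message names the line."""


class VertexParseError(ValueError):
    """A vertex-file line could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """A structure file yielded zero atoms."""


@dataclasses.dataclass
class Atom:
    """A point partial charge: the leaf of the structural hierarchy.

    Attributes
    ----------
    serial : int
        Atom serial number from the input file.
    name, residue_name : str
        Atom and residue names (free-form short strings).
    chain_id : str
        Chain identifier; ``""`` for the chainless PQR dialect.
    residue_number : int
        Residue sequence number within the chain.
    position : (3,) ndarray
        Cartesian coordinates, Å.
    charge : float
        Partial charge, elementary charge units e.
    radius : float
        Atomic radius, Å (carried through but not used by the potential).
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    charge: float
    radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be a 3-vector, got shape {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position {self.position}")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius {self.radius}")


@dataclasses.dataclass
class VertexSet:
    """Surface evaluation points plus the reference center for the kernel.

    ``center`` is the structure center entering the screened term of the
    potential; it may be left ``None`` at read time and supplied by the
    caller before evaluation.
    """

    points: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (P, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("vertex coordinates must be finite")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)
            if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
                raise ValueError("center must be a finite 3-vector")

    def __len__(self) -> int:
        return self.points.shape[0]


_PQR_RECORDS = ("ATOM", "HETATM")


def read_pqr(path: str | Path) -> list[Atom]:
    """Parse a PQR file into a list of :class:`Atom` in file order.

    Only ``ATOM``/``HETATM`` records are read; everything else (REMARK,
    TER, END, ...) is ignored.  Records are split on whitespace; 10 tokens
    mean the chain-id column is absent (mapped to ``chain_id=""``), 11
    tokens mean it is present.

    Raises
    ------
    PQRParseError
        On a malformed record (wrong token count or non-numeric field).
    EmptyStructureError
        If the file contains no atom records.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0] not in _PQR_RECORDS:
                continue
            if len(tokens) == 10:
                chain = ""
                serial, name, resname, resnum = tokens[1], tokens[2], tokens[3], tokens[4]
                rest = tokens[5:]
            elif len(tokens) == 11:
                serial, name, resname, chain, resnum = tokens[1:6]
                rest = tokens[6:]
            else:
                raise PQRParseError(
                    f"{path}:{lineno}: expected 10 or 11 whitespace-delimited fields, "
                    f"got {len(tokens)}"
                )
            try:
                atom = Atom(
                    serial=int(serial),
                    name=name,
                    residue_name=resname,
                    chain_id=chain,
                    residue_number=int(resnum),
                    position=np.array([float(rest[0]), float(rest[1]), float(rest[2])]),
                    charge=float(rest[3]),
                    radius=float(rest[4]),
                )
            except ValueError as exc:
                raise PQRParseError(f"{path}:{lineno}: {exc}") from exc
            atoms.append(atom)
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    return atoms


def write_pqr(atoms: Sequence[Atom], path: str | Path) -> None:
    """Write atoms as whitespace-delimited PQR (chain column iff non-empty).

    Coordinates and charges are written with 6 decimals, radii with 4, so a
    read/write/read round trip is the identity at that precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        for a in atoms:
            x, y, z = a.position
            chain = f" {a.chain_id}" if a.chain_id else ""
            fh.write(
                f"ATOM {a.serial} {a.name} {a.residue_name}{chain} {a.residue_number} "
                f"{x:.6f} {y:.6f} {z:.6f} {a.charge:.6f} {a.radius:.4f}\n"
            )


def read_vertices(path: str | Path, center: Sequence[float] | None = None) -> VertexSet:
    """Read a plain-text vertex file: one ``x y z`` triple per line.

    Lines starting with ``#`` and blank lines are skipped.  ``center`` is
    attached if given; otherwise the caller must set it (normally to the
    structure center) before evaluation.
    """
    path = Path(path)
    points: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 3:
                raise VertexParseError(f"{path}:{lineno}: expected 3 numbers, got {len(tokens)}")
            try:
                points.append([float(t) for t in tokens])
            except ValueError as exc:
                raise VertexParseError(f"{path}:{lineno}: {exc}") from exc
    if not points:
        raise VertexParseError(f"{path}: no vertex lines found")
    return VertexSet(points=np.asarray(points), center=None if center is None else center)


def write_vertices(vertices: VertexSet | np.ndarray, path: str | Path) -> None:
    """Write vertex coordinates, one triple per line, 6 decimals."""
    pts = vertices.points if isinstance(vertices, VertexSet) else np.atleast_2d(vertices)
    path = Path(path)
    with path.open("w") as fh:
        for x, y, z in pts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def write_result_table(result, vertices: VertexSet, path: str | Path) -> None:
    """Write per-vertex potentials as CSV plus a JSON accounting summary.

    The CSV has columns ``index,x,y,z,potential`` (potential printed with 12
    significant digits so a re-read reproduces values to 9+ digits).  The
    JSON sidecar — same path with a ``.json`` suffix — records the total
    potential, the kernel-call count and the per-level usage histogram.

    Raises
    ------
    ValueError
        If ``result`` and ``vertices`` disagree in length, or are empty.
    """
    import pandas as pd

    n = len(result.potentials)
    if n == 0:
        raise ValueError("result is empty: nothing to write")
    if n != len(vertices):
        raise ValueError(f"length mismatch: {n} potentials vs {len(vertices)} vertices")
    path = Path(path)
    frame = pd.DataFrame(
        {
            "index": np.arange(n),
            "x": vertices.points[:, 0],
            "y": vertices.points[:, 1],
            "z": vertices.points[:, 2],
            "potential": np.asarray(result.potentials, dtype=float),
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")
    summary = {
        "n_vertices": n,
        "total_potential": float(result.total_potential),
        "kernel_calls": int(result.kernel_calls),
        "level_usage": {k: int(v) for k, v in result.level_usage.items()},
    }
    json_path = path.with_suffix(".json") if path.suffix == ".csv" else Path(str(path) + ".json")
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
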