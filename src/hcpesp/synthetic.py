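"""Synthetic hierarchical structures and surface vertex sets.

Real biomolecular inputs require externally prepared PQR files and surface
meshes; the generator here produces structures with the same 4-level shape
(complex > strand > residue > atom) entirely in memory, so every engine and
metric is testable without downloads.

Geometry model: each strand's backbone is an independent 3-D random walk
with step ``residue_spacing`` (default 3.8 Å, the Cα-Cα distance of a
polypeptide); strand origins themselves follow a random walk with step
``strand_spacing`` so multi-chain assemblies spread out instead of piling
onto one point.  Each residue's atoms are uniform in a ball of radius
``residue_extent`` about its backbone point.

Charge models (``charge_law``):

* ``uniform`` — i.i.d. uniform(-0.5, 0.5) partial charges;
* ``neutral_residues`` — uniform, then shifted so every residue is exactly
  neutral (probing the regime where the monopole approximation carries no
  information);
* ``unit_dipole`` — first two atoms of each residue carry ±0.5, the rest 0.

Evaluation points are placed on a sphere of radius (max atom distance from
the structure center + ``offset``) by a Fibonacci spiral lattice, randomly
but deterministically rotated from the seed.  Lying outside the whole
charge distribution, they guarantee positive distances for every kernel
call — surface realism is irrelevant to the correctness the tests probe.
"""

from __future__ import annotations

import dataclasses
import string

import numpy as np

from .hierarchy import Structure, build_hierarchy
from .io_structs import Atom, VertexSet

CHARGE_LAWS = ("uniform", "neutral_residues", "unit_dipole")

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclasses.dataclass
class SynthSpec:
    """Parameters of a synthetic structure.

    Counts are all >= 1. ``residue_spacing`` is the backbone step (Å),
    ``residue_extent`` the radius of the atom-placement ball (Å),
    ``strand_spacing`` the step of the walk placing strand origins (Å).
    """

    n_strands: int
    residues_per_strand: int
    atoms_per_residue: int
    residue_spacing: float = 3.8
    residue_extent: float = 1.8
    strand_spacing: float = 20.0
    charge_law: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_strands, self.residues_per_strand, self.atoms_per_residue) < 1:
            raise ValueError("all counts must be >= 1")
        if self.residue_spacing <= 0 or self.strand_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.residue_extent < 0:
            raise ValueError("residue_extent must be >= 0")
        if self.charge_law not in CHARGE_LAWS:
            raise ValueError(f"charge_law must be one of {CHARGE_LAWS}")
        if self.charge_law == "unit_dipole" and self.atoms_per_residue < 2:
            raise ValueError("unit_dipole needs at least 2 atoms per residue")
        if self.n_strands > len(_CHAIN_IDS):
            raise ValueError(f"at most {len(_CHAIN_IDS)} strands supported (single-char chain ids)")

    @property
    def n_atoms(self) -> int:
        return self.n_strands * self.residues_per_strand * self.atoms_per_residue


def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ball_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    return _random_units(rng, n) * radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)


def generate_structure(spec: SynthSpec) -> Structure:
    """Build a synthetic structure; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    serial = 1

    origin = np.zeros(3)
    for s in range(spec.n_strands):
        if s > 0:
            origin = origin + spec.strand_spacing * _random_units(rng, 1)[0]
        backbone = origin + np.cumsum(
            spec.residue_spacing * _random_units(rng, spec.residues_per_strand), axis=0
        )
        for ri in range(spec.residues_per_strand):
            offsets = _ball_points(rng, spec.atoms_per_residue, spec.residue_extent)
            if spec.charge_law == "unit_dipole":
                charges = np.zeros(spec.atoms_per_residue)
                charges[0], charges[1] = 0.5, -0.5
            else:
                charges = rng.uniform(-0.5, 0.5, size=spec.atoms_per_residue)
                if spec.charge_law == "neutral_residues":
                    charges = charges - charges.mean()
            for ai in range(spec.atoms_per_residue):
                atoms.append(
                    Atom(
                        serial=serial,
                        name=f"X{ai + 1}",
                        residue_name="SYN",
                        chain_id=_CHAIN_IDS[s],
                        residue_number=ri + 1,
                        position=backbone[ri] + offsets[ai],
                        charge=float(charges[ai]),
                        radius=1.5,
                    )
                )
                serial += 1
    return build_hierarchy(atoms)


def generate_vertices(
    structure: Structure, P: int, offset: float = 2.0, seed: int = 0
) -> VertexSet:
    """P evaluation points on the bounding sphere plus ``offset`` Å.

    Points are placed by a Fibonacci spiral lattice (near-uniform angular
    coverage) on the sphere of radius ``R_max + offset`` about the
    structure center, where ``R_max`` is the largest atom distance from
    the center; the lattice is rotated by a seed-derived random rotation.
    Every vertex is therefore at least ``offset`` from every atom.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if offset <= 0:
        raise ValueError("offset must be positive")
    center = structure.center
    pos = np.array([a.position for a in structure.atoms])
    radius = float(np.linalg.norm(pos - center, axis=1).max()) + offset

    i = np.arange(P)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / P
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    dirs = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])

    # seed-derived rotation (QR of a Gaussian matrix, det fixed to +1)
    rng = np.random.default_rng(seed)
    qmat, rmat = np.linalg.qr(rng.normal(size=(3, 3)))
    qmat = qmat * np.sign(np.diag(rmat))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] = -qmat[:, 0]
    points = center + radius * dirs @ qmat.T

    # all atoms lie within radius - offset of the center, so this holds by
    # construction; kept as a cheap guard on the invariant
    assert radius - float(np.linalg.norm(pos - center, axis=1).max()) >= offset / 2
    return VertexSet(points=points, center=center.copy())


def spread_out_spec(n_atoms: int, seed: int = 0) -> SynthSpec:
    """Spec of the spread-out assembly used for work-scaling studies.

    The atom count is scaled through the number of strands (25 residues of
    4 atoms each per strand, so ``n_atoms`` must be a multiple of 100),
    mirroring how larger biomolecular assemblies grow by chain count.
    Generous spacings (8 Å backbone step, 60 Å between strand origins)
    make the assembly extent large compared with the distance thresholds,
    so added strands land mostly in the far field.
    """
    if n_atoms % 100 != 0 or n_atoms < 100:
        raise ValueError("n_atoms must be a positive multiple of 100")
    return SynthSpec(
        n_strands=n_atoms // 100,
        residues_per_strand=25,
        atoms_per_residue=4,
        residue_spacing=8.0,
        residue_extent=1.5,
        strand_spacing=60.0,
        charge_law="uniform",
        seed=seed,
    )
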