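"""Natural 4-level partitioning of a biomolecule and charge approximation.

A structure is partitioned complex > strand > residue > atom, following the
natural organisation of biomolecules: strands are polymer chains (grouped by
chain id), residues are amino-acid/nucleotide groups (grouped by chain id +
residue number), atoms are the leaves.  Each non-leaf component carries a
geometric center, a bounding radius, and a small set of representative point
charges that stand in for its full charge distribution when the component is
far from the evaluation point.

Two approximation orders are supported:

* **order 1** (monopole): one point charge, the component's net charge,
  placed at the |q|-weighted centroid of its atoms.
* **order 2** (split monopoles): the total positive charge at the
  positive-charge-weighted centroid and the total negative charge at the
  negative-charge-weighted centroid, which preserves the component's net
  charge *and* leading dipole.  A side with zero total is omitted; when all
  charges share one sign this reduces to order 1.

Both orders conserve the component's net charge exactly, so the far-field
monopole term of the potential is always represented without error.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, Union

import numpy as np

from .io_structs import Atom

#: Hierarchy levels from root to leaves (atoms are implicit leaves).
LEVELS = ("complex", "strand", "residue")

#: Approximation orders every component is populated with.
SUPPORTED_ORDERS = (1, 2)


@dataclasses.dataclass
class PointCharge:
    """A representative point charge approximating part of a component."""

    position: np.ndarray
    charge: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("point-charge position must be a finite 3-vector")


@dataclasses.dataclass
class Component:
    """A hierarchy node: complex, strand, or residue.

    ``children`` are Components for complex/strand nodes and Atoms for
    residues.  ``approx_charges`` maps approximation order (1 or 2) to the
    representative point charges.  Private ndarray caches (positions and
    charges flattened per order, and member-atom arrays for residues) are
    populated at build time so the evaluation engines can vectorise.
    """

    level: str
    children: list
    center: np.ndarray
    bounding_radius: float
    approx_charges: dict[int, list[PointCharge]]
    total_charge: float
    # vectorisation caches, filled by build_hierarchy
    _approx_pos: dict[int, np.ndarray] = dataclasses.field(default_factory=dict, repr=False)
    _approx_q: dict[int, np.ndarray] = dataclasses.field(default_factory=dict, repr=False)
    _atom_pos: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _atom_q: np.ndarray | None = dataclasses.field(default=None, repr=False)
    _atom_index: np.ndarray | None = dataclasses.field(default=None, repr=False)


@dataclasses.dataclass
class Structure:
    """A complete partitioned structure.

    ``atoms`` keeps the flat input order (the traversal order of the
    engines, fixed for reproducibility); ``center`` is the arithmetic mean
    of all atom positions and serves as the reference point of the screened
    potential term.
    """

    root: Component
    atoms: list[Atom]
    center: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def census(self) -> dict[str, int]:
        """Component counts per level (one complex, S strands, R residues, N atoms)."""
        strands = self.root.children
        residues = [res for s in strands for res in s.children]
        return {
            "complexes": 1,
            "strands": len(strands),
            "residues": len(residues),
            "atoms": len(self.atoms),
        }


def approximate_charges(member_atoms: Sequence[Atom], order: int) -> list[PointCharge]:
    """Representative point charges of a group of atoms at a given order.

    Order 1 returns a single charge ``sum(q)`` at the |q|-weighted centroid
    (geometric centroid when all charges vanish).  Order 2 returns up to two
    charges: the positive-side total at the positive-charge-weighted
    centroid and likewise for the negative side; a side with zero total is
    omitted.

    Raises
    ------
    ValueError
        If ``member_atoms`` is empty or ``order`` is not 1 or 2.
    """
    if not member_atoms:
        raise ValueError("cannot approximate an empty set of atoms")
    if order not in SUPPORTED_ORDERS:
        raise ValueError(f"unsupported approximation order {order}; expected one of {SUPPORTED_ORDERS}")
    pos = np.array([a.position for a in member_atoms], dtype=float)
    q = np.array([a.charge for a in member_atoms], dtype=float)

    if order == 1:
        weight = np.abs(q).sum()
        if weight > 0:
            centroid = (np.abs(q)[:, None] * pos).sum(axis=0) / weight
        else:
            centroid = pos.mean(axis=0)
        return [PointCharge(position=centroid, charge=float(q.sum()))]

    charges: list[PointCharge] = []
    for mask in (q > 0, q < 0):
        total = q[mask].sum()
        if mask.any() and total != 0.0:
            centroid = (q[mask][:, None] * pos[mask]).sum(axis=0) / total
            charges.append(PointCharge(position=centroid, charge=float(total)))
    return charges


def _finalize(comp: Component, member_atoms: list[Atom], atom_index: np.ndarray) -> None:
    pos = np.array([a.position for a in member_atoms], dtype=float)
    comp.center = pos.mean(axis=0)
    comp.bounding_radius = float(np.linalg.norm(pos - comp.center, axis=1).max())
    comp.total_charge = float(sum(a.charge for a in member_atoms))
    comp.approx_charges = {k: approximate_charges(member_atoms, k) for k in SUPPORTED_ORDERS}
    for k, pcs in comp.approx_charges.items():
        comp._approx_pos[k] = (
            np.array([pc.position for pc in pcs], dtype=float) if pcs else np.empty((0, 3))
        )
        comp._approx_q[k] = np.array([pc.charge for pc in pcs], dtype=float)
    if comp.level == "residue":
        comp._atom_pos = pos
        comp._atom_q = np.array([a.charge for a in member_atoms], dtype=float)
        comp._atom_index = atom_index


def build_hierarchy(atoms: Sequence[Atom]) -> Structure:
    """Partition a flat atom list into complex > strand > residue > atom.

    Strands are formed by chain id in first-appearance order; residues by
    (chain id, residue number) in first-appearance order within the strand.
    A single complex roots the hierarchy.  All centers (arithmetic means of
    member positions), bounding radii, total charges, and approximate
    charges at both supported orders are populated.

    Raises
    ------
    ValueError
        If ``atoms`` is empty.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("cannot build a hierarchy from an empty atom list")

    # group preserving first-appearance order
    strand_keys: list[str] = []
    strand_members: dict[str, list[tuple[int, Atom]]] = {}
    for i, a in enumerate(atoms):
        if a.chain_id not in strand_members:
            strand_members[a.chain_id] = []
            strand_keys.append(a.chain_id)
        strand_members[a.chain_id].append((i, a))

    strands: list[Component] = []
    for chain in strand_keys:
        res_keys: list[int] = []
        res_members: dict[int, list[tuple[int, Atom]]] = {}
        for i, a in strand_members[chain]:
            if a.residue_number not in res_members:
                res_members[a.residue_number] = []
                res_keys.append(a.residue_number)
            res_members[a.residue_number].append((i, a))
        residues: list[Component] = []
        for rnum in res_keys:
            pairs = res_members[rnum]
            res = Component(
                level="residue",
                children=[a for _, a in pairs],
                center=np.zeros(3),
                bounding_radius=0.0,
                approx_charges={},
                total_charge=0.0,
            )
            _finalize(res, [a for _, a in pairs], np.array([i for i, _ in pairs], dtype=int))
            residues.append(res)
        strand = Component(
            level="strand",
            children=residues,
            center=np.zeros(3),
            bounding_radius=0.0,
            approx_charges={},
            total_charge=0.0,
        )
        _finalize(
            strand,
            [a for _, a in strand_members[chain]],
            np.array([i for i, _ in strand_members[chain]], dtype=int),
        )
        strands.append(strand)

    root = Component(
        level="complex",
        children=strands,
        center=np.zeros(3),
        bounding_radius=0.0,
        approx_charges={},
        total_charge=0.0,
    )
    _finalize(root, atoms, np.arange(len(atoms)))
    return Structure(root=root, atoms=atoms, center=root.center.copy())


def iter_components(structure: Structure):
    """Yield every non-leaf component (complex, strands, residues) top-down."""
    stack = [structure.root]
    while stack:
        comp = stack.pop()
        yield comp
        if comp.level != "residue":
            stack.extend(reversed(comp.children))
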