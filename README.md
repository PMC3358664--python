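# hcpesp

Electrostatic surface potential (ESP) of biomolecules computed with the
analytic linearized Poisson–Boltzmann (ALPB) model, with an exact all-atom
engine and the hierarchical charge partitioning (HCP) multi-scale
approximation.

## The problem and the method

Mapping the electrostatic potential onto a molecular surface is a routine
step in structural analysis — rationalising binding, docking, and pKa
behaviour.  For a solute of interior permittivity ε_in immersed in a solvent
of permittivity ε_out, the ALPB model gives the potential at an outside
point due to a single interior point charge *q* in closed form:

```
φ = (q / ε_in) · 1/(1 + αβ) · [ (1 + α)/d − α(1 − β)/r ],   β = ε_in/ε_out
```

where *d* is the charge-to-point distance, *r* the structure-center-to-point
distance, and α ≈ 0.580127 the universal ALPB constant.  When
ε_in = ε_out the expression collapses exactly to Coulomb's law *q*/(ε·d),
which anchors the package's analytic tests.  The potential at a surface
vertex is the sum of this kernel over all charges; with *N* atoms and *P*
vertices the exact computation costs O(N·P) kernel evaluations.

HCP cuts that cost by exploiting the natural hierarchy of biomolecules:
complex > strand (chain) > residue > atom.  Each component carries a small
set of representative point charges (order 1: net charge at the
|q|-weighted centroid; order 2: separate positive and negative centroids,
preserving net charge and leading dipole).  For each vertex the hierarchy
is walked top-down: a component farther from the vertex than its level's
distance threshold (defaults: residues 10 Å, strands 70 Å, the complex
never) contributes through its few representative charges; a nearer one is
opened, down to exact atoms.  Under treelike structural organisation the
work falls to O(P log N), with a small and threshold-controllable accuracy
cost measured here as relative RMSE against the exact engine.

Inputs are PQR structure files (coordinates in Å, partial charges in e,
radii in Å) and plain-text vertex files (one `x y z` per line); a synthetic
generator produces hierarchy-shaped structures and sphere-lattice vertex
sets so everything is testable without external data.

## Worked example

```
$ hcpesp synth --strands 2 --residues 8 --atoms 4 --n-vertices 32 --seed 7 --out demo
structure: 1 complex, 2 strands, 16 residues, 64 atoms

$ hcpesp esp --mode exact --pqr demo.pqr --vertices demo.vert --out demo_exact
structure: 1 complex, 2 strands, 16 residues, 64 atoms
total potential 5.728981736 over 32 vertices; 2048 kernel calls

$ hcpesp compare --pqr demo.pqr --vertices demo.vert
{
  "relative_rmse": 0.002435094281510787,
  "max_abs_diff": 0.001331375101371518,
  "kernel_calls_a": 2048,
  "kernel_calls_b": 1051,
  "work_ratio": 0.51318359375,
  "level_usage": {
    "residue": 469,
    "atom": 172
  }
}
```

The first command writes a synthetic 64-atom structure (`demo.pqr`) and 32
surface vertices (`demo.vert`).  The second evaluates the exact ALPB
potential at every vertex (2048 = 64 × 32 kernel calls; per-vertex values
in `demo_exact.csv`, accounting in `demo_exact.json`; potentials are in
natural units of e/Å scaled by 1/ε — pass `--unit-factor 332.0636` for
kcal/(mol·e)).  The third runs HCP at the default 10/70 Å thresholds
against the exact reference: here it reproduces the potentials to 0.24%
relative RMSE while doing 51% of the kernel work — 469 vertex–residue
interactions were served by two representative charges each, and only 172
atom evaluations remained in the near field.  On larger, more spread-out
assemblies the work ratio drops far below this (see `hcpesp scaling`).

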