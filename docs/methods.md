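# Methods

## Model

The per-charge kernel is the ALPB (analytic linearized Poisson–Boltzmann)
outside potential

φ = (q/ε_in) · 1/(1 + αβ) · [ (1+α)/d − α(1−β)/r ],  β = ε_in/ε_out,

with d the charge→vertex distance, r the structure-center→vertex distance,
and α the universal ALPB constant.  The model assumes a linear-response
dielectric two-phase picture (uniform ε_in inside the solute, ε_out
outside, no mobile-ion screening term) and is valid for observation points
outside the charge distribution; the inside-potential branch and effective
electrostatic size estimation are out of scope.  Two limits are exact and
are enforced by tests: ε_in = ε_out collapses the kernel to Coulomb's law
q/(ε·d), and α → 0 gives q/(ε_in·d).

The reference point for r is the arithmetic mean of all atom positions,
computed once per structure and shared by every kernel evaluation of a
vertex.  This is a package decision (the center is not otherwise pinned
down by the model as used here); any fixed interior point changes only the
screening term smoothly.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ε_in | 1.0 | – | solute interior permittivity |
| ε_out | 80.0 | – | solvent permittivity (water) |
| α | 0.580127 | – | universal ALPB constant |
| unit_factor | 1.0 | – | output scale; 332.0636 → kcal/(mol·e) |
| h_residue | 10.0 | Å | approximate residues farther than this |
| h_strand | 70.0 | Å | approximate strands farther than this |
| h_complex | ∞ | Å | the single complex is never approximated |
| order | 2 | – | charge-approximation order |

`unit_factor` defaults to 1 so the analytic tests are exact closed forms;
physical units are opt-in.  The 10 Å / 70 Å thresholds are the standard
parameterisation of the hierarchical method for residue and strand levels;
the complex level defaults to ∞ because single-complex inputs are the
supported case (multi-complex files are out of scope).

## Hierarchical charge partitioning

Structures are partitioned complex > strand > residue > atom by chain id
and (chain id, residue number), in first-appearance file order; that order
also fixes the traversal order, so results are bit-reproducible on a
platform.  Each component's representative charges are built as:

* **order 1** — one charge Σq at the |q|-weighted centroid (geometric
  centroid if all charges vanish).  Conserves net charge; a neutral
  component carries zero information.
* **order 2** (default) — the positive-side total at the positive-charge-
  weighted centroid plus the negative-side total at the negative-charge-
  weighted centroid (a side with zero total is omitted).  Conserves net
  charge *and* the dipole moment: with p⁺ = Σ_{q>0} q x / Q⁺ the positive
  moment Σ_{q>0} q x = Q⁺ p⁺ is reproduced exactly, likewise the negative
  side, so the leading far-field error is quadrupole, O((R/D)²) relative
  at distance D for component extent R.  When all charges share one sign
  order 2 reduces to order 1.

The construction of the representative charges was a genuinely open design
point; the split-centroid form was chosen because it is the smallest charge
set that keeps neutral components informative, matching the method's
"limited and controllable accuracy impact" character.  The distance test
uses the component's geometric center only (not center minus bounding
radius); bounding radii are exposed so users can keep thresholds safely
above typical component extents.  With thresholds ≥ component extents the
traversal is well-behaved; a threshold comparable to the extent merely
degrades accuracy gracefully (the error-controllability test covers the
extreme 2 Å/10 Å case).

Work is accounted platform-neutrally as single-charge kernel evaluations
(`kernel_calls`) plus a per-level usage histogram; wall-clock speedups are
deliberately not measured or claimed, since they are hardware-dependent.

## Numerical choices

* Accumulation is double precision by default.  The single-precision mode
  casts kernel operands and accumulators to float32 while keeping all
  traversal distance tests in double, so both precisions visit identical
  charge sets and the precision study isolates rounding from
  approximation-path divergence.
* Vertices closer than 1e−9 Å to an atom or to the center are rejected as
  coincident (the kernel diverges at d → 0).
* Relative RMSE is RMS(test − reference)/RMS(reference) — scale-invariant
  and zero iff equal.  This definition matters when comparing accuracy
  figures across implementations; it is stated here because "relative
  RMSE" is not standardised.
* PQR parsing is whitespace-token based; the 10-token (chainless) and
  11-token (chained) dialects are distinguished by token count alone.

## Synthetic study conditions

The generator emulates the 4-level hierarchy, not protein geometry: strand
backbones are 3-D random walks with step 3.8 Å (the Cα–Cα distance),
strand origins follow a coarser walk (default step 20 Å) so multi-chain
assemblies spread out, and each residue's atoms are uniform in a 1.8 Å
ball.  Charge laws: i.i.d. uniform(−0.5, 0.5); per-residue-neutralised;
or ±0.5 unit dipoles.  Evaluation points are a Fibonacci sphere lattice at
(max atom radius + 2 Å) from the center, seed-rotated — by construction at
least the offset away from every atom.  What passing tests therefore show
is correctness of the kernel, hierarchy, traversal, and accounting, and
the qualitative accuracy/work trade-off of the approximation; they do not
certify accuracy on real solvent-excluded surfaces, force-field charge
distributions, or secondary-structure geometry.

Fixed study conditions used by the test suite and the acceptance script:

* **Ensemble**: 20 structures of 4 strands × 15 residues × 5 atoms
  (300 atoms), uniform charges, 64 vertices each; sized to the regime of
  small single-digit-chain structures where the approximation error is
  largest and the per-structure RMSE bound (< 0.25) is meaningful.
* **Spread-out assembly** (scaling studies): strand count scales the atom
  total (25 residues × 4 atoms per strand), with 8 Å backbone steps and
  60 Å strand-origin steps so the assembly extent exceeds the 70 Å strand
  threshold and added strands land mostly in the far field — mirroring how
  large biomolecular assemblies grow by chain count.  Problem sizes are
  N = 1000 and 2000 atoms with P = 50 vertices.
* The measured growth factor kernel_calls(2N)/kernel_calls(N) compares two
  independently generated random assemblies (per-size seeds are decoupled
  as seed + N), so a single draw is noisy; the reported factor is the mean
  over five replicate seed bases, a lower-variance estimator of the same
  scaling behaviour.

## Known limitations

* Outside-potential branch only; no salt (κ = 0), no nonlinear PB, no
  forces or energies, no inside-the-surface evaluation.
* One complex per input; multi-complex assemblies would need a fourth
  finite threshold and are not supported.
* The distance criterion ignores component extent; pathological inputs
  with bounding radii larger than a threshold lose accuracy rather than
  failing loudly (the bounding radius is available for users to check).
* Synthetic vertices are a bounding sphere, not a molecular surface; real
  surface meshes must be supplied externally as vertex files.
* The HCP traversal is pure Python per vertex (the exact engine is fully
  vectorised); it is meant for method study, not production throughput.
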