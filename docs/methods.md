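# Methods

## Scope and data flow

`hofaudit` analyzes what happens when experimentally determined protein
structures are relaxed by an energy-minimizing structure model.  The
energy engine itself (a semiempirical quantum-chemistry method with
conductor-like implicit solvation) is out of scope: its results enter
as *records* — four heats of formation (single-point and fully
optimized, gas and aqueous, kcal/mol) plus the atom count per protein.
The packaged table covers 19 PDB entries with resolution ≤ 1.0 Å,
hydrogenated to a pH-7 convention, with entrained waters retained.

Everything that needs a live energy function runs on a surrogate force
field instead (below).  Conclusions drawn from surrogate-based tests
are therefore about the *pipeline machinery* — optimizers, scans,
detectors, statistics — not about the quantum-chemical engine.

## Per-atom statistics and the orthogonal partition

For phase *p*, ε(tot_p) = (ΔH_f(X-ray,p) − ΔH_f(opt,p)) / n.  Dividing
by *n* makes proteins of very different size comparable; using energy
rather than coordinate RMSD weights covalent-geometry errors (stiff
force constants) far more than tertiary displacements (soft), which is
the scientifically interesting weighting because chemistry is governed
by energies.

The method error and the experimental/environmental change are
uncorrelated, so ε(tot)² = ε(PDB)² + ε(method)².  With the calibrated
constant ε(method) = 0.12 kcal/mol/atom (both phases — solvation
effects on the method error largely cancel), ε(PDB) follows by
subtraction in quadrature.  Choices:

- **Full precision until the report layer.**  ε values are computed
  from unrounded energies; the published-style tables round to two
  decimals at output only.  (Both routes — partitioning rounded or
  unrounded ε(tot) — reproduce the reference tables at two decimals;
  we verified this before fixing the convention.)
- **Degenerate inputs.**  If ε(tot) < ε(method) the subtraction would
  be imaginary; the component is clamped to 0 and flagged rather than
  erroring, preserving auditability of anomalous records.
- **Cohort means are unweighted across proteins** (not atom-weighted),
  matching the reference convention.  The gas→aqueous contrast is
  reported as 100·(mean_aq − mean_gas)/mean_gas, rounded to integer
  percent.

## Method-error calibration

The estimator mirrors the benchmark protocol: for each benchmark dimer
with a definitive reference geometry, compute the single-point energy,
optimize without constraints, and call (E_ref − E_opt)/n the per-atom
geometric error of the method for that system; average over systems
without nucleic acids (73 of the 88 S22+S66 entries; which systems are
flagged is an *input*, not hard-coded, since the excluded list is not
published).  Running this with a real semiempirical engine reproduces
the 0.12 constant; offline, the estimator is exercised with surrogate
backends against closed-form 12-6 oracles, and the packaged default
constant is 0.12.

## Surrogate force field

Harmonic bonds k_b(b−b₀)² with k_b = 300 kcal/mol/Å² and b₀ the
covalent-radius sum (X–H pairs overridden to standard ideal lengths);
harmonic angles k_θ(θ−θ₀)² with k_θ = 50 kcal/mol/rad², θ₀ = 109.47°;
12-6 terms 4ε[(σ/r)¹²−(σ/r)⁶] over pairs separated by ≥ 3 bonds
(1-2/1-3 excluded, 1-4 full strength), σ per element set so the pair
minimum falls at vdW contact (σ = 2·r_vdw/2^(1/6)), ε = 0.1 kcal/mol.
The aqueous phase multiplies every pair well depth by 0.6 — a scalar
stand-in for the attenuation of nonbonded attraction in a polarizable
continuum; no electrostatics, torsions, or boundary conditions.  The
parameters are documented defaults in a plain-text file, not fitted to
anything; the surrogate exists so the pipeline is deterministic and
testable offline.  Gradients are analytic and verified against central
finite differences (1e-4 relative) in the test suite.  Optimization is
quasi-Newton (L-BFGS-B), deterministic, with a safeguard that never
accepts a final energy above the starting one.

## Hydrogenation

Deposited hydrogens are stripped and a full pH-7 complement re-added
from residue templates: Lys/Arg protonated, Asp/Glu deprotonated, His
neutral with the proton on NE2, termini charged (ammonium detected
from connectivity; carboxylate O/OXT bare).  Placement uses the parent
atom's hybridization and existing neighbors: tetrahedral completion at
sp3 centers, in-plane bisectors at sp2, staggered fans around single
bonds with the torsion referenced to a second-shell atom, a documented
fallback (with warning) for degenerate collinear neighborhoods.  X–H
lengths: C–H 1.09, N–H 1.01, O–H 0.96, S–H 1.34 Å.

Entrained waters are deposited as lone O atoms; re-addition gives every
water the same absolute H orientation (O–H 0.9572 Å, H–O–H 104.52°) —
deliberately reproducing the utility-style artifact — after which
hydrogen positions are relaxed with every heavy atom frozen
(bit-identical heavy coordinates by construction; gradient tolerance
0.1 kcal/mol/Å, cap 2000 iterations).  The geometric rules are a
documented reimplementation, not a bit-match of any particular
hydrogenation utility.

## Clash analysis

A clash is a nonbonded pair whose Bondi-radius spheres overlap by at
least 0.4 Å; the clashscore is clashes per 1000 atoms.  Conventions
(all configurable):

- pairs within 3 covalent bonds are ineligible.  (1-4 partners sit
  inside vdW contact even at ideal covalent geometry — carbonyl O to
  CB is 2.72 Å — so counting them would flag every structure.)
- hydrogens bonded to N/O/S use a reduced radius of 1.0 Å (the
  electron-cloud convention for polar hydrogens); C-bonded hydrogens
  keep Bondi 1.20 Å.
- H···N/O/S pairs within 2.5 Å with donor–H···acceptor angle ≥ 120°
  are hydrogen bonds, marked exempt and not counted.
- each unordered pair counts once; reports are sorted by decreasing
  overlap; hydrogen positions are nuclear.

This is an overlap-based detector, not a probe/contact-dot algorithm;
published clashscores from such tools (which also require the
externally optimized geometries) are therefore not reproduction
targets.  Candidate pairs come from a KD-tree; equivalence with
all-pairs enumeration is asserted in the tests.

## PES scans

Rigid two-fragment scans: fragment B is translated along a fixed axis
(default: through the closest inter-fragment H–H pair) so the monitored
distance takes each grid value (default 1.4–5.0 Å, 0.1 Å steps); no
relaxation at any point, so profiles are deterministic and compare
fixed-fragment interaction shapes.  Energies are reported relative to
the largest separation.  The minimum is refined by fitting a cubic
through the four points bracketing the grid minimum (falling back to a
three-point quadratic); on 12-6 oracles this places the minimum within
0.0005 Å of 2^(1/6)σ for the default grid and within 0.02 Å even on a
0.2 Å grid, where a plain quadratic vertex errs by ~0.04 Å.  Profiles
whose minimum falls on a grid endpoint are returned as-is and flagged
unbound.

## Synthetic generators

- **Polyalanine** chains from ideal internal coordinates (Engh-Huber-
  style lengths/angles; helix φ=−57°, ψ=−47°; extended φ=−139°,
  ψ=135°; CB at the L-configuration improper of −122.6°), hydrogenated
  through the same template machinery, with charged termini.  The
  helix reproduces i→i+4 O···H(N) distances ≈ 2.1 Å and both
  conformations are clash-free — the generator's qualification tests.
- **Two-chain complex**: a rigid copy of the chain offset
  perpendicular to its plane so the closest interchain contact is
  2.6 Å — nonbonded coupling with no covalent link.
- **Perturbations** separate two error channels: Gaussian displacement
  of each bonded atom *along a bond direction* (covalent jitter,
  σ default per experiment) versus rigid translation of a residue set
  (tertiary displacement).  Along-bond jitter is chosen over isotropic
  noise precisely so the covalent channel is clean.
- **Relaxation trajectories**: starting from a perturbed structure,
  minimize E + w·Σ|x−x_start|² for a decreasing weight ladder ending
  at 0, warm-starting each stage; record RMSD from the start and the
  cumulative fraction of the final (unrestrained) energy drop.  The
  base structure is pre-relaxed to a surrogate minimum so the drop is
  purely the injected perturbation energy.  With covalent jitter
  (σ = 0.02 Å) plus a 1 Å rigid chain shift, ~60% of the drop is
  recovered within 0.1 Å RMSD; an equal-RMSD shift-only perturbation
  recovers ~4% — the qualitative mirror, under the surrogate, of
  covalent errors dominating the energy drop at small displacements.
  This holds for all 10 seeds in the acceptance suite.
- **Energy-record fixtures** with exactly known partitions: records
  are constructed so ε(tot) = √(ε_pdb² + ε_method²) holds to machine
  precision, giving an exact parameter-recovery harness.

What the generators do *not* emulate: crystal packing, rotamer
libraries, thermal motion, real side-chain chemistry beyond alanine,
and any engine-specific energetics.  A green synthetic test validates
the analysis machinery, not the quantum-chemical claims.

## Numerical and interface conventions

- Coordinates in Å, energies in kcal/mol throughout; atom serials are
  the stable identity; 0-based indexing internally, 1-based only in
  PDB text.
- Bond inference: distance ≤ r_cov(a)+r_cov(b)+0.4 Å (Cordero radii);
  hydrogens are forced to exactly one bond (nearest heavy neighbor,
  with warning).  H–H pairs are never bonded.
- PDB reading keeps the highest-occupancy alternate location and takes
  elements from columns 77–78, falling back to name-based inference.
- All report rounding happens in the CLI/report layer; reruns with the
  same inputs produce byte-identical CSV/JSON.
- Random number use is confined to the synthetic generators, always
  through seeded generators.

## Known limitations

- The hydrogen placement is geometric; no pKa prediction, tautomer
  search, or side-chain flips.
- The surrogate force field has no electrostatics, so salt-bridge or
  hydrogen-bond energetics are only caricatured by the 12-6 wells.
- The clash detector's conventions approximate, but do not bit-match,
  probe-based validation tools.
- The calibration module reproduces the protocol, not the published
  constant, unless an external engine is plugged in via the
  output-file adapter.
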