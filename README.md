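# hofaudit

Audit of energy-minimized protein geometries against X-ray structures.

## The problem

When a high-resolution X-ray protein structure is fully relaxed with an
energy-minimizing structure model (a semiempirical quantum-chemistry
method with implicit solvation, for instance), the heat of formation
ΔH_f drops substantially.  That drop mixes three things: experimental
error in the deposited coordinates, the genuine geometric change
between the crystal and the solution environment, and error in the
energy method itself.  `hofaudit` packages the analysis that separates
these contributions, together with the structure-validation tooling
(hydrogen placement, steric-clash scoring, rigid potential-energy-
surface scans) used to audit the optimized geometries.

For each protein with *n* atoms the total per-atom energy change in
phase *p* ∈ {gas, aqueous} is

    ε(tot_p) = (ΔH_f(X-ray, p) − ΔH_f(optimized, p)) / n     [kcal mol⁻¹ atom⁻¹]

Because the method error and the experimental/environmental change are
uncorrelated, they add orthogonally,

    ε(tot)² = ε(PDB)² + ε(method)²,

so with a method-error constant calibrated on benchmark dimer sets
(0.12 kcal mol⁻¹ atom⁻¹, obtained as the mean per-atom relaxation
energy over the 73 protein-like systems of the S22/S66 sets), the
experimental/environmental component is recovered as
ε(PDB) = √(ε(tot)² − 0.12²).  The two sub-parts of ε(PDB) — coordinate
error and crystal-to-solution change — cannot be separated and are
reported as one quantity.

The quantum-chemistry engine that produced the packaged records is
*not* re-implemented: energies are consumed as records, and a simple
surrogate force field (harmonic bonds/angles + 12-6 pairs, with an
aqueous well-depth factor) stands in wherever the pipeline needs a live
energy function — hydrogen-position relaxation, clash studies, PES
scans, and perturbation experiments.

## Worked example

The packaged fixture table carries the four heats of formation and atom
count for 19 high-resolution (≤ 1.0 Å) PDB entries.  Running the
partition stage:

```sh
$ hofaudit partition --out-dir out
19 structures: mean eps(tot) gas 0.98, aqueous 0.78; mean eps(pdb) gas 0.97, aqueous 0.77 (-20% gas->aqueous)
```

Reading: relaxing these structures releases on average 0.98 kcal/mol
per atom in the gas phase and 0.78 in aqueous phase (the −20%
difference reflects the more realistic solvated model); after removing
the 0.12 method-error component, 0.97 and 0.77 kcal/mol/atom remain
attributable to the X-ray coordinates and the crystal-to-solution
change.  Per-protein values land in `out/partition.csv`, the cohort
summary in `out/partition_summary.json`.

The same numbers from Python:

```python
>>> import hofaudit as ha
>>> results = ha.partition_records(ha.packaged_energy_table())
>>> ha.summarize(results).rounded()
{'n_structures': 19, 'mean_eps_tot_gas': 0.98, 'mean_eps_tot_aq': 0.78,
 'mean_eps_pdb_gas': 0.97, 'mean_eps_pdb_aq': 0.77,
 'percent_difference_tot': -20}
```

Structure validation on the packaged engineered close-contact fixture
(two hydrophobic groups with their nearest hydrogens at 1.78 Å — far
inside vdW contact):

```sh
$ hofaudit audit src/hofaudit/data/synthetic_clash_fixture.pdb --out audit.json
clashscore all=83.33 h_only=83.33; wrote audit.json
```

Other sub-commands: `hydrogenate` (strip/re-add/relax hydrogens),
`clash` (overlap report + clashes-per-1000-atoms score), `scan` (rigid
two-fragment PES), `calibrate` (benchmark-dimer method-error estimate),
`simulate` (synthetic fixtures).  See `hofaudit <cmd> --help`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged records and nothing else, the cohort mean
of the experimental/environmental error component ε(PDB) in each phase
(gas-phase target `t3`, aqueous target `t4`, kcal mol⁻¹ atom⁻¹, rounded
to two decimals) and writes them as JSON.

## Layout

- `src/hofaudit/structure.py` — PDB I/O, bond inference, atom counting
- `src/hofaudit/hydrogenation.py` — template-based H addition, frozen-heavy-atom relaxation
- `src/hofaudit/energy.py` — energy-backend contract, surrogate force field, record I/O
- `src/hofaudit/partition.py` — ε statistics and orthogonal partitioning
- `src/hofaudit/calibration.py` — benchmark-dimer method-error protocol
- `src/hofaudit/clash.py` — vdW-overlap clash detection and clashscore
- `src/hofaudit/pes.py` — rigid-fragment distance scans
- `src/hofaudit/synthetic.py` — peptide/perturbation/record generators
- `src/hofaudit/cli.py` — command-line entry points
- `docs/methods.md` — models, assumptions, numerical choices
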