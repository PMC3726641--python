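# cleftscope

Analysis toolkit for protein–ligand cleft interaction studies: geometric
interaction fingerprinting, NOE-style effective proton distances,
superposition-based trajectory geometry, a well-tempered metadynamics
engine on analytic toy potentials, and end-point binding free-energy
bookkeeping — plus a synthetic-data generator so every stage is testable
without external downloads.

## Modules

| module | what it does |
|---|---|
| `cleftscope.model_io` | Domain types (structures, annotated topologies, trajectories, bias hills) and readers/writers for PDB (ATOM/HETATM/MODEL), XYZ, PLUMED-style HILLS text and TSV |
| `cleftscope.synthetic_data` | Deterministic toy complex (protein-like scaffold, three-ring ligand, two cation sites, optional water shell), trajectories with planted interaction schedules, Gaussian energy-component tables, analytic toy potentials |
| `cleftscope.interactions` | Hydrogen bonds (donor–acceptor < 3.5 Å, 4.0 Å for methionine sulphur, D–H–A angle > 120°), π-π stacking (centroid < 5 Å, inter-normal angle < 45°), salt-bridge filtering, occupancy/lifetime summaries |
| `cleftscope.noe_compare` | r⁻⁶-averaged effective proton–proton distances over equivalence groups (6 Å detection cutoff), distance-class bins, comparison against experimental class tables |
| `cleftscope.geometry` | Kabsch superposition (proper-rotation corrected), RMSD series, RMSF about the iterative average structure, ion displacement distributions, dihedral populations with circular mode reports |
| `cleftscope.metadynamics` | Well-tempered bias deposition (height 0.1 kcal/mol, σ 0.2 Å, pace 1 ps, γ = 10 defaults), one-sided harmonic walls, overdamped Langevin sampling, FES reconstruction `F = −(γ/(γ−1))V`, profile averaging, Boltzmann projection of 3-CV surfaces |
| `cleftscope.energetics` | Snapshot cadence selection, ΔG = ΔH + (−TΔS) with quadrature uncertainties, per-block ΔΔG columns |
| `cleftscope.cli` | `cleftscope` command wiring all stages with JSON run manifests |

Units throughout: Å, ps, kcal/mol; k_B = 0.0019872 kcal·mol⁻¹·K⁻¹.

## CLI

```bash
cleftscope simulate-fixtures --preset contacts --seed 7 --out fixtures
cleftscope hbonds --traj fixtures/contacts.pdb --window 0:500ps --subject all --out hb
cleftscope pipi --traj fixtures/contacts.pdb --out pp
cleftscope noe --traj fixtures/contacts.pdb --noe-table exp.tsv --mode r6 --out noe
cleftscope mobility --traj fixtures/ions.pdb --out mob
cleftscope dihedrals --traj fixtures/contacts.pdb --out dih
cleftscope metad --steps 200000 --seed 1 --out metad
cleftscope fes --hills metad/HILLS --grid -2.5:2.5:201 --out fes
cleftscope energetics --samples samples.tsv --reference M1 --out en
```

Presets: `contacts`, `ions`, `metad`, `energy`. Every run writes a
`manifest.json` recording the config, package version and input
checksums. Exit codes: 0 success, 1 data error, 2 usage error; logs go
to stderr.

## Conventions worth knowing

- Detector inequalities at the cutoffs are strict ("smaller than" /
  "larger than"); the D–H–A angle has its vertex at H with 180° linear.
- The salt-bridge percentage is reported as a truncated integer
  (8.8/11.2 → 78), the convention consistent with the reference rows it
  reproduces; see the docstring of `salt_bridge_percentage`.
- NOE averaging pools all frames and equivalent-pair distances into one
  r⁻⁶ power mean; bins are lower-edge inclusive and 6.0 Å is still
  `very_weak`.
- The torsion angle uses the standard convention: invariant under full
  atom-order reversal, negated by mirror reflection.
- The metadynamics free-energy estimator is the direct well-tempered
  scaling of the deposited bias; time-averaged estimators are out of
  scope.
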