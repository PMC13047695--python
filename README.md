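# cgnmr

NMR-derived restraints for coarse-grained (CG) bead simulations: a small
neural network predicts secondary chemical shifts from CG bead geometry,
chemical-shift and NOE data become differentiable restraint potentials with
analytic forces, and a minimal Langevin engine plus an ensemble-metric suite
make the whole pipeline runnable and testable end to end on synthetic
fixtures — no external data required.

## What's inside

| Module | Role |
| --- | --- |
| `cgnmr.io_formats` | Domain types + readers/writers: CG/atomistic PDB, CSV shift/NOE/mapping tables, JSON model weights, YAML configs. Units are nm/ps/kJ·mol⁻¹/ppm internally. |
| `cgnmr.geometry` | Bead bond angles and dihedrals with analytic Cartesian gradients (batch + scalar APIs). |
| `cgnmr.shiftnet` | 96→26→6 ELU network over tripeptide features (22-value substitution-matrix embedding + sin/cos of five local angles), training with early stopping, and the prediction Jacobian w.r.t. bead coordinates. |
| `cgnmr.restraint_cs` | Flat-bottom chemical-shift restraint: energy, forces through the network Jacobian, K ramp, scaled CS-RMSD, K scan. |
| `cgnmr.restraint_noe` | Atomistic→CG NOE mapping (r⁻⁶ condensation, bead-pair averaging, conflict filtering) and the piecewise distance restraint with optional time-averaged forces. |
| `cgnmr.engine` | Force-provider contract, toy bead force field, steepest-descent minimization, BAOAB Langevin integration, ramp schedules, positional/z restraints. |
| `cgnmr.protocols` | Restrained-production runbook (minimize → equilibrate → ramp → production) and the monomer-detachment assay. |
| `cgnmr.analysis` | RMSD/RMSF, dihedral RMSD, pseudo-Ramachandran, S-matrix, helix tilt (τ/ω), free-energy profiles with bootstrap errors, transition-based contact lifetimes, MSD diffusion, radial profiles, fibril twist, ADF stationarity, PCA representatives. |
| `cgnmr.fixtures` | Deterministic synthetic generators: toy peptides, teacher networks, shift/NOE tables, scripted and Brownian trajectories. |

## CLI

```bash
cgnmr make peptide --n-residues 12 --seed 1 --out pep.pdb
cgnmr make shifts --structure pep.pdb --out shifts.csv
cgnmr make noe --structure pep.pdb --n-pairs 10 --out noe.csv
cgnmr train --structures s1.pdb --shifts s1.csv --coil coil.csv \
            --stats stats.csv --out model.json
cgnmr predict --model model.json --structure pep.pdb --out pred.csv
cgnmr noe-map --atomistic ref.pdb --cg ref_cg.pdb --mapping map.csv \
              --noe noe.csv --out cg_restraints.csv
cgnmr simulate --config run.yaml
cgnmr analyze --traj traj.pdb --metric rmsd --out rmsd.csv
```

`run.yaml` lists the structure, optional model/shift/restraint files and a
`run:` block mirroring `cgnmr.protocols.ProductionConfig`
(temperature, dt, ramp rate, K maxima, step counts, seed).

## Conventions worth knowing

- CG PDB dialect: bead names (`BB`, `SC1`..`SC4`) in the atom-name column;
  residue names are the standard 20 plus `CYO` (oxidized cysteine) and
  `PRC` (cis-proline). Trajectories are multi-model PDB.
- The featurization layout is versioned
  (`tripeptide-32x3-v1`); model weights refuse to load against a different
  layout so trained models and featurizers can never mix conventions.
- Restraint force constants: K_CS multiplies squared ppm residuals and is
  reported in kJ·mol⁻¹ with the ppm² absorbed; K_NOE is a conventional
  kJ·mol⁻¹·nm⁻².
- Time-averaged NOE forces keep the running average in r⁻³ space with
  memory e^(−Δt/τ) and act only when both the instantaneous and the
  averaged distance violate the same bound. The default `cap_mode`
  ("effective") recovers the instantaneous force in the memoryless limit;
  `"literal"` keeps the printed product form.
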