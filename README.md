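# modexcite

Normal-mode-excited conformational sampling and landscape analysis for
coarse-grained bead models.

The package implements an enhanced-sampling protocol in which short Langevin
dynamics segments are repeatedly "kicked" by injecting a fixed amount of
kinetic energy along randomized combinations of low-frequency normal modes.
Directions are kept only if they are sufficiently diverse (RMSD between
structures displaced 1 Å along them), and are adaptively re-oriented when the
realized motion swings away from the excited direction.  Downstream analyses
map the conformational landscape of a flexible tail relative to a globular
domain: per-residue RMSF, RMSD series with plateau detection, tracking of the
tail-helix center of mass in an anchored inertia frame, residue-pair
interaction-energy maps, and convex-hull coverage statistics.

Everything runs at desk scale on a synthetic two-domain bead system (a
compact quasi-spherical core plus a flexible tail ending in an ideal helix)
with a toy force field (harmonic bonds/angles, switched Lennard-Jones and
Coulomb nonbonded terms), so the full pipeline is exercised in seconds and
every stage is testable against closed forms.

## Layout

| module                  | contents |
|-------------------------|----------|
| `modexcite.synthetic`   | synthetic two-domain generator, Gaussian-noise validation trajectories |
| `modexcite.structure`   | PDB I/O, selection grammar, Kabsch superposition, segment grafting |
| `modexcite.modes`       | network/numerical Hessians, mass-weighted diagonalization, per-mode RMSF, mode selection |
| `modexcite.dynamics`    | toy potential + exact forces, staged restrained minimization, BAOAB Langevin |
| `modexcite.excitation`  | direction sampling, diversity filter, kinetic-energy injection, adaptive updates, replica campaigns |
| `modexcite.landscape`   | RMSF/RMSD, anchored inertia frames, COM tracks, interaction-energy maps, coverage stats |

## CLI

The console script `modexcite` exposes the pipeline stages:

```sh
# chimera construction by segment overlap
modexcite graft --base base.pdb --donor donor.pdb --overlap 40:44 --graft 45:52 --out chimera.pdb

# normal modes + selection of the 4 modes dominating the tail's fluctuation
modexcite modes --spec spec.json --k 4 --region 41:52 --out modes.npz

# excitation campaign (per-replica trajectories + line-delimited JSON event log)
modexcite excite --spec spec.json --modes modes.npz --select-modes 6,7,8,9 \
    --replicas 4 --excitations 200 --delta-e 1.25 --t-exc 0.2 --seed 1 \
    --out-prefix campaign

# analyses
modexcite comtrack --traj campaign.replica0.traj --spec spec.json \
    --anchor 40 --domain 1:40 --helix 45:52 --out track.csv
modexcite imap --traj campaign.replica0.traj --spec spec.json \
    --set-a 1:40 --set-b 41:52 --out imap.csv
modexcite rmsf --traj campaign.replica0.traj --spec spec.json --out rmsf.csv
modexcite rmsd --traj campaign.replica0.traj --ref system.pdb --out rmsd.csv
```

Structures are PDB (one bead = one CA record); system blueprints are JSON
(`SyntheticSpec.to_json`); trajectories are a raw float64 array with a JSON
sidecar (`Trajectory.save`/`load`).

Selection grammar: inclusive residue ranges `resid 1:172`, atom-name filters
`name CA`, combined with `and`, `or`, `not` and parentheses.

## Units

Å, ps, amu, kcal/mol, elementary charge.  One named constant converts
kinetic energy (1 kcal/mol = 418.4 amu·Å²/ps²); k_B = 0.0019872041
kcal/mol/K; Coulomb constant 332.0636 kcal·Å/(mol·e²).  See
`modexcite/constants.py`.

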