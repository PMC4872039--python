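# hydrokin

Analysis toolkit for the coupling between **local hydration-structure
changes and collective domain motions** in multi-domain proteins, built
around the kind of study done on hexameric glutamate dehydrogenase (GDH):
an enzyme whose nucleotide-binding N-domain swings against the core
C-domain to open and close the active-site cleft, while a hydrophobic
pocket in the cleft "wets"/"dries" and a hydrophilic crevice gains and
loses individual water molecules.

The package implements the full chain of analyses a trajectory of such a
system needs, plus synthetic-scene generators with known ground truth so
every estimator can be validated end to end:

- **Domain PCA** with separate superposition and analysis atom sets: each
  conformation is superposed on a reference via the static-domain Cα set,
  and the covariance of the moving-domain core Cα coordinates is
  eigendecomposed. The projection on the first principal component (PC1,
  in Å, positive = open cleft) is the collective open/close coordinate;
  conformations with projection > +15 Å are *open*, < −15 Å *closed*. A
  screw-axis (Chasles) decomposition between the extreme conformations
  recovers the hinge axis.
- **Windowed solvent density maps**: each 50-ps window (1-ps stride) is
  rigidly superposed on a local anchor helix, the transform applied to all
  atoms including waters, and water-atom electrons (O = 8 e, H = 1 e)
  counted into 1-Å cube voxels and time-averaged. The region-integrated
  charge Q (electrons) over a site mask counts resident waters in units of
  ~10 e per water.
- **Hydration-state kinetics**: snapshots are classified from the jaw
  distance d and charge Q into wet-open / wet-half-open / dry-half-open /
  closed (d > 7 Å & Q > 8 e, 5 < d < 7 & Q > 8, 5 < d < 7 & Q < 4,
  d < 5 & Q < 4); off-box snapshots get the temporally nearest state.
  Residence times t_res > 5 ps are fitted with 1 − exp(−t_res/τ_AB), where
  1/τ_AB is the A→B rate constant.
- **Per-residue change maps**: R^ASA and R^WAT, the relative change of
  side-chain solvent-accessible surface area and of hydration-water count
  (3.5 Å cutoff) between the open and closed ensembles; buried residues
  (⟨ASA⟩_open < 10 Å²) are excluded.
- **Height-distribution mixtures**: the moving-domain tip height along a
  surface normal, modelled as two equal-σ Gaussians — the statistic that
  links simulated domain motion to scanning-probe topography of protein
  crystals.

## Worked example

Run the bundled synthetic study — a rigid two-domain protein whose hinge
angle and pocket occupancy are driven by one four-state Markov process —
and recover the wetting/drying kinetics from the density maps:

```python
from hydrokin.pipeline import RunConfig, run_pipeline
from hydrokin.synthetic import KineticScheme

scheme = KineticScheme.two_state("wet_half_open", "dry_half_open", 57.0, 81.0)
cfg = RunConfig(
    n_frames=6000, seed=3, scheme=scheme,
    state_angles={"wet_half_open": 10.0, "dry_half_open": 10.0},
    state_pocket_waters={"wet_half_open": 2, "dry_half_open": 0},
)
summary = run_pipeline(cfg)
for pair, est in summary["rates"].items():
    print(pair, round(est["tau_ps"], 1), "ps from", est["n_dwells"], "dwells")
```

prints

```
dry_half_open->wet_half_open 70.8 ps from 41 dwells
wet_half_open->dry_half_open 60.3 ps from 41 dwells
```

The drying and wetting time constants used to generate the scene were 57
and 81 ps; the estimates recovered from the full chain (explicit waters →
windowed density maps → Q series → state classification → dwell-time fits)
agree within three standard errors at 41 dwells each. The same run also
reports the PC1 variance fraction (≈ 1.0 for a single-hinge scene), the
gauge ranges and the state populations.

The same pipeline runs from a shell:

```sh
hydrokin run --seed 4 --out run_dir          # TSV tables + summary.json
hydrokin simulate --n-frames 200 --out t.pdb # synthetic trajectory as PDB
```

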