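# protdepth

Depth-based structural analysis of proteins: residue **depth**, cavity
detection with calibrated volumes, small-molecule **ligand-binding site
prediction** enhanced by sequence conservation, and empirical **pKa
prediction** for ionizable residues — for structural biologists and
bioinformaticians who need fast, geometry-driven annotation of PDB
structures.

Depth is the distance of an atom or residue to the closest *bulk* water
molecule.  The protein is repeatedly immersed in a randomly oriented
water lattice; waters with fewer than 2 neighbours within 4.2 Å are
non-bulk and mark cavities.  Clusters (1.2 Å linkage, ≥ 2 waters) of
non-bulk waters are cavities whose volumes come from a power-distance
voxel partition, re-calibrated as V_c = 0.8·V + 21 Å³, and a cavity is
buried when its shallowest lining residue is deeper than 3.75 Å.
Binding sites combine a per-residue probability P(R, D, S) with
Jensen–Shannon conservation J (BLOSUM62 pseudo-counts, m = 5) as
q = 0.7·P′ + 0.3·J′, turn q into noisy-OR water-displacement likelihoods
within 5.6 Å shells, apply the two-water rule, and call residues seen
near displaced waters (6.5 Å) in > 60% of iterations with β = 0.8.
pKa is a per-residue-type linear model over five environment features
(main-chain depth, polar side-chain depth, H-bonds, 12 Å-truncated
vacuum electrostatics, side-chain accessibility).

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Detect the cavity carved into a synthetic atom lattice (a 4 Å sphere,
analytic volume 268 Å³) and measure its volume:

```python
import numpy as np
from protdepth import (make_fixture, SolvationConfig, detect_cavities,
                       VolumeCalibration)
from protdepth.cavities import measure_cavity_volumes

st, truth = make_fixture("lattice_with_cavity",
                         {"extent": 25.2, "cavity_radius": 4.0})
cfg = SolvationConfig(seed=1, n_iterations=20)
depth, cavities = detect_cavities(st, cfg, compute_volumes=False)
waters = np.concatenate([w.coords for w in depth.water_sets])
non_bulk, _ = depth.pooled_non_bulk()
measure_cavity_volumes(st, waters, non_bulk, cavities, grid_step=0.5)

raw = sum(c.raw_volume for c in cavities)
print(f"ground truth {truth['cavity_volume']:.1f} A^3")
print(f"raw {raw:.1f} A^3 -> calibrated "
      f"{VolumeCalibration().calibrate(raw):.1f} A^3")
print(f"buried: {all(c.buried for c in cavities)}")
```

prints

```
ground truth 268.1 A^3
raw 331.9 A^3 -> calibrated 286.5 A^3
buried: True
```

The raw voxel estimate overshoots the carved void (water cells spill
into the lattice grooves between wall atoms); the affine calibration
corrects precisely this systematic bias, landing within ~8% of the
analytic volume.  `buried` is true because every residue lining the
pocket is deeper than 3.75 Å.

The same pipelines run from the shell on any PDB file:

```bash
depth run      --pdb protein.pdb --iterations 10 --seed 7 --out depth.tsv
depth cavities --pdb protein.pdb --grid 0.5 --out cavities.tsv
depth bindsite --pdb protein.pdb --msa homologues.fasta --out sites.tsv
depth pka      --pdb protein.pdb --out pka.tsv
```

`depth run` can also write a PDB with per-atom depth in the B-factor
column (`--pdb-out`), ready for colouring in any molecular viewer.

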