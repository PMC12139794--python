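# hydrosite

Hydration-site prediction and scoring from molecular-dynamics water
densities, for structural biologists who need to place — or validate —
ordered water molecules around a protein model, e.g. when building
solvent into cryo-EM or crystallographic maps where water density is
hard to tell from noise.

## What it computes

Given a trajectory of water-oxygen positions around a fixed solute,
`hydrosite` locates the regions of highest water density and scores
each by the **excess chemical potential** of water, the "work to
transfer" WT a water molecule from bulk to a position *x*:

```
WT(x) = -kT · ln( ρ(x) / ρ(∞) )
```

where ρ(x) is the local water-oxygen number density and
ρ(∞) = 0.033 Å⁻³ the bulk density of liquid water. Strongly negative
WT marks positions where water is far more localized than bulk —
exactly the positions that show up as ordered waters in experimental
maps.

The pipeline:

1. **Site finding** — water oxygens within 3.25 Å of the solute (the
   first hydration shell) are binned on a 0.1 Å voxel grid summed over
   all frames; a sliding 10×10×10 window (a 1 Å cube) finds the cubes
   holding the most water, kept greedily subject to 2.25 Å
   cube–cube and cube–solute separation. Each accepted cube yields a
   predicted water at the mean position of its member waters.
2. **WT scoring** — around each cube center a ±0.5 Å fine grid of
   0.005 Å voxels (8,000,000 voxels) is built and WT is
   Boltzmann-averaged over the densest 1% (n = 80,000 voxels):
   `WT(V) = -kT · ln( Σ exp(-WT(dV)/kT) / n )`, which reduces to
   `-kT · ln( S / (n·F·dV·ρ(∞)) )` with S the summed count of the
   selected voxels over F frames.
3. **Consensus analysis** — waters deposited with multiple
   experimental structures are superposed (Kabsch), pooled within 4 Å
   of a reference protomer, single-linkage clustered (< 1 Å),
   restricted to the 3.25 Å first shell, and classified
   high-consensus (seen in ≥ 5 structures) or lower-consensus.
4. **Evaluation** — predicted and experimental waters are matched
   one-to-one within 2.2 Å (greedy by distance, one prediction per
   experimental water) to give precision = TP/(TP+FP) and
   recall = TP/(TP+FN).

A synthetic-data module generates trajectories with planted Gaussian
hydration sites of known occupancy and width over uniform bulk, plus
jittered pseudo-experimental structures, with analytic expectations
for the WT estimator — so the entire pipeline is testable without any
MD engine or downloads.

## Worked example

Five Gaussian sites (occupancies 1.00–0.80, σ = 0.15 Å) planted 2.8 Å
above a five-atom pseudo-solute, over 0.033 Å⁻³ bulk, 20,000 frames:

```python
import numpy as np
from hydrosite import make_thermo, find_sites, score_sites, match_waters
from hydrosite.synth import benchmark_spec, generate_trajectory

spec = benchmark_spec(seed=1, n_frames=20000)
traj = generate_trajectory(spec)
sites = find_sites(traj, spec.solute, max_sites=5)
scored = score_sites(traj, sites, make_thermo(300.0, 0.033))
for s in scored:
    x, y, z = s.mean_position
    print(f"{s.rank:>4} {x:6.2f} {y:6.2f} {z:6.2f} {s.wt:7.3f} {s.density_ratio:7.0f}")

truth = np.array([s.center for s in spec.sites])
rep = match_waters([s.mean_position for s in scored], truth, cutoff=2.2)
print(f"precision={rep.precision:.2f} recall={rep.recall:.2f} (tp={rep.tp})")
```

prints

```
   1   2.00   2.00   3.80  -4.795    3113
   2   2.00  10.00   4.00  -4.768    2974
   3  10.00   2.00   3.60  -4.735    2813
   4  10.00  10.00   3.90  -4.702    2664
   5   6.00   6.00   4.10  -4.668    2517
precision=1.00 recall=1.00 (tp=5)
```

All five planted sites are recovered at their true positions (the
columns are rank, mean x/y/z in Å, WT in kcal/mol, and the implied
local-to-bulk density ratio); WT ranks follow the planted occupancies,
and a WT near -4.8 kcal/mol corresponds to a ~3000-fold density excess
over bulk. Every value agrees with the analytic expectation of the
estimator to better than 0.01 kcal/mol.

## Command line

```sh
hydrosite simulate  --spec system.yaml --out-dir sim/    # synthetic inputs
hydrosite predict   --trajectory sim/trajectory.pdb --solute sim/solute.pdb \
                    --out-prefix pred                    # ranked WT sites
hydrosite consensus sim/pseudo_*.pdb --reference sim/pseudo_SYN1.pdb \
                    --out-prefix cons                    # consensus clusters
hydrosite evaluate  --predicted pred.csv --experimental cons.pdb \
                    --out-prefix eval                    # precision/recall
```

Inputs are PDB/mmCIF (structures) and multi-model PDB/XYZ or any
MDAnalysis-readable format (trajectories); predicted sites are written
as CSV and as PDB with WT in the B-factor column. All tunables live in
a flat YAML config (`--config`) with the defaults listed in
`hydrosite.RunConfig`.

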