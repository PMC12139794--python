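# Methods

## Model

The excess chemical potential of water at a position *x* near a fixed
solute — the free energy of transferring a water molecule from bulk to
*x*, written WT — is estimated entirely from the equilibrium density of
water oxygens:

    WT(x) = -kT · ln( ρ(x) / ρ(∞) )

with ρ(∞) = 0.033 Å⁻³ the number density of bulk liquid water
(0.997 g/cm³ gives 0.0333 Å⁻³; the rounded conventional value is the
default and is user-overridable, since rigid three-site water models
equilibrate to a slightly different bulk density than experiment).
kB is fixed at 0.0019872041 kcal·mol⁻¹·K⁻¹ and the default temperature
is 300 K, so kT = 0.59616 kcal/mol. The density route assumes the
solute is rigid and the trajectory is long enough that occupancy
fluctuations average out; no free-energy-perturbation or insertion
estimator is attempted, and there is no entropy/enthalpy decomposition
or orientational statistics.

## Site finding (coarse grid)

Water oxygens within 3.25 Å of any solute atom — the first hydration
shell — are binned over all frames on a grid of 0.1 Å voxels spanning
the solute bounding box plus a padding of shell + 1 Å (padding below
the shell radius would clip in-shell waters and is rejected). Voxels
are half-open intervals, so each observation lands in exactly one
voxel and counts are conserved. A 10×10×10 sliding window (edge 1 Å,
stride 1) sums occupancy with an integer summed-area table, which is
bit-identical to direct summation at any grid size. Candidate windows
are accepted greedily in descending count with a lexicographic
lowest-corner tie-break (deterministic across platforms); a window is
kept only if its geometric center (lowest corner + 0.5 Å per axis) is
at least 2.25 Å from every accepted center and from every solute atom.
Separation is measured center-to-center and center-to-atom; the
window "position" needed a convention and the geometric center is the
natural one. There is no minimum-count threshold: ranking plus
`max_sites` (default 200) and downstream WT thresholds govern how many
sites are reported. Each accepted cube's predicted water position is
the arithmetic mean of all member water observations (pooled over
frames, restricted to the cube; the grid already holds only in-shell
counts, so the mean inherits the shell filter). Trajectories are
assumed pre-imaged with the solute whole and fixed; no periodic
imaging is performed.

## WT scoring (fine grid)

Around each accepted cube center a fine grid of 0.005 Å voxels spans
±0.5 Å per axis: 200³ = 8,000,000 voxels of volume dV = 1.25·10⁻⁷ Å³.
"Extending 0.5 Å in x, y and z" is read as ±0.5 Å — the stated
8-million-voxel budget forces this. Per voxel,
WT(dV) = -kT·ln(c/(F·dV·ρ(∞))) with c the count over F frames; empty
voxels have WT = +∞ and contribute 0 to any Boltzmann sum. The
site-level value averages the Boltzmann factors of the densest 1% of
voxels (n = 80,000):

    WT(V) = -kT · ln( (1/n) Σ_selected exp(-WT(dV)/kT) )
          = -kT · ln( S / (n·F·dV·ρ(∞)) ),   S = Σ_selected c.

The algebraic form is what the code evaluates; the exp-sum form is
kept as an independent oracle in the tests (agreement to 1e-9).
Selection is by count; equal counts contribute equally, so ties at the
selection boundary are provably WT-neutral and `np.partition` can be
used without a deterministic ordering. When fewer than n voxels are
occupied, zero-count voxels pad the selection: the numerator keeps
every observation and the denominator stays the fixed selected
sub-volume n·dV. In that sparse regime a bulk-only cube tends to the
baseline WT = -kT·ln(V/(n·dV)) = -kT·ln 100 ≈ -2.75 kcal/mol — every
observation lands in its own selected voxel, so the estimator reports
the ratio of the cube volume to the selected sub-volume rather than 0.
The estimator is reported as-is, without subtracting this baseline; an
explicit `boltzmann_wt` caller can subtract -kT·ln(V/(n·dV)) if a
bulk-referenced scale is wanted, but no such correction is applied
anywhere by default. Counts are raw point occupancies — no kernel
smoothing.

## Consensus analysis

Structures are superposed by least-squares rigid-body fitting
(Kabsch, via scipy's rotation alignment) on Cα atoms of one chain
paired by residue number (or all atoms paired by index, for synthetic
records); a rank check rejects collinear selections, whose rotation is
undetermined. Waters from all records, mapped into the reference
frame, are pooled within 4.0 Å of the reference protomer (default:
the first chain of the reference). Single-linkage clustering connects
pairs strictly closer than 1.0 Å ("less than" is strict; the
companion shell test "more than 3.25 Å … discarded" makes the shell
comparison inclusive ≤ 3.25 Å on the cluster mean). Cluster size is
the number of *distinct* source structures — two waters from one
deposition closer than 1 Å still count once, which is what bounds
cluster sizes by the number of input structures. Clusters seen in ≥ 5
structures are high-consensus, 1–4 lower-consensus. Distances to the
solute use all solute atoms (deposited models carry no hydrogens).
No resolution- or B-factor weighting is applied, and ions are never
treated as pseudo-waters.

## Matching and precision/recall

Predicted and experimental waters are matched one-to-one: all pairs
within 2.2 Å (inclusive — "within") are visited in ascending distance
with (predicted, experimental) index tie-breaks, and a pair is
accepted when neither member is already matched. This globally greedy
scheme is deterministic, order-independent, and enforces one
prediction per experimental water; it is deliberately *not* optimal
Hungarian assignment, which is not what the evaluation protocol
describes. precision = TP/(TP+FP), recall = TP/(TP+FN); a zero
denominator yields 0 with a logged warning. The precision/recall
curve admits sites by WT threshold or top-k rank; TP is non-decreasing
in k, precision need not be monotone.

## Synthetic data and what it does (not) show

The generator emulates the statistical structure the estimators
consume: each planted site emits, per frame, one water at
Normal(center, σ²I) with probability `occupancy`; bulk waters are
Poisson(ρ·V) uniform in the box. Occupancy draws are independent
across frames — the WT estimator is a per-frame density functional,
so temporal autocorrelation changes error bars, not expectations.
Pseudo-experimental structures subsample the true sites with a
detection probability and Gaussian positional jitter. The standard
benchmark plants five sites (occupancies 1.00/0.95/0.90/0.85/0.80,
σ = 0.15 Å) 2.8 Å above a five-atom pseudo-solute — inside the 3.25 Å
shell, outside the 2.25 Å exclusion — in a 12×12×5 Å box over
0.033 Å⁻³ bulk, 20,000 frames: small enough to run the full pipeline
in seconds on one CPU, dense enough that Monte-Carlo noise on WT is
~0.003 kcal/mol. What passing these tests shows: the grids, selection
logic, estimator algebra, clustering and matching are correct, and
WT recovers planted density ratios quantitatively. What it does not
show: force-field realism, solute flexibility, correlated water
networks, hydrogen placement, or periodic-boundary effects — real
trajectories bring all of these and only change the inputs, not the
estimator.

The analytic expectation `expected_wt` integrates the Gaussian + bulk
density over the fine voxels exactly (the Gaussian factorizes per
axis). The realized estimator keeps the n densest *observed* voxels;
when the expected number of occupied voxels K = Σ(1-exp(-μᵢ)) is
below n — the case at realistic frame counts — every observation is
selected and the expected selected count is Σμᵢ, which the oracle
uses; above that it falls back to the top-n expected counts, an
approximation that ignores selection noise and is documented as such.

## Numerical choices and edge cases

- Half-open voxel intervals everywhere; binning conserves counts.
- All-zero fine grids are a validation error (WT undefined); sites
  whose cube is empty are dropped from scoring with a warning.
- Degenerate (collinear) superposition selections raise rather than
  return an arbitrary rotation; coplanar selections are fine.
- The site-table PDB writer stores WT in the B-factor column
  (2 decimals) and the consensus writer stores n_structures in the
  occupancy column; round-trips are tested at PDB precision (10⁻³ Å).
- Every stochastic path takes an explicit seed; identical seeds give
  byte-identical outputs.

## Known limitations

- The coarse grid is dense in memory (~8 bytes/voxel); a full
  protein-sized box at 0.1 Å resolution runs to hundreds of millions
  of voxels and needs a few GiB. Chunked accumulation would lift this
  but is not implemented.
- Waters from alternate conformers (altloc B and later) are dropped on
  reading, not merged.
- `aggregate_waters` assumes every record can be superposed onto the
  reference with the chosen atom selection; there is no fallback to
  sequence alignment for numbering mismatches.
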