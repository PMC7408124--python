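# Methods

## Compound set

The 39 coumarins are reconstructed from their substituent specification
(position 3 plus ring positions 6/7/8) on the 2H-chromen-2-one scaffold
under standard coumarin numbering (O1, C2=O, C3, C4, C4a, C5–C8, C8a). The
SMILES template walks the scaffold in numbering order so each group lands on
its named position; all 39 canonical structures are distinct. Two compounds
(6,8-dibromo- and 7-methoxy-3-benzoyl) lack a readable LOX assay and are
excluded from modelling; the two assay standards (Trolox, NDGA) are carried
but never modelled. The external test set is the published eight-compound
list; the single training outlier (the only 7-diethylamino compound,
standard residual −2.65) is excluded from the refined fit, giving training
sizes 29 and 28 for the initial and refined models.

The "6-dihydroxyamino" group of two compounds is chemically unusual and is
encoded literally as N(OH)₂ attached at C6; no claim is made that this
matches the original authors' intent.

The printed log-activity column is carried as-is. For three compounds it
differs from log₁₀ of the printed % by a hair more than pure log-rounding
(the original logs were evidently taken before the % column was rounded),
so consistency between the two columns is asserted within the combined
rounding bound ±(0.005 + 0.05/(pct·ln10)) rather than ±0.005.

## Geometry

Semi-empirical optimisation in the original workflow is replaced by
distance-geometry embedding (ETKDGv3, seeded) of eight conformers followed
by MMFF94 minimisation, keeping the lowest-energy conformer. This removes
the quantum-chemistry dependency, is bitwise-deterministic per
(SMILES, seed), and in practice converges to the same minimum across seeds
for these mostly rigid scaffolds. Descriptor values on these geometries
differ from values computed on semi-empirical geometries by several
percent; comparisons against the published descriptor values therefore use
a ±20 % band, while all internal invariants (rotation/translation
invariance, brute-force pair-sum identities) hold to 1e−9 or better.

## Aromaticity and fragment typing

For fragment typing, aromaticity is restricted to six-membered all-carbon
rings: the coumarin benzo ring and any pendant phenyls are aromatic, the
2-pyranone ring is not (RDKit's default model would aromatise it). C-026
counts aromatic carbons with exactly two aromatic-carbon ring neighbours
and a heteroatom substituent (O, N, S or halogen); ring-fusion carbons
(three aromatic neighbours) never qualify. This reproduces the published
worked counts (one such carbon in the 3-benzoyl compound — its lactone-
oxygen-bearing C8a — and two in the 3-benzoyl-7-benzyloxy compound). The
remaining carbon types are coarser classes (aromatic C–H, aromatic C–C,
sp³ by hydrogen count and heteroatom attachment, carbonyl, nitrile,
vinylic) sufficient to populate a realistic selection pool; the full
120-type fragment table is out of scope.

## Descriptors

* **Weights.** Elemental properties (mass, van der Waals volume, Sanderson
  electronegativity, polarizability) are scaled to carbon, so w(C) = 1
  exactly; polarizabilities are the standard table values (H 0.667, C 1.76,
  N 1.10, O 0.802, Cl 2.18, Br 3.05 Å ³). Raw (unscaled) weights are
  available via a flag and recorded in the matrix metadata.
* **RDF.** Gaussian smoothing constant β = 100 Å⁻² (the conventional
  default of the descriptor literature; configurable). Hydrogens included.
  Grid: r = 1.0–15.5 Å in 0.5 Å steps, five weighting schemes, names
  `RDF{10r:03d}{u,m,v,e,p}`.
* **HATS.** Leverages from the SVD of the centred coordinate matrix
  (pseudo-inverse convention), so planar and linear geometries are handled
  with leverage sums 2 and 1. Lags 0–8, unordered atom pairs at exact
  topological distance, hydrogens included.

## Filtering and splitting

Three elimination passes in fixed order: any-missing columns dropped; then
columns with a non-zero fraction below 0.1 dropped (threshold inclusive);
then greedy pairwise-correlation pruning at R² > 0.7 in column order
(constant columns dropped first; the surviving set has all pairwise R² ≤
0.7 and is invariant to column rescaling). "Multiple correlations" beyond
pairwise are not defined in the source workflow and are not implemented.

Cluster-based test selection z-scores (descriptors + activity), builds a
single-linkage Euclidean dendrogram, cuts at n_test clusters and takes one
medoid per cluster (lowest index on ties). The shipped pipeline honours the
published split by default; clustering is opt-in (`split_source=
"clustering"`), because reproducing the published model takes precedence
over re-deriving its split from descriptors of different provenance.

## GA-MLR

Chromosomes are descriptor subsets of fixed size (3); fitness is Q²_LOO of
the OLS fit, computed in closed form from the hat diagonal (PRESS), which
makes a fitness evaluation a single QR factorisation. Tournament selection
(size 3), union-resampling crossover (rate 0.8), per-gene replacement
mutation (rate 0.05), elitism 5 (best fitness is monotone by
construction), population 200, up to 300 generations with early stop after
50 stagnant generations, a cache of evaluated subsets, and a mandatory
seed. Ranking collapses duplicates and breaks ties by subset size then
lexicographic order. The defaults solve 12-column problems to the
exhaustive optimum and recover planted 3-descriptor signals among 50
correlated decoys at n = 28.

OLS itself is computed by QR with an explicit rank check (rank-deficient
designs raise, naming the offending columns); standardized coefficients
are b·sd(x)/sd(y) with n−1 denominators.

## Validation battery

All statistics are computed from first principles: R²/R²adj/s/F from the
fit; Q²_LOO via the PRESS/hat identity (verified against explicit refits
to 1e−10); RMSE/MAE/CCC for training, LOO and external predictions (Lin's
concordance with population variances); Q²F1/F2/F3 with the training-mean,
external-mean and per-observation-variance denominators (Q²F1 ≥ Q²F2 holds
identically); r²m from both regression directions with the slope-through-
origin convention for r₀², reporting average and absolute difference and
clamping r² − r₀² at zero when numerically negative; Kxx/ΔK from the
eigenvalues of the (response-augmented) correlation matrix; Y-scrambling
with 500 seeded permutations (means and standard errors reported — the
null expectation of R² is p/(n−1) ≈ 0.11 at n = 28, p = 3); leverages of
arbitrary points against the training design with h* = 3p′/n, standardized
residuals e/s (the leverage-corrected variant is deliberately not the
default, matching how the source analysis quotes residuals), outliers at
|e/s| > 2.

Exact reproduction of the published statistics table is not a target: the
original descriptor matrix came from semi-empirical geometries and a
proprietary engine. The pipeline instead asserts the qualitative
agreements that survive a change of descriptor provenance (coefficient
signs, pairwise descriptor correlations below 0.7, the scrambling null
level) — and, in practice, the refit on recomputed descriptors lands very
close to the published fit (R² ≈ 0.70, Q²_LOO ≈ 0.61, with the same
outlier and out-of-domain compounds flagged on the Williams plot).

## Synthetic data

The generator draws descriptor matrices from a seeded multivariate normal
with configurable correlation (scalar equicorrelation or a full matrix,
PSD-checked; optional Poisson count columns mimic fragment counts) and
responses from a sparse linear model with Gaussian noise, optionally
rescaled to the 0.85–1.98 log-activity window of the real set. Defaults
(n = 28 compounds, 53 descriptors, equicorrelation 0.5, truth
{5, 12, 21} with coefficients (3, −2, 1), noise sd 0.5) mirror the scale
of the real problem with a clearly recoverable signal. Real descriptors
are skewed, discrete and block-structured; passing recovery tests on
Gaussian surrogates validates the selection/validation machinery, not
descriptor behaviour on real chemistry. Toy geometries (diatomics, chains,
flat rings with typed substituents, a regular tetrahedron) pin the
descriptor edge cases: rank-deficient geometries, lags beyond the graph
diameter, single-pair closed forms, hand-typed fragment counts.

## Problem sizes

The shipped test suite and the acceptance script embed a handful of
compounds (or all 37 once, in the pipeline test), use 100–500 scrambling
iterations, 20 GA recovery runs and 50-problem LOO equivalence sweeps —
sizes chosen so the whole battery runs in well under a minute of numerics
plus a few seconds of conformer generation per compound, while every
statistical conclusion is already stable at those sizes.

## Known limitations

* Descriptor values are not bit-compatible with commercial engines; only
  the three published per-compound values are compared, within a band.
* The fragment table covers this chemistry only; molecules with aromatic
  heterocycles would need the aromaticity rule revisited.
* The GA assumes subsets of exactly the configured size; smaller models
  are obtainable only by lowering the limit.
* IC₅₀ dose–response fitting, docking, and assay execution are outside the
  package's scope; only the inhibition-rate arithmetic and the log
  transform of the assay section are implemented.
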