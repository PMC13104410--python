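# Methods

## Pose model and in-place RMSD

Poses are ordered ensembles of conformers sharing the reference's heavy-atom
element multiset; pose order is file order, and "pose rank N" always means
the 1-based position of a pose in that order (docking programs emit poses
ordered by their native score, so for the native function rank coincides
with score order). Coordinates are Å in the receptor frame and are never
recentred on read.

RMSD is computed over heavy atoms only (hydrogens are retained through I/O
and stripped at comparison time, so protonation bookkeeping remains
possible) and **without re-superposition**: redocking accuracy is a
statement about where the pose sits in the binding site, so positional error
must count. A superpose-first comparison would answer a different question
and is deliberately not the default.

Symmetry correction minimises the RMSD over the automorphisms of the
molecular graph (element- and bond-order-preserving permutations), found by
networkx's VF2 matcher with a hard cap of 10⁴ enumerated mappings. It is
**off by default**: docking suites typically report the identity-mapping
value, and the toggle lets both conventions be compared. A conformer without
bonds (e.g. a ligand extracted from PDB HETATM records) has no usable
automorphism structure; symmetry work requires bonded input, and the cap
turns the degenerate all-permutations case into an explicit error.

Reporting conventions, chosen to match how such tables are conventionally
printed: success rates as whole percent, column-mean RMSDs and enrichment
factors to one decimal. Rounding is half-away-from-zero applied to the
shortest decimal representation of the binary float; this reproduces every
printed mean in the bundled benchmark layout, including the one column whose
exact mean is 2.05 but whose float sum rounds down to 2.0. The strict
`< cutoff` rule (2.0 Å exactly fails) and the pooled overall success rate
(success counts summed over both docking algorithms before dividing) follow
the benchmark's own footnotes.

## Enrichment and ROC

The selection size for the enrichment factor is `floor(f · NC_tot)`. Floor
(rather than rounding or ceiling) is forced by the arithmetic of the
reference values the tests pin: 303 compounds at 10 % must select 30
(EF ceiling contribution 303/30 = 10.1) and 271 must select 27
(271/27 ≈ 10.0); a ceiling rule would give 303/31 ≈ 9.8. Compounds with a
missing score for a combination are excluded from that combination's ranking
*and* from its NC_tot — a compound a docking run never retrieved is not part
of that run's scored database, which is how a 303-compound database can be a
271-compound database for another algorithm.

AUC is the midrank (Mann–Whitney) estimator: ties between an active and a
decoy score count ½. This equals the trapezoidal area under the tie-aware
ROC curve on every instance, a property the suite verifies against
scikit-learn's independently computed curve on 1,000 random tables. The
standard error is Hanley–McNeil; the test against AUC = 0.5 is the
two-sided normal approximation to the rank-sum statistic (with tie
correction, via scipy), starred at α = 0.05 and 0.01. For the tiny active
classes typical of seeded databases (3 actives) the normal approximation is
coarse; the p-values are reported as conventional annotations, not as exact
tail probabilities. Band boundaries are closed below (AUC = 0.9 is
"excellent").

Score orientation is per-function configuration, defaulting to
higher-is-better for all eight scoring-function columns.

## Protocol selection and hit calling

The default validity criterion is the most stringent ROC band
("excellent"); minimum success rate and minimum EF are optional additional
criteria. Every threshold outcome is recorded on the verdict. Hit calling is
the union over validated combinations (either algorithm, any validated
function) and fails closed when nothing validates.

The per-compound "flagged" rule is deliberately configurable because it is
the one step of the protocol with no canonical operational definition. Two
rules are provided: membership of the top-fraction selection used for the EF
(default, top 10 %), and a score threshold (e.g. the reference ligand's own
score). The planted-binder fixture uses the threshold rule: it plants a
+10 σ score gap, so a mid-gap threshold recovers exactly the planted set,
whereas a top-10 % selection of a 65-compound screen necessarily flags
floor(6.5) = 6 compounds and cannot return exactly 4.

## Franz-cell analysis

Full-volume withdrawal makes the cumulative amount an exact running sum of
sampled amounts — no back-dilution correction exists to apply. The partial
withdrawal mode (off by default) adds the `V_a·C_n + V_w·Σ_{i<n}C_i`
mass-balance form. Flux is an ordinary least-squares slope of Q against
time, fitted **per replicate**, then P_app = flux/(A·C0) is aggregated as
mean ± sd across the n = 6 cells; fitting the pooled points instead would
understate between-cell variability. The default window uses all six
samples (20–120 min); the post-lag window drops leading points until
R² reaches a configurable minimum (default 0.95; a stricter value is needed
when the lag is short relative to the sampling interval, since a lagged
line through the origin region can still fit all points with R² > 0.95 and
a downward-biased slope) with at least three points retained.

The diffusion area is a required parameter and is echoed alongside every
P_app, because a P_app is meaningless without it; the synthetic default is
1.77 cm², a typical 15-mm Franz cell orifice. Donor concentrations of
extract components are `extract strength × content %` (20 mg/mL × 3.465 %
= 693 µg/mL), applied multiplicatively regardless of the %-basis wording of
the content assay. Tissue retention assumes a 5 mL lysate volume by default.

Integrity gating passes when the marker's P_app is at or below a
configurable threshold (default 5 × 10⁻⁶ cm/s, the order of magnitude of an
exclusion marker across intact nasal epithelium; the bound is closed).
Permeability classification assigns the nearest benchmark on a linear scale
— marker ≈ 2.92 × 10⁻⁶ (low), acyclovir-like 12.4 × 10⁻⁶ (low-moderate),
atenolol-like 47.3 × 10⁻⁶ cm/s (moderate-high) — with the class interval
bounds (midpoints between adjacent benchmarks) returned so reports can show
them explicitly.

## Synthetic generators: what they emulate and what they do not

* **Pose generator.** Rigid translation by a vector of length t changes the
  in-place RMSD by exactly t, giving analytic targets; the jitter mode adds
  a small centroid-preserving rotation and sizes a translation orthogonal to
  the mean displacement by bisection (|achieved − target| ≤ 0.01 Å). These
  ensembles have realistic RMSD *values* but not realistic docking
  *geometry* — no conformational change, no binding-site sterics — so they
  validate the measurement machinery, not docking itself.
* **Seeded database.** Equal-variance binormal scores (decoys N(0,1),
  actives N(δ,1)) give expected AUC Φ(δ/√2), verified empirically at
  δ ∈ {0, 1, 3}. Real scoring-function distributions are heavier-tailed and
  inter-correlated; the generator makes no attempt at property-matched
  decoys.
* **Redock fixture.** The published three-structure benchmark layout is
  stored as (RMSD, rank) cells; ensembles are built so that recomputation
  reproduces every cell, with filler poses strictly above the best-pose
  RMSD. Two source rows state a 7-pose ensemble alongside ranks up to 61 —
  an internal inconsistency of the source layout — and the generator
  enlarges such ensembles to the maximum rank. The seed changes geometry
  only, never the reported values.
* **Franz generator.** Strictly linear sink-condition kinetics with
  multiplicative Gaussian noise (CV-based, mirroring LC-MS precision quoted
  as RSD). It does not emulate donor depletion, tissue saturation, active
  transport or evaporation; passing recovery tests therefore demonstrates
  estimator correctness under the sink model, not robustness to those
  violations.

## Problem sizes and determinism

Stochastic checks use 200 replicate simulations (AUC calibration, noisy
P_app recovery) and 1,000 random instances (trapezoid-vs-concordance,
permutation null), sizes at which Monte-Carlo standard errors are a few
×10⁻³ on the quantities compared; all randomness flows through seeded
`numpy.random.default_rng` generators and the hypothesis profile is
derandomised, so the suite is reproducible run to run.

## Known limitations

PDB ligand extraction handles HETATM/altloc selection only (no CONECT bond
recovery, no V3000, no MOL2 dialects). The automorphism cap makes symmetry
correction unavailable for highly symmetric or bond-free inputs rather than
silently slow. ROC p-values rely on the normal approximation (see above).
Published P_app values for real tissue experiments are not recomputable
without the raw time courses and diffusion area, so the permeation stage is
validated by simulator round trips and mass-balance oracles rather than by
pinning literature values.
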