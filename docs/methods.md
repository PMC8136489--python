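# Methods

This note documents the models, numerical choices and known limits of
`lipidshift`, in the order the pipeline runs them.

## Codon alignments and the divergence statistic

Alignments are in-frame FASTA; cleaning removes whole codon columns
(never taxa) that contain a stop codon, an ambiguous base, or a partial
gap codon, so the taxon set stays concordant with the species tree. All
reported coordinates are 1-based codon/residue numbers. The divergence
statistic is the fraction of columns in which every sequence carries
the identical residue, computed on the amino-acid alignment with
gap-containing columns excluded from the denominator by default; the
`count_gap_columns` policy is exposed because the convention behind
published identity percentages is often unstated, and both are exact
counts, not heuristics.

## Selection scan

**Model.** GY94 over the 61 sense codons with F3×4 frequencies
(position-specific nucleotide frequencies multiplied and renormalized
after excluding stops). Site-class mixtures: M1 (ω₀ ≤ 1, ω = 1), M2
(adds ω_s ≥ 1), M7 (Beta(p, q) discretized into k equal-probability
categories, category ω at the category median; k = 10 by default,
configurable), M8 (beta plus an ω_s ≥ 1 class with weight 1 − p₀).
Gaps are missing data (partial likelihood 1). Likelihoods come from
Felsenstein pruning over compressed site patterns, with per-node
rescaling against underflow and transition probabilities from the
symmetric eigendecomposition of the reversible generator.

**Branch lengths and κ.** The input tree's branch lengths are taken as
given up to one global stretch. An M0 (single-ω) fit estimates κ, ω̂₀
and that stretch; site-model fits then hold κ and the stretch fixed and
optimize only mixture parameters. Internally the stretch is stored as
an absolute multiplier on the *unnormalized* generator, which makes
each class's site likelihood a function of its own ω alone. This is an
equivalent parametrization of the fixed-tree problem (the conventional
mixture-mean-rate normalization just relabels the stretch) and it is
applied identically to null and alternative models, so LRT calibration
is unaffected; its payoff is the ω-grid surrogate below.

**Optimization.** L-BFGS-B on bounded parameters (p, q ∈ [0.02, 99];
p₀ ∈ (0, 1); ω_s ∈ [1, 50]) from a fixed list of starting points, five
by default, plus optional informed starts (M8 is seeded from the M7
optimum). Convergence tolerance is tight enough that nested-model lnL
inversions exceed 1e-4 only rarely; when they do, the LRT statistic is
clamped at zero with a warning.

**Fast surrogate.** `OmegaGridApproximator` evaluates per-site log
likelihoods exactly on a 64-point geometric ω grid (1e-4 … 50) in one
batched pruning pass, then interpolates with a cubic spline in
log(ω + 1e-3) during optimization. Because the separable convention
makes each class's likelihood depend only on its own ω, the surrogate
introduces no structural approximation, only interpolation error
(≲ 1e-3 lnL units in the region optimizers visit; a test pins the
grid-vs-exact fit agreement to < 0.05). Calibration experiments use it;
`fit_site_model` defaults to exact pruning.

**Tests of selection.** M7-vs-M8 and M1-vs-M2 are compared by
2·ΔlnL ~ χ²(2) (the PAML convention; the boundary-mixture refinement
would only make the test more conservative, and the null calibration is
measured directly, see below). Per-site evidence is the naive
empirical-Bayes posterior of the ω > 1 class under the fitted mixture;
full BEB prior-averaging is out of scope and the choice is stated here
because reports often say only "posterior probability".

**Counting path.** Ancestral codons by Fitch parsimony (ties broken
lexicographically and recorded; unrooted trees are rooted on the edge
of the alphabetically first leaf). Per site, synonymous and
nonsynonymous changes are summed over branches, averaging over minimal
mutational paths for multi-nucleotide codon differences and discarding
stop-crossing orderings when a stop-free ordering exists. Expected site
fractions are averaged over all node states and weighted κ:1 for
transitions vs transversions — plain NG86 counting (κ = 1) biases
pooled dN/dS to ≈ 0.85 on neutral κ = 2 simulations, and the pipeline
passes the M0 κ̂. The binomial test of nonsynonymous excess is
two-sided by default; `alternative="greater"` gives the one-tailed
positive-selection convention, which is what a recovery analysis should
use (two-sided p-values roughly double and counting loses most of its
already-limited power). Raw p-values are reported alongside a
Benjamini–Hochberg column; the headline intersection rule (posterior ≥
0.9 and p ≤ 0.1) applies the raw values, matching per-site threshold
practice.

**Calibration (measured, not assumed).** Under the null (M7, 19 taxa,
300 codons, exponential branch lengths of mean 0.05) the M7-vs-M8 LRT
at α = 0.05 rejects ≈ 5% of 100–200 replicates — within the expected
[1%, 11%] band for the boundary-conservative χ² reference. Under M8
with p₁ = 0.10, ω_s = 4 the test rejects essentially always and the
median fitted ω_s lands within a few percent of truth. The test suite
runs 100 null + 25 alternative replicates; `scripts/acceptance.py`
defaults to 200 + 100. Replicate counts are the only scaled-down knob;
the generating conditions are never changed.

## Structure layer

PDB I/O goes through biotite (first model, highest-occupancy altlocs,
waters dropped). Superposition is the SVD Kabsch solution with a
det = +1 correction; collinear or < 3-point inputs are rejected.
Refined superposition iteratively drops pairs deviating by more than
`cutoff_sigma` (default 2.0) times the current RMS deviation and
re-fits, up to 5 cycles — the align-style convention; both plain and
refined RMSDs are always available because published RMSDs rarely say
which was used. Conservation is operationalized as mean pairwise Cα
deviation across models after superposing all onto the first
(configurable reference), linearly rescaled so the least-divergent
residue scores 1 and the most-divergent 0; the score is written into
the B-factor column at 2 decimals with 99.99 marking unpaired residues.
Point mutations are stubs: the residue is renamed and side-chain atoms
beyond Cβ removed (Cβ too when mutating to glycine), with a loud header
remark — no rotamer is built, and mutated structures destined for
docking must be rebuilt with a side-chain packer first.

## Pocket volumetrics

Cavity volume is measured on a regular grid (default spacing 0.5 Å):
voxels within vdW + probe (probe 0.75 Å, Bondi-style united-atom radii
bundled in `pocket.DEFAULT_RADII`) of any atom are occupied, free
voxels connected to the bounding box are solvent, and the remainder is
buried cavity; volume = voxel count × spacing³ exactly. This is a grid
approximation, not an alpha-shape reproduction: volumes are comparable
across structures run with identical settings but are not calibrated to
alpha-shape servers, and an *open* pocket (connected to solvent at the
probe scale) reports zero buried volume by construction. Portals are
counted morphologically: a portal is a connected set of voxels
reachable from the exterior by the small probe, sealed by a binary
closing of the occupancy at the large-probe radius (default 2.5 Å), and
touching both the exterior and the enclosed cavity. A literal
"reachable at small probe but not at large probe" region merges all
channels through the cavity interior, so the closing form is what makes
two bored channels count as two. On analytic shell fixtures the volume
is exact to ≤ 2.5% (including rotations) and planted channel counts of
0/1/2 are recovered exactly.

## Affinity and swap logic

Kd = exp(ΔG/RT), R = 0.0019872 kcal·mol⁻¹·K⁻¹, T = 298.15 K by default
(the temperature behind published docking Kds is rarely printed; it is
exposed in config and recorded in outputs). Only the lowest-energy pose
per receptor × ligand enters any verdict, so adding worse poses can
never change a call. The swap rule assumes the tightest endogenous
ligand is the competitor present in abundance — a stated simplification
— and calls *swap* iff Kd(best endo)/Kd(exo) ≥ threshold, default 1
(ties swap). No published fold cutoff exists for this rule, so all
folds are always reported and any cutoff can be re-applied. The
mutational scan compares best-pose Kds per ligand between a background
and a mutant receptor and reports fold changes, directions, and the
swap-verdict flip if an exogenous ligand is named.

## Synthetic generators

The generators define the test conditions. Codon alignments: 19 taxa
by default, random bifurcating topology by sequential pair joining,
exponential branch lengths (mean 0.05 substitutions/codon — the primate
ortholog scale), κ = 2, 300 codons, root codons uniform over sense
codons (the F3×4-consistent choice for uniform nucleotide usage), site
classes drawn from the truth mixture, and evolution by exact GY94
transition probabilities. Cavity fixtures: pseudo-atom cubic shells
on a 0.5 Å wall lattice whose inner occupancy surface sits exactly at
the analytic void boundary, with optional ~3 Å channels bored through
opposite faces (voids of 10 Å are used for portal fixtures so the
large probe fits inside). Ensembles: ideal Cα helices with a planted
mobile loop (residues 16–25) and random rigid scrambles. Affinity
tables: endogenous ΔG ~ Normal(−7, 1) kcal/mol, exogenous ΔG placed at
a controlled Kd gap factor, mutant effect as a uniform endogenous
shift, decoy poses added, and truth verdicts computed by the swap rule
itself on the truth Kds. Per-component RNG streams are spawned from one
master seed, so outputs are byte-reproducible and adding a stage never
perturbs earlier streams.

What the generators do *not* emulate: alignment error, recombination,
among-site rate variation beyond the ω mixture, indel processes,
realistic side-chain packing or lipid chemistry, and docking-pose
geometry. Passing tests therefore demonstrate correctness of the
inference machinery under its own model assumptions, not robustness to
real-data violations of them.

## Known limitations

- NEB (not BEB) posteriors; no branch-site or episodic models.
- Branch lengths are rescaled by one global factor, never re-optimized
  per branch.
- Parsimony ancestral states undercount changes on long branches, so
  counting dN/dS saturates with divergence.
- The χ²(2) LRT reference is conservative at the boundary null (by
  design; measured, not corrected).
- Pocket volumes are grid-based and probe-definition-dependent;
  portal counts are a best-effort morphological definition.
- Stub mutations carry no rotamer; downstream docking requires
  rebuilding.
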