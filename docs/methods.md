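# Methods

## Scope and model

`nrpbm` analyses single-nucleotide-variant (SNV) protein-binding
microarrays for nuclear-receptor (NR) heterodimers. NRs of the type II
class bind direct repeats (DRn): two 6-bp half-sites with consensus
RGKTCA separated by a 0–5 bp spacer. The analysis starts from a set of
*seed* sequences — concrete DR sites embedded with 5-bp flanks in a
34-nt probe variable region — and measures binding to the seed plus
every single-base variant of its context. For a context of length
`12 + S + 10` (spacer length S) there are `3·(22+S)` SNVs; with the
default 24 seeds per spacer class this yields 10,728 unique seed+SNV
sequences across DR0–DR5.

The downstream quantities are:

- **z-score** per unique sequence: replicate-averaged log fluorescence
  standardized against the mean/SD of 500 random genomic background
  probes, `z = (x − μ_bg)/σ_bg`.
- **Δz energy matrix** per seed: at each context position the four base
  variants (seed base plus three SNVs) give four z values; Δz subtracts
  the per-position median, so each position's four entries have median
  zero.
- **PFM** via the Boltzmann/softmax transform
  `f_i = exp(βz_i)/Σ_k exp(βz_k)` with `β = 15/z_max`, `z_max` the
  maximum replicate-averaged z over the seed and its SNVs. The cited
  source for this transform fixes only β; the softmax functional form is
  this package's (standard) choice and alternative transforms can be
  plugged in.
- **PWM** through the pseudocount construction
  `p_ij = (f_ij + s·b_i)/(Σ_i f_ij + s)`, `S_ij = log2(p_ij/b_i)` with
  `s = 0.001` and background `b` defaulting to accessible-chromatin
  frequencies (A 0.24, C 0.26, G 0.26, T 0.24) for genomic scoring and
  uniform elsewhere.
- **Binding mode** per seed: full-site versus 5′/3′ half-site, from the
  Δz matrix (below).
- **Genomic enrichment**: ROC/AUC of PWM scores over bound vs
  size-matched unbound regions, with the Wilcoxon–Mann–Whitney identity
  `AUC = U/(n₊·n₋)`, continuity-corrected two-sided p and Bonferroni
  adjustment across models tested.
- **Relative Kd** from competition EMSA titrations, fit against an exact
  two-ligand mass-action equilibrium.

## Mode classification

The clustering criterion behind published full-site/half-site calls is
not specified anywhere we could follow; the rule used here is an
explicit operationalization. For half h (its six core positions; flanks
inform logos but not mode):

    perturbation_h = Σ_pos (max_base Δz − min_base Δz)

Half h is *engaged* when `perturbation_h ≥ engage_abs` (default 2.0
z-units) **and** `perturbation_h ≥ engage_frac · (p₅ + p₃)` (default
0.25). Both engaged → `full`; exactly one → that half's mode; maximum z
below `z_threshold` (default 3.0, the affinity cutoff for functional
sites) → `none`. A degenerate above-threshold seed where neither half
clears the absolute floor resolves to `full` (binding that no single
variant perturbs is treated as canonical engagement); boundary ties
likewise resolve to `full`. All three knobs are configuration
parameters.

Near the z threshold the engagement statistic is noise-limited: weak
secondary matches elsewhere in the probe contribute genuine but
site-unrelated Δz. Recovery guarantees quoted below therefore apply to
bound (z ≥ 3) seeds under the generator's default signal levels, where
the planted site dominates occupancy.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biophysics of any particular receptor:

- **Occupancy**: `occ(seq) = baseline + Σ_modes w_mode Σ_windows
  exp(−E_mode(window))` over both strands. Three modes: full-site
  (12+S footprint per spacer class; half-site cores informative, spacer
  neutral) and two half-site modes (6-bp core + 5-bp flank footprint).
  Energies are additive per-position penalties in natural-log units,
  0 for the preferred base.
- **Fluorescence**: occupancy × orientation bias (o2 probes ×0.8 by
  default) × lognormal noise (σ = 0.1 default), 5 replicates per
  orientation for SNV probes, 4 for all others. Array intensities are
  positive and right-skewed, hence multiplicative lognormal noise.
- **Parameter defaults** (fixed once, from what the assay reports):
  core penalties U(1.2, 2.2) per mismatch (≈3–9× occupancy loss per
  base change), half-site flank penalties U(0.3, 0.7), specific weight
  ≈30× the nonspecific baseline. Under these, full-site consensus
  seeds reach z ≈ 25–30 and half-site binders z ≈ 8–10, matching the
  z ranges the assay class produces, with background probes at
  z = 0 ± 1 by construction.
- **Identifiability choices**: in single-mode scenarios the unengaged
  half is kept ≥3 mismatches from the consensus on both strands, and
  the engaged half's flank matches the model's flank preference —
  otherwise the planted mode is not recoverable by any method and
  parameter-recovery tests would measure the generator, not the
  pipeline. Half-site modes include flank preferences because half-site
  binding in vitro involves flanking contacts (it is also what gives a
  6-bp core enough information to stand out of random sequence). The
  probe filler sequence contains no 6-bp window within 2 mismatches of
  RGKTCA on either strand.
- **Mutant scenario**: wild type is a full-site binder on genuine full
  sites; the DNA-binding-domain mutant loses full-site binding and
  retains weak 5′-half binding that leans heavily on flank contacts,
  anchoring residual binding to the 5′ half. Without that anchoring the
  equivalent 3′ core is bound as well and the classifier correctly
  reports "full" — the real mutant data imply such an asymmetry without
  explaining it.
- **Genomic benchmark**: regions tiled on one synthetic chromosome;
  positives carry one PFM-sampled motif instance (random strand,
  uniform offset) with probability `planted_fraction`; negatives never
  do. TSS/DE tables place a configurable fraction of positives within
  10 kb upstream (strand-aware) of a differentially-expressed gene.
  Ground truth (plant offsets) is always written alongside.

What passing tests on these simulations do **not** show: robustness to
spatial array artifacts, scanner saturation, sequence-dependent
double-stranding efficiency, or cooperative/cofactor effects — none of
which the generator models.

## Numerical choices

- z-scores on natural-log intensities (config: linear); replicate
  summary is the mean (config: median). Background referencing makes
  z invariant to global rescaling.
- Softmax computed with max-shift for overflow safety; shift-invariance
  in z is exact.
- PFM columns renormalized after averaging; column sums checked to
  1e-9.
- Region score = max window score over both strands (config: sum);
  N bases score log2(1) = 0 (background probability convention).
- Reciprocal-overlap boundary is inclusive (≥ frac of *both* interval
  lengths). Coordinates are 0-based half-open throughout; for a
  −-strand TSS at p the upstream window is [p, p+window).
- Competition fit: free protein solved by Brent's method on the
  two-ligand conservation equation at every competitor concentration
  (no IC50 approximation); log10(Kd) fit by bounded least squares from
  four starting points; percentile bootstrap (200 residual resamples,
  seeded, warm-started) for the CI. Concentrations are molar
  internally; interfaces accept nM.
- All randomness flows through `numpy.random.default_rng` generators
  seeded per invocation; library build, simulation and negative-set
  sampling are bit-reproducible given their seeds.

## Problem sizes

Default analyses run the complete design (144 seeds, ~113k probes,
~12k unique sequences); simulation and scoring are vectorized, so a
full scenario (design → simulate → normalize → motifs → modes) takes a
few seconds. The enrichment benchmark uses 300 regions per class and
the EMSA round trip a 9-point half-log titration — the sizes a desk
validation of these methods needs.

## Known limitations

- The engagement rule is an interpretation; published mode counts from
  deposited array data cannot be reproduced without the original
  criterion, so cross-condition mutant checks are qualitative.
- The cross-array normalization is a single-factor median equalization,
  not the full linear-regression array normalization used for real
  scanner data.
- The generator's binding modes are independent; no dimerization
  equilibrium, ligand effect or cooperativity is modeled.
- Kd estimation assumes the competitor acts through simple competitive
  mass action with known probe Kd and active protein concentration.
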