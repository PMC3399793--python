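# Methods

This note documents the models implemented in `grsim`, the defaults and
why they were chosen, the numerical choices, and what the synthetic
fixtures can and cannot tell you about real data.

## Data model

A haplotype panel is an `n_sites × n_haplotypes` matrix over {0, 1} with
per-site metadata (identifier, 1-based bp position, the two alleles).
Sites must be biallelic with strictly increasing, distinct positions;
multi-allelic VCF records and duplicate positions are errors rather than
silently split or tie-broken.  Allele 1 is whatever the legend's
`allele1` column (or the VCF ALT) says; all statistics are computed under
that fixed orientation.

A genetic map is a list of physical positions with local rates (cM/Mb)
and cumulative genetic distance (cM).  Genetic distance between arbitrary
positions is linearly interpolated from the cumulative column; maps are
treated as translation invariant (the cumulative baseline is arbitrary).
Conversion from genetic distance to a per-meiosis recombination fraction
uses the Haldane map function `½(1 − e^(−2d))` (no crossover
interference), consistent with the exponential forms of the copying
model.

## LD statistics

Inputs are phased, so LD comes from direct gamete counts (no EM).  For
allele-1 frequencies `p_a`, `p_b` and joint frequency `p_ab`:
`D = p_ab − p_a p_b`; `D′ = D/D_max` with the usual frequency bound on
the side matching the sign of D; `r = D/√(p_a q_a p_b q_b)`.  LD with a
monoallelic site is undefined and raised as an error; callers drop such
pairs (per replicate, not globally).

Standard errors: `SE(r) = √((1 − r²)/(n − 2))` with `n` the haplotype
count.  For D′ we use the asymptotic variance under multinomial sampling
of the four gamete classes, computed by the delta method with a central
numerical gradient of D′ in the class proportions (step 1e-7): the
variance of a smooth statistic of multinomial proportions is
`(Σ p_i g_i² − (Σ p_i g_i)²)/n`.  On the boundary `|D′| = 1` (an empty
gamete class) the asymptotic variance is degenerate and the SE is
reported as undefined (NaN), never as 0; such pairs are excluded from
SD/SE ratio summaries and the exclusions counted.  The SE tracks a
10,000-draw multinomial bootstrap within ~3% at n = 200 for interior D′
(worst case under 10% in our checks; the test tolerance is 15%).

### Sign conventions in comparisons

`pair_ld` keeps the signed D′ and r.  The evaluation layer, however, uses
the magnitude |D′| for ΔD′ deltas, LD strata and the D′ SD/SE ratio.
Reason: for a pair in repulsion (D′ < 0), any attenuation moves D′
*toward zero*, i.e. upward; pooling signed deltas would mix positive and
negative "loss" terms and mask a systematic LD loss.  |D′| ∈ [0, 1] is
also the scale on which LD software conventionally reports D′.  r keeps
its sign where the SD and SE of r are compared, matching the closed-form
SE above.

## Resampling with recombination

Each output haplotype is generated independently: two parents drawn with
replacement, a uniformly chosen starting strand, and independent
strand-switches between adjacent sites with probability
`min(0.5, w · c_j)` (`c_j` the interval's Haldane fraction, `w` the
recombination weight, default 1).  The cap at 0.5 reflects free
recombination; it only binds for `w ≥ 5` on hotspot intervals.  One
offspring is produced per drawn pair (not both reciprocal products),
keeping output haplotypes i.i.d.  "2,000 subjects" therefore means 4,000
independent offspring.  With `w → 0` the method reduces to plain
haplotype resampling, which slightly *increases* LD when the output
sample is larger than the input (duplicate haplotypes) — visible as a
small positive mean ΔD′ at default settings.

## Mosaic copying model

Parameters: mutation parameter θ ≥ 0 (expected mutations per SNP for the
original sample; per-SNP flip probability `θ/(θ + k₀)`), effective
population size Ne > 0 (default 11,418, the value conventionally used for
European-ancestry panels), recombination weight w > 0 (default 1), start
locus (default random), and panel growth (default on).

The per-interval template-switch probability is
`1 − exp(−4·Ne·w·d_j / k)` with `d_j` in Morgans and `k` the *current*
template count — the Li–Stephens parameterization in which the population
recombination intensity `4·Ne·c` is shared across `k` templates.  This
form was chosen because it reproduces the empirically observed direction
of the Ne effect (larger Ne ⇒ more switching ⇒ lower LD).  The switch
target is uniform over the panel *including* the current template
(self-switches allowed), so the formula is the total transition mass.
With panel growth, `k` in the switch probability grows as haplotypes are
appended, while the mutation probability always uses the original count
`k₀`.

Construction of one haplotype: pick the start locus and a uniform
template; walk right then left from the start, independently, switching
templates at each crossed interval as above; then flip each site
independently with the mutation probability.  Because the template chain
is uniform-stationary and reversible, the construction is start-locus
invariant in distribution — verified by a replicate-level KS test (the
pooled per-pair deltas are mutually dependent within a replicate, so the
valid comparison unit is the replicate mean).

## Gaussian-threshold simulator

Thresholds are `z_i = Φ⁻¹(p_i)` for allele-1 frequency `p_i`; output
allele is 1 when the latent draw is ≤ `z_i` (the lower-tail convention;
by symmetry the choice is immaterial because the correlation fit uses the
same convention).  The latent correlation for each pair solves
`Φ₂(z_i, z_j; ρ) = p_ab` (tetrachoric correlation).  `Φ₂` is computed via
Owen's T function identity (near machine precision); the inversion is by
bisection on ρ ∈ [−1+1e-9, 1−1e-9].  Bisection iterates on interval
width (down to 1e-13) rather than on the CDF residual alone, because
`∂Φ₂/∂ρ` vanishes as |ρ| → 1 and a residual-only rule returns poor roots
there.  Joint frequencies at a Fréchet bound map to ρ = ±1 exactly.

The resulting correlation matrix (unit diagonal; thresholds absorb the
marginals) is generally not positive definite when boundary pairs are
present.  It is repaired by eigenvalue flooring: eigenvalues below the
tolerance (default 1e-6; the repair is idempotent) are raised to it and
the matrix reassembled.  Flooring perturbs the diagonal slightly, which
is the price of this classical repair; the per-site frequency bias it
introduces is far below sampling noise at the default tolerance.
Monoallelic sites have no finite threshold and must be removed before
fitting (`HaplotypePanel.drop_monoallelic`), mirroring how this method
family is used in practice.

Why this method loses LD: dichotomizing bivariate normal variables at
cuts `c₁, c₂` yields a phi coefficient
`(Φ₂(c₁,c₂;ρ) − Φ(c₁)Φ(c₂)) / √(Φ(c₁)(1−Φ(c₁))Φ(c₂)(1−Φ(c₂)))` whose
magnitude is strictly below |ρ| (equal to `2·arcsin(ρ)/π` for median
cuts).  Fitting recovers each pair's joint probability exactly, but
boundary pairs (|D′| = 1, ρ = ±1) cannot survive the PD repair plus
finite sampling, and the attenuation mechanism drags moderate-to-high-LD
pairs toward independence.  The evaluation framework shows the loss
concentrated in the original-D′ ≥ 0.8 stratum while ≤ 0.2 pairs are
essentially unbiased.

## Evaluation framework

Deltas are replicate − original, pooled over sites×replicates (MAF) or
pairs×replicates (LD); the per-replicate-mean aggregation is also exposed.
Summaries report N/min/Q1/median/Q3/max/mean/SD with type-7 (linear
interpolation) quantiles and n−1 SDs.  Stratification is keyed by the
*original* panel: LD bins (≤0.2, 0.2–0.8, ≥0.8) on the original pair
value, MAF bins (≤0.1, 0.1–0.3, ≥0.3) requiring both sites in the bin.
Pairs involving a site monoallelic in a given replicate are dropped from
that replicate only, so pooled N need not be a multiple of the replicate
count.  The SD/SE ratio compares the across-replicate SD of each pair's
LD estimate with the original-panel SE; ratios below 1 mean the simulator
introduces less variation than the sampling uncertainty of the original
panel.

## Synthetic fixtures

The founder-block generator gives provable control of LD structure
without an external simulator: blocks partition the sites, each block
gets a few founder haplotypes (allele frequencies from a MAF spectrum
with a floor, skewed toward rare variants), each output haplotype copies
one founder per block (uniformly, independently across blocks), and a
small per-site mutation noise is applied.  Two founders per block ⇒ at
most two haplotype classes per block ⇒ within-block |D′| = 1 before
noise; independent founder choice across blocks ⇒ between-block linkage
equilibrium up to 1/n sampling noise.

The default fixture ("GR-mini") is 100 sites over 300 kb, 400
haplotypes, four blocks of two founders, mutation noise 0.02, MAF floor
0.05, background 1 cM/Mb with three 10 kb hotspots of 50 cM/Mb at the
block boundaries (total map ≈ 1.8 cM, a hotspot-rich gene region; ≈2
expected copy-switches per mosaic haplotype at Ne = 11,418, k = 400).
This scale keeps every study-size run (50 replicates × 500 subjects) in
seconds while populating all LD and MAF strata.

What the fixture does *not* emulate: coalescent genealogy (no gradual LD
decay with distance within blocks), realistic allele-frequency spectra,
recurrent mutation, or population structure.  Passing tests on GR-mini
demonstrate the estimators and the direction and stratification of the
methods' biases; they do not calibrate the *magnitude* of bias expected
on any particular real region, which depends on that region's LD.

## Numerical and degenerate-input choices

* Crossover/switch probabilities are exact closed forms (`expm1`), not
  small-d approximations.
* `make_positive_definite` requires symmetry (1e-10), returns the input
  unchanged when its spectrum already clears the floor.
* Degenerate limits are honored exactly: zero recombination weight (or a
  vanishing map) makes resampling emit exact input copies; a vanishing Ne
  with θ = 0 and a frozen panel makes the mosaic method whole-haplotype
  resampling.
* A requested output of zero haplotypes yields a valid empty panel.
* Monoallelic sites: errors in LD and in the latent-Gaussian fit; dropped
  pairwise per replicate in the evaluation layer.
* All simulators take an integer seed and are bit-reproducible; replicate
  seeds in the CLI are spawned from one master `SeedSequence`.

## Known limitations

* The D′ SE is asymptotic; for very small n or near-boundary D′ it can
  deviate from the bootstrap by more than its usual few percent.
* The mosaic transition formula is one member of the Li–Stephens family;
  other software may scale `4·Ne·d` differently (e.g. fixed vs growing
  k), changing the absolute amount of switching but not the direction of
  any parameter effect.
* The Gaussian-threshold fit matches pairwise joint probabilities only;
  higher-order haplotype structure is not preserved even before repair.
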