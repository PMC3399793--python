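# grsim — gene-region haplotype simulation and LD-fidelity evaluation

Simulation studies of genetic-association methods need replicate haplotype
panels whose linkage disequilibrium (LD) looks like a real gene region.
`grsim` implements, in one toolkit, the three standard families of
"simulate directly from a phased panel" methods and the evaluation
machinery to ask the question that matters: *does the simulator preserve
the panel's LD, or does it systematically lose it?*

## The three simulators

Given a phased panel of *k* haplotypes over *m* biallelic SNPs and a
variable recombination map (cM/Mb along the region):

* **Resampling with recombination** (`simulate_resample`) — for each output
  haplotype, draw two haplotypes with replacement and recombine them, with
  per-interval crossover probability `min(0.5, w · c_j)` where `c_j` is the
  Haldane recombination fraction `½(1 − e^(−2d_j))` for the interval's
  genetic distance `d_j` (Morgans) and `w` a user weight.  One generation
  of random mating; no mutation.
* **Mosaic copying model** (`simulate_mosaic`) — Li–Stephens-style: each
  new haplotype copies segments of existing ones, switching templates at
  interval *j* with probability `1 − exp(−4·Ne·w·d_j / k)` and flipping
  each site independently with mutation probability `θ/(θ + k₀)` (`k₀` the
  original haplotype count).  New haplotypes join the template panel,
  emulating several generations of random mating.
* **Gaussian threshold** (`simulate_gauss`) — fit per-site thresholds
  `z_i = Φ⁻¹(p_i)` and a tetrachoric (latent-normal) correlation matrix
  from the pairwise joint allele probabilities, repair it to positive
  definite by eigenvalue flooring, draw multivariate normals and
  dichotomize at the thresholds.

## The evaluation framework

For replicate sets the package computes pooled per-site ΔMAF and per-pair
ΔLD (D′ and r²) distributions against the original panel
(N/min/Q1/median/Q3/max/mean/SD summaries), LD- and MAF-stratified
summaries, site×site median-delta matrices, and the per-pair ratio of the
replicate SD of the LD estimate to its original-panel SE
(`SE(r) = √((1−r²)/(n−2))`; an asymptotic delta-method SE for D′).
`phi_dichotomized(ρ, c₁, c₂)` quantifies the dichotomization-attenuation
mechanism — thresholding correlated normals always shrinks correlation
(`2·arcsin(ρ)/π` for median cuts) — which is exactly why the
Gaussian-threshold family loses LD at moderate-to-high-LD pairs.

## Worked example

Build the bundled synthetic gene region ("GR-mini": 100 SNPs over 300 kb,
400 haplotypes, four LD blocks separated by recombination hotspots),
simulate 20 replicates of 500 subjects with each method, and compare:

```python
import grsim as g
from grsim.gauss import fit_latent_model

spec = g.gr_mini_spec(seed=3)
panel, gmap = g.make_panel(spec), g.make_map(spec)

reps = {
    "resample": [g.simulate_resample(panel, gmap,
                 g.ResampleConfig(n_haplotypes_out=1000, seed=s))
                 for s in range(20)],
    "mosaic":   [g.simulate_mosaic(panel, gmap,
                 g.MosaicConfig(n_haplotypes_out=1000, seed=s))
                 for s in range(20)],
}
src = panel.drop_monoallelic()           # required by the threshold method
model = fit_latent_model(src)
reps["gauss"] = [g.simulate_gauss(src,
                 g.GaussConfig(n_haplotypes_out=1000, seed=s), model=model)
                 for s in range(20)]

for name, rr in reps.items():
    base = src if name == "gauss" else panel
    dD = g.delta_ld(base, rr, "Dprime").summary
    dr2 = g.delta_ld(base, rr, "r2").summary
    ratio = g.sd_se_ratio(base, rr, "Dprime")
    print(f"{name:9s} mean dD'={dD.mean:+.3f}  mean dr2={dr2.mean:+.4f}  "
          f"SD/SE median={ratio.median:.2f}")
```

which prints

```
resample  mean dD'=+0.025  mean dr2=+0.0007  SD/SE median=0.54
mosaic    mean dD'=-0.004  mean dr2=-0.0019  SD/SE median=0.70
gauss     mean dD'=-0.350  mean dr2=-0.0061  SD/SE median=0.26
```

Reading: resampling and the mosaic model are essentially unbiased in r²
(|mean Δr²| < 0.01) while the Gaussian-threshold method loses a third of a
unit of D′ on average — the attenuation is concentrated in pairs whose
original D′ ≥ 0.8 (see `stratified_deltas`).  The SD/SE ratios show
resampling introduces the least between-replicate variation and the mosaic
model the most, all below the original sampling uncertainty (ratio < 1).

The same pipeline is scriptable from a shell:

```bash
grsim synth --preset gr-mini --seed 3 --out-prefix fix
grsim simulate --method mosaic --hap fix.hap --legend fix.legend \
      --map fix.map --n-subjects 500 --n-replicates 20 --out-dir reps/
grsim evaluate --original-hap fix.hap --original-legend fix.legend \
      --replicate-dir reps/ --out-prefix report
grsim phi --rho 0.5        # -> 0.333333 (median-cut attenuation)
```

`grsim` reads and writes IMPUTE-style `.hap`/`.legend` pairs, phased VCF,
and HapMap-format genetic maps (position, cM/Mb, cumulative cM).

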