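# Methods

## Model and assumptions

The package targets one experimental design: *N* paternal half-sib families
(one sire, many dams, one progeny per dam) genotyped at *p* dense SNPs in a
target region of roughly 1 cM, with a quantitative phenotype whose regional
heritability h² is attributed to κ causal variants ("QTL signals") inside
the region.  Genotypes are coded additively, `X ∈ {1, 0, −1}` for A/A, A/B,
B/B with A the major allele; columns of X and the phenotype are centered
within family and scaled to mean square one, which removes the allele-
frequency dependence of effect sizes and makes `(1/n) X'X` a correlation
matrix.

### Theoretical region correlation

The central substitution is to replace the observed `(1/n) X'X` of a future
progeny generation by its expectation **R**, computable at design time.
Decomposing each genotype into independently inherited paternal and
maternal half-codes gives, per SNP pair (k, l),

```
K_kl = D^d_kl + Σ_s w_s D^s_kl + Σ_s w_s E^s_k E^s_l − Ē_k Ē_l ,
K_kk = p_k(1 − p_k) + ¼ − Ē_k² ,          Ē = Σ_s w_s E^s
```

with maternal gametic LD `D^d`, maternal allele frequency `p_k`, family
weights `w_s = n_s/n`, sire phase term `D^s_kl = a_k a_l (1 − 2θ_kl)/4`
(`a = hap1 − hap2 ∈ {−1, 0, 1}`, so the sign distinguishes coupling from
repulsion and homozygous loci vanish) and paternal expectation
`E^s_k = (hap1_k + hap2_k − 1)/2`.  The identity `a_k²/4 + E_k² = ¼` makes
the generic pair formula reproduce the variance formula on the diagonal,
which the implementation exploits to build K in one vectorized expression.
R is K scaled to unit diagonal after dropping loci with variance below
1e−12 (dropped indices are reported, never silently renumbered).

Recombination rates come from Haldane's map function,
`θ = (1 − e^(−2d))/2` with d in Morgan.  No interference is assumed, which
matches the gamete simulator (independent crossovers per marker interval).
Physical positions are converted at 1 Mbp = 1 cM when no genetic positions
are supplied.  These are conventions, not estimates; both are configurable
at the map level.

### Multi-SNP power

With ridge estimation `β̂ = (X'X + λI)⁻¹X'y`, the z-statistic
`T_k = β̂_k / SD(β̂_k)` is treated as normal with variance 1 (the ridge
estimator does not satisfy the conditions for a t distribution).  Its mean
under the alternative follows from the moments of β̂ with `(1/n) X'X → R`:

```
μ_k = √n/σ_e · {(R + λ/n I)⁻¹ R β}_k / √{(R + λ/n I)⁻¹ R (R + λ/n I)⁻¹}_kk
```

Only β/σ_e enters, so σ_e ≡ 1 internally.  Equal variance contributions of
the κ signals give `β/σ_e = √(h²/(κ(1 − h²)))`, and the design-time
shrinkage is the closed-form Hoerl value `λ = p(1 − h²)/h²` (a
linkage-equilibrium approximation; a data-driven REML/CV λ is out of scope
at design time).  λ is held fixed while n varies — the statistic depends on
λ/n.  Two-sided power is `π(μ) = Φ(μ − z_{1−α/2}) + Φ(−z_{1−α/2} − μ)`.

The per-SNP tests of the multi-SNP model use the overall α (default 0.01)
without multiplicity correction: the joint fit already accounts for the
other SNPs, and correcting only the baseline keeps the two models
comparable on the footing users encounter them.

### Sample-size search

For one draw of κ QTL positions, the minimal n with
`min_k π(μ_k(n)) ≥ target` is found by integer bisection over [1, 5000];
monotonicity of power in n is checked at the bracket and a linear scan is
the fallback (never observed to trigger in practice).  The minimum over
signals is used because the declared aim is to distinguish *every* signal;
a mean-power criterion is available as an option.  Positions are redrawn
(default 100 times, each draw seeded by (seed, draw) so subsets reproduce)
and the median of successful draws is `n_opt*`; an even number of draws
takes the upper-rounded mean of the middle pair, conservatively.  Draws
whose target is unreachable at n_max are excluded from the median and
reported; if more than half fail the result is "> n_max".

Repeated evaluation uses a one-time eigendecomposition of R
(`μ` reduces to weighted spectral sums), numerically identical to the
direct symmetric solve, which makes a full 100-draw search on a 300-SNP
region take well under a second.  Eigenvalues are clipped at zero only
inside this kernel and inside M_eff; stored K/R are never repaired.

### Single-SNP baseline

Per-SNP OLS gives an exactly noncentral-t statistic (n − 1 df,
`δ = β/σ_e √n`).  The exact noncentral-t CDF is required — the normal
approximation misses small-n solutions by several animals.  The lower-tail
term is computed through the symmetry `P(T_{df,δ} < q) = P(T_{df,−δ} > −q)`
because scipy's Boost-based `nct.cdf` returns NaN for negative quantiles at
moderate noncentrality.  The region-wide level is `α_k = α/M_eff` with
M_eff from the simpleM rule: the smallest number of descending eigenvalues
of R whose cumulative sum reaches 99.5 % of the trace (negatives clipped,
ties resolve to the smaller count).

## Synthetic data

The generator reproduces the study conditions end to end.  Defaults: 300
SNPs on 1 cM, 2000 diploid founders (half candidate sires, half dams),
N = 10 sires truncation-selected on a one-QTL founder phenotype, 1000
maternal gametes for estimating `D^d`, balanced families.

**Coalescent founders (default).**  msprime ancestry with a recent
effective size of 100 and stepwise ancestral sizes 500 / 1 500 / 6 000 /
12 000 / 100 000 at 100 / 10³ / 10⁴ / 10⁵ / 10⁶ generations — a
livestock-like history of strong recent drift against deep ancestral
diversity — on 1 Mbp with recombination 1e−8 per bp.  The mutation rate is
5e−8, the smallest round value that reliably yields ≥ 300 segregating
sites for 4000 sampled haplotypes on 1 Mbp; 300 sites are then taken evenly
over the segregating sites.  This realizes the calibration target of a mean
adjacent-SNP r² of 0.45 (±0.05 across replicates) together with long-range
linkage blocks of alternating phase — the feature that drives both the low
effective-test counts (M_eff ≈ 50 of 300) and the inflated sample sizes of
unlucky QTL draws.  Calibration used only the adjacent-r² statistic.

**Markov founders (option).**  A first-order Markov haplotype chain whose
transition probabilities are solved per adjacent pair to hit the target r²
exactly at drawn allele frequencies.  It is exactly calibrated and fast but
carries *no* LD beyond first order: its R matrices have near-full effective
dimension (M_eff ≈ 270 of 300) and mild sample-size inflation.  It is kept
for controlled unit-level experiments; conclusions about realistic designs
should use the coalescent engine.  Externally simulated or phased real
haplotypes can be wrapped directly in `FounderPopulation`.

Gametes recombine independently in each marker interval with the adjacent
Haldane θ (no interference), matching the covariance derivation.  Progeny
phenotypes place equal effects on the observed-genotype scale at the chosen
QTL and set the residual variance from the realized genetic variance so
that the regional variance fraction equals h²; there is no polygenic
background term — h² is strictly the regional QTL fraction.

What the generator does **not** emulate: mutation within the pedigree,
genotyping error, multi-generation selection, population admixture, or a
polygenic background outside the region.  Passing tests therefore show that
the theory and its implementation are mutually consistent under the stated
population model, not that any particular cattle population has exactly
this LD profile.

## Validation stage

`ridge_fit`/`ridge_test` implement the exact ridge solution and the z-test
with `V(β̂) = (X'X + λI)⁻¹X'X(X'X + λI)⁻¹σ_e²`.  When σ_e² is not supplied
it is estimated from ridge residuals with effective degrees of freedom
`df = tr[(X'X + λI)⁻¹X'X]`; simulations may pass the true σ_e².  This
plug-in replaces a REML variance component estimate; it makes the null test
slightly conservative, which the null-calibration test bounds at 1.5·α.
The single-SNP scan BH-adjusts its p-values (multi-SNP p-values stay raw).
Detection scoring counts a QTL as found if any significant SNP lies within
±0.01 cM; significant SNPs outside all (merged) windows are false
positives, with the number of outside-window SNPs as FPR denominator.  The
window convention and denominator are configurable.

## Numerical and design choices

* `A = R + (λ/n)I` is SPD for λ > 0; solves use Cholesky, no inverses.
* Indefiniteness of theoretical R (possible after estimation noise in D^d)
  is handled by clipping eigenvalues at zero inside the power kernel and
  M_eff only.
* Family weights default to equal; planned sizes are accepted for
  unbalanced designs (design-time weights, since realized sizes are
  unknown when the experiment is sized).
* All randomness flows from `numpy.random.Generator`s seeded explicitly;
  study replicates use child seeds (seed, replicate), QTL draws
  (seed, draw), so identical configurations are bit-reproducible.
* The replicated study driver at its default scale (25 replicates × 100
  draws) runs in ~30 s; the choice balances median stability (SE ≈ 3
  animals) against interactive turnaround.

## Known limitations

* The theoretical R assumes dams are random draws from one dam population;
  assortative mating or dam selection would bias `D^d`.
* The normal approximation of the ridge z-statistic ignores estimation
  error in σ_e² and the dependence among the p tests; empirical rejection
  rates match within Monte-Carlo error in the tested regimes but small-n
  extreme-α behaviour is approximate.
* M_eff from the 99.5 % rule is sensitive to near-zero eigenvalues and
  hence to the haplotype diversity of the founder pool; with the Markov
  engine it is several-fold larger than with coalescent founders at the
  same adjacent r².
* Dominance coding and mixed-model (polygenic background) association are
  not implemented.
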