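# Methods

This note records the models, parameter choices, and numerical decisions
behind methylpod, and what the synthetic-data tests do and do not establish
about real data.

## Occupancy scoring

Raw inputs are per-base-pair coverage tracks for input DNA, IPOD (total
protein occupancy), and RNAP-ChIP, three biological replicates each, on a
circular chromosome. The scoring chain per genotype:

1. **Quantile normalization** across all replicates of all data types of
   that genotype: each track's sorted values are replaced by the
   position-wise mean of all tracks' sorted values. Ties within a track
   receive the mean of the reference values their ranks span. Whether
   normalization should pool across genotypes as well is exposed by simply
   passing a different track list to `normalize_replicates`; the default
   (within genotype) matches the joint treatment of "each replicate of each
   data type" for one strain. A practical consequence worth knowing:
   strong enrichment occupying a visible fraction of the genome is
   compressed by joint quantile normalization (a 5× planted ChIP peak ends
   up near robust z ≈ 2 rather than ≈ 5), because the reference
   distribution averages enriched and unenriched channels.
2. **Median scaling to 100** per track, then a **pseudocount of 0.25**, so
   every output median is 100.25 and log ratios are defined everywhere.
3. **log2(signal/input)** per paired replicate.
4. **Robust z**: `(x − median) / (1.4826 · MAD)`; the constant makes MAD a
   consistent σ estimate under normality. Signed p-scores are
   `sign(z) · (−log10 p)` with p the two-sided normal tail, floored at the
   smallest positive double so extreme z stays finite.
5. **Jackknife summary** over replicates: leave-one-out means θ̂ᵢ,
   `SE² = (n−1)/n · Σ(θ̂ᵢ − θ̄)²`, CI = mean ± 1.96·SE. The normal
   multiplier (not t with 2 df) follows common jackknife reporting; at
   positions where all replicates agree exactly the SE is set to exactly
   zero rather than left to float round-off.

Genotype subtraction for difference tracks is `max(mutant, 0) −
max(wildtype, 0)`: negative occupancy scores carry no evidence of binding,
so they are clamped before subtracting to highlight mutant-specific gains.

## EPOD calling

Thresholds come from the 256 bp circular rolling median of robust z: its
90th percentile (strict) or 75th (loose), linearly interpolated. A domain
is a maximal run where the 768 bp rolling median exceeds the threshold,
kept if ≥ 1,024 bp. Over such a run the median of the 768 bp rolling median
trivially exceeds the threshold, so the run realizes the defining phrase
("a region of at least 1,024 bp over which the median of a 768 bp rolling
median exceeds the percentile") while placing boundaries at the signal
edges. An alternative operationalization — sliding a 1,024 bp qualification
window and taking the union of qualifying windows — was implemented first
and rejected: window qualification extends every call by roughly 850 bp per
flank regardless of the true domain edge (median-of-median geometry), which
caps base-pair Jaccard against planted 2 kb domains near 0.57. The run
rule recovers the same domains with boundary error of a few hundred base
pairs (Jaccard ≈ 0.77 under the standard simulation).

Rolling windows of even width use left-inclusive centering: position *i*
summarizes `[i − w/2, i − w/2 + w)` on the circle, consistently across the
256/768/1024/75 bp widths, so tracks of different smoothing widths stay
aligned and the caller is exactly equivariant under genome rotation.

### Reproducibility filtering (IDR)

Replicate-level calls are union-merged into candidates; each candidate is
scored per replicate by its mean robust z. For each replicate pair the
scores are rank-transformed to pseudo-uniform values and mapped to
pseudo-data through the inverse marginal CDF of the current mixture model
(semiparametric step), then a two-component bivariate Gaussian mixture is
fitted by EM: a fixed irreproducible component (standard bivariate normal,
ρ = 0) and a reproducible component N((μ,μ), σ², ρ). The posterior
probability of the irreproducible component is the local idr; candidates
sorted by local idr are cumulatively averaged to a global IDR. Candidates
whose **worst pairwise** global IDR is ≤ 0.05 are retained — the
conservative multi-replicate rule. EM runs to tolerance 1e−6 (≤ 500
iterations) inside ≤ 40 pseudo-data updates.

Small candidate sets are a real failure mode: with fewer than four
candidates, or when EM degenerates (mixing weight at a bound, or
non-convergence), the filter falls back to retaining candidates called in
every replicate and emits a warning. EPOD analyses routinely produce only
tens of candidates, so this fallback is considered part of the method, not
an error path.

## Symmetrized overlap distance

`SOD = 1 − sqrt(A_B · B_A)` with `X_Y` the fraction of *Y*'s strict
intervals sharing ≥ 1 bp with *X*'s loose intervals. It is symmetric by
construction, 0 for coinciding landscapes and 1 for disjoint ones. For peak
sets the same formula is applied with strict = loose = the 2.0-threshold
peaks.

## Motif windows and density loci

Dam sites are forward-strand GATC matches; Dcm sites are CCAGG or CCTGG.
GATC is its own reverse complement and the two Dcm words are mutual reverse
complements, so forward scanning covers both strands without double
counting. Windows add 50 bp per side (104 bp for Dam, 105 bp for Dcm),
wrapping across the origin on circular genomes and clamping on linear ones.
Density counts same-class sites whose **full motif** lies inside the window
— symmetric and unambiguous at window edges. Unique loci at a density level
are the merged unions of overlapping-or-bookended windows carrying exactly
that density flag; `collapse_rule_sensitivity` reports the counts under two
alternatives (strict-overlap merging; density ≥ level) since the collapsing
rule is a genuine free choice. On planted-cluster genomes all three rules
agree at high densities; they diverge only when same-density windows abut
without overlapping.

## Shuffled-interval depletion regression

Genomic intervals define 10 AT%-quantile bins (AT% = A/T fraction of the
interval's sequence). 1,000 shuffles preserve every interval length and
place starts uniformly on the circle; in "no overlaps" mode placements
intersecting the originals are rejected (≤ 10,000 attempts each). All
intervals enter a Poisson GLM: `count ~ genomic_indicator + bin`, offset
`log(length/1000)`, fitted by IRLS (statsmodels), with Wald 95% CIs. The
"overlaps" mode is the weaker design: when the genomic intervals cover a
noticeable genome fraction, shuffles landing inside them inherit the
depletion and attenuate the coefficient toward zero (observed: planted
−0.3 recovered as ≈ −0.20 at 30% coverage vs ≈ −0.26 in "no overlaps"
mode). Null calibration: across 200 seeded null replicates the 95% Wald CI
covers zero ≈ 97% of the time.

## Peak calling and the KL threshold sweep

Smoothed scores are the 75 bp circular rolling mean of robust z; a peak at
threshold *t* is a maximal run strictly above *t*. For each grid threshold
(default 0.5–6.0, step 0.25) one same-length non-peak region per peak is
placed uniformly, rejecting peak overlap; KL(peak ‖ non-peak) is estimated
on a shared 100-bin histogram spanning the pooled range with +1 pseudocount
per bin. Ties break toward the lower threshold; thresholds with no peaks
are recorded as missing. The 2.0-threshold peak set is always kept as the
cross-strain reference.

A property of this estimator worth stating plainly: for cleanly separated
plateaus of height *h*, KL increases gently with threshold (ramp base pairs
leave the peak distribution, concentrating it) and the maximum lands at the
highest grid threshold still below *h* — not in the middle of the flat
region. The landscape is nonetheless "virtually flat" (relative variation
2–7% over thresholds 1–3 in our simulations), which is why a fixed 2.0
reference threshold is the meaningful cross-strain anchor. When the same
peaks travel through the full coverage-to-robust-z chain, quantile
normalization compresses the effective plateau height and the sweep picks
2.0.

## Expression and regulons

Directional significance is `sign(log2FC) · (−log10 q)` with q floored at
1e−300 — the continuous input format for downstream gene-set enrichment. A
transcript is "within EPODs" when its gene interval overlaps the wild-type
strict EPOD set by ≥ 1 bp (reference genotype configurable); the contrast
is median(inside) − median(outside) with a two-sided rank-sum p. Regulon
coherence multiplies each non-dual target's log2FC by +1 (activator) or −1
(repressor) and averages; dual-mode edges are excluded. The statistic is
linear in the fold changes, so negating all target responses negates it.
The alternative reading — signing relative to the regulator's own
expression change — is deliberately not folded in; the regulator's own
log2FC is reported alongside for that comparison.

## BEST credible intervals

One-sample data are modelled as Student-t(ν, μ, σ) with the method's
standard vague priors: μ ~ Normal(x̄, 1000·s), σ ~ Uniform(s/1000, 1000·s),
ν − 1 ~ Exponential(1/29). The posterior is sampled in (μ, log σ,
log(ν−1)) with an affine-invariant ensemble sampler (emcee, 8 walkers,
vectorized likelihood), seeded; half the chain is burn-in. Walkers are
grouped into four pseudo-chains for a split-R-hat check (< 1.05 required;
failure raises rather than returning a silently unconverged interval), and
the 95% HDI for μ comes from arviz. At n = 5,000 the HDI width agrees with
the classical t-interval within a few percent.

## Synthetic data

The generators emulate the study's data shapes, not its biology:

- **Genomes**: i.i.d. bases at a requested GC (default 0.508, the *E. coli*
  value); motif clusters are written verbatim with 8 bp spacing after
  scrubbing the neighbourhood of accidental same-class matches, so a
  planted density-*d* cluster scans back at exactly density *d*.
- **Coverage**: negative binomial per base pair (Var = μ + φμ², default
  depth 50, φ = 0.1), independent across replicates and positions. The
  standard occupancy conditions are 10 domains of 1.5–3 kb at 2.5×
  enrichment on 1 Mb with 3 replicates. No autocorrelation is modelled:
  real coverage is locally correlated through fragment size, so real
  boundary error will exceed the simulated one. GC-coverage bias,
  replication-origin gradients, and mappability are likewise absent —
  passing recovery tests here demonstrates the estimators are correct, not
  that they are robust to those artifacts.
- **Expression**: baseline log2FC ~ Normal(0, σ), planted effects add
  mode-sign × δ to a regulator's targets; q-values are BH-adjusted
  two-sided z-tests. Gene-level measurement error correlation is ignored.
- **Read ends**: Poisson per position with optional single-position
  pile-ups.

Every generator takes a single seed and emits a machine-readable truth
record; recovery tests consume only the simulated inputs plus that record.

## Problem sizes and runtimes

The bundled analyses use 0.8–1 Mb genomes (vs 4.6 Mb for the real
chromosome), 200 intervals × 1,000 shuffles for the regression, 200 null
replicates at 50 shuffles for CI calibration, and 5,000 draws for the BEST
check — sizes chosen so the full suite and the acceptance script each
complete in a few minutes on one CPU while keeping every estimate's Monte
Carlo error well inside the tolerances being tested. All statistics scale
linearly in genome length, so running the same code at full chromosome
scale changes nothing but time.

## Known limitations

- The IDR mixture is fitted on interval-level mean scores; with strongly
  graded (non-separated) score distributions the global IDR ≤ 0.05 cut is
  conservative and drops weak-but-real candidates, as any rank-based IDR
  does.
- "Overlaps"-mode shuffle regression is attenuated at high interval
  coverage (see above); the no-overlaps coefficient is the cleaner
  estimate of planted depletion.
- The KL threshold sweep selects the top of the viable threshold range for
  idealized plateaus (see above); its value is in flagging the flat region
  and anchoring cross-strain comparisons, not in the argmax per se.
- Circular-genome wrap-around is supported throughout, but multi-chromosome
  or linear-eukaryotic layouts are out of scope.
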