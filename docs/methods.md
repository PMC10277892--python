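# Methods

## The quantity being computed

Fragment analysis of a PCR-amplified short-tandem-repeat locus (e.g. the CAG
tract of *Htt*) yields an electropherogram: fluorescence (RFU) against
fragment size (bp). In tissue where the repeat is somatically unstable, the
amplicon pool is a mixture of lengths and the trace shows a ladder of peaks
one repeat unit apart. The **somatic instability index** condenses this
ladder into one signed number:

1. the **main allele** `m` is the tallest peak in the analysis window (ties
   break to the smaller repeat);
2. peaks below `threshold_frac` of the main-peak height are discarded — the
   *signal-to-noise threshold*, 0.05 by default;
3. retained heights are normalized to sum to one, `h̃_i`;
4. `index = Σ h̃_i (repeat_i − m)`.

The **expansion index** restricts the sum to `repeat_i > m` and the
**contraction index** to `repeat_i < m`, but both use the *jointly*
normalized `h̃`, so `expansion + contraction = index` holds exactly (the
package computes the signed index as that sum, and an independent
brute-force oracle in the test suite checks the summed value to 1e-12).
Contraction peaks enter with negative sign; this is what allows a slightly
negative index in young tissue where minus-stutter products outweigh true
expansion. At `threshold_frac = 0` the index is exactly the height-weighted
mean displacement from the main allele.

A false-sounding monotonicity claim is worth recording: raising the height
of an expansion peak does *not* always raise the index. The derivative of
`index = S/T` with respect to height `h_i` is `(Δ_i·T − S)/T²`, so the index
moves toward `Δ_i`: up if `Δ_i` exceeds the current index, down otherwise.
The property test asserts this directional form.

## Microsatellite-instability comparison

For mononucleotide (poly-A) marker loci of a Bethesda-style panel the
package compares each sample to a reference sample at the same locus:
main-allele shift (sample − reference, integer repeats) and the difference
of instability indices. A sample is flagged unstable when the absolute
shift reaches `min_shift` (default 1 repeat, the smallest detectable novel
allele). The comparison is antisymmetric under swapping sample and
reference. Index differences are reported but do not by themselves flag
instability: stutter-driven index wobble at a stable locus is expected.

## Peak calling and repeat binning

`call_peaks` replaces interactive peak picking: moving-average smoothing
(default 0.5 bp), rolling-minimum baseline subtraction (default 20 bp
window), `scipy.signal.find_peaks` with absolute height and prominence
filters (defaults 50 and 25 RFU against a default render amplitude of
10,000), and 3-point parabolic apex interpolation for sub-grid sizing. For
mononucleotide loci (1 bp lattice) narrower settings are appropriate; the
tests use smoothing 0.15 bp and peak width 0.25 bp.

`bin_to_repeats` maps apex sizes to the lattice
`size = flank_bp + unit_len × repeat`, dropping peaks whose lattice residual
exceeds `residual_tol_bp` (default 1.0 bp for a 3 bp unit — a guard of a
third of a unit against sizing error) and peaks outside the analysis
window. The window is what excludes the unexpanded wild-type allele of a
heterozygous animal from the expanded-allele index; the packaged CAG locus
uses repeats 70–170. When two peaks bin to one repeat the taller wins and
the collision is logged. The amplicon flank length is assay-specific and
user-supplied; `estimate_flank` recovers it from a sample of known repeat
number (flank = tallest-peak size − unit × known repeat).

## Synthetic data: what it emulates, and what it does not

The generator exists so every stage has ground truth.

**Expansion model** (`simulate_cell_population`): a mosaic compound-Poisson
process. A fraction `expanding_fraction` of cells is expansion-competent;
each competent cell draws `Poisson(expansion_rate × months)` unit gains and
`Poisson(contraction_rate × months)` unit losses; repeat counts are floored
at 1. The mosaic fraction (default 0.5, a bulk striatal punch being roughly
half neurons) is essential, not cosmetic: if every cell expanded with mean
gain 4, the *modal* allele would shift by ~3 and an index defined relative
to the tallest peak would read ~0.8. With a competent fraction the mode
stays at the inherited allele and the threshold-0 index equals the
tissue-level mean gain `expanding_fraction × (rate difference) × months`,
which is also the truth value the cohort simulator emits. With
`expanding_fraction = 1` the model reduces to plain compound Poisson.

**Stutter** (`apply_stutter`): geometric slippage — weight `minus_ratio^k`
at `n−k` and `plus_ratio^k` at `n+k`, `k ≤ max_steps`, then renormalize.
Defaults 0.15 / 0.01 / 4 match typical trinucleotide stutter; poly-A loci
get a higher minus ratio (0.25 in the tests). Stutter biases the index
slightly negative (about −0.13 for a pure allele at the default settings)
and truncation at the 5% threshold biases a gain-4 group's index to ~3.75;
both groups of a comparison carry the stutter bias, so group *differences*
are the meaningful readout — which is how the index is used.

**Rendering** (`render_trace`): Gaussian peaks (default sigma 0.6 bp) on the
locus lattice, per-peak sizing jitter (SD 0.05 bp), amplitude decay per
repeat above the main allele (default 1.0 = off), additive baseline noise
(SD 20 RFU), clipped at zero; the tallest apex equals `amplitude` before
noise.

**Cohorts** (`simulate_cohort`, `blocked_expansion_design`): groups of 5–6
animals mirroring a blocked-expansion study — baseline at injection age
(gain 0), vehicle and non-targeting controls expanding freely (gain 4 over
2 months), treated group strongly suppressed (gain 0.5). Per-animal seeds
derive from SHA-256 of (design seed, group label, animal index), so cohorts
are bit-reproducible and seeds never collide across groups. Inter-animal
heterogeneity is a per-group gamma multiplier on both rates (`rate_cv`,
mean 1); the study-shaped helper defaults to CV 0.3, consistent with the
group-level spreads real cohorts show. Without it, at 1e5 cells the only
per-animal noise is sampling error (index SD ~0.03) and any nonzero group
difference would be declared significant.

Not emulated: within-trace dye pull-up, off-scale clipping, heterozygous
wild-type allele signal (excluded by the window in real data), PCR
competition between alleles beyond the single decay factor, and any
mechanistic mismatch-repair biology. Passing tests therefore demonstrate
the *quantification machinery* is correct and calibrated on data whose
generative structure is known — not that the biological model is right.

## Group statistics

`one_way_anova` is the textbook between/within decomposition (cross-checked
against `scipy.stats.f_oneway`). Degenerate conventions: all groups
identical and constant → `(F=0, p=1)`; zero within-group variance with
distinct means → `(inf, 0)`.

`dunnett` compares each treatment to a named control with family-wise error
control. Observed statistics are pooled-variance t's; adjusted p-values are
`P(max_j |T*_j| ≥ |t_i|)` under the joint null, estimated by seeded Monte
Carlo (group means ~ normal with the right 1/n scaling, pooled variance ~
scaled chi-square; default 200,000 draws, Monte Carlo SE reported per
contrast). This handles unbalanced groups exactly in distribution; with one
treatment it reduces to the two-sided pooled t-test. The implementation is
cross-checked against `scipy.stats.dunnett` in the tests, and its
family-wise error under a global null (3 treatments, n=6) calibrates to
0.05 within binomial error over 1000 replicates. The calibration runs use
20,000 draws per call (adjusted-p Monte Carlo SE ≈ 0.0015 near p = 0.05),
a precision/runtime choice.

`t_test` is pooled-variance Student by default (Welch by flag), two-sided,
with the degenerate zero-variance conventions stated in its docstring.
`fit_4pl` fits `y = bottom + (top − bottom)/(1 + (d/IC50)^hill)` by least
squares with IC50 on the log scale, extremes-based initialization, a loose
data-driven parameter box to keep the optimizer out of runaway plateaus,
and an honest `converged` flag. The dose-response generator emulates the
screening assay as run in practice: triplicate wells per dose, 7-point 2×
dilution bracketing the expected potency (top dose 8 × IC50), 5%
multiplicative (assay-CV) noise. Under those conditions median IC50
recovery error is ~7% across the 15–479 nM potency range; with single
wells and additive noise of 5% of the signal range the same fit degrades
to ~25% median error — replication, not the fitter, is what buys the
precision.

## Problem sizes and tolerances

Defaults chosen once for the test suite and acceptance script: 1000 random
peak sets for the index-oracle check at 1e-12; cohort recovery with n = 6
animals, 1e5 cells per animal (sampling SE on a group mean index ≈ 0.01);
the four-group detection scenario with 100 replicate cohorts at 2e4 cells
per animal and 2e4 Dunnett draws; MSI null with 100 seeds × 20 rendered
traces; IC50 recovery with 100 seeds. Everything runs in well under a
minute on one CPU.

## Known limitations

- No stutter deconvolution before indexing: indices are compared between
  groups sharing the same stutter, as the assay is used; absolute index
  values carry a stutter- and threshold-dependent bias.
- No modal-allele-change-over-time tracking; the index is cross-sectional.
- Binary chromatogram formats (ABIF/.fsa) are out of scope; traces and peak
  tables are plain delimited text.
- The "5% signal-to-noise threshold" is interpreted as 5% of the tallest
  in-window peak; instruments or scripts defining it against baseline noise
  would retain a different peak set at very low signal.
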