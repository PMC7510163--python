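# Methods

## The read-density model

A genome of length `G` (bp) carries `n` binding events. Each event has
a forward-read enriched region `E_f` of width `w` and, `d` bp
downstream, a reverse-read enriched region `E_g` of the same width;
`E_g` is indexed by reverse-read 5′ coordinates (the rightmost aligned
base), so the matching forward and reverse 5′ ends sit exactly
`d + w` apart and `d + w` plays the role of the mean fragment length.
Of `M` mapped reads (`M/2` per strand), a fraction `α ∈ [0, 1]` are
signal reads whose 5′ ends are uniform over the enriched regions; the
rest are noise, uniform over the genome. Densities are binarised:
`f(i), g(i) ∈ {0, 1}` record whether ≥ 1 read 5′ end sits at `i`, so
duplicated positions collapse and `M_u` denotes the post-collapse
count.

The *degree of saturation* `Mα / 2nw` decides the regime: above one,
the expected signal reads exceed the `nw` available enriched positions
per strand and the binarised regions fill up ("saturated"); the
boundary value 1 is treated as unsaturated. Unsaturated per-position
rates are `μ = M/2G`, `p_N = μ(1−α)` and
`p_S = p_N + (Mα/2nw)(1 − p_N)`.

Counting window positions by enrichment status on both strands
(`|X_SS|, |X_SN|, |X_NS|, |X_NN|`) gives the expected shifted AND
count `⟨|D_x|⟩ = |X_SS| p_S² + (|X_SN|+|X_NS|) p_S p_N + |X_NN| p_N²`
and hence the expected coefficient
`⟨NCC(x)⟩ = (⟨|D_x|⟩/(G−x) − μ²)/σ` with `σ = μ(1−μ)`. At full overlap
(`x = d + w`) this yields the closed-form maximum, whose cascade of
approximations ends at `(M/2nw)α²` (requires `d + w ≪ G`, then
`M ≪ G`); at zero overlap (`x₀`) it yields the minimum, a small
negative number `≈ −Mα(M(1−α)² + Gα) / (2G−M)G` that approximates 0
only once `M ≪ G`. We verified symbolically that the closed forms and
the expected-count route are the same polynomial identity; the test
suite re-checks the identity numerically to 1e−12 over a 144-point
parameter grid. In the saturated regime only the two printed limits
are carried (minimum ≈ 0; maximum `nw / (M_u/2 · (1−α) + nw)`); exact
saturated expressions are out of scope and requesting other levels
returns the same saturated value.

For shifts between the two extremes the per-pair overlap is
`max(0, w − |x − (d+w)|)` under the (exact, by construction)
assumption that sites do not interact, giving the full expected
triangular profile; this extension beyond the printed endpoint cases
is validated against simulation.

## Estimators

`NCC(x)` is the Pearson correlation of `f(i)` and `g(i+x)` over
`i ∈ [0, L−x)`. Two estimators are available:

- **exact** (default): means and variances per shift over the actual
  window, computed from exact integer sums; the coefficient follows
  from `n·Σfg − Σf·Σg` in integer arithmetic, so results are
  bit-reproducible. The default was chosen because the global form is
  explicitly an approximation.
- **global**: `μ = M_u/2L`, `σ = μ(1−μ)` genome-wide, coefficient
  `(|D_x|/(L−x) − μ²)/σ`; cheaper by one popcount and the form the
  theory manipulates. For sparse densities (`M ≪ L`, small `x/L`) the
  two agree to ~1e−3, which a test asserts.

`MSCC(x)` restricts the index set to doubly mappable positions
`{i : m_f(i) = 1 ∧ m_r(i+x) = 1}` with means/variances over that set.
Masks come from BigWig tracks (values < 1, including missing data,
binarised to 0), from exact k-mer uniqueness for small synthetic
genomes (exact-match only — stricter than mismatch-tolerant real-data
tracks, which are loaded rather than computed), or synthesised
directly. A reverse placement with 5′ end `j` occupies `[j−R+1, j]`,
so the reverse mask is the leftmost-base mask shifted right by `R−1`;
mask entries whose placement would overhang a chromosome end are
cleared. Fewer than 4 contributing positions, or a zero-variance
window, makes a coefficient undefined (propagated as missing, never
as zero).

All per-shift sums are shifted-AND popcounts over bit vectors packed
at all 8 bit offsets, so a shift is a byte-aligned slice: one AND +
popcount pass per quantity per shift (1 for NCC, 4 for MSCC), ~G/8
bytes each. Sparse per-window strand sums come from sorted position
arrays by binary search.

Per-chromosome coefficients merge by Fisher's r-to-z transformation
with a weighted mean and back-transform. The weights are
`max(count − 3, 1)` — the inverse asymptotic variance of z — with
chromosome length available as an alternative; `|r| = 1` is clamped to
`1 − 1e−8` with a warning before the transform. Chromosomes undefined
at a shift drop out of that shift's average.

## QC metrics

- **Fragment length**: argmax of the merged profile with shifts in
  `[R − h, R + h]` excluded (default half-width `h = 10` bp) to skip
  the phantom peak; ties break toward the smaller shift. Exclusion is
  harmless for MSCC, which suppresses the phantom anyway.
- **Width `w`**: FWHM of the fragment peak. The model's peak is
  triangular with base `2w`, so FWHM ≈ `w`. The half-maximum baseline
  is the profile minimum over the computed range (the baseline is
  otherwise undefined; the range minimum is the least structured
  choice), and crossings interpolate linearly between evaluated
  shifts. `adjust_w` divides by a cohort-calibrated slope (from a
  no-intercept regression of FWHM on an independent width estimate,
  `fit_w_slope`); default slope 1 since any calibration is
  dataset-specific.
- **VSN** `= (2w/M) · max(MSCC)`, the coefficient taken at the
  estimated fragment length; under the model `VSN ≈ α²/n`.
- **NSC/RSC**: `cc(frag)/cc_min` and
  `(cc(frag) − cc_min)/(cc(R) − cc_min)`, provided for comparison with
  legacy pipelines. The minimum defaults to the range minimum
  (a "minimum at the largest shift" mode is available). A
  non-positive minimum makes NSC undefined — which the theory predicts
  for clean data, since the true minimum is slightly negative.
- **Cohort workflow**: `α̂` from FRiP via the exact inversion
  `α̂ = (FRiP − n(2w+d)/G)/(1 − n(2w+d)/G)` (clamped at 0 with a
  warning below the noise floor; the `FRiP ≈ α` shortcut applies when
  `G` is unknown), then unweighted OLS of `log10 n̂` on `log10 α̂`
  (log-log because the relation is a power law; base 10 for
  readability). A new sample's VSN solves
  `α = (VSN · 10^a)^{1/(2−b)}`, `n = 10^{a + b·log10 α}`; slope
  `b = 2` is degenerate and rejected, and solutions with `α ∉ (0, 1]`
  are flagged as extrapolation.

## The simulator

`simulate_sites` places `n` non-overlapping `2w + d` footprints by
seeded rejection sampling (cap `1000n` tries), apportioned to
chromosomes by length, kept clear of chromosome ends so every
full-length read fits (reads that would overhang are rejected at
write time and skipped at read time). `simulate_reads` draws, per
strand, `round(Mα/2)` signal 5′ positions uniformly *without
replacement* over the enriched positions and `round(M(1−α)/2)` noise
positions without replacement over the chromosome. Within-component
uniqueness is the model's own unsaturated assumption — the binarised
densities are required to sum to exactly `Mα/2` and `M(1−α)/2` — while
signal/noise collisions still collapse on binarisation and `M_u`
reports the post-collapse count. When the signal allocation exceeds
`nw` the regions fill completely (the saturated regime) and the
surplus reads are duplicates. A `multinomial` allocation mode draws
the per-strand signal count from `Binomial(M/2, α)` for realism;
the deterministic default keeps the model's identities exact in
tests. Defaults `w = 100`, `d = 200`, `R = 50` bp are the package's
fixture constants throughout.

Synthetic genomes (`simulate_genome`) are uniform-random sequence with
a chosen fraction overwritten by copies of one repeat unit placed in
phase-aligned slots, so repeat territory is genuinely non-unique under
exact mappability while the background stays unique. For
chromosome-scale studies, where exhaustive k-mer enumeration is not
practical, `simulate_mappability` synthesises a mask directly as
random unmappable blocks (geometric lengths, mean 1 kb), and
`apply_mappability` drops reads at unmappable 5′ placements the way
alignment would. Because the reverse mask is the base mask shifted by
`R − 1`, masked *noise* reads alone produce the read-length phantom
peak in NCC — the mechanism behind the artefact — and MSCC removes it.

What the simulator does *not* emulate: sequencing errors, GC and
fragment-size biases, distributions over `w` and `d`, aligner
behaviour, or paired-end reads. Passing tests therefore demonstrate
correctness of the estimators and formulas under the model, not
robustness to every bias of real libraries; on real data, fragment
peaks are broader and baselines higher than the model's.

## Validation studies and problem sizes

Scenario sizes were chosen so the whole suite runs on one CPU in a few
minutes while keeping the measured quantities far from their sampling
noise (`SD(r̂) ≈ 1/√G` per shift at a background shift):

- **Oracle equivalence**: 200 random instances (vectors ≤ 2000 bp,
  shifts ≤ 200, random masks for the MSCC half) against naive
  position-by-position Pearson; agreement to 1e−12.
- **Reduced-scale simulation study**: `G = 10⁷`, `M = 10⁵`, `n = 10³`,
  `w = 100`, `d = 200`, `R = 50`, `α ∈ {1, 0.5, 0.1}`, 5 seeds each —
  a mammalian-scale design shrunk ~300× with the saturation degree
  (0.5, 0.25, 0.05) and geometry preserved. The NCC coefficient at
  `d + w` is compared with `(M/2nw)α²` (observed agreement ~1%,
  asserted at 15%). The minimum is evaluated at the theoretical
  non-overlap shift `x₀ = d` and compared with the exact closed form
  (within 1e−3): note that at this scale the exact minimum itself is
  −5×10⁻³ at α = 1 (it is `−M/(2G−M)` there), so "minimum ≈ 0" in
  absolute terms is asserted only where the model predicts it
  (α = 0.1, |min| ≤ 1e−3). Evaluating the minimum at `x₀` rather than
  as the extreme over ~10³ background shifts avoids conflating the
  model prediction with extreme-value statistics of the background
  (the expected extreme alone is ~3.2/√G ≈ 1e−3).
- **Low-enrichment MSCC detectability**: `α = 10⁻³` at `G = 10⁸`,
  `n = 60`, `w = 100`, saturation degree 0.8 (`M = 9.6×10⁶`), 20% of
  the genome unmappable in random blocks, reads dropped at unmappable
  placements; the MSCC coefficient at `d + w` (theory ≈ 7.6×10⁻⁴) is
  required to exceed mean + 3 SD of the background shifts
  (≈ 3.4×10⁻⁴); two seeds are averaged. The scenario was designed by
  power analysis to give a typical z of 5–7.
- **Saturated limit**: α = 1 at saturation degree 5; the enriched
  regions fill and the peak reaches 1 (asserted within 5%).
- **Parameter recovery**: on the α = 0.5 reduced-scale runs, the
  fragment-length argmax must hit 300 in ≥ 4/5 seeds (apex jitter of
  ±1–2 bp from site-sampling noise makes occasional misses expected)
  and the FWHM must lie within 20% of `w = 100`. VSN is compared with
  `α²/n` using the known `w` (the FWHM error is assessed separately):
  within 25% at α ∈ {0.5, 0.1} (reduced scale; the argmax maximum is
  biased upward by ~1 SD, worth ~5–10% at α = 0.1) and at α = 0.01 at
  `G = 10⁸`, `n = 500`, saturation degree 0.5 (`M = 5×10⁶`), where the
  observed error is ~2–3%.
- **Analytic round trips**: FRiP↔α to 1e−12 over an α grid; the
  VSN-inversion back-substitution `α²/n = VSN` to 1e−10.
- **Cohort workflow**: a 4-sample synthetic cohort following
  `log10 n = 3 + 0.5 log10 α` at `G = 2×10⁶`; the regression is fitted
  with one sample held out and the held-out `(α, n)` recovered from
  its VSN within 30%.

## Numerical and design notes

- Internal coordinates are 0-based half-open; only I/O converts
  (SAM/BED/BigWig conventions respected; BED "−" records use
  `end − 1` as the 5′ end).
- Default `mapq_min = 0` (binarisation already absorbs duplicates;
  explicit filtering is left to the caller), configurable per run.
  Mixed read lengths warn and use the modal length, since the model
  assumes a single `R`.
- The default shift range is 0..1000 (covers `d + w = 300` and the
  `R = 50` phantom with margin); profiles also accept arbitrary shift
  sets, which the large-genome studies use to sample densely near the
  peak and coarsely elsewhere.
- Without-replacement sampling uses rejection with top-up below 5%
  draw density (O(k) memory) and numpy's sampler above it.
- Argmax ties break toward the smaller shift; merged profiles at
  shifts where every chromosome is undefined stay missing.
- Fragment lengths on noisy real profiles may need manual review of
  the MSCC profile; the automatic argmax is the deterministic
  stand-in.
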