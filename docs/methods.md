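# Methods

This note documents the models, parameter choices and numerical decisions
behind `sigmascan`, and what the simulation-based tests do and do not
establish about real data.

## Coverage model and peak calling

Coverage tracks are per-base, single-chromosome vectors. Normalization
divides by the median per-base coverage rather than total depth: enriched
bases produce a long right tail that inflates the mean but barely moves the
median, so median scaling puts the background at ~1 and makes the fixed
thresholds meaningful across libraries. The median is computed over
non-excluded bases only; excluded intervals (artifact regions such as a
plasmid-borne copy of a chromosomal gene) are zeroed and ignored by both
the median and the peak predicate. The alternative order — normalize, then
exclude — is available via `normalize_before_exclusion` but biases the
scale whenever the excluded interval is strongly covered.

The peak predicate is deliberately literal: base *i* qualifies iff
normalized IP(i) > `ip_threshold` (default 4) and, for *every* supplied
control track, control(i) < `control_threshold` (default 3). Requiring all
controls is the strictest reading when both an input and a mock IP are
available. Maximal qualifying runs (gaps ≤ `merge_gap`, default 0, bridged;
width ≥ `min_width`, default 1) become peaks. Summit ties break leftmost for
determinism.

**Triangularity.** A localized binding event yields a sharply peaked,
roughly triangular pileup, while artifacts (copy-number steps, repeats)
yield plateaus or ragged profiles. The screen computes the Pearson
correlation between observed coverage on `[summit − f, summit + f]` and an
ideal symmetric triangle apexed at the summit. In `call_peaks` the flank is
`window_width + peak_width/2`, so the comparison window spans the whole
pileup plus flanking background; with that choice, simulated true peaks
score ≈ 0.83–0.90 and the one-to-two-base threshold-edge slivers that raw
run extraction produces score < 0 and are rejected at the default cutoff
of 0.8. A zero-variance window scores 0 by convention. The cutoff is a
reproducible surrogate for a visual screen and is deliberately configurable;
0.8 was chosen from the simulated score distributions (clear bimodal
separation), not from any universal property of ChIP data.

## Motif model

Counts from aligned windows convert to probabilities with
p = (count + pseudocount) / (n + 4·pseudocount). The scanning matrix built
directly from peak windows uses pseudocount 0 — numerical safeguarding is
delegated to the log-odds smoothing step, keeping the probability matrix a
plain summary of the observed sites.

Information content per column is R_seq = 2 − H(column) bits against a
uniform background, with 0·log 0 = 0. Schneider's small-sample correction
(−3/(2 ln2 · n) to first order, ~0.16 bits at n = 13) is available via
`small_sample_correction=True` but off by default; with the masking
threshold at 1 bit, the correction's effect is to mask slightly more
columns, and callers doing inference from few sites should consider it.

**Masking.** Columns with R_seq ≤ 1 bit (default) are replaced by the query
sequence's own mononucleotide composition. Because the log-odds score is
log2((p + ε)/(b + ε)) with the same smoothing ε in numerator and
denominator, a masked column scores exactly 0 for every letter: masked
positions are score-neutral by construction, not approximately.

## ZOOPS-EM discovery

The generative model: each sequence carries, with probability γ, exactly
one motif occurrence at a uniformly chosen offset (and uniformly chosen
strand when `both_strands=True`); all other positions follow a 0-order
background estimated from the aggregate composition of the input windows.
EM alternates posterior assignment over (no site, every placement) with
updates of the probability matrix and γ.

Numerical choices:

- **Initialization:** every distinct width-w word in the data becomes a
  candidate seed (its PPM puts 0.7 on the seed letter, 0.1 elsewhere);
  seeds are ranked by one-shot ZOOPS log-likelihood at γ = 0.5 and EM runs
  from the `n_starts` (default 5) best. This is the MEME substring
  heuristic; it also means the recovered motif is usually in the phase of
  an actual planted site rather than shifted.
- **Prior:** each column carries a Dirichlet prior of strength 0.5 times
  the background. The maximized objective is therefore the MAP objective
  (log-likelihood plus the Dirichlet kernel), which EM increases
  monotonically; the implementation asserts non-decrease every iteration.
  The raw likelihood is reported separately (`log_likelihood`, relative to
  the background-only model, which is exactly 0 on that scale).
- **Convergence:** relative objective change below `tol` (default 1e-6),
  cap `max_iter` = 200; non-convergence returns best-so-far with a warning.
- γ is clipped to [1e-4, 1 − 1e-4] to keep the mixture non-degenerate.

Motif width is a parameter (default 20 in the pipeline); the simulator's
planted motif is width 20, and in real use the width would be chosen by
rerunning discovery over a small range and comparing likelihoods.

## Exact p-values and FDR

Per-position log-odds scores (bits) are discretized at `step` = 0.001 bits
with round-half-even. The null distribution of the total discretized score
under the 0-order background is computed exactly by convolving the four-point
per-position distributions position by position; a window's p-value is the
exact tail probability of its discretized score. Discretization perturbs a
window's score axis by at most width × step (0.02 bits at width 20); tests
verify the DP tails agree with brute-force enumeration over all 4^w words to
< 1e-12. Windows containing non-ACGT letters are skipped. Minus-strand
windows are scored against the reverse-complement matrix and reported in
forward coordinates.

The default scanning background is each query's own composition (matching
the masking rule); a uniform option exists for comparison. q-values are
Benjamini–Hochberg computed over *all* scored windows of a run — not just
reported hits — via a pooled p-value vector; this matches the step-up
formula exactly (tested against an independent implementation) but is not
bit-identical to FIMO's internal q-value machinery. Overlapping hits are all
reported; no non-overlap pruning is applied.

Promoters are the 100 bp immediately upstream of each annotated CDS:
`[start − 100, start)` for plus-strand genes, `[end, end + 100)`
reverse-complemented for minus-strand genes, truncated (and flagged) at
contig edges.

## Simulator: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

- genome: i.i.d. bases at a specified GC fraction;
- sites: sampled column-independently from the motif PPM, planted at
  non-overlapping positions (≥ ~200 bp apart), strand-randomized
  (minus-strand sites planted as reverse complements);
- IP coverage: for each site, a Poisson(`enrichment`) number of fragments
  of fixed `fragment_length`, midpoints Laplace-displaced around the site
  center with scale `peak_spread`, piled up per base, plus i.i.d.
  Poisson(`background_depth`) background; control: background only;
- annotation: `n_genes` CDS records, `n_genes_with_sites` of them placed so
  a planted site falls inside their 100-bp upstream window, the rest kept
  clear of all planted peaks.

The Laplace displacement gives the sharply peaked, near-triangular expected
pileup characteristic of localized binding; fragment-level simulation (as
opposed to independent per-base noise around the expected pileup) gives the
*correlated* coverage noise of real pileups, which is what makes coverage
argmaxes usable as summits. Defaults — background_depth 10, enrichment 600
fragments/site, fragment_length 50, peak_spread 10 — describe a strongly
induced, epitope-tagged factor: normalized site coverage ≈ 55× background
median. At these settings a design-stage Monte Carlo puts the probability
of a summit falling > 10 bp from the site center below 1e-4 per site.

Not emulated: read-level artifacts (mappability, duplicates, GC bias),
fragment-length variation, overdispersion beyond Poisson, closely spaced or
overlapping sites, multi-chromosome genomes, and background composition
structure (the genome is i.i.d.). Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated model,
not robustness to every artifact of real libraries — the thresholds that
matter for real data (4/3 coverage rule, triangularity 0.8, q ≤ 0.6) remain
judgment calls the configuration exposes.

## Degenerate inputs and tie-breaks

- Zero median after exclusions → normalization error (an empty/failed
  sample); the pipeline stage maps a fully empty IP track to a clean
  zero-peak result instead.
- Normalizing an already normalized track is an error, not a no-op.
- Constant coverage in a triangularity window scores 0.
- Summit windows that would overrun a chromosome end are dropped with a
  logged warning.
- BH rejects p-values outside (0, 1]; ties in p receive equal q.
- MEME text is written at 6 decimals; rows are renormalized on read only
  when they are off by more than the 6-decimal rounding envelope (2e-6), so
  clean round trips are faithful to ≤ 5e-7.

## Known limitations

- With FIMO's default reporting threshold p ≤ 1e-4, any screen of N
  windows expects ~N × 1e-4 false positives; "exactly the planted
  promoters" is therefore only a high-probability outcome at small fixture
  scale (the default 8-gene fixture scans ~1300 windows), and genome-scale
  screens should rely on the q-value column rather than the p cut.
- Coverage tracks are single-chromosome; multi-replicate IP handling is
  limited to the all-controls predicate (no replicate averaging).
- The discovery module fits a single motif (no multi-motif erasure pass)
  and a 0-order background only.
- Problem sizes in the test and validation suites (100-kb genomes, 12
  sites, 20-seed recovery experiments) were chosen as the smallest scales
  at which the statistical checks are sharp.
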