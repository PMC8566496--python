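# Methods

## Scope

`polwave` quantifies RNA Pol II traveling and promoter recycling from timed
ChIP-seq of Ser2-phosphorylated Pol II (or of elongation factors such as
PAF1) collected during a CDK9-inhibitor (e.g. flavopiridol) block and after
drug washout. It couples the analysis stack (coverage tracks, pausing
ratios, metagenes, wave fronts) to a stochastic kinetic simulator that
generates fully synthetic datasets with known ground truth, so every stage
is testable without external downloads.

## Coverage tracks

Aligned reads (BED6, 0-based half-open) are replaced by fixed-length
fragments anchored at the read 5' end and oriented 5'→3' (plus strand:
`[start, start+L)`; minus strand: `[end−L, end)`), with `L` = 300 bp by
default, a typical ChIP library insert size. Fragments are clamped to
chromosome bounds rather than discarded; clamped mass is therefore absent
from conservation accounting. Per-base fragment overlap is averaged into
fixed-width bins (default 10 bp) and multiplied by
`target_depth / N_reads`, rescaling every library to the same effective
depth (default 5×10⁷ reads). The factor is computed from the raw aligned
read count before extension or clamping. An exact-duplicate ("clonal")
read filter is available but off by default — deduplication is normally
the aligner pipeline's job. `N_reads = 0` is an error: the rescaling is
undefined for an empty library.

At 1 bp bins the track equals a per-base overlap counter exactly, and
total track mass equals (fragment base pairs after clamping) × factor;
both are enforced by tests.

## Three-region bins and pausing statistics

Each gene longer than 700 bp is divided, in transcription coordinates,
into a 5'-end bin `[TSS−50, TSS+200)`, a gene-body bin
`[TSS+200, TTS−500)` and a 3'-end bin `[TTS−500, TTS+500)`. For a
minus-strand gene the transcription interval `[a, b)` maps to the genomic
interval `[TSS−b, TSS−a)` (base `k` of the transcript is genomic base
`TSS−1−k`). The 5' pausing ratio is the 5'-bin mean per-base density over
the gene-body mean; the 3' release ratio is the 3'-bin mean over the
gene-body mean. Both are invariant under global track rescaling.

A gene whose body mean density is zero is flagged invalid (NaN ratios)
rather than given a pseudocount or an infinite ratio; downstream summaries
use valid genes only and log the exclusion count. Overlapping genes are
scored independently. "Promoter region" means the 5'-end bin everywhere
in the package.

## Metagenes and promoter series

The scaled metagene divides each gene body (TSS→TTS) into a fixed number
of equal sub-intervals (default 100) whose mean densities are averaged
position-wise across genes; 2 kb flanks are kept at 50 bp resolution, and
minus-strand genes are traversed in transcription orientation. Anchored
profiles average unscaled density around the TSS or TTS. Positions that
fall off-chromosome contribute NaN and are excluded from the averages.

The promoter series records each gene's 5'-bin density at every time
point of one condition; genes unscorable at any time point are excluded
pairwise so the gene set is constant. The central statistic is the median
(the mean is available behind a flag). The percent decrease between two
time points is `100 × (1 − median(t₁)/median(t₀))`; it can be negative.
Between-condition comparisons at one time point use the Kruskal–Wallis
rank test (tie-corrected), requiring at least three genes per arm.

## Wave fronts and elongation rate

During the block, no new Pol II is released into elongation, so the
already-elongating population forms a retreating wave; after washout the
newly released population forms an emerging wave. The front statistic is
the cumulative-mass quantile of gene-body density accumulated 5'→3' —
first base at which the running sum reaches quantile q of the total body
mass — which is depth-robust and avoids an absolute signal cutoff.
Defaults: q = 0.1 for the trailing (5') edge of the retreating wave,
q = 0.9 for the leading (3') edge of the emerging wave, both exposed as
options. Per-gene fronts are aggregated by the median across genes, and
ordinary least squares of front position against time gives the
elongation rate in bp/min. Genes shorter than the farthest expected front
position should be excluded from rate fitting (saturation at the TTS);
the rate-recovery protocol enforces this by construction. This
quantile-front regression is the package's own, documented stand-in for
wave-based rate estimation; it is a field-standard style of analysis, not
a reproduction of any particular published procedure.

The recycling index — an artifact-defined summary, labeled as such in
reports — is the least-squares slope of the median promoter density over
block time, divided by the initial median gene-body density (units
1/min). It is positive when terminating polymerases re-engage promoters
during the block and ≈ 0 or negative without recycling.

`condition_report` tabulates, per condition: median pausing ratio per
time point, washout promoter percent-decrease (first washout sample to
20 min later by default), recycling index, and emerging-wave elongation
rate; plus Kruskal–Wallis p-values between conditions at each shared time
point. A "recycling defect" is flagged when the depleted condition shows
both a lower recycling index (by more than 10% relative) and a smaller
washout percent-decrease (by more than 5 percentage points). The margins
keep sampling noise between identically parameterized replicates from
raising the flag; with the default effect sizes the true differences
exceed them several-fold. With a single condition or a single washout
sample the report degrades gracefully (comparisons omitted, rate reported
as unavailable) rather than failing.

## Kinetic simulator

Each polymerase molecule on each gene occupies one of four compartments:

* **U** — promoter-engaged, not yet released; Ser2-unphosphorylated and
  therefore invisible to a Ser2 ChIP;
* **E** — elongating at position x (visible);
* **T** — dwelling at the termination site (visible);
* **R** — recycled back at the promoter after termination (visible:
  the Ser2 mark is acquired at first release and retained through
  recycling — a modeling choice consistent with drug-block experiments in
  which existing Ser2 Pol II keeps traveling while new phosphorylation is
  blocked, and with the Ser2 signal that accumulates at TSSs during the
  block).

Fixed-step tau-leaping (default dt = 0.05 min) advances the system: per
step each gene initiates a new U with probability `k_init·dt`; each U and
R releases into E with probability `k_release·dt` unless the CDK9 block
is engaged (release probability 0; already-elongating molecules are
unaffected, matching the drug mechanism); E advances by
`Normal(v·dt, v_sd·√dt)` truncated at zero displacement; E reaching the
gene end enters T for `term_dwell` minutes; an expiring T recycles to R
with probability ρ and otherwise leaves the template. Any per-event
probability above 0.2 per step raises an error instructing a smaller dt,
keeping leap error small. Exact event-driven simulation was rejected in
favor of linear-time scaling in molecule count.

Defaults (per-minute rates; the package's own literature-scale choices,
config-exposed): `k_init` 0.5 (one initiation per 2 min per gene),
`k_release` 2.0 (drug-free pause release within ~20 s), `v` 2000 bp/min,
`v_sd` 200, `term_dwell` 1 min, ρ 0.9. The default factor-depleted
condition reduces ρ to 0.2, `v` to 1200 bp/min and `k_release` to
0.02/min. All three reductions are grounded in the depletion phenotypes
the package targets: less Ser2 Pol II recycled to promoters during the
block, slower gene-body progression, and markedly reduced release of
promoter Pol II into gene bodies after washout. A (ρ, v)-only depletion
cannot reproduce the washout pattern in this scheme: efficient recycling
replenishes control promoters during washout, so without a release-rate
deficit the depleted condition would always lose a *larger* fraction of
its promoter signal than control — the opposite of what timed ChIP-seq
experiments of this design report. Each knob is independently
configurable.

### Read sampling and background

Sampled time points draw exactly `depth` reads (default 3×10⁵) from a
multinomial over the Ser2-visible occupancy histogram (25 bp bins; R at
the TSS bin, T at the TTS bin) plus a uniform nonspecific background over
each gene ± 2 kb. The `background` parameter (default 0.40) is the
nonspecific fraction of the library at the first sampled time point; the
pedestal is then held fixed in absolute molecule-equivalent units for the
rest of the course. This anchoring emulates the invariant rest-of-genome
signal that buffers fixed-depth normalization in a real library. A pure
fraction-of-reads background was rejected because, on a panel-only
synthetic genome, it makes normalization purely compositional: when the
visible pool collapses (depleted condition, late block) the few remaining
molecules would absorb nearly the whole library and inflate the depleted
promoter signal to control-like levels, erasing the very patterns the
time course is designed to expose. Read 5' ends fall at the sampled
position on the gene's strand, with `read_length` 50 bp.

### Study design and sizes

The default schedule matches the motivating experimental design: 60 min
of drug block sampled at 0/10/20/40 min, washout sampled at 0/10/20/40
min after drug removal (absolute times 60/70/80/100). A 60 min burn-in
precedes the schedule. The default panel is 50 genes of 20–80 kb, one
gene per synthetic chromosome with 5 kb margins, alternating strands.
These sizes were chosen once as the package's desk-scale study
conditions: large enough for stable medians and rank tests, small enough
that a full two-condition course simulates in seconds.

Two dedicated protocols exercise specific quantities:

* **Rate recovery** (`washout_rate_protocol`): 200 genes of length
  `max(100 kb, 1.25·v·t_max)` (no TTS saturation), no burn-in, 30 min
  block to accumulate the paused pool, washout samples at 10/20/40 min,
  depth 10⁶, background 0.05, `k_release` 2/min so the pool releases as a
  sharp pulse whose leading edge tracks v (with slow release the washout
  body profile is quasi-uniform and the q = 0.9 front advances at ~0.9v).
  Recovered rates are within a few percent of truth for v ∈ {1000, 2000,
  4000} bp/min.
* **Recycling response** (`block_recycling_protocol`): 30 genes of
  90–110 kb — longer than v × 40 min, so the body never fully drains
  within the sampled block and the termination flux feeding the promoter
  pool stays proportional to ρ (with short genes, fixed-depth
  normalization pins all remaining late-block signal at the promoter for
  any ρ > 0, flattening the response). The recycling index is strictly
  increasing over ρ ∈ {0, 0.3, 0.6, 0.9}.

### Determinism

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawns: one stream for the gene panel, one
per condition for the dynamics, one per sample time for read sampling.
Identical config + seed reproduces byte-identical BED outputs; run
manifests record a config hash and sha256 of every file.

## What the generator does and does not emulate

It emulates: promoter-proximal pausing, drug-blocked release, retreating
and emerging waves, termination, promoter recycling, fixed-depth
normalization, uniform nonspecific background, multinomial read noise.
It does not emulate: pause-site sequence specificity, nucleosome or
chromatin structure, ChIP/antibody efficiency, fragment-size variation,
mappability, replicate-level batch effects, inter-gene rate
heterogeneity, or genome-wide signal outside the panel (beyond the
anchored background). Passing tests therefore demonstrate that the
statistics recover known kinetic ground truth under idealized sampling —
not that the pipeline is robust to every artifact of real libraries.

## Numerical choices and degenerate inputs

Bins are clamped to chromosome bounds; a gene whose 5' bin is entirely
off-chromosome is invalid. Gene length must exceed 700 bp (bin geometry)
and, for scaled metagenes, the number of body bins. `d_body = 0` →
invalid flag; empty intervals, zero body mass for wave fronts, fewer than
two distinct time points for regression, and zero baseline for the
recycling index raise errors. bedGraph output run-length-encodes and
omits zero intervals; round trips are exact to 1e-6. The browser-track
bin width (10 bp) is a display/storage choice; all statistics are
computed on per-nucleotide densities derived from the track.

## Known limitations

The elongation-rate estimate from the default two-condition report (short
genes, slow depleted release) is qualitative; use the dedicated rate
protocol geometry for quantitative recovery. The recycling index and the
defect-flag margins are package-defined conventions, not published
statistics. Percent-decrease magnitudes depend on the background fraction
and the release kinetics; only their cross-condition ordering is treated
as a modeled prediction.
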