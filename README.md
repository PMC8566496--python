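# polwave

Time-resolved RNA Pol II pausing and promoter-recycling analysis for
CDK9-inhibitor block/washout ChIP-seq experiments, with a stochastic
kinetic simulator for fully synthetic, ground-truthed test data.

## The problem

CDK9 inhibitors such as flavopiridol block the release of promoter-paused
RNA Pol II into productive elongation without stopping polymerases that
are already elongating. Timed ChIP-seq of Ser2-phosphorylated Pol II
around such a block therefore shows a *retreating wave* of elongating
polymerase vacating gene bodies during drug treatment — while recycled,
still-phosphorylated Pol II accumulates at transcription start sites —
and an *emerging wave* of newly released polymerase after drug washout.
Tracking these waves and the promoter signal over time lets one measure
elongation velocity and promoter recycling, and detect recycling defects
caused by depleting factors such as PAF1. `polwave` is for genomics
analysts who have such timed coverage data (or want to simulate it) and
need the standard quantitative readouts in one tested toolkit.

## Statistics implemented

* **Coverage tracks** — each aligned read is replaced by a 300 bp fragment
  anchored at its 5′ end and oriented 5′→3′; per-base overlap is binned
  and rescaled to a common effective depth of 5×10⁷ reads
  (`target_depth / N_reads`). bedGraph and bigWig output.
* **Pausing/release ratios** — each gene > 700 bp gets a 5′-end bin
  [TSS−50, TSS+200), a gene-body bin [TSS+200, TTS−500) and a 3′-end bin
  [TTS−500, TTS+500). The 5′ pausing ratio is d₅/d_body and the 3′
  release ratio d₃/d_body, with d the mean per-nucleotide density; genes
  with d_body = 0 are flagged invalid rather than given pseudocounts.
* **Metagenes** — gene bodies rescaled to 100 bins with 2 kb fixed-bp
  flanks, averaged across genes in transcription orientation; TSS/TTS
  anchored profiles; per-gene promoter (5′-bin) density series with
  median summaries, percent-decrease statistics and Kruskal–Wallis rank
  tests between conditions.
* **Wave fronts and rates** — the front of a wave is the position at which
  the 5′→3′ cumulative gene-body mass reaches a quantile q (q = 0.9 for
  the emerging wave's leading edge, q = 0.1 for the retreating wave's
  trailing edge); ordinary least squares of median front position against
  time yields the elongation rate in bp/min.
* **Recycling index** — slope of the median promoter density over block
  time divided by the initial median gene-body density (1/min); an
  artifact-defined summary of promoter re-accumulation during the block.
* **Simulator** — per-molecule kinetics of initiation → pause →
  release → elongation → termination → recycling (probability ρ), with a
  drug schedule that zeroes release during the block, Ser2 visibility
  acquired at first release, multinomial read sampling at fixed depth
  over visible occupancy plus an anchored uniform background, and full
  ground truth alongside every dataset. See `docs/methods.md` for the
  model, parameter defaults and their rationale.

## Worked example

Simulate the default two-condition experiment — control (ρ = 0.9,
v = 2000 bp/min, release 2/min) versus factor-depleted (ρ = 0.2,
v = 1200 bp/min, release 0.02/min), 60 min block sampled at 0/10/20/40
min plus washout sampled at 0/10/20/40 min, 50 genes, 3×10⁵ reads per
sample — then run the full analysis:

```python
from polwave import SimConfig, DrugSchedule, depleted_config
from polwave.workflows import compare_conditions

report = compare_conditions(SimConfig(), depleted_config(), DrugSchedule(), seed=1)
for cond in ("control", "depleted"):
    c = report["conditions"][cond]
    print(f"{cond:9s} pr5@40min={c['pr5_median'][40.0]:8.1f}  "
          f"washout decrease={c['washout_percent_decrease']:5.1f}%  "
          f"recycling index={c['recycling_index']:.2f}/min")
print("recycling defect flagged:", report["recycling_defect"])
```

prints

```
control   pr5@40min=   105.9  washout decrease= 99.6%  recycling index=1.71/min
depleted  pr5@40min=    19.3  washout decrease= 80.3%  recycling index=0.45/min
recycling defect flagged: True
```

Reading the numbers: after 40 min of block, the control median pausing
ratio has risen to ~106 because recycled Ser2-positive Pol II keeps
re-accumulating at promoters while gene bodies empty; the depleted
condition reaches only ~19. After washout, control promoters release
their accumulated pool into gene bodies (promoter signal down 99.6% at
20 min of release) whereas the depleted condition, with its release
deficit, retains far more (down 80.3%). The block-phase recycling index
is ~4-fold lower under depletion, and the joint criterion (lower index
*and* smaller washout decrease) flags a recycling defect.

The same workflow is available from the shell:

```sh
polwave simulate --outdir ds --seed 1
polwave report --dataset ds --outdir ds_report
```

which writes per-(condition, time) BED files with ground truth, then
ratio tables, metagene profiles, promoter series, the condition report
(JSON + TSV) and summary plots. `polwave coverage / pausing / metagene /
dynamics` run the individual stages on arbitrary BED + chrom.sizes +
gene-model inputs, with the 300 bp extension, 5×10⁷ target depth, bin
widths and quantiles all exposed as options.

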