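"""Wave-front tracking, elongation-rate regression, and recycling summaries.

During a CDK9-inhibitor block no new Pol II is released into productive
elongation, so the already-elongating (Ser2-phosphorylated) population
forms a "retreating wave" whose trailing (5') edge advances at the
elongation velocity; after washout the newly released population forms an
"emerging wave" whose leading (3') edge advances at the same velocity.
Both edges are located as cumulative-mass quantiles of the gene-body
density accumulated 5'->3' (trailing edge: low quantile, default 0.1;
leading edge: high quantile, default 0.9) — a depth-robust statistic that
avoids an absolute signal cutoff.  Per-gene fronts are aggregated by the
median across genes, and an ordinary least-squares fit of front position
against time yields the elongation rate in bp/min.

The recycling index summarizes promoter re-accumulation during the block:
the least-squares slope of the median promoter (5'-bin) density over block
time, divided by the initial median gene-body density.  It is an
artifact-defined summary (labeled as such in reports), positive when
terminating polymerases re-engage promoters and near zero or negative
without recycling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metagene import PromoterSeries, compare_distributions, percent_decrease, promoter_series
from .pausing import (
    FIVE_PRIME_DOWN,
    THREE_PRIME_FLANK,
    GeneModel,
    bin_scheme,
    mean_density,
    per_base_transcription,
    ratio_table,
)
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)

TRAILING_QUANTILE = 0.1  # block phase: 5' edge of the retreating wave
LEADING_QUANTILE = 0.9   # washout phase: 3' edge of the emerging wave


@dataclass(frozen=True)
class WaveFront:
    """Wave-edge position for one gene (or gene-set median) at one time.

    ``position`` is in transcription coordinates, bp downstream of the TSS.
    """

    time: float
    position: float
    quantile: float

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile < 1.0):
            raise ValueError("quantile must be in (0, 1)")


@dataclass(frozen=True)
class RateFit:
    """OLS fit of front position (bp from TSS) against time (min)."""

    rate: float          # slope, bp/min
    intercept: float     # bp
    residual_sd: float   # RMS residual, bp
    n: int


@dataclass(frozen=True)
class RecyclingIndex:
    """Slope of median promoter density over block time, per unit baseline."""

    slope: float     # density units / min
    baseline: float  # initial median gene-body density
    index: float     # 1/min


def wave_front(
    track: CoverageTrack,
    gene: GeneModel,
    quantile: float = LEADING_QUANTILE,
    time: float = math.nan,
) -> WaveFront:
    """Cumulative-mass quantile position of the gene-body signal.

    The gene-body density ([TSS+200, TTS-500), transcription orientation)
    is accumulated 5'->3'; the front is the first base at which the running
    sum reaches ``quantile`` of the total body mass, reported in bp
    downstream of the TSS.  Zero body mass is an error.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    L = gene.length
    pb = np.nan_to_num(per_base_transcription(track, gene, FIVE_PRIME_DOWN, L - THREE_PRIME_FLANK))
    total = pb.sum()
    if total <= 0:
        raise ValueError(f"gene {gene.id}: zero gene-body signal mass")
    c = np.cumsum(pb)
    idx = int(np.searchsorted(c, quantile * total))
    return WaveFront(time=time, position=float(FIVE_PRIME_DOWN + idx), quantile=quantile)


def median_front(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    quantile: float,
    time: float,
    min_gene_length: int = 0,
) -> Optional[WaveFront]:
    """Median per-gene front across genes with positive body mass.

    Genes shorter than ``min_gene_length`` are excluded (used to avoid
    fronts saturating at the TTS over long time courses).  Returns None if
    no gene qualifies.
    """
    positions = []
    for gene in genes:
        if gene.length < min_gene_length:
            continue
        try:
            positions.append(wave_front(track, gene, quantile, time).position)
        except ValueError:
            continue
    if not positions:
        return None
    return WaveFront(time=time, position=float(np.median(positions)), quantile=quantile)


def elongation_rate(fronts: Sequence[WaveFront]) -> RateFit:
    """OLS regression of front position against time; the slope is bp/min."""
    if len(fronts) < 2:
        raise ValueError("elongation_rate requires >= 2 wave fronts")
    t = np.array([f.time for f in fronts], dtype=float)
    x = np.array([f.position for f in fronts], dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("elongation_rate requires >= 2 distinct time points")
    res = stats.linregress(t, x)
    resid = x - (res.slope * t + res.intercept)
    return RateFit(
        rate=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        n=len(fronts),
    )


def recycling_index(
    series: PromoterSeries,
    baseline: float,
    times: Optional[Sequence] = None,
    stat: str = "median",
) -> RecyclingIndex:
    """Promoter re-accumulation rate during the block, per unit baseline.

    Least-squares slope of the central promoter density over the given
    block time points, divided by ``baseline`` (initial median gene-body
    density).  baseline <= 0 is an error.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if times is None:
        times = series.times
    if len(times) < 2:
        raise ValueError("recycling_index requires >= 2 block time points")
    t = np.asarray([float(x) for x in times])
    y = np.asarray([series.central(x, stat) for x in times])
    if np.allclose(y, y[0]):
        slope = 0.0
    else:
        slope = float(stats.linregress(t, y).slope)
    return RecyclingIndex(slope=slope, baseline=float(baseline), index=slope / baseline)


def median_body_density(track: CoverageTrack, genes: Sequence[GeneModel]) -> float:
    """Median per-gene gene-body mean density (recycling-index baseline)."""
    vals = []
    for gene in genes:
        s, e = bin_scheme(gene).body
        try:
            vals.append(mean_density(track, gene.chrom, s, e))
        except ValueError:
            continue
    if not vals:
        raise ValueError("no gene with a scorable body bin")
    return float(np.median(vals))


def condition_report(
    tracks: Mapping[str, Mapping[float, CoverageTrack]],
    genes: Sequence[GeneModel],
    schedule,
    control: str = "control",
    depleted: Optional[str] = "depleted",
    washout_quantile: float = LEADING_QUANTILE,
    decrease_interval: float = 20.0,
    min_rate_gene_length: int = 0,
    index_margin: float = 0.10,
    decrease_margin: float = 5.0,
) -> dict:
    """Cross-condition time-course summary.

    For each condition: median 5' pausing ratio per time point, washout
    promoter percent-decrease (from the first washout sample to
    ``decrease_interval`` min later, or the last washout sample), the
    recycling index over block samples, and the emerging-wave elongation
    rate over washout samples.  Between conditions: Kruskal-Wallis rank
    tests on per-gene promoter densities at shared time points, and a
    "recycling defect" flag raised when the depleted condition shows both a
    lower recycling index (by > ``index_margin`` relative) and a smaller
    washout percent-decrease (by > ``decrease_margin`` percentage points).
    The margins keep sampling noise between identically parameterized
    replicates from raising the flag.

    ``tracks`` maps condition -> {sample time (min) -> CoverageTrack}.
    With ``depleted=None`` (single-condition data) the comparison block is
    omitted.  The recycling index is an artifact-defined summary statistic,
    flagged as such in the output.
    """
    conditions = [control] + ([depleted] if depleted else [])
    for cond in conditions:
        if cond not in tracks:
            raise ValueError(f"condition {cond!r} missing from tracks")
    times0 = sorted(tracks[control])
    for cond in conditions[1:]:
        if sorted(tracks[cond]) != times0:
            raise ValueError("conditions must share the same sample time points")

    block_times = [t for t in times0 if schedule.phase(t) == "block"]
    washout_times = [t for t in times0 if schedule.phase(t) == "washout"]

    rt = ratio_table(
        {(t, cond): tracks[cond][t] for cond in conditions for t in times0}, list(genes)
    )

    per_cond: Dict[str, dict] = {}
    series_by_cond: Dict[str, PromoterSeries] = {}
    for cond in conditions:
        valid = rt[(rt["condition"] == cond) & rt["valid"]]
        pr5_median = {
            float(t): float(valid[valid["time"] == t]["pr5"].median()) for t in times0
        }
        series = promoter_series({t: tracks[cond][t] for t in times0}, list(genes), cond)
        series_by_cond[cond] = series

        entry: dict = {
            "pr5_median": pr5_median,
            "n_genes": int(series.data.shape[0]),
        }

        if len(washout_times) >= 2:
            t0 = washout_times[0]
            later = [t for t in washout_times if t - t0 >= decrease_interval]
            t1 = later[0] if later else washout_times[-1]
            entry["washout_percent_decrease"] = percent_decrease(series, t0, t1)
            entry["washout_decrease_t0"] = float(t0)
            entry["washout_decrease_t1"] = float(t1)
        else:
            entry["washout_percent_decrease"] = None

        if len(block_times) >= 2:
            baseline = median_body_density(tracks[cond][block_times[0]], genes)
            ri = recycling_index(series_by_cond[cond], baseline, times=block_times)
            entry["recycling_index"] = ri.index
            entry["recycling_index_note"] = (
                "artifact-defined summary: promoter-density slope during block / baseline body density"
            )
        else:
            entry["recycling_index"] = None

        rate_times = washout_times[1:] if len(washout_times) > 2 else washout_times
        fronts = []
        for t in rate_times:
            f = median_front(
                tracks[cond][t], genes, washout_quantile,
                time=float(t - schedule.block_end), min_gene_length=min_rate_gene_length,
            )
            if f is not None:
                fronts.append(f)
        if len({f.time for f in fronts}) >= 2:
            fit = elongation_rate(fronts)
            entry["elongation_rate_bp_per_min"] = fit.rate
            entry["rate_n_points"] = fit.n
        else:
            entry["elongation_rate_bp_per_min"] = None  # unavailable, not an error
        per_cond[cond] = entry

    report = {
        "conditions": per_cond,
        "times": [float(t) for t in times0],
        "block_times": [float(t) for t in block_times],
        "washout_times": [float(t) for t in washout_times],
        "n_genes": len(genes),
    }

    if depleted:
        g_ctrl = set(series_by_cond[control].data.index)
        g_depl = set(series_by_cond[depleted].data.index)
        shared = sorted(g_ctrl & g_depl)
        tests = {}
        for t in times0:
            a = PromoterSeries(series_by_cond[control].data.loc[shared], control)
            b = PromoterSeries(series_by_cond[depleted].data.loc[shared], depleted)
            r = compare_distributions(a, b, t)
            tests[float(t)] = {"statistic": r.statistic, "pvalue": r.pvalue}
        report["rank_tests"] = tests

        c, d = per_cond[control], per_cond[depleted]
        defect = False
        if c["recycling_index"] is not None and d["recycling_index"] is not None:
            idx_lower = d["recycling_index"] < c["recycling_index"] - index_margin * abs(
                c["recycling_index"]
            )
            dec_lower = (
                c["washout_percent_decrease"] is not None
                and d["washout_percent_decrease"] is not None
                and d["washout_percent_decrease"]
                < c["washout_percent_decrease"] - decrease_margin
            )
            defect = bool(idx_lower and dec_lower)
        report["recycling_defect"] = defect
    return report


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a condition report into a long DataFrame for TSV output."""
    rows = []
    for cond, entry in report["conditions"].items():
        for t, v in entry["pr5_median"].items():
            rows.append({"condition": cond, "metric": "pr5_median", "time": t, "value": v})
        for key in ("washout_percent_decrease", "recycling_index", "elongation_rate_bp_per_min"):
            rows.append({"condition": cond, "metric": key, "time": None, "value": entry.get(key)})
    for t, r in report.get("rank_tests", {}).items():
        rows.append({"condition": "both", "metric": "kruskal_pvalue", "time": t, "value": r["pvalue"]})
    if "recycling_defect" in report:
        rows.append(
            {
                "condition": "both",
                "metric": "recycling_defect",
                "time": None,
                "value": float(report["recycling_defect"]),
            }
        )
    return pd.DataFrame(rows)
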