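"""Scaled metagene profiles and promoter-density time-course statistics.

The scaled metagene rescales every gene body (TSS to TTS) to a fixed number
of bins and averages position-wise across genes, with upstream/downstream
flanks kept at absolute bp resolution; minus-strand genes are traversed in
transcription orientation.  The promoter series tracks each gene's 5'-bin
([TSS-50, TSS+200)) mean density across time points of one condition, with
the median as the central statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .pausing import (
    GeneModel,
    bin_scheme,
    mean_density,
    per_base_transcription,
)
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Average signal profile: fixed-bp flanks around a rescaled gene body.

    ``values`` is the concatenation of upstream flank bins (at ``flank_res``
    bp), ``body_bins`` scaled-body bins, and downstream flank bins.  For
    anchor profiles body_bins is 0 and the two flanks are the window halves.
    """

    upstream_flank: int
    body_bins: int
    downstream_flank: int
    flank_res: int
    values: np.ndarray
    n_genes: int

    def positions(self) -> List[str]:
        labels = []
        for i in range(self.upstream_flank // self.flank_res):
            labels.append(f"up:{-self.upstream_flank + i * self.flank_res}")
        for i in range(self.body_bins):
            labels.append(f"body:{i}")
        for i in range(self.downstream_flank // self.flank_res):
            labels.append(f"down:{i * self.flank_res}")
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions(), "mean_density": self.values, "n_genes": self.n_genes}
        )


@dataclass
class PromoterSeries:
    """Per-gene promoter (5'-bin) densities across time for one condition."""

    data: pd.DataFrame  # index: gene id; columns: time points (sorted)
    condition: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("PromoterSeries requires at least one time point")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("promoter densities must be non-negative")

    @property
    def times(self) -> List:
        return list(self.data.columns)

    def central(self, time, stat: str = "median") -> float:
        col = self.data[time]
        return float(col.median() if stat == "median" else col.mean())

    @property
    def medians(self) -> pd.Series:
        return self.data.median(axis=0)


def _flank_bins(arr: np.ndarray, res: int) -> np.ndarray:
    """Mean of consecutive res-bp chunks, NaN-aware."""
    n = len(arr) // res
    return np.nanmean(arr[: n * res].reshape(n, res), axis=1)


def _body_profile(pb: np.ndarray, body_bins: int) -> np.ndarray:
    """Rescale one gene's per-base body signal to body_bins means."""
    L = len(pb)
    edges = np.floor(np.linspace(0, L, body_bins + 1)).astype(int)
    c = np.concatenate([[0.0], np.cumsum(np.nan_to_num(pb))])
    counts = np.concatenate([[0.0], np.cumsum(~np.isnan(pb))])
    widths = np.diff(edges)
    sums = c[edges[1:]] - c[edges[:-1]]
    ns = counts[edges[1:]] - counts[edges[:-1]]
    with np.errstate(invalid="ignore"):
        out = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    out[widths == 0] = np.nan
    return out


def scaled_metagene(
    track: CoverageTrack,
    genes: List[GeneModel],
    body_bins: int = 100,
    flank: int = 2000,
    flank_res: int = 50,
) -> MetageneProfile:
    """Average scaled-gene-body profile across genes.

    Each gene body (TSS..TTS) is divided into ``body_bins`` equal
    sub-intervals whose mean densities are averaged position-wise across
    genes; ``flank`` bp upstream of the TSS and downstream of the TTS are
    averaged at ``flank_res`` bp resolution.  Genes shorter than
    ``body_bins`` bp are skipped (logged).
    """
    if not genes:
        raise ValueError("scaled_metagene requires a non-empty gene list")
    if body_bins < 10:
        raise ValueError("body_bins must be >= 10")
    if flank % flank_res:
        raise ValueError("flank must be a multiple of flank_res")
    rows = []
    n_skipped = 0
    for gene in genes:
        L = gene.length
        if L < body_bins:
            n_skipped += 1
            continue
        up = per_base_transcription(track, gene, -flank, 0)
        body = per_base_transcription(track, gene, 0, L)
        down = per_base_transcription(track, gene, L, L + flank)
        rows.append(
            np.concatenate(
                [_flank_bins(up, flank_res), _body_profile(body, body_bins), _flank_bins(down, flank_res)]
            )
        )
    if n_skipped:
        logger.info("scaled_metagene: skipped %d genes shorter than %d bp", n_skipped, body_bins)
    if not rows:
        raise ValueError("no gene long enough for the requested body_bins")
    values = np.nanmean(np.vstack(rows), axis=0)
    return MetageneProfile(flank, body_bins, flank, flank_res, values, len(rows))


def anchor_profile(
    track: CoverageTrack,
    genes: List[GeneModel],
    anchor: str = "TSS",
    window: int = 2000,
    res: int = 50,
) -> MetageneProfile:
    """Unscaled average density around the TSS or TTS, transcription-oriented."""
    if not genes:
        raise ValueError("anchor_profile requires a non-empty gene list")
    if window <= 0:
        raise ValueError("window must be > 0")
    if window % res:
        raise ValueError("window must be a multiple of res")
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    rows = []
    for gene in genes:
        off = 0 if anchor == "TSS" else gene.length
        pb = per_base_transcription(track, gene, off - window, off + window)
        rows.append(_flank_bins(pb, res))
    values = np.nanmean(np.vstack(rows), axis=0)
    return MetageneProfile(window, 0, window, res, values, len(rows))


def promoter_series(
    tracks: Mapping[object, CoverageTrack],
    genes: List[GeneModel],
    condition: str = "",
) -> PromoterSeries:
    """Per-gene 5'-bin densities at each time point of one condition.

    Genes whose promoter bin cannot be evaluated at any time point are
    excluded pairwise so the gene set is identical at every time point.
    """
    if len(tracks) < 2:
        raise ValueError("promoter_series requires at least two time points")
    times = sorted(tracks)
    cols: Dict[object, Dict[str, float]] = {}
    for t in times:
        track = tracks[t]
        col = {}
        for gene in genes:
            s, e = bin_scheme(gene).five_prime
            try:
                col[gene.id] = mean_density(track, gene.chrom, s, e)
            except ValueError:
                col[gene.id] = math.nan
        cols[t] = col
    df = pd.DataFrame(cols)
    keep = df.notna().all(axis=1)
    if (~keep).any():
        logger.info("promoter_series: excluded %d genes with unscorable promoter bins", int((~keep).sum()))
    df = df[keep]
    if df.empty:
        raise ValueError("no gene with a scorable promoter bin at every time point")
    return PromoterSeries(data=df, condition=condition)


def percent_decrease(
    series: PromoterSeries, t0, t1, stat: str = "median"
) -> float:
    """Percent decrease of the central promoter density from t0 to t1.

    100 * (1 - central(t1) / central(t0)); negative values mean an increase.
    """
    for t in (t0, t1):
        if t not in series.data.columns:
            raise KeyError(f"time point {t!r} not in series")
    c0 = series.central(t0, stat)
    c1 = series.central(t1, stat)
    if c0 == 0:
        raise ValueError("central promoter density at t0 is zero")
    return 100.0 * (1.0 - c1 / c0)


@dataclass(frozen=True)
class RankTestResult:
    """Kruskal-Wallis rank test between two promoter-density samples."""

    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def compare_distributions(
    series_a: PromoterSeries, series_b: PromoterSeries, time
) -> RankTestResult:
    """Rank-based (Kruskal-Wallis) comparison of per-gene promoter densities
    between two conditions at one time point."""
    for s in (series_a, series_b):
        if time not in s.data.columns:
            raise KeyError(f"time point {time!r} not in series")
    a = series_a.data[time].to_numpy()
    b = series_b.data[time].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("compare_distributions requires >= 3 genes per condition")
    if np.array_equal(a, b):
        # identical samples: statistic 0 by definition; scipy raises on all-ties
        return RankTestResult(0.0, 1.0, len(a), len(b))
    stat, p = stats.kruskal(a, b)
    return RankTestResult(float(stat), float(p), len(a), len(b))
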