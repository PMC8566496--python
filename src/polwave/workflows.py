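"""End-to-end orchestration: simulate -> tracks -> statistics -> report.

Thin composition of the library stages, shared by the command-line
interface, the test suite and the reproduction script.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .dynamics import (
    RateFit,
    condition_report,
    elongation_rate,
    median_body_density,
    median_front,
    recycling_index,
)
from .metagene import promoter_series
from .pausing import GeneModel
from .simdata import DrugSchedule, SimConfig, gene_panel, run_course
from .tracks import CoverageTrack, GenomeTable, TrackConfig, build_coverage, extend_reads


def coverage_from_raw_reads(
    reads, genome: GenomeTable, cfg: Optional[TrackConfig] = None
) -> CoverageTrack:
    """Extend raw reads 5'-anchored and build the depth-normalized track."""
    cfg = cfg or TrackConfig()
    return build_coverage(extend_reads(reads, genome, cfg), genome, cfg)


def simulate_condition_tracks(
    cfg: SimConfig,
    schedule: DrugSchedule,
    genes: Sequence[GeneModel],
    genome: GenomeTable,
    seed,
    track_cfg: Optional[TrackConfig] = None,
) -> Dict[float, CoverageTrack]:
    """Simulate one condition and return coverage tracks keyed by sample time."""
    reads_by_time, _ = run_course(cfg, schedule, genes, genome, seed)
    return {
        t: coverage_from_raw_reads(reads, genome, track_cfg)
        for t, reads in reads_by_time.items()
    }


def compare_conditions(
    control: SimConfig,
    depleted: SimConfig,
    schedule: DrugSchedule,
    seed: int,
    track_cfg: Optional[TrackConfig] = None,
    **report_kw,
) -> dict:
    """Simulate both conditions on a shared gene panel and report."""
    ss = np.random.SeedSequence(seed)
    panel_ss, ctrl_ss, depl_ss = ss.spawn(3)
    genes, genome = gene_panel(control, np.random.default_rng(panel_ss))
    tracks = {
        "control": simulate_condition_tracks(control, schedule, genes, genome, ctrl_ss, track_cfg),
        "depleted": simulate_condition_tracks(depleted, schedule, genes, genome, depl_ss, track_cfg),
    }
    return condition_report(tracks, genes, schedule, **report_kw)


def washout_rate_protocol(
    v: float,
    seed: int,
    n_genes: int = 200,
    depth: int = 1_000_000,
    v_sd: float = 200.0,
    release_times: Sequence[float] = (10.0, 20.0, 40.0),
    quantile: float = 0.9,
) -> RateFit:
    """Emerging-wave elongation-rate recovery run.

    A clean washout design: no pre-block elongation (burn-in 0, block from
    t=0), 30 min of block accumulating the paused pool, then washout
    samples at the given release times.  Gene length is max(100 kb,
    1.25 * v * max release time) so fronts cannot saturate at the TTS
    (genes shorter than v * t_max are excluded by construction).
    """
    t_max = max(release_times)
    gene_len = int(max(100_000, 1.25 * v * t_max))
    cfg = SimConfig(
        v=v,
        v_sd=v_sd,
        rho=0.5,
        k_release=2.0,    # fast release: the accumulated pool leaves as a sharp pulse
        background=0.05,  # low nonspecific floor so the front tracks the wave, not the flat background
        n_genes=n_genes,
        gene_lengths=tuple([gene_len] * n_genes),
        depth=depth,
        burn_in=0.0,
    )
    block_len = 30.0
    schedule = DrugSchedule(
        block_start=0.0,
        block_end=block_len,
        sample_times=tuple(block_len + t for t in release_times),
    )
    ss = np.random.SeedSequence(seed)
    panel_ss, cond_ss = ss.spawn(2)
    genes, genome = gene_panel(cfg, np.random.default_rng(panel_ss))
    tracks = simulate_condition_tracks(cfg, schedule, genes, genome, cond_ss)
    fronts = []
    for t, track in sorted(tracks.items()):
        f = median_front(track, genes, quantile, time=t - block_len)
        if f is not None:
            fronts.append(f)
    return elongation_rate(fronts)


def block_recycling_protocol(
    rho: float,
    seed: int,
    n_genes: int = 30,
    gene_length_range: Tuple[int, int] = (90_000, 110_000),
    depth: int = 100_000,
    burn_in: float = 30.0,
    block_times: Sequence[float] = (0.0, 10.0, 20.0, 40.0),
) -> float:
    """Recycling index from a block-phase-only run at one recycling efficiency.

    Genes are longer than v * max block time so the gene body never fully
    drains within the sampled block: the termination flux feeding the
    promoter pool then stays proportional to the recycling efficiency
    instead of saturating (once a short gene's body is empty, fixed-depth
    normalization pins all remaining signal at the promoter for any
    rho > 0, which would flatten the rho response).
    """
    cfg = SimConfig(
        rho=rho,
        n_genes=n_genes,
        gene_length_range=gene_length_range,
        depth=depth,
        burn_in=burn_in,
    )
    schedule = DrugSchedule(
        block_start=0.0,
        block_end=max(block_times) + 1.0,
        sample_times=tuple(block_times),
    )
    ss = np.random.SeedSequence(seed)
    panel_ss, cond_ss = ss.spawn(2)
    genes, genome = gene_panel(cfg, np.random.default_rng(panel_ss))
    tracks = simulate_condition_tracks(cfg, schedule, genes, genome, cond_ss)
    series = promoter_series(tracks, genes)
    baseline = median_body_density(tracks[block_times[0]], genes)
    return recycling_index(series, baseline, times=list(block_times)).index
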