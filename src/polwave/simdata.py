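"""Stochastic kinetic simulator of Pol II transcription with recycling.

The model tracks individual polymerase molecules per gene through four
compartments:

* ``U`` — promoter-engaged, not yet released (pre-release, Ser2-unmodified,
  therefore invisible to a Ser2 ChIP);
* ``E`` — elongating at position x bp downstream of the TSS (visible);
* ``T`` — dwelling at the termination site (visible);
* ``R`` — recycled back at the promoter after termination (visible: the
  Ser2 mark is acquired at first release and retained through recycling).

Per time step dt (fixed-step tau-leaping): each gene gains a new U with
probability k_init*dt; each U and R releases into E with probability
k_release*dt unless a CDK9-inhibitor block is engaged (release probability
0 during the block — already-elongating molecules are unaffected, matching
the drug's mechanism); E advances by Normal(v*dt, v_sd*sqrt(dt)) truncated
at 0; E reaching the gene end enters T for ``term_dwell`` minutes; an
expiring T becomes R with probability rho (the recycling efficiency) and
otherwise leaves the template.  Every per-event probability must stay
<= 0.2 per step, enforced, so leap error stays small.

Synthetic ChIP-seq reads are drawn multinomially from the Ser2-visible
occupancy histogram plus a uniform background fraction over the gene
+/- 2 kb, and written as BED6 alongside the ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pausing import GeneModel, write_genes
from .tracks import GenomeTable, write_bed, write_chrom_sizes

logger = logging.getLogger(__name__)

MAX_EVENT_PROB = 0.2
BACKGROUND_FLANK = 2000  # bp of uniform nonspecific signal beyond gene ends
GENE_MARGIN = 5000       # bp of bare chromosome flanking each gene


@dataclass(frozen=True)
class SimConfig:
    """Kinetic parameters and sampling sizes for one condition.

    Rates are per minute; positions and lengths in bp.  ``rho`` is the
    probability that a terminating polymerase recycles to its promoter.
    Defaults describe a plausible mammalian gene panel at desk scale:
    initiation every 2 min, drug-free pause release within ~20 s,
    2 kb/min elongation, 1 min termination dwell, efficient recycling.

    ``background`` is the nonspecific (uniform) fraction of the library at
    the first sampled time point; the background pedestal is held fixed in
    absolute (molecule-equivalent) units across the time course, emulating
    the invariant rest-of-genome signal that buffers fixed-depth
    normalization in a real library.
    """

    k_init: float = 0.5           # initiations / min / gene
    k_release: float = 2.0        # pause releases / min
    v: float = 2000.0             # elongation velocity, bp/min
    v_sd: float = 200.0           # velocity jitter, bp/min^0.5 scale
    term_dwell: float = 1.0       # min at the termination site
    rho: float = 0.9              # recycling probability per termination
    n_genes: int = 50
    gene_length_range: Tuple[int, int] = (20_000, 80_000)
    gene_lengths: Optional[Tuple[int, ...]] = None
    depth: int = 300_000          # reads per sampled time point
    read_length: int = 50
    dt: float = 0.05              # integration step, min
    burn_in: float = 60.0         # min of pre-schedule steady-state run
    background: float = 0.40      # nonspecific library fraction at first sample
    occupancy_bin: int = 25       # bp, histogram resolution

    def __post_init__(self) -> None:
        for name in ("k_init", "k_release", "v", "v_sd", "term_dwell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def depleted_config(base: Optional[SimConfig] = None) -> SimConfig:
    """Default factor-depleted condition.

    Depletion is modeled as a simultaneous reduction of recycling
    efficiency (rho 0.9 -> 0.2), elongation velocity (2000 -> 1200 bp/min)
    and pause-release rate (2.0 -> 0.02 /min): the depleted cells in the
    motivating experiments show less Ser2 Pol II recycled to promoters
    during the block, slower gene-body progression, and reduced release of
    promoter Pol II into gene bodies after washout.  Each knob can be
    varied independently through SimConfig.
    """
    base = base or SimConfig()
    return base.replace(rho=0.2, v=1200.0, k_release=0.02)


@dataclass(frozen=True)
class DrugSchedule:
    """Block/washout timing and sample times, all in minutes.

    A sample time t is in phase 'pre' (t < block_start), 'block'
    (block_start <= t < block_end) or 'washout' (t >= block_end; the
    sample at exactly block_end is the 0-min washout point).
    """

    block_start: float = 0.0
    block_end: float = 60.0
    sample_times: Tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 60.0, 70.0, 80.0, 100.0)

    def __post_init__(self) -> None:
        if self.block_start >= self.block_end:
            raise ValueError("block_start must precede block_end")
        if list(self.sample_times) != sorted(self.sample_times):
            raise ValueError("sample_times must be sorted")

    def phase(self, t: float) -> str:
        if t < self.block_start:
            return "pre"
        if t < self.block_end:
            return "block"
        return "washout"

    def in_block(self, t: float) -> bool:
        return self.block_start <= t < self.block_end

    @property
    def block_times(self) -> List[float]:
        return [t for t in self.sample_times if self.phase(t) == "block"]

    @property
    def washout_times(self) -> List[float]:
        return [t for t in self.sample_times if self.phase(t) == "washout"]

    def to_dict(self) -> dict:
        return {
            "block_start": self.block_start,
            "block_end": self.block_end,
            "sample_times": list(self.sample_times),
        }


@dataclass
class SimState:
    """Molecule bookkeeping for all genes of one condition.

    Compartments: ``paused`` (U) and ``recycled`` (R) as per-gene counts;
    elongating molecules (E) as parallel gene-index/position arrays;
    terminating molecules (T) as gene-index/remaining-dwell arrays.
    Allowed transitions: U->E, E->T, T->R or T->gone, R->E.
    """

    gene_lengths: np.ndarray
    paused: np.ndarray
    recycled: np.ndarray
    e_gene: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    e_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_gene: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    t_left: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def empty(cls, gene_lengths: Sequence[int]) -> "SimState":
        gl = np.asarray(gene_lengths, dtype=np.int64)
        n = len(gl)
        return cls(gl, np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_lengths)

    def total_molecules(self) -> int:
        return int(self.paused.sum() + self.recycled.sum() + len(self.e_pos) + len(self.t_left))

    def visible_molecules(self) -> int:
        return int(self.recycled.sum() + len(self.e_pos) + len(self.t_left))


def step(
    state: SimState,
    cfg: SimConfig,
    in_block: bool,
    rng: np.random.Generator,
    dt: Optional[float] = None,
) -> SimState:
    """Advance the kinetic model by one tau-leap of dt minutes (in place).

    Raises ValueError if any per-event probability (k_init*dt or
    k_release*dt) exceeds 0.2 — reduce dt.
    """
    dt = cfg.dt if dt is None else dt
    p_init = cfg.k_init * dt
    p_release = cfg.k_release * dt
    if max(p_init, p_release) > MAX_EVENT_PROB:
        raise ValueError(
            f"per-step event probability exceeds {MAX_EVENT_PROB} "
            f"(k_init*dt={p_init:.3g}, k_release*dt={p_release:.3g}); use a smaller dt"
        )
    n = state.n_genes

    # pause release (blocked by the drug; elongating molecules unaffected)
    if not in_block and p_release > 0:
        rel_u = rng.binomial(state.paused, p_release)
        rel_r = rng.binomial(state.recycled, p_release)
        state.paused -= rel_u
        state.recycled -= rel_r
        n_new = rel_u + rel_r
        if n_new.sum():
            new_genes = np.repeat(np.arange(n), n_new)
            state.e_gene = np.concatenate([state.e_gene, new_genes])
            state.e_pos = np.concatenate([state.e_pos, np.zeros(len(new_genes))])

    # elongation advance, truncated at zero displacement
    if len(state.e_pos):
        if cfg.v_sd > 0:
            adv = rng.normal(cfg.v * dt, cfg.v_sd * np.sqrt(dt), size=len(state.e_pos))
            np.maximum(adv, 0.0, out=adv)
        else:
            adv = cfg.v * dt
        state.e_pos = state.e_pos + adv
        done = state.e_pos >= state.gene_lengths[state.e_gene]
        if done.any():
            g_done = state.e_gene[done]
            state.t_gene = np.concatenate([state.t_gene, g_done])
            state.t_left = np.concatenate([state.t_left, np.full(len(g_done), cfg.term_dwell)])
            state.e_gene = state.e_gene[~done]
            state.e_pos = state.e_pos[~done]

    # termination dwell and recycling decision
    if len(state.t_left):
        state.t_left = state.t_left - dt
        expired = state.t_left <= 0
        if expired.any():
            g_exp = state.t_gene[expired]
            recycle = rng.random(len(g_exp)) < cfg.rho
            if recycle.any():
                np.add.at(state.recycled, g_exp[recycle], 1)
            state.t_gene = state.t_gene[~expired]
            state.t_left = state.t_left[~expired]

    # new initiation into the unreleased (Ser2-invisible) pool
    if p_init > 0:
        state.paused += (rng.random(n) < p_init).astype(np.int64)
    return state


def visible_occupancy(state: SimState, bin_width: int) -> List[np.ndarray]:
    """Per-gene histograms of Ser2-visible molecules in transcription coords.

    R molecules count at the TSS bin, T molecules at the TTS bin, E at
    their current position; U molecules are invisible.  Each gene's
    histogram has floor(L / bin_width) + 1 bins so the TTS bin exists.
    """
    gl = state.gene_lengths
    n_bins = gl // bin_width + 1
    offsets = np.concatenate([[0], np.cumsum(n_bins)])
    total = int(offsets[-1])
    idx_parts = []
    if len(state.e_pos):
        b = np.minimum(state.e_pos, gl[state.e_gene]).astype(np.int64) // bin_width
        idx_parts.append(offsets[state.e_gene] + b)
    if len(state.t_left):
        idx_parts.append(offsets[state.t_gene] + gl[state.t_gene] // bin_width)
    rec_genes = np.flatnonzero(state.recycled)
    if len(rec_genes):
        idx_parts.append(np.repeat(offsets[rec_genes], state.recycled[rec_genes]))
    if idx_parts:
        flat = np.bincount(np.concatenate(idx_parts), minlength=total)
    else:
        flat = np.zeros(total, dtype=np.int64)
    return [flat[offsets[i] : offsets[i + 1]] for i in range(state.n_genes)]


def gene_panel(cfg: SimConfig, rng: np.random.Generator) -> Tuple[List[GeneModel], GenomeTable]:
    """Synthetic gene panel: one gene per chromosome, alternating strands.

    Each chromosome is the gene plus a 5 kb margin on both sides so read
    extension and background flanks never clip.
    """
    if cfg.gene_lengths is not None:
        lengths = np.asarray(cfg.gene_lengths, dtype=np.int64)
    else:
        lo, hi = cfg.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    genes: List[GeneModel] = []
    genome: GenomeTable = {}
    for i, L in enumerate(lengths):
        chrom = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"g{i:04d}", chrom, strand, GENE_MARGIN, GENE_MARGIN + int(L)))
        genome[chrom] = int(L) + 2 * GENE_MARGIN
    return genes, genome


def sample_reads(
    occupancy: List[np.ndarray],
    genes: Sequence[GeneModel],
    genome: GenomeTable,
    depth: int,
    read_length: int,
    bin_width: int,
    bg_weight: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw ChIP-seq-like reads from the visible occupancy.

    Read 5' positions are multinomial with weights proportional to
    occupancy plus a uniform background of total weight ``bg_weight``
    (molecule-equivalent units) spread over each gene +/- 2 kb; each read
    is ``read_length`` bp on the gene's strand.  Zero total occupancy with
    zero background is an error.  Exactly ``depth`` reads are returned.
    """
    off = BACKGROUND_FLANK // bin_width
    n_ext = [len(o) + 2 * off for o in occupancy]
    edges = np.concatenate([[0], np.cumsum(n_ext)])
    total_bins = int(edges[-1])
    occ_w = np.zeros(total_bins)
    for i, o in enumerate(occupancy):
        occ_w[edges[i] + off : edges[i] + off + len(o)] = o
    w = occ_w + bg_weight / total_bins
    w_sum = w.sum()
    if w_sum == 0:
        raise ValueError("zero total occupancy with zero background weight")
    p = w / w_sum
    counts = rng.multinomial(depth, p)
    nz = np.flatnonzero(counts)
    bin_idx = np.repeat(nz, counts[nz])
    gene_idx = np.searchsorted(edges, bin_idx, side="right") - 1
    local = bin_idx - edges[gene_idx]
    # transcription coordinate of the read 5' end
    x = (local - off) * bin_width + rng.integers(0, bin_width, size=len(bin_idx))

    chroms = np.array([g.chrom for g in genes], dtype=object)[gene_idx]
    strands = np.array([g.strand for g in genes], dtype=object)[gene_idx]
    tss = np.array([g.tss for g in genes], dtype=np.int64)[gene_idx]
    lengths = np.array([genome[g.chrom] for g in genes], dtype=np.int64)[gene_idx]

    plus = strands == "+"
    g5 = np.where(plus, tss + x, tss - 1 - x)
    start = np.where(plus, g5, g5 - read_length + 1)
    end = start + read_length
    start = np.clip(start, 0, lengths - 1)
    end = np.clip(end, start + 1, lengths)
    df = pd.DataFrame({"chrom": chroms, "start": start, "end": end, "strand": strands})
    # stable order for byte-identical outputs
    return df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def run_course(
    cfg: SimConfig,
    schedule: DrugSchedule,
    genes: Sequence[GeneModel],
    genome: GenomeTable,
    seed,
) -> Tuple[Dict[float, pd.DataFrame], dict]:
    """Simulate one condition through the schedule, sampling reads.

    ``seed`` may be an int or a numpy SeedSequence.  Returns
    ({sample time -> read table}, truth dict with per-time aggregate
    visible-occupancy histograms and compartment counts).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(1 + len(schedule.sample_times))
    rng = np.random.default_rng(children[0])
    lengths = np.array([g.length for g in genes], dtype=np.int64)
    state = SimState.empty(lengths)

    t0 = -cfg.burn_in
    t_end = schedule.sample_times[-1]
    n_steps = int(round((t_end - t0) / cfg.dt))
    sample_at = {int(round((t - t0) / cfg.dt)): (i, t) for i, t in enumerate(schedule.sample_times)}

    reads_by_time: Dict[float, pd.DataFrame] = {}
    truth_hist: Dict[float, dict] = {}
    bg_weight: Dict[str, float] = {}  # absolute pedestal, fixed at first sample

    def take_sample(i: int, t: float) -> None:
        occ = visible_occupancy(state, cfg.occupancy_bin)
        if "value" not in bg_weight:
            occ0 = float(sum(o.sum() for o in occ))
            if cfg.background >= 1.0:
                raise ValueError("background fraction must be < 1")
            bg_weight["value"] = (
                cfg.background / (1.0 - cfg.background) * max(occ0, 1.0)
            )
        srng = np.random.default_rng(children[1 + i])
        reads_by_time[t] = sample_reads(
            occ, genes, genome, cfg.depth, cfg.read_length, cfg.occupancy_bin,
            bg_weight["value"], srng,
        )
        agg_bins = 500 // cfg.occupancy_bin
        agg = np.zeros(int(lengths.max()) // 500 + 1)
        for o in occ:
            coarse = np.add.reduceat(o, np.arange(0, len(o), agg_bins))
            agg[: len(coarse)] += coarse
        truth_hist[t] = {
            "phase": schedule.phase(t),
            "visible": state.visible_molecules(),
            "paused_unreleased": int(state.paused.sum()),
            "recycled_at_tss": int(state.recycled.sum()),
            "elongating": int(len(state.e_pos)),
            "terminating": int(len(state.t_left)),
            "occupancy_hist_500bp": [int(v) for v in agg],
        }

    if 0 in sample_at:
        take_sample(*sample_at[0])
    for k in range(1, n_steps + 1):
        t = t0 + k * cfg.dt
        step(state, cfg, schedule.in_block(t - cfg.dt), rng)
        if k in sample_at:
            take_sample(*sample_at[k])

    truth = {
        "config": dataclasses.asdict(cfg),
        "schedule": schedule.to_dict(),
        "per_time": {str(t): truth_hist[t] for t in schedule.sample_times},
    }
    return reads_by_time, truth


def make_timecourse(
    control: SimConfig,
    depleted: Optional[SimConfig],
    schedule: DrugSchedule,
    outdir,
    seed: int,
) -> dict:
    """Generate the full synthetic dataset on disk.

    Writes one BED6 per (condition, sample time), the shared gene panel
    (genes.tsv), chrom.sizes, and truth.json; both conditions share the
    gene panel and schedule and differ only in their stated kinetic
    parameters.  Returns a manifest dict (also written as manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    panel_ss, ctrl_ss, depl_ss = ss.spawn(3)
    genes, genome = gene_panel(control, np.random.default_rng(panel_ss))

    conditions = [("control", control, ctrl_ss)]
    if depleted is not None:
        conditions.append(("depleted", depleted, depl_ss))

    files: Dict[str, str] = {}
    truth: dict = {"seed": seed, "conditions": {}}
    for name, cfg, cond_ss in conditions:
        reads_by_time, cond_truth = run_course(cfg, schedule, genes, genome, cond_ss)
        for t, reads in reads_by_time.items():
            fname = f"{name}_t{int(t):04d}.bed"
            write_bed(reads, outdir / fname)
            files[fname] = _sha256(outdir / fname)
        truth["conditions"][name] = cond_truth

    write_genes(genes, outdir / "genes.tsv")
    files["genes.tsv"] = _sha256(outdir / "genes.tsv")
    write_chrom_sizes(genome, outdir / "chrom.sizes")
    files["chrom.sizes"] = _sha256(outdir / "chrom.sizes")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    files["truth.json"] = _sha256(outdir / "truth.json")

    manifest = {
        "seed": seed,
        "schedule": schedule.to_dict(),
        "conditions": [name for name, _, _ in conditions],
        "n_genes": len(genes),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
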