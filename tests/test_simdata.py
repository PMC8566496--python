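"""Kinetic simulator: closed-form limits, occupancy, read sampling, datasets."""

import json

import numpy as np
import pytest
from scipy import stats

from polwave.pausing import GeneModel
from polwave.simdata import (
    DrugSchedule,
    SimConfig,
    SimState,
    depleted_config,
    gene_panel,
    make_timecourse,
    run_course,
    sample_reads,
    step,
    visible_occupancy,
)


def fresh_rng(seed=7):
    return np.random.default_rng(seed)


class TestStep:
    def test_deterministic_advance_of_single_elongating_molecule(self):
        cfg = SimConfig(k_init=0.0, k_release=0.0, rho=0.0, v=2000.0, v_sd=0.0)
        state = SimState.empty([50_000])
        state.e_gene = np.array([0])
        state.e_pos = np.array([1_000.0])
        step(state, cfg, in_block=False, rng=fresh_rng())
        assert state.e_pos[0] == pytest.approx(1_000.0 + 2000.0 * cfg.dt)

    def test_block_with_only_unreleased_molecules_has_zero_visible_signal(self):
        cfg = SimConfig(v_sd=0.0)
        state = SimState.empty([10_000, 10_000])
        state.paused[:] = 25
        for _ in range(200):
            step(state, cfg, in_block=True, rng=fresh_rng())
        occ = visible_occupancy(state, 100)
        assert sum(o.sum() for o in occ) == 0
        assert state.paused.sum() == 50  # nothing released, nothing lost

    def test_molecule_conservation_with_infinite_dwell(self):
        cfg = SimConfig(k_init=0.0, term_dwell=np.inf, v_sd=0.0)
        state = SimState.empty([5_000] * 3)
        state.paused[:] = 10
        state.recycled[:] = 2
        total0 = state.total_molecules()
        rng = fresh_rng()
        for _ in range(500):
            step(state, cfg, in_block=False, rng=rng)
        assert state.total_molecules() == total0

    def test_molecule_conservation_with_certain_recycling(self):
        cfg = SimConfig(k_init=0.0, rho=1.0, term_dwell=0.5, v_sd=0.0)
        state = SimState.empty([5_000] * 3)
        state.paused[:] = 10
        total0 = state.total_molecules()
        rng = fresh_rng()
        for _ in range(1_000):
            step(state, cfg, in_block=False, rng=rng)
        assert state.total_molecules() == total0

    def test_oversized_time_step_is_rejected(self):
        cfg = SimConfig(k_release=2.0)
        state = SimState.empty([5_000])
        with pytest.raises(ValueError, match="smaller dt"):
            step(state, cfg, in_block=False, rng=fresh_rng(), dt=0.2)


class TestVisibleOccupancy:
    def test_elongating_molecule_lands_in_position_bin(self):
        state = SimState.empty([5_000])
        state.e_gene = np.array([0])
        state.e_pos = np.array([1_500.0])
        (occ,) = visible_occupancy(state, 100)
        assert occ[15] == 1 and occ.sum() == 1

    def test_recycled_and_terminating_map_to_tss_and_tts(self):
        state = SimState.empty([5_000])
        state.recycled[0] = 3
        state.t_gene = np.array([0])
        state.t_left = np.array([0.7])
        (occ,) = visible_occupancy(state, 100)
        assert occ[0] == 3
        assert occ[50] == 1  # TTS bin

    def test_histogram_total_equals_visible_molecules(self, rng):
        state = SimState.empty([8_000, 12_000])
        state.paused[:] = 5  # invisible
        state.recycled[:] = [2, 4]
        state.e_gene = np.repeat([0, 1], 10)
        state.e_pos = rng.uniform(0, 8_000, 20)
        occ = visible_occupancy(state, 250)
        assert sum(o.sum() for o in occ) == state.visible_molecules() == 26


class TestSampleReads:
    GENES = [GeneModel("g0", "chr1", "+", 5_000, 15_000),
             GeneModel("g1", "chr2", "-", 5_000, 15_000)]
    GENOME = {"chr1": 20_000, "chr2": 20_000}

    def test_exact_depth_and_single_bin_concentration(self):
        occ = [np.zeros(401), np.zeros(401)]
        occ[0][40] = 9.0  # transcription coords [1000, 1025)
        reads = sample_reads(occ, self.GENES, self.GENOME, 1_000, 50, 25, 0.0, fresh_rng())
        assert len(reads) == 1_000
        assert (reads["chrom"] == "chr1").all()
        starts = reads["start"].to_numpy()
        assert ((starts >= 6_000) & (starts < 6_025)).all()  # 5' ends inside the bin

    def test_minus_strand_reads_carry_gene_strand(self):
        occ = [np.zeros(401), np.zeros(401)]
        occ[1][0] = 5.0  # TSS bin of the minus-strand gene (TSS = 15000)
        reads = sample_reads(occ, self.GENES, self.GENOME, 200, 50, 25, 0.0, fresh_rng())
        assert (reads["strand"] == "-").all()
        # 5' end (end-1) within [TSS-25, TSS)
        assert ((reads["end"] - 1 <= 14_999) & (reads["end"] - 1 >= 14_975)).all()

    def test_zero_occupancy_without_background_errors(self):
        occ = [np.zeros(401), np.zeros(401)]
        with pytest.raises(ValueError):
            sample_reads(occ, self.GENES, self.GENOME, 100, 50, 25, 0.0, fresh_rng())

    def test_uniform_occupancy_read_counts_pass_goodness_of_fit(self):
        occ = [np.full(401, 2.0), np.zeros(401)]
        depth = 100_000
        reads = sample_reads(occ, self.GENES, self.GENOME, depth, 50, 25, 0.0, fresh_rng(3))
        # bin the 5' starts back into the occupancy grid
        x = reads.loc[reads["chrom"] == "chr1", "start"].to_numpy() - 5_000
        counts = np.bincount(x // 25, minlength=401)
        chi2, p = stats.chisquare(counts)
        assert p > 0.01


class TestRunCourse:
    def test_trailing_edge_of_retreating_wave_advances_at_v(self):
        """During the block no new Pol II is released, so the 5' edge of the
        elongating compartment sits at ~v*t downstream of the TSS."""
        cfg = SimConfig(v=2_000.0, v_sd=0.0, n_genes=6,
                        gene_lengths=tuple([80_000] * 6), depth=10_000, burn_in=30.0)
        schedule = DrugSchedule(block_start=0.0, block_end=25.0,
                                sample_times=(5.0, 10.0, 20.0))
        genes, genome = gene_panel(cfg, fresh_rng())
        ss = np.random.SeedSequence(11)
        # reach inside: run and check the truth histograms' first nonzero bin
        _, truth = run_course(cfg, schedule, genes, genome, ss)
        for t in schedule.sample_times:
            hist = np.array(truth["per_time"][str(t)]["occupancy_hist_500bp"])
            body = hist[1:]  # skip the TSS bin holding recycled molecules
            first = (np.flatnonzero(body)[0] + 1) * 500
            assert first == pytest.approx(2_000.0 * t, abs=600)

    def test_determinism_same_seed_same_reads(self):
        cfg = SimConfig(n_genes=4, gene_length_range=(5_000, 9_000), depth=5_000,
                        burn_in=2.0)
        schedule = DrugSchedule(block_start=0.0, block_end=5.0, sample_times=(0.0, 4.0))
        genes, genome = gene_panel(cfg, fresh_rng(5))
        r1, _ = run_course(cfg, schedule, genes, genome, 99)
        r2, _ = run_course(cfg, schedule, genes, genome, 99)
        for t in r1:
            assert r1[t].equals(r2[t])


class TestMakeTimecourse:
    def test_full_dataset_layout_and_determinism(self, tmp_path):
        cfg = SimConfig(n_genes=3, gene_length_range=(5_000, 8_000), depth=2_000,
                        burn_in=2.0, dt=0.05)
        schedule = DrugSchedule(block_start=0.0, block_end=6.0,
                                sample_times=(0.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0))
        out1, out2 = tmp_path / "a", tmp_path / "b"
        m1 = make_timecourse(cfg, depleted_config(cfg), schedule, out1, seed=42)
        m2 = make_timecourse(cfg, depleted_config(cfg), schedule, out2, seed=42)
        beds = [f for f in m1["files"] if f.endswith(".bed")]
        assert len(beds) == 16  # 8 sample times x 2 conditions
        assert m1["files"] == m2["files"]  # byte-identical (sha256 match)
        truth = json.loads((out1 / "truth.json").read_text())
        assert set(truth["conditions"]) == {"control", "depleted"}
        assert (out1 / "genes.tsv").exists() and (out1 / "chrom.sizes").exists()

    def test_single_condition_dataset(self, tmp_path):
        cfg = SimConfig(n_genes=2, gene_length_range=(5_000, 6_000), depth=1_000,
                        burn_in=1.0)
        schedule = DrugSchedule(block_start=0.0, block_end=4.0, sample_times=(0.0, 3.0))
        m = make_timecourse(cfg, None, schedule, tmp_path / "solo", seed=7)
        assert m["conditions"] == ["control"]
        assert sum(f.endswith(".bed") for f in m["files"]) == 2


def test_tss_occupancy_grows_during_block_with_high_recycling():
    """With efficient recycling the Ser2-visible TSS pool is non-decreasing
    in expectation while release is blocked."""
    cfg = SimConfig(rho=0.9, n_genes=20, gene_length_range=(15_000, 25_000),
                    depth=10_000, burn_in=20.0, v_sd=0.0)
    schedule = DrugSchedule(block_start=0.0, block_end=45.0,
                            sample_times=(0.0, 10.0, 20.0, 40.0))
    counts = []
    for seed in range(5):
        genes, genome = gene_panel(cfg, fresh_rng(seed))
        _, truth = run_course(cfg, schedule, genes, genome, seed)
        counts.append([truth["per_time"][str(t)]["recycled_at_tss"]
                      for t in schedule.sample_times])
    med = np.median(np.array(counts), axis=0)
    assert all(np.diff(med) >= 0)
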