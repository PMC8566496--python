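import numpy as np
import pytest

from polwave.tracks import CoverageTrack


def make_track(per_base: dict, bin_width: int = 1, factor: float = 1.0) -> CoverageTrack:
    """Build a CoverageTrack directly from per-base arrays (bin_width 1)
    or pre-binned arrays (bin_width > 1 with explicit genome lengths)."""
    genome = {c: len(a) * (1 if bin_width == 1 else bin_width) for c, a in per_base.items()}
    data = {c: np.asarray(a, dtype=float) for c, a in per_base.items()}
    return CoverageTrack(
        data=data, bin_width=bin_width, normalization_factor=factor,
        effective_depth=1, genome=genome,
    )


def uniform_track(genome: dict, value: float, bin_width: int = 10) -> CoverageTrack:
    data = {c: np.full(-(-int(L) // bin_width), float(value)) for c, L in genome.items()}
    return CoverageTrack(
        data=data, bin_width=bin_width, normalization_factor=1.0,
        effective_depth=1, genome=dict(genome),
    )


@pytest.fixture
def toy_genome():
    return {"chrA": 100_000, "chrB": 60_000}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
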