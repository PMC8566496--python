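"""Strand-aware three-region gene bins and pausing/release ratio statistics.

Each gene longer than 700 bp is divided into a 5'-end bin [TSS-50, TSS+200),
a gene-body bin [TSS+200, TTS-500) and a 3'-end bin [TTS-500, TTS+500), all
in transcription coordinates.  The 5' pausing ratio is the mean per-base
density in the 5' bin divided by the gene-body mean; the 3' release ratio
is the 3'-bin mean over the gene-body mean.  Both are scale-free: they do
not depend on the track's depth normalization.

For a minus-strand gene the transcription interval [a, b) (downstream
positive) maps to the genomic interval [TSS-b, TSS-a); base k of the
transcript is genomic base TSS-1-k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .tracks import STRANDS, CoverageTrack, GenomeTable

logger = logging.getLogger(__name__)

# Bin-scheme offsets in transcription coordinates (bp relative to TSS / TTS).
FIVE_PRIME_UP = 50
FIVE_PRIME_DOWN = 200
THREE_PRIME_FLANK = 500
MIN_GENE_LENGTH = 700  # body bin [TSS+200, TTS-500) empty at or below this


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with derived TSS/TTS."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def genomic_interval(self, a: int, b: int) -> Tuple[int, int]:
        """Map transcription-coordinate interval [a, b) to genomic [s, e)."""
        if self.strand == "+":
            return self.tss + a, self.tss + b
        return self.tss - b, self.tss - a


@dataclass(frozen=True)
class BinScheme:
    """Genomic intervals of the three per-gene regions."""

    five_prime: Tuple[int, int]
    body: Tuple[int, int]
    three_prime: Tuple[int, int]


@dataclass(frozen=True)
class PausingRatios:
    """Per-gene bin densities and ratios at one time point/condition.

    ``valid`` is False when the gene-body mean density is zero (or a bin is
    entirely off-chromosome); the ratios are then NaN rather than infinite.
    """

    gene_id: str
    d5: float
    dbody: float
    d3: float
    pr5: float
    rr3: float
    valid: bool


def bin_scheme(gene: GeneModel) -> BinScheme:
    """Three-region scheme for one gene; requires gene length > 700 bp."""
    L = gene.length
    if L <= MIN_GENE_LENGTH:
        raise ValueError(
            f"gene {gene.id}: length {L} <= {MIN_GENE_LENGTH}, gene-body bin empty"
        )
    return BinScheme(
        five_prime=gene.genomic_interval(-FIVE_PRIME_UP, FIVE_PRIME_DOWN),
        body=gene.genomic_interval(FIVE_PRIME_DOWN, L - THREE_PRIME_FLANK),
        three_prime=gene.genomic_interval(L - THREE_PRIME_FLANK, L + THREE_PRIME_FLANK),
    )


def load_genes(path, genome: Mapping[str, int], min_length: int = MIN_GENE_LENGTH) -> List[GeneModel]:
    """Load gene models from a 5-column TSV (id, chrom, strand, start, end)
    or BED6 (chrom, start, end, name, score, strand; name used as id).

    Genes on chromosomes absent from ``genome`` and genes with
    length <= ``min_length`` are dropped with logged counts.  Duplicate ids
    raise ValueError.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] >= 6 and df[5].isin(list(STRANDS)).all():
        genes_df = pd.DataFrame(
            {
                "id": df[3],
                "chrom": df[0],
                "strand": df[5],
                "start": pd.to_numeric(df[1]).astype(np.int64),
                "end": pd.to_numeric(df[2]).astype(np.int64),
            }
        )
    elif df.shape[1] >= 5:
        genes_df = pd.DataFrame(
            {
                "id": df[0],
                "chrom": df[1],
                "strand": df[2],
                "start": pd.to_numeric(df[3]).astype(np.int64),
                "end": pd.to_numeric(df[4]).astype(np.int64),
            }
        )
    else:
        raise ValueError(f"{path}: expected 5-column gene TSV or BED6")
    if genes_df["id"].duplicated().any():
        dup = genes_df.loc[genes_df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    known = genes_df["chrom"].isin(set(genome))
    if (~known).any():
        logger.info("load_genes: dropped %d genes on unknown chromosomes", int((~known).sum()))
    genes_df = genes_df[known]
    long_enough = (genes_df["end"] - genes_df["start"]) > min_length
    if (~long_enough).any():
        logger.info(
            "load_genes: dropped %d genes with length <= %d", int((~long_enough).sum()), min_length
        )
    genes_df = genes_df[long_enough]
    return [
        GeneModel(r.id, r.chrom, r.strand, int(r.start), int(r.end))
        for r in genes_df.itertuples(index=False)
    ]


def write_genes(genes: List[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")


def mean_density(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Mean per-nucleotide normalized signal over the clamped interval."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    s, e = track.clamp(chrom, start, end)
    if e <= s:
        raise ValueError(
            f"interval [{start}, {end}) lies entirely outside chromosome {chrom!r}"
        )
    return track.interval_sum(chrom, s, e) / (e - s)


def pausing_ratios(track: CoverageTrack, gene: GeneModel) -> PausingRatios:
    """5' pausing ratio and 3' release ratio for one gene on one track.

    A gene whose body mean density is zero, or whose 5' bin is entirely
    off-chromosome, yields ``valid=False`` with NaN ratios — not an error
    and not a pseudocount.
    """
    scheme = bin_scheme(gene)
    densities = {}
    for name, (s, e) in (
        ("d5", scheme.five_prime),
        ("dbody", scheme.body),
        ("d3", scheme.three_prime),
    ):
        try:
            densities[name] = mean_density(track, gene.chrom, s, e)
        except ValueError:
            densities[name] = math.nan
    d5, dbody, d3 = densities["d5"], densities["dbody"], densities["d3"]
    valid = dbody > 0 and not any(math.isnan(x) for x in (d5, dbody, d3))
    pr5 = d5 / dbody if valid else math.nan
    rr3 = d3 / dbody if valid else math.nan
    return PausingRatios(gene.id, d5, dbody, d3, pr5, rr3, valid)


def ratio_table(
    tracks: Mapping[Tuple[object, str], CoverageTrack], genes: List[GeneModel]
) -> pd.DataFrame:
    """Pausing/release ratios for every (gene, time point, condition).

    ``tracks`` maps (time, condition) -> CoverageTrack.  Returns a long
    DataFrame with columns gene/time/condition/d5/dbody/d3/pr5/rr3/valid.
    """
    if not tracks or not genes:
        raise ValueError("ratio_table requires at least one track and one gene")
    rows = []
    for (time, condition), track in tracks.items():
        n_invalid = 0
        for gene in genes:
            r = pausing_ratios(track, gene)
            n_invalid += not r.valid
            rows.append(
                {
                    "gene": r.gene_id,
                    "time": time,
                    "condition": condition,
                    "d5": r.d5,
                    "dbody": r.dbody,
                    "d3": r.d3,
                    "pr5": r.pr5,
                    "rr3": r.rr3,
                    "valid": r.valid,
                }
            )
        if n_invalid:
            logger.info(
                "ratio_table: %d/%d genes invalid (zero body density) at time=%r condition=%r",
                n_invalid, len(genes), time, condition,
            )
    return pd.DataFrame(rows)


def sorted_ratio_curve(
    table: pd.DataFrame, time, condition: str, column: str = "pr5"
) -> np.ndarray:
    """Sorted valid ratio values for one track (rank-vs-value curve)."""
    sub = table[(table["time"] == time) & (table["condition"] == condition) & table["valid"]]
    return np.sort(sub[column].to_numpy())


def per_base_transcription(
    track: CoverageTrack, gene: GeneModel, k0: int, k1: int
) -> np.ndarray:
    """Per-base signal over transcription coordinates [k0, k1), 5'->3'.

    Positions falling outside the chromosome are NaN so averages can skip
    them explicitly.
    """
    if k1 <= k0:
        raise ValueError("empty transcription interval")
    gs, ge = gene.genomic_interval(k0, k1)
    cs, ce = track.clamp(gene.chrom, gs, ge)
    out = np.full(k1 - k0, np.nan)
    if ce > cs:
        vals = track.per_base(gene.chrom, cs, ce)
        out[cs - gs : ce - gs] = vals
    if gene.strand == "-":
        out = out[::-1]
    return out
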