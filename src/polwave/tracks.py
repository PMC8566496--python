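"""Genomic interval I/O and depth-normalized coverage tracks.

The coverage model follows common ChIP-seq browser-track practice: each
aligned read is replaced by a fixed-length fragment anchored at its 5' end
and oriented 5'->3' (plus strand extends right, minus strand extends left),
per-base fragment overlap is counted, and the signal is rescaled so every
library has the same effective sequencing depth (default 50 million reads).

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = frozenset({"+", "-"})

READ_COLUMNS = ["chrom", "start", "end", "strand"]


class ReadRecord(NamedTuple):
    """One aligned read (or extended fragment) as a strand-annotated interval."""

    chrom: str
    start: int
    end: int
    strand: str


# GenomeTable is a plain mapping chrom -> length; helpers below validate it.
GenomeTable = Dict[str, int]


@dataclass(frozen=True)
class TrackConfig:
    """Parameters of the track-building step.

    extension_length
        Fragment length substituted for each read, anchored at the read 5'
        end (default 300 bp, a typical ChIP library insert size).
    target_depth
        Effective depth every library is rescaled to (default 5e7 reads).
    bin_width
        Storage resolution of the track in bp.
    """

    extension_length: int = 300
    target_depth: float = 50_000_000.0
    bin_width: int = 10

    def __post_init__(self) -> None:
        if self.extension_length <= 0:
            raise ValueError("extension_length must be > 0")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")


def validate_genome(genome: Mapping[str, int]) -> None:
    for name, length in genome.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")


def read_chrom_sizes(path) -> GenomeTable:
    """Read a two-column chrom.sizes file into a name -> length mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise ValueError(f"duplicate chromosome name {dup!r} in {path}")
    genome = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    validate_genome(genome)
    return genome


def write_chrom_sizes(genome: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{int(length)}\n")


def reads_from_records(records: Iterable[ReadRecord]) -> pd.DataFrame:
    """Build the columnar read table from ReadRecord tuples."""
    rows = list(records)
    if not rows:
        return pd.DataFrame(columns=READ_COLUMNS)
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def iter_records(reads: pd.DataFrame) -> Iterator[ReadRecord]:
    """Iterate a read table as ReadRecord tuples (row order preserved)."""
    for row in reads.itertuples(index=False):
        yield ReadRecord(row.chrom, int(row.start), int(row.end), row.strand)


def _as_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    return reads_from_records(reads)


def read_bed(path) -> pd.DataFrame:
    """Parse a BED6 file of aligned reads.

    Returns a DataFrame with columns chrom/start/end/strand, one row per
    line in file order, coordinates kept 0-based half-open.  Malformed
    lines (non-integer coordinates, start >= end, strand outside {+,-},
    fewer than 6 fields) raise ValueError naming the 1-based line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            dtype=str,
            keep_default_na=False,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=READ_COLUMNS)
    if df.shape[1] < 6:
        # pandas drops trailing empty columns; find first short line for the message
        raise ValueError(f"{path}: BED6 requires >= 6 tab-separated fields, got {df.shape[1]}")
    start = pd.to_numeric(df[1], errors="coerce")
    end = pd.to_numeric(df[2], errors="coerce")
    strand = df[5]

    def _fail(mask: pd.Series, reason: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValueError(f"{path}: line {line}: {reason}")

    _fail(start.isna() | end.isna(), "non-integer coordinate")
    _fail((start % 1 != 0) | (end % 1 != 0), "non-integer coordinate")
    start = start.astype(np.int64)
    end = end.astype(np.int64)
    _fail(start < 0, "negative start")
    _fail(start >= end, "start >= end")
    _fail(~strand.isin(list(STRANDS)), "strand must be '+' or '-'")
    out = pd.DataFrame(
        {"chrom": df[0].astype(str), "start": start, "end": end, "strand": strand}
    )
    return out


def write_bed(reads: pd.DataFrame, path) -> None:
    """Write a read table as BED6 (name '.', score 0)."""
    df = _as_frame(reads)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "name": ".",
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def drop_duplicate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Optional exact-duplicate ('clonal') filter on chrom/start/end/strand."""
    df = _as_frame(reads)
    out = df.drop_duplicates(subset=READ_COLUMNS, keep="first").reset_index(drop=True)
    n_dropped = len(df) - len(out)
    if n_dropped:
        logger.info("drop_duplicate_reads: removed %d exact duplicates", n_dropped)
    return out


def extend_reads(reads, genome: Mapping[str, int], cfg: TrackConfig) -> pd.DataFrame:
    """Replace each read by an extension_length fragment anchored at its 5' end.

    Plus-strand reads become [start, start+L); minus-strand reads become
    [end-L, end).  Fragments are clamped to [0, chrom length).  Reads on
    chromosomes absent from the genome table raise KeyError.
    """
    df = _as_frame(reads)
    if df.empty:
        return df.copy()
    unknown = set(df["chrom"].unique()) - set(genome)
    if unknown:
        raise KeyError(f"chromosome(s) not in genome table: {sorted(unknown)!r}")
    ext = cfg.extension_length
    plus = (df["strand"] == "+").to_numpy()
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    new_start = np.where(plus, start, end - ext)
    new_end = new_start + ext
    lengths = df["chrom"].map(genome).to_numpy(np.int64)
    new_start = np.clip(new_start, 0, lengths)
    new_end = np.clip(new_end, 0, lengths)
    return pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": new_start,
            "end": new_end,
            "strand": df["strand"].to_numpy(),
        }
    )


@dataclass
class CoverageTrack:
    """Depth-normalized coverage signal at fixed bin width per chromosome.

    ``data[chrom][i]`` is the mean per-base fragment coverage over bin i,
    multiplied by ``normalization_factor = target_depth / effective_depth``.
    The last bin of a chromosome may be partial; its value averages only
    over the bases that exist.
    """

    data: Dict[str, np.ndarray]
    bin_width: int
    normalization_factor: float
    effective_depth: int
    genome: GenomeTable = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return len(self.data[chrom])

    def chrom_length(self, chrom: str) -> int:
        return int(self.genome[chrom])

    def clamp(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        L = self.chrom_length(chrom)
        return max(0, int(start)), min(L, int(end))

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over the (clamped) interval [start, end)."""
        s, e = self.clamp(chrom, start, end)
        if e <= s:
            return 0.0
        w = self.bin_width
        vals = self.data[chrom]
        i0, i1 = s // w, (e - 1) // w
        if i0 == i1:
            return float(vals[i0] * (e - s))
        total = vals[i0] * ((i0 + 1) * w - s) + vals[i1] * (e - i1 * w)
        if i1 > i0 + 1:
            total += vals[i0 + 1 : i1].sum() * w
        return float(total)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over the (clamped) interval, expanded from bins."""
        s, e = self.clamp(chrom, start, end)
        if e <= s:
            return np.empty(0)
        w = self.bin_width
        i0, i1 = s // w, (e - 1) // w
        expanded = np.repeat(self.data[chrom][i0 : i1 + 1], w)
        off = s - i0 * w
        return expanded[off : off + (e - s)]

    def total_mass(self) -> float:
        """Sum over all bases of the per-base signal (bin value x bin width)."""
        total = 0.0
        for chrom, vals in self.data.items():
            widths = self._bin_widths(chrom)
            total += float(np.dot(vals, widths))
        return total

    def _bin_widths(self, chrom: str) -> np.ndarray:
        L = self.chrom_length(chrom)
        w = self.bin_width
        n = len(self.data[chrom])
        widths = np.full(n, w, dtype=np.int64)
        widths[-1] = L - (n - 1) * w
        return widths

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            data={c: v * factor for c, v in self.data.items()},
            bin_width=self.bin_width,
            normalization_factor=self.normalization_factor * factor,
            effective_depth=self.effective_depth,
            genome=dict(self.genome),
        )


def build_coverage(reads, genome: Mapping[str, int], cfg: TrackConfig) -> CoverageTrack:
    """Count extended-fragment overlap per base, bin, and depth-normalize.

    ``reads`` must already be extended fragments (see :func:`extend_reads`);
    the normalization factor is target_depth / N where N is the number of
    fragments (the raw aligned-read count, which extension preserves).
    N = 0 is an error: the rescaling is undefined for an empty library.
    """
    df = _as_frame(reads)
    n_reads = len(df)
    if n_reads == 0:
        raise ValueError("cannot normalize an empty read set (N = 0)")
    validate_genome(genome)
    factor = cfg.target_depth / n_reads
    w = cfg.bin_width
    data: Dict[str, np.ndarray] = {}
    grouped = dict(tuple(df.groupby("chrom", sort=False)))
    for chrom, length in genome.items():
        length = int(length)
        n_bins = -(-length // w)
        sub = grouped.get(chrom)
        if sub is None or sub.empty:
            data[chrom] = np.zeros(n_bins)
            continue
        starts = np.clip(sub["start"].to_numpy(np.int64), 0, length)
        ends = np.clip(sub["end"].to_numpy(np.int64), 0, length)
        diff = np.zeros(length + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        per_base = np.cumsum(diff[:-1])
        padded = np.zeros(n_bins * w)
        padded[:length] = per_base
        sums = padded.reshape(n_bins, w).sum(axis=1)
        widths = np.full(n_bins, w, dtype=np.int64)
        widths[-1] = length - (n_bins - 1) * w
        data[chrom] = sums / widths * factor
    return CoverageTrack(
        data=data,
        bin_width=w,
        normalization_factor=factor,
        effective_depth=n_reads,
        genome=dict(genome),
    )


def _bedgraph_intervals(track: CoverageTrack, chrom: str):
    """Run-length encode one chromosome's bins into (start, end, value)."""
    vals = track.data[chrom]
    if len(vals) == 0:
        return
    w = track.bin_width
    L = track.chrom_length(chrom)
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    for b0, b1 in zip(starts, ends):
        v = vals[b0]
        if v == 0:
            continue
        yield int(b0) * w, min(int(b1) * w, L), float(v)


def write_track(track: CoverageTrack, path, format: str = "bedGraph") -> None:
    """Write a track as bedGraph (run-length text) or bigWig (via pyBigWig)."""
    if format == "bedGraph":
        with open(path, "w") as fh:
            for chrom in track.data:
                for s, e, v in _bedgraph_intervals(track, chrom):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    elif format == "bigWig":
        import pyBigWig

        bw = pyBigWig.open(str(path), "w")
        bw.addHeader([(c, track.chrom_length(c)) for c in track.data])
        for chrom in track.data:
            ivals = list(_bedgraph_intervals(track, chrom))
            if not ivals:
                continue
            starts = [s for s, _, _ in ivals]
            ends = [e for _, e, _ in ivals]
            values = [v for _, _, v in ivals]
            bw.addEntries([chrom] * len(ivals), starts, ends=ends, values=values)
        bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(
    path,
    genome: Mapping[str, int],
    bin_width: int,
    format: str = "bedGraph",
    normalization_factor: float = 1.0,
    effective_depth: int = 0,
) -> CoverageTrack:
    """Read a bedGraph/bigWig written by :func:`write_track` back into a track.

    Interval boundaries must align with ``bin_width`` (as written tracks do),
    except at chromosome ends.
    """
    validate_genome(genome)
    data = {
        chrom: np.zeros(-(-int(L) // bin_width)) for chrom, L in genome.items()
    }
    if format == "bedGraph":
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        rows = df.itertuples(index=False)
    elif format == "bigWig":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        rows = []
        for chrom in genome:
            if chrom not in (bw.chroms() or {}):
                continue
            for s, e, v in bw.intervals(chrom) or []:
                rows.append((chrom, s, e, v))
        bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")
    for chrom, s, e, v in rows:
        if chrom not in data:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        b0 = int(s) // bin_width
        b1 = -(-int(e) // bin_width)
        data[chrom][b0:b1] = v
    return CoverageTrack(
        data=data,
        bin_width=bin_width,
        normalization_factor=normalization_factor,
        effective_depth=effective_depth,
        genome=dict(genome),
    )
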