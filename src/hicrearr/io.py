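"""Text I/O: triplet matrices, 4DN-style pairs, bedGraph, BED, BEDPE.

Triplet matrix format (one file per matrix)::

    #resolution=<int>
    #uvp=<int>
    #chrom=<name>:<length>        (one line per chromosome, layout order)
    binA<TAB>binB<TAB>count

Lower-triangle entries are normalized to the upper triangle on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import BinIndex, GenomeLayout
from .matrix import ContactMatrix, pairs_to_matrix
from .tracks import BinnedTrack

__all__ = [
    "write_matrix",
    "read_matrix",
    "read_pairs_matrix",
    "write_pairs",
    "write_bedgraph",
    "read_bedgraph_track",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def write_matrix(matrix: ContactMatrix, path) -> None:
    path = Path(path)
    coo = matrix.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with path.open("w") as fh:
        fh.write(f"#resolution={matrix.bins.resolution}\n")
        fh.write(f"#uvp={matrix.uvp}\n")
        for name, length in zip(matrix.bins.layout.names, matrix.bins.layout.lengths):
            fh.write(f"#chrom={name}:{length}\n")
        for k in order:
            v = coo.data[k]
            v_str = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{coo.row[k]}\t{coo.col[k]}\t{v_str}\n")


def read_matrix(path) -> ContactMatrix:
    path = Path(path)
    resolution = None
    uvp = 0
    names: list[str] = []
    lengths: list[int] = []
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, val = line[1:].split("=", 1)
                    if key == "resolution":
                        resolution = int(val)
                    elif key == "uvp":
                        uvp = int(val)
                    elif key == "chrom":
                        name, length = val.rsplit(":", 1)
                        names.append(name)
                        lengths.append(int(length))
                except ValueError as e:
                    raise ParseError(f"{path}:{lineno}: bad header {line!r}") from e
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad triplet {line!r}") from e
            rows.append(min(i, j))
            cols.append(max(i, j))
            data.append(v)
    if resolution is None or not names:
        raise ParseError(f"{path}: missing #resolution or #chrom header")
    bins = BinIndex(GenomeLayout(tuple(names), tuple(lengths)), resolution)
    n = bins.n_bins
    counts = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    counts.sum_duplicates()
    return ContactMatrix(bins, counts, uvp=uvp)


def read_pairs_matrix(path, bins: BinIndex) -> ContactMatrix:
    """Bin a 4DN-style pairs text file (readID chrA posA chrB posB [strands])."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        usecols=[1, 2, 3, 4],
        names=["chrA", "posA", "chrB", "posB"],
        dtype={"chrA": str, "chrB": str},
    )
    return pairs_to_matrix(
        (
            df["chrA"].to_numpy(),
            df["posA"].to_numpy(np.int64),
            df["chrB"].to_numpy(),
            df["posB"].to_numpy(np.int64),
        ),
        bins,
    )


def write_pairs(pairs, path) -> None:
    """Write (chromA,posA,chromB,posB) tuples as 4DN-style pairs text."""
    with Path(path).open("w") as fh:
        fh.write("## pairs format v1.0\n")
        for k, (ca, pa, cb, pb) in enumerate(pairs):
            fh.write(f"read{k}\t{ca}\t{pa}\t{cb}\t{pb}\t+\t+\n")


def write_bedgraph(track: BinnedTrack, path) -> None:
    with Path(path).open("w") as fh:
        for b in range(track.bins.n_bins):
            v = track.values[b]
            if np.isnan(v):
                continue
            chrom, start, end = track.bins.bin_interval(b)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_bedgraph_track(path, bins: BinIndex, label: str = "") -> BinnedTrack:
    """Read a bedGraph into a BinnedTrack; intervals must align with bins."""
    values = np.full(bins.n_bins, np.nan)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    for chrom, start, value in zip(df["chrom"], df["start"], df["value"]):
        values[bins.bin_id(str(chrom), int(start))] = value
    return BinnedTrack(bins, values, label=label)


def read_bed(path) -> pd.DataFrame:
    """BED (3-6 columns) as a DataFrame with chrom/start/end[/name/score/strand]."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


BEDPE_COLUMNS = [
    "chromA", "startA", "endA", "chromB", "startB", "endB",
    "name", "score", "strandA", "strandB",
]


def read_bedpe(path) -> pd.DataFrame:
    """BEDPE with optional extra columns after the canonical ten."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 3: str})
    if list(df.columns[:2]) != BEDPE_COLUMNS[:2]:
        # headerless file: re-read assigning canonical names
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
        ncol = df.shape[1]
        names = BEDPE_COLUMNS[:ncol] + [f"extra{k}" for k in range(ncol - 10)]
        df.columns = names[:ncol]
    return df


def write_bedpe(df: pd.DataFrame, path, header: bool = True) -> None:
    df.to_csv(path, sep="\t", header=header, index=False)
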