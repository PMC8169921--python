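"""Readers and writers for the text formats the pipeline exchanges.

BED and bedGraph are written 0-based half-open and sorted by (genome order,
start) so outputs diff stably. Contact matrices travel either as dense
whitespace-delimited square text per chromosome or in a cooler-style
single-resolution HDF5 container (``chroms``/``bins``/``pixels`` tables with
upper-triangle COO pixels), addressed by chromosome on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:
    import h5py
except ImportError:  # pragma: no cover
    h5py = None

from .errors import InputError
from .genome import BinnedTrack, GenomeTable, validate_intervals
from .hic import ContactMatrix

__all__ = [
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_dense_matrix",
    "read_dense_matrix",
    "write_cooler",
    "read_cooler",
]


def _sort_genomic(df: pd.DataFrame, genome: GenomeTable | None) -> pd.DataFrame:
    if genome is not None:
        order = {c: i for i, c in enumerate(genome.names)}
        key = df["chrom"].map(order)
    else:
        key = df["chrom"]
    return df.assign(_k=key).sort_values(["_k", "start"], kind="stable").drop(columns="_k")


def write_bed(df: pd.DataFrame, path, genome: GenomeTable | None = None) -> None:
    """Write intervals as BED; label in column 4 and score in column 5 if present."""
    validate_intervals(df)
    out = _sort_genomic(df, genome)
    cols = ["chrom", "start", "end"]
    if "label" in out.columns:
        cols.append("label")
        if "score" in out.columns:
            cols.append("score")
    out[cols].to_csv(path, sep="\t", header=False, index=False, na_rep=".")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into an interval frame with optional label/score columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "label", "score"][: df.shape[1]]
    df = df.iloc[:, : len(names)]
    df.columns = names
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return validate_intervals(df)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a binned track as 4-column bedGraph, skipping missing bins."""
    rows = []
    for chrom in track.genome.names:
        vec = track.values.get(chrom)
        if vec is None:
            continue
        edges = track.genome.bin_edges(chrom, track.bin_size)
        for start, end, v in zip(edges[:-1], edges[1:], vec):
            if np.isfinite(v):
                rows.append((chrom, int(start), int(end), float(v)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bedgraph(path, genome: GenomeTable, bin_size: int, kind: str = "coverage_fraction") -> BinnedTrack:
    """Read a bedGraph whose intervals align to the given binning; gaps become NaN."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    values = {
        chrom: np.full(genome.n_bins(chrom, bin_size), np.nan) for chrom in genome.names
    }
    for row in df.itertuples(index=False):
        if row.chrom not in genome:
            raise InputError(f"{path}: unknown chromosome {row.chrom!r}")
        if row.start % bin_size:
            raise InputError(f"{path}: interval {row.start}-{row.end} not aligned to {bin_size}-bp bins")
        values[row.chrom][row.start // bin_size] = row.value
    return BinnedTrack(genome, bin_size, values, kind=kind)


def write_dense_matrix(m: ContactMatrix, path) -> None:
    np.savetxt(path, m.counts, fmt="%.8g", delimiter="\t")


def read_dense_matrix(path, chrom: str, bin_size: int, normalization: str = "raw") -> ContactMatrix:
    counts = np.loadtxt(path, delimiter="\t", ndmin=2)
    return ContactMatrix(chrom, bin_size, counts, normalization)


def _require_h5py():
    if h5py is None:  # pragma: no cover
        raise InputError("h5py is required for cooler-style containers")


def write_cooler(path, genome: GenomeTable, matrices: dict[str, ContactMatrix]) -> None:
    """Write per-chromosome matrices into a single-resolution cooler-style file."""
    _require_h5py()
    bin_sizes = {m.bin_size for m in matrices.values()}
    if len(bin_sizes) != 1:
        raise InputError("all matrices must share one resolution")
    bin_size = bin_sizes.pop()
    chrom_ids, starts, ends = [], [], []
    offsets = {}
    for cid, (chrom, length) in enumerate(genome.items()):
        offsets[chrom] = len(starts)
        edges = genome.bin_edges(chrom, bin_size)
        chrom_ids.extend([cid] * (len(edges) - 1))
        starts.extend(edges[:-1])
        ends.extend(edges[1:])
    b1, b2, cnt = [], [], []
    for chrom, m in matrices.items():
        off = offsets[chrom]
        iu = np.triu_indices(m.n_bins)
        vals = m.counts[iu]
        keep = np.isfinite(vals) & (vals != 0)
        b1.append(iu[0][keep] + off)
        b2.append(iu[1][keep] + off)
        cnt.append(vals[keep])
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = bin_size
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(genome.names, dtype="S"))
        g.create_dataset("length", data=np.array(genome.lengths, dtype=np.int64))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.array(chrom_ids, dtype=np.int32))
        g.create_dataset("start", data=np.array(starts, dtype=np.int64))
        g.create_dataset("end", data=np.array(ends, dtype=np.int64))
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=np.concatenate(b1).astype(np.int64))
        g.create_dataset("bin2_id", data=np.concatenate(b2).astype(np.int64))
        g.create_dataset("count", data=np.concatenate(cnt))


def read_cooler(path, chrom: str) -> ContactMatrix:
    """Read one chromosome's cis matrix from a cooler-style container."""
    _require_h5py()
    with h5py.File(path, "r") as f:
        bin_size = int(f.attrs["bin-size"])
        names = [n.decode() for n in f["chroms/name"][:]]
        if chrom not in names:
            raise InputError(f"{path}: chromosome {chrom!r} not present")
        cid = names.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        idx = np.flatnonzero(bin_chrom == cid)
        lo, n = idx[0], len(idx)
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
    keep = (b1 >= lo) & (b1 < lo + n) & (b2 >= lo) & (b2 < lo + n)
    counts = np.zeros((n, n))
    i, j = b1[keep] - lo, b2[keep] - lo
    counts[i, j] = cnt[keep]
    counts[j, i] = cnt[keep]
    return ContactMatrix(chrom, bin_size, counts, "raw")
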