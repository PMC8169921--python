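"""Genome coordinate plumbing: chromosome tables, interval frames, binned tracks.

Conventions
-----------
All coordinates are 0-based half-open (BED convention). Interval collections
(repeat annotations, TADs, compartment calls) are plain :class:`pandas.DataFrame`
objects with at least ``chrom``, ``start``, ``end`` columns — the bioframe style —
validated by :func:`validate_intervals`. Per-bin signal lives in
:class:`BinnedTrack`, one float vector per chromosome with NaN marking missing
data (never silently zero-filled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "GenomeTable",
    "BinnedTrack",
    "validate_intervals",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosome names and lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise InputError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise InputError("chromosome names must be unique")
        if any(length <= 0 for length in self.lengths):
            raise InputError("chromosome lengths must be positive")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "lengths", tuple(int(length) for length in self.lengths))

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeTable":
        return cls(tuple(sizes), tuple(sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise InputError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length(chrom) / bin_size)

    def bin_edges(self, chrom: str, bin_size: int) -> np.ndarray:
        """Bin edge coordinates including the (possibly partial) terminal edge."""
        length = self.length(chrom)
        edges = np.arange(0, length + bin_size, bin_size)
        edges[-1] = min(edges[-1], length)
        if edges[-1] < length:  # pragma: no cover - arange already covers length
            edges = np.append(edges, length)
        return edges

    def items(self) -> Iterable[tuple[str, int]]:
        return zip(self.names, self.lengths)


def read_chrom_sizes(path) -> GenomeTable:
    """Read a two-column ``chrom.sizes`` table."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"], comment="#")
    if df.empty:
        raise InputError(f"empty chrom.sizes file: {path}")
    return GenomeTable(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)))


def validate_intervals(
    df: pd.DataFrame,
    genome: GenomeTable | None = None,
    *,
    allow_zero_length: bool = True,
) -> pd.DataFrame:
    """Check 0-based half-open interval invariants; return the frame unchanged."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise InputError(f"interval frame missing column {col!r}")
    if (df["start"] < 0).any():
        raise InputError("negative interval start")
    bad = df["end"] < df["start"] if allow_zero_length else df["end"] <= df["start"]
    if bad.any():
        raise InputError("interval with end before start")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise InputError(f"interval on unknown chromosome {chrom!r}")
            if (sub["end"] > genome.length(chrom)).any():
                raise InputError(f"interval beyond end of {chrom}")
    return df


VALUE_KINDS = ("coverage_fraction", "normalized_density", "log_ratio", "eigenvector")


@dataclass
class BinnedTrack:
    """Fixed-width per-bin scalar signal across a genome.

    ``values`` maps chromosome name to a float vector of ``ceil(length / bin_size)``
    entries. NaN means missing. Terminal partial bins are kept; their coverage
    denominators use the true (shorter) bin width.
    """

    genome: GenomeTable
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    kind: str = "coverage_fraction"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise InputError("bin_size must be positive")
        if self.kind not in VALUE_KINDS:
            raise InputError(f"unknown value kind {self.kind!r}")
        for chrom, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            expected = self.genome.n_bins(chrom, self.bin_size)
            if vec.shape != (expected,):
                raise InputError(
                    f"{chrom}: expected {expected} bins at {self.bin_size} bp, got {vec.shape}"
                )
            self.values[chrom] = vec
        if self.kind == "coverage_fraction":
            for vec in self.values.values():
                with np.errstate(invalid="ignore"):
                    if np.nanmin(vec, initial=0.0) < -1e-9 or np.nanmax(vec, initial=0.0) > 1 + 1e-9:
                        raise InputError("coverage_fraction values outside [0, 1]")

    def compatible_with(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.names == other.genome.names
            and self.genome.lengths == other.genome.lengths
        )

    def flat(self) -> np.ndarray:
        """Concatenate per-chromosome vectors in genome order."""
        return np.concatenate([self.values[c] for c in self.genome.names if c in self.values])

    def with_values(self, values: dict[str, np.ndarray], kind: str | None = None) -> "BinnedTrack":
        return replace(self, values=values, kind=kind or self.kind)
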