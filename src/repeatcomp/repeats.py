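"""Repeat-annotation parsing and binned density tracks.

The central primitive is exact union coverage: overlapping elements of the
queried subfamily are merged before any base is counted, so a bin's value is
(bases of the bin covered by at least one matching element) / (bin width).
Coverage is evaluated through a closed-form prefix function: with merged
intervals ``(s_k, e_k)`` sorted by start, the number of covered bases in
``[0, x)`` is piecewise linear and can be evaluated at arbitrary coordinates
with one ``searchsorted`` — bin values and per-interval contents then follow by
differencing, with no per-bin loops.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, InputError
from .genome import BinnedTrack, GenomeTable, validate_intervals

__all__ = [
    "parse_repeatmasker",
    "select_subfamily",
    "merge_intervals",
    "bin_coverage",
    "track_correlation",
    "interval_repeat_content",
    "shuffle_intervals",
    "tad_content_correlation",
]

ANNOTATION_COLUMNS = ["chrom", "start", "end", "subfamily", "strand"]


def _looks_like_repeatmasker(first_lines: list[str]) -> bool:
    # RepeatMasker .out files open with a "SW score" banner and a blank line.
    head = " ".join(first_lines[:2]).lower()
    return "sw" in head and "score" in head


def parse_repeatmasker(
    path,
    genome: GenomeTable,
    subfamilies: set[str] | None = None,
    *,
    prefix: bool = False,
) -> pd.DataFrame:
    """Parse RepeatMasker ``.out`` or BED3/BED6 into a repeat annotation frame.

    RepeatMasker coordinates (1-based inclusive) are converted to 0-based
    half-open. Records on chromosomes absent from ``genome`` are skipped with
    a warning carrying the skip count; records extending past a chromosome end
    are clipped. ``subfamilies`` filters by exact label, or by label prefix
    when ``prefix=True`` (e.g. ``{"L1"}`` keeps ``L1Md_T``); ``None`` keeps all.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)

    records: list[tuple[str, int, int, str, str]] = []
    skipped = 0
    rm = _looks_like_repeatmasker(lines)
    start_line = 3 if rm else 0
    for lineno, line in enumerate(lines[start_line:], start=start_line + 1):
        fields = line.split()
        if not fields:
            continue
        try:
            if rm:
                # score div del ins query begin end (left) strand name class ...
                chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                name = fields[9]
                start = begin - 1  # 1-based inclusive -> 0-based half-open
            else:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                strand = fields[5] if len(fields) > 5 else "."
            if start < 0 or end < start:
                raise ValueError("bad coordinates")
        except (IndexError, ValueError) as exc:
            raise InputError(f"{path}: malformed line {lineno}: {line.strip()!r}") from exc
        if chrom not in genome:
            skipped += 1
            continue
        end = min(end, genome.length(chrom))
        start = min(start, end)
        records.append((chrom, start, end, name, strand))

    if skipped:
        warnings.warn(f"{path}: skipped {skipped} records on chromosomes absent from genome")
    df = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    if subfamilies is not None:
        df = select_subfamily(df, subfamilies, prefix=prefix)
    return df.reset_index(drop=True)


def select_subfamily(
    annotation: pd.DataFrame, subfamilies: set[str] | str, *, prefix: bool = False
) -> pd.DataFrame:
    """Subset an annotation by exact subfamily labels or by label prefix."""
    if isinstance(subfamilies, str):
        subfamilies = {subfamilies}
    labels = annotation["subfamily"].astype(str)
    if prefix:
        mask = labels.str.startswith(tuple(subfamilies))
    else:
        mask = labels.isin(subfamilies)
    return annotation[mask]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/abutting intervals; returns sorted disjoint intervals."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    emax = np.maximum.accumulate(e)
    # a new merged block starts where an interval begins after every prior end
    new_block = np.ones(len(s), dtype=bool)
    new_block[1:] = s[1:] > emax[:-1]
    idx = np.flatnonzero(new_block)
    merged_s = s[idx]
    merged_e = np.append(emax[idx[1:] - 1], emax[-1])
    return merged_s, merged_e


class _PrefixCoverage:
    """Covered-bases-in-[0, x) evaluator over merged intervals."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.s, self.e = merge_intervals(starts, ends)
        self.cum = np.concatenate([[0], np.cumsum(self.e - self.s)])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.int64)
        idx = np.searchsorted(self.s, x, side="right")
        cov = self.cum[idx].astype(np.int64)
        inside = idx > 0
        if inside.any():
            overhang = np.clip(self.e[idx[inside] - 1] - x[inside], 0, None)
            cov[inside] -= overhang
        return cov


def bin_coverage(
    annotation: pd.DataFrame,
    genome: GenomeTable,
    bin_size: int,
    subfamily: set[str] | str | None = None,
    *,
    prefix: bool = False,
) -> BinnedTrack:
    """Union-coverage fraction of the given subfamily per fixed-width bin.

    An empty annotation yields an all-zero track. Terminal partial bins are
    normalized by their true width.
    """
    if bin_size <= 0:
        raise InputError("bin_size must be positive")
    if subfamily is not None:
        annotation = select_subfamily(annotation, subfamily, prefix=prefix)
    validate_intervals(annotation, genome)
    values: dict[str, np.ndarray] = {}
    grouped = dict(iter(annotation.groupby("chrom", sort=False))) if len(annotation) else {}
    for chrom, _length in genome.items():
        edges = genome.bin_edges(chrom, bin_size)
        widths = np.diff(edges)
        sub = grouped.get(chrom)
        if sub is None or sub.empty:
            values[chrom] = np.zeros(len(widths))
            continue
        cov = _PrefixCoverage(sub["start"].to_numpy(), sub["end"].to_numpy())
        covered = np.diff(cov(edges))
        values[chrom] = covered / widths
    return BinnedTrack(genome, bin_size, values, kind="coverage_fraction")


def track_correlation(a: BinnedTrack, b: BinnedTrack, method: str = "pearson") -> float:
    """Pairwise-complete correlation between two tracks on identical binning."""
    if not a.compatible_with(b):
        raise InputError("tracks have different genomes or bin sizes")
    x, y = a.flat(), b.flat()
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise DegenerateStatisticError("fewer than 3 complete bin pairs")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("constant track; correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise InputError(f"unknown correlation method {method!r}")


def interval_repeat_content(
    annotation: pd.DataFrame,
    intervals: pd.DataFrame,
    subfamily: set[str] | str | None = None,
    *,
    prefix: bool = False,
) -> np.ndarray:
    """Union-coverage fraction of a subfamily within each query interval."""
    validate_intervals(intervals)
    if (intervals["end"] <= intervals["start"]).any():
        raise InputError("zero-length interval in query set")
    if subfamily is not None:
        annotation = select_subfamily(annotation, subfamily, prefix=prefix)
    intervals = intervals.reset_index(drop=True)
    out = np.zeros(len(intervals))
    grouped = dict(iter(annotation.groupby("chrom", sort=False))) if len(annotation) else {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        ann = grouped.get(chrom)
        if ann is None or ann.empty:
            continue
        cov = _PrefixCoverage(ann["start"].to_numpy(), ann["end"].to_numpy())
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        out[sub.index.to_numpy()] = (cov(ends) - cov(starts)) / (ends - starts)
    return out


def shuffle_intervals(intervals: pd.DataFrame, genome: GenomeTable, seed: int) -> pd.DataFrame:
    """Random non-overlapping placement preserving per-chromosome length multisets.

    Lengths are shuffled, then starts are assigned by distributing the free
    space uniformly: draw one offset per interval uniformly in the total slack,
    sort, and lay intervals end to end at those offsets. This samples placements
    without rejection and fails only when the lengths genuinely cannot fit.
    """
    validate_intervals(intervals, genome)
    rng = np.random.default_rng(seed)
    pieces = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        lengths = (sub["end"] - sub["start"]).to_numpy(np.int64)
        total = int(lengths.sum())
        L = genome.length(chrom)
        if total > L:
            raise InputError(f"cannot place {total} bp of intervals on {chrom} ({L} bp)")
        lengths = rng.permutation(lengths)
        slack = L - total
        offsets = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
        starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
        frame = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + lengths}
        )
        pieces.append(frame)
    out = pd.concat(pieces, ignore_index=True) if pieces else intervals.iloc[0:0][["chrom", "start", "end"]]
    return out


def tad_content_correlation(
    annotation: pd.DataFrame,
    tads: pd.DataFrame,
    *,
    l1_label: str = "L1",
    b1_label: str = "B1",
    prefix: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-domain L1 and B1 coverage fractions and their Pearson correlation.

    Mirrors the domain-level anti-correlation analysis: each topological domain
    gets one L1 and one B1 content value and the association is summarized by
    a single Pearson r.
    """
    if len(tads) < 3:
        raise InputError("need at least 3 domains")
    l1 = interval_repeat_content(annotation, tads, l1_label, prefix=prefix)
    b1 = interval_repeat_content(annotation, tads, b1_label, prefix=prefix)
    if np.ptp(l1) == 0 or np.ptp(b1) == 0:
        raise DegenerateStatisticError("constant repeat content across domains")
    r = float(stats.pearsonr(l1, b1).statistic)
    return l1, b1, r
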