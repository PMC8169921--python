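"""Contact-matrix statistics: O/E, correlation, eigenvector, saddle, segregation.

The analysis chain follows the standard compartment workflow: per-chromosome
observed/expected normalization against the mean distance-decay profile, a
Pearson correlation matrix of O/E rows, its leading eigenvector as the
compartment coordinate (sign anchored so that positive values track the
SINE-B1-dense, A-like state), equal-occupancy saddle plots with corner-ratio
compartment strength, and the homotypic/heterotypic segregation index.

The segregation index operates on whatever interaction-frequency matrix it is
given. On a distance-flat matrix it returns exact pooled-pair means; in the
pipeline it is fed the O/E matrix so that distance decay — which places
same-compartment pairs at systematically shorter separations — does not
masquerade as homotypic affinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import compartments_to_bins
from .errors import DegenerateStatisticError, InputError
from .genome import BinnedTrack

__all__ = [
    "ContactMatrix",
    "EigenTrack",
    "SaddleResult",
    "SegregationResult",
    "balance_matrix",
    "expected_by_distance",
    "observed_over_expected",
    "correlation_matrix",
    "compartment_eigenvector",
    "saddle_strength",
    "segregation_index_chrom",
    "segregation_index",
    "trans_segregation_index",
    "conservation_across_samples",
]


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact matrix.

    ``bad_bins`` is a boolean mask of bins excluded from all statistics (e.g.
    unmappable rows); NaN-only rows are folded into it at construction.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    normalization: str = "raw"  # raw | balanced | oe
    bad_bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InputError("contact matrix must be square")
        finite = np.isfinite(self.counts)
        sym_ok = np.allclose(
            np.where(finite, self.counts, 0.0),
            np.where(finite.T, self.counts.T, 0.0),
            rtol=1e-6,
            atol=1e-9,
        )
        if not sym_ok:
            raise InputError("contact matrix is not symmetric")
        n = self.counts.shape[0]
        bad = np.zeros(n, dtype=bool) if self.bad_bins is None else np.asarray(self.bad_bins, bool).copy()
        bad |= ~np.isfinite(self.counts).any(axis=1)
        self.bad_bins = bad

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def good_bins(self) -> np.ndarray:
        return ~self.bad_bins


def balance_matrix(m: ContactMatrix, n_iter: int = 50, tol: float = 1e-5) -> ContactMatrix:
    """Iterative proportional fitting (row/column sum equalization) of a raw matrix."""
    if m.normalization != "raw":
        raise InputError("balance_matrix expects a raw matrix")
    w = m.counts.copy()
    good = m.good_bins
    w[~good, :] = 0.0
    w[:, ~good] = 0.0
    for _ in range(n_iter):
        s = w.sum(axis=1)
        target = s[good].mean()
        if target == 0:
            raise DegenerateStatisticError("all-zero matrix cannot be balanced")
        bias = np.ones_like(s)
        bias[good] = np.sqrt(s[good] / target)
        w = w / np.outer(bias, bias)
        if np.abs(s[good] / target - 1).max() < tol:
            break
    w[~good, :] = np.nan
    w[:, ~good] = np.nan
    return ContactMatrix(m.chrom, m.bin_size, w, "balanced", m.bad_bins.copy())


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean contact over good-bin pairs at each separation (no smoothing)."""
    good = m.good_bins
    if not good.any():
        raise InputError("all bins are bad")
    n = m.n_bins
    expected = np.full(n, np.nan)
    for s in range(n):
        d = np.diagonal(m.counts, offset=s)
        ok = good[: n - s] & good[s:] & np.isfinite(d)
        if ok.any():
            expected[s] = d[ok].mean()
    return expected


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each pixel by the mean contact at its separation; mask bad bins."""
    expected = expected_by_distance(m)
    n = m.n_bins
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp_mat = expected[sep]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = m.counts / exp_mat
    zero_exp = (exp_mat == 0) & np.isfinite(m.counts) & (m.counts > 0)
    if zero_exp.any():
        warnings.warn("zero expected value at a populated separation; pixels masked")
    oe[exp_mat == 0] = np.nan
    oe[m.bad_bins, :] = np.nan
    oe[:, m.bad_bins] = np.nan
    return ContactMatrix(m.chrom, m.bin_size, oe, "oe", m.bad_bins.copy())


def correlation_matrix(oe: ContactMatrix) -> np.ndarray:
    """Pearson correlation of O/E rows over mutually good bins.

    Returns a full n x n matrix with NaN rows/columns at bad or constant bins,
    unit diagonal on good bins, entries clipped to [-1, 1].
    """
    if oe.normalization != "oe":
        raise InputError("correlation_matrix expects an O/E matrix")
    good = np.flatnonzero(oe.good_bins)
    if len(good) < 3:
        raise DegenerateStatisticError("fewer than 3 good bins")
    sub = oe.counts[np.ix_(good, good)]
    # columns finite in every row; with row/col masking already applied this
    # drops only pixels masked by a zero expected separation
    col_ok = np.isfinite(sub).all(axis=0)
    if col_ok.sum() < 3:
        raise DegenerateStatisticError("fewer than 3 complete O/E columns")
    data = sub[:, col_ok]
    sd = data.std(axis=1)
    const = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(data)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    corr = np.clip(corr, -1.0, 1.0)
    full = np.full((oe.n_bins, oe.n_bins), np.nan)
    full[np.ix_(good, good)] = corr
    return full


@dataclass
class EigenTrack:
    """Leading eigenvector of a contact correlation matrix for one chromosome.

    ``orientation`` records the sign anchoring: ``anchored`` (kept),
    ``flipped`` (negated to correlate positively with the anchor track) or
    ``ambiguous`` (zero anchor correlation; sign kept as computed). Positive
    values correspond to the A-like, anchor-dense state.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    orientation: str = "anchored"
    explained_variance: float = float("nan")

    @property
    def good(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_binned_track(self, genome) -> BinnedTrack:
        return BinnedTrack(genome, self.bin_size, {self.chrom: self.values.copy()}, kind="eigenvector")


def compartment_eigenvector(
    corr: np.ndarray,
    anchor: np.ndarray,
    *,
    chrom: str = "",
    bin_size: int = 0,
) -> EigenTrack:
    """Leading eigenvector of the correlation matrix, sign-anchored.

    ``anchor`` is a per-bin track on the same bins (conventionally B1/SINE
    density, so that positive eigenvector values mark the A-like state). The
    explained-variance share is the top eigenvalue over the sum of absolute
    eigenvalues.
    """
    corr = np.asarray(corr, dtype=float)
    good = np.flatnonzero(np.isfinite(corr).any(axis=1))
    if len(good) < 3:
        raise DegenerateStatisticError("fewer than 3 good bins for eigendecomposition")
    sub = corr[np.ix_(good, good)]
    sub = np.where(np.isfinite(sub), sub, 0.0)
    sub = (sub + sub.T) / 2
    eigvals, eigvecs = np.linalg.eigh(sub)
    if not np.all(np.isfinite(eigvals)):
        raise DegenerateStatisticError("eigendecomposition failed")
    if np.ptp(eigvals) == 0:
        raise DegenerateStatisticError("degenerate (flat) eigenvalue spectrum")
    lead = eigvecs[:, -1]
    if np.ptp(lead) < 1e-12:
        raise DegenerateStatisticError(
            "degenerate spectrum: leading eigenvector is constant (no compartment split)"
        )
    share = float(eigvals[-1] / np.abs(eigvals).sum())
    values = np.full(corr.shape[0], np.nan)
    values[good] = lead
    anchor = np.asarray(anchor, dtype=float)
    ok = np.isfinite(values) & np.isfinite(anchor)
    orientation = "ambiguous"
    if ok.sum() >= 3 and np.ptp(values[ok]) > 0 and np.ptp(anchor[ok]) > 0:
        r = stats.pearsonr(values[ok], anchor[ok]).statistic
        if r < 0:
            values = -values
            orientation = "flipped"
        elif r > 0:
            orientation = "anchored"
    return EigenTrack(chrom, bin_size, values, orientation, share)


@dataclass
class SaddleResult:
    """Quantile-ordered mean O/E matrix and the corner-ratio compartment strength."""

    saddle: np.ndarray
    n_quantiles: int
    corner_fraction: float
    strength: float
    corner_means: dict[str, float] = field(default_factory=dict)


def saddle_strength(
    oe: ContactMatrix,
    ev: EigenTrack,
    n_quantiles: int = 50,
    corner_fraction: float = 0.2,
    min_separation_bins: int = 2,
) -> SaddleResult:
    """Saddle plot of cis O/E by eigenvector quantile and compartment strength.

    Bins are ranked by eigenvector value into ``n_quantiles`` equal-occupancy
    groups (ascending: group 0 is most B-like, the last group most A-like).
    Strength = (mean AA corner + mean BB corner) / (mean AB + mean BA), with
    corners the extreme ``corner_fraction`` of quantiles. Pixels closer than
    ``min_separation_bins`` are excluded so diagonal dominance cannot leak in.
    """
    if oe.normalization != "oe":
        raise InputError("saddle_strength expects an O/E matrix")
    if ev.values.shape[0] != oe.n_bins:
        raise InputError("eigenvector and matrix have different bin counts")
    usable = np.flatnonzero(oe.good_bins & np.isfinite(ev.values))
    if len(usable) < n_quantiles:
        n_quantiles = max(2, len(usable) // 2)
        warnings.warn(f"too few good bins; reducing to {n_quantiles} quantiles")
    order = usable[np.argsort(ev.values[usable], kind="stable")]
    gid = np.full(oe.n_bins, -1)
    for q, chunk in enumerate(np.array_split(order, n_quantiles)):
        gid[chunk] = q

    n = oe.n_bins
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = (
        (gid[ii] >= 0)
        & (gid[jj] >= 0)
        & (np.abs(ii - jj) >= min_separation_bins)
        & np.isfinite(oe.counts)
    )
    pq = gid[ii[mask]] * n_quantiles + gid[jj[mask]]
    vals = oe.counts[mask]
    sums = np.bincount(pq, weights=vals, minlength=n_quantiles**2)
    counts = np.bincount(pq, minlength=n_quantiles**2)
    with np.errstate(invalid="ignore"):
        saddle = (sums / counts).reshape(n_quantiles, n_quantiles)

    k = max(1, int(round(n_quantiles * corner_fraction)))
    aa = float(np.nanmean(saddle[-k:, -k:]))
    bb = float(np.nanmean(saddle[:k, :k]))
    ab = float(np.nanmean(saddle[:k, -k:]))
    ba = float(np.nanmean(saddle[-k:, :k]))
    het = ab + ba
    if not np.isfinite(het) or het == 0:
        raise DegenerateStatisticError("empty heterotypic saddle corners")
    strength = (aa + bb) / het
    return SaddleResult(saddle, n_quantiles, corner_fraction, strength, {"AA": aa, "BB": bb, "AB": ab, "BA": ba})


@dataclass
class SegregationResult:
    """Per-chromosome homotypic/heterotypic means and index, plus genome summary."""

    per_chrom: pd.DataFrame  # chrom, homotypic_mean, heterotypic_mean, index
    summary_index: float  # mean over autosomes
    excluded_chroms: tuple[str, ...] = ("chrX", "chrY")


def segregation_index_chrom(
    m: ContactMatrix,
    compartments: pd.DataFrame,
    min_separation_bins: int = 2,
) -> tuple[float, float, float]:
    """(homotypic mean, heterotypic mean, index) for one chromosome.

    Each bin inherits the label of the compartment covering its midpoint;
    unlabeled and bad bins are excluded. Homotypic pools both same-label
    pairings; pairs closer than ``min_separation_bins`` are ignored.
    """
    labels = compartments_to_bins(compartments, m.chrom, m.n_bins, m.bin_size)
    classes = sorted({l for l in labels if l})
    if len(classes) != 2:
        raise DegenerateStatisticError(
            f"{m.chrom}: need exactly two label classes, found {classes}"
        )
    lab_idx = np.full(m.n_bins, -1)
    for k, cls in enumerate(classes):
        lab_idx[labels == cls] = k
    lab_idx[m.bad_bins] = -1
    ii, jj = np.triu_indices(m.n_bins, k=min_separation_bins)
    ok = (lab_idx[ii] >= 0) & (lab_idx[jj] >= 0) & np.isfinite(m.counts[ii, jj])
    ii, jj = ii[ok], jj[ok]
    same = lab_idx[ii] == lab_idx[jj]
    if not same.any() or same.all():
        raise DegenerateStatisticError(f"{m.chrom}: no homotypic or no heterotypic pairs")
    hom = float(m.counts[ii[same], jj[same]].mean())
    het = float(m.counts[ii[~same], jj[~same]].mean())
    if het == 0:
        raise DegenerateStatisticError(f"{m.chrom}: zero heterotypic mean")
    return hom, het, hom / het


def segregation_index(
    matrices: dict[str, ContactMatrix] | list[ContactMatrix],
    compartments: pd.DataFrame,
    min_separation_bins: int = 2,
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY"),
) -> SegregationResult:
    """Per-chromosome segregation indices; the summary averages autosomes only."""
    if isinstance(matrices, dict):
        matrices = list(matrices.values())
    rows = []
    for m in matrices:
        try:
            hom, het, s = segregation_index_chrom(m, compartments, min_separation_bins)
        except DegenerateStatisticError as exc:
            warnings.warn(str(exc))
            continue
        rows.append((m.chrom, hom, het, s))
    per_chrom = pd.DataFrame(rows, columns=["chrom", "homotypic_mean", "heterotypic_mean", "index"])
    if per_chrom.empty:
        raise DegenerateStatisticError("no chromosome yielded a segregation index")
    auto = per_chrom[~per_chrom["chrom"].isin(exclude_chroms)]
    if auto.empty:
        raise DegenerateStatisticError("no autosomes left after exclusion")
    return SegregationResult(per_chrom, float(auto["index"].mean()), exclude_chroms)


def trans_segregation_index(
    counts: np.ndarray,
    labels_rows: np.ndarray,
    labels_cols: np.ndarray,
) -> tuple[float, float, float]:
    """Homotypic/heterotypic means over an inter-chromosomal block.

    ``labels_*`` are per-bin string labels ('' = unlabeled). No distance
    normalization applies in trans.
    """
    counts = np.asarray(counts, dtype=float)
    lr = np.asarray(labels_rows, dtype=object)
    lc = np.asarray(labels_cols, dtype=object)
    ok = (lr[:, None] != "") & (lc[None, :] != "") & np.isfinite(counts)
    same = (lr[:, None] == lc[None, :]) & ok
    diff = (~(lr[:, None] == lc[None, :])) & ok
    if not same.any() or not diff.any():
        raise DegenerateStatisticError("missing homotypic or heterotypic trans pairs")
    hom = float(counts[same].mean())
    het = float(counts[diff].mean())
    if het == 0:
        raise DegenerateStatisticError("zero heterotypic trans mean")
    return hom, het, hom / het


@dataclass
class ConservationResult:
    """Cross-sample compartment-label consistency with a permutation null."""

    consistent_fraction: float
    invariant_fraction: float
    null_consistent_fraction: float
    null_invariant_fraction: float
    k: int
    n_samples: int
    n_bins: int
    n_permutations: int
    seed: int


def conservation_across_samples(
    tracks: list[np.ndarray],
    k: int,
    n_permutations: int = 100,
    seed: int = 0,
) -> ConservationResult:
    """Fraction of bins with a modal A/B label in >= k samples and in all samples.

    Each track is a per-bin signed compartment coordinate; its sign gives the
    label. Bins missing (NaN or zero) in any sample are excluded throughout.
    The null permutes each sample's labels independently across bins,
    preserving per-sample A/B marginals, and reports mean null fractions.
    """
    if len(tracks) < 2:
        raise InputError("need at least 2 samples")
    arrays = [np.asarray(t, dtype=float).ravel() for t in tracks]
    if len({a.shape for a in arrays}) != 1:
        raise InputError("samples have mismatched binning")
    arr = np.vstack(arrays)
    labels = np.sign(arr)
    ok = np.isfinite(arr).all(axis=0) & (labels != 0).all(axis=0)
    labels = labels[:, ok]
    n_samples, n_bins = labels.shape
    if n_bins == 0:
        raise DegenerateStatisticError("no bins present in every sample")
    if not (1 <= k <= n_samples):
        raise InputError("k must be between 1 and the number of samples")

    def fractions(lab: np.ndarray) -> tuple[float, float]:
        pos = (lab > 0).sum(axis=0)
        modal = np.maximum(pos, n_samples - pos)
        return float((modal >= k).mean()), float((modal == n_samples).mean())

    cons, inv = fractions(labels)
    rng = np.random.default_rng(seed)
    null_c = np.empty(n_permutations)
    null_i = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = np.vstack([row[rng.permutation(n_bins)] for row in labels])
        null_c[p], null_i[p] = fractions(perm)
    return ConservationResult(
        cons, inv, float(null_c.mean()), float(null_i.mean()), k, n_samples, n_bins, n_permutations, seed
    )
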