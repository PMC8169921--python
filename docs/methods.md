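# Methods

`repeatcomp` implements a repeat-sequence view of chromatin A/B
compartmentalization: the genome's two dominant retrotransposon subclasses —
LINE-1 (L1, ~6–7 kb, AT-rich, heterochromatin-associated) and SINE B1/Alu
(~150–300 bp, GC-rich, euchromatin-associated) — occupy largely mutually
exclusive megabase-scale domains, and the local balance of their densities
predicts the A/B compartments seen in Hi-C. The package provides the
statistics needed to state and test that claim quantitatively, together with
planted-truth generators so the whole chain is verifiable without any
external data.

## Coordinates and containers

All intervals are 0-based half-open (BED convention); RepeatMasker `.out`
input (1-based inclusive) is converted on read. Binned signal is a
`BinnedTrack`: one float vector per chromosome, NaN for missing bins —
missing data propagates and is never silently zero-filled. Terminal partial
bins are kept, with coverage normalized by their true width, so small test
genomes carry no edge bias.

## Repeat density

A bin's density is the union coverage fraction of the queried subfamily:
overlapping elements are merged before counting, so nested or fragmented
annotations cannot exceed 1.0. Coverage is length-weighted (a truncated L1
fragment contributes its actual bases), matching a density-based reading of
the annotation; a copy-number mode was considered and deliberately not
implemented. Subfamily selection is by exact label or by label prefix
("L1" selects every L1 subfamily label), because the analysis operates on
whole subclass aggregates. Strand is ignored — density does not depend on it.
The 10-kb bin is the default for descriptive repeat tracks; compartment
calling uses 100-kb bins.

## De novo compartment calling

Per 100-kb bin, each density is normalized to its genome background
(defaults: 19% L1, 3% B1 — the genome-wide fractions in mouse) and the
statistic is

    r = log2( ((d_B1 + ε)/f_B1) / ((d_L1 + ε)/f_L1) )

with pseudocount ε = 1e-4 coverage units. ε is smaller than one ~10-bp
element per 100-kb bin: it keeps empty bins finite but cannot flip the sign
of any populated bin. Maximal runs of same-sign bins become compartments
(r > 0 → B1-rich / A-like; r < 0 → L1-rich / B-like); runs with genomic
length ≤ 500 kb are discarded. Two deliberate choices: bins with r exactly 0
or missing belong to neither sign and break runs (the sign rule is strict,
and zero is measure-zero on real data); and discarded short runs leave gaps —
flanking same-sign regions are never merged across them, since the filter is
a filter, not a smoother, and merging would inflate compartment sizes.

Overlap scoring assigns each predicted compartment the reference label
covering the majority (> 50%) of its length; exact ties or majority-uncovered
predictions are "unassigned". The majority rule is the package's own
definition of "overlaps" — the coarser alternative (any overlap) would score
near 100% trivially. The four concordance classes (B1.A, B1.B, L1.A, L1.B)
are exported for downstream feature comparison of discordant regions.

## Hi-C statistics

Statistics are cis and per-chromosome unless stated otherwise. The chain is
the standard one: expected contact per separation (plain mean over good-bin
pairs, no smoothing), observed/expected (O/E), Pearson correlation of O/E
rows, and the leading eigenvector of the correlation matrix as the
compartment coordinate. The eigenvector's global sign is arbitrary, so it is
anchored: the sign is chosen to correlate positively with a B1-density track
(positive = A-like). B1 density is used rather than GC or gene density for
internal consistency — the package's central claim is exactly that B1
density tracks the A state — and the anchor is a parameter. The
explained-variance share reported is the top eigenvalue over the sum of
absolute eigenvalues. A constant leading eigenvector (e.g. from a constant
matrix) is a degenerate-statistic error, not a silent answer.

Saddle plots rank bins by eigenvector value into equal-occupancy quantiles
(default 50) and average O/E per quantile pair, excluding pairs closer than
2 bins so diagonal dominance cannot leak into compartment signal. Strength
is (mean AA corner + mean BB corner) / (mean AB + mean BA) over the extreme
20% of quantiles.

The segregation index is the mean interaction frequency between same-labeled
bins (both homotypic pairings pooled) divided by the mean between
differently-labeled bins, at separation ≥ 2 bins; per chromosome, with the
genome summary averaging autosomes only (chrX/chrY excluded by default,
configurable). The function computes means of whatever matrix it is given.
On a distance-flat toy matrix that is the literal pooled-pair ratio; the
pipeline feeds it the O/E matrix, because with raw counts the index is
confounded by distance decay — same-compartment pairs sit at systematically
shorter separations, which alone roughly doubles the "homotypic" mean on
realistic block structures even with no affinity at all. Distance
normalization makes the index 1.0 under the null, which is the property a
segregation measure must have. A raw-counts mode remains available
(`--raw` in the CLI) for comparison, and a trans variant computes the same
ratio over inter-chromosomal pixels without distance normalization.

Known estimator property: even on O/E, the index carries a small negative
finite-size bias relative to the generating affinity ratio, because
homotypic pairs concentrate at separations where the mean affinity (hence
the expected value used for normalization) is higher. On single ~20-Mb
chromosomes with ~1.5-Mb blocks the bias is ~5–10%; at 40 Mb it is ~3%. The
regression suite therefore exercises the closure at the generators' default
chromosome scale.

Matrix balancing (iterative row/column equalization, 50 iterations,
tolerance 1e-5) is provided for raw input; externally normalized matrices
are accepted as-is.

Cross-sample conservation: each sample's compartment track contributes a
per-bin sign label; a bin is "consistent in ≥ k samples" if its modal label
occurs in at least k of them, and "invariant" if in all. Bins missing in any
sample are excluded. The chance baseline is a permutation null — each
sample's labels permuted independently across bins, preserving that sample's
A/B marginal (100 permutations by default). For fair labels this null has a
binomial closed form (2·P(X ≥ k), X ~ Bin(n, ½)), which the test suite uses
as the independent oracle.

## FISH segregation index

The imaging index is the negative Pearson correlation of the L1 and B1
channel intensities over nuclear pixels: +1 fully segregated, −1 fully
co-localized. Correlation is computed on raw intensities within the mask —
the definition is on signals, not corrected signals — with rolling-ball
background subtraction available as an option. 3-D stacks are pooled over
all masked voxels (one number per nucleus, rather than per-slice averages).
When no mask is supplied, one is derived from the DNA channel by Otsu
thresholding, hole filling, and largest-connected-component selection;
DAPI-dense chromocenters are not excluded. The index is invariant to
positive affine rescaling of either channel (a property of Pearson r), so
detector gain and offset do not matter.

## Synthetic data

The generators emulate exactly the structure the estimators assume, with
defaults chosen as the study conditions:

* **Repeat genome** — 5 chromosomes × 40 Mb, tiled by alternating L1/B1
  blocks with log-normal lengths (median 1.5 Mb, σ = 0.5 in log-space, a
  realistic megabase-scale spread). Element coverages: L1 0.30 in L1 blocks
  / 0.05 in B1 blocks; B1 0.08 / 0.01 — contrasts consistent with the
  genome-background fractions while guaranteeing signed log-ratio contrast.
  Element lengths are uniform on 6–7 kb (L1) and 150–300 bp (B1). Placement
  within a block is uniform without same-family overlap, via the exact
  gap-allocation construction; coverage targets are met to within one
  element length (< 0.01 absolute on blocks ≥ 1 Mb).
* **Contact matrices** — E[C_ij] = depth · (bp separation)^(−α) · A(ℓ_i, ℓ_j),
  Poisson-sampled and symmetrized. Defaults: α = 1 (generic interphase-like
  decay), homotypic affinity 1.5, heterotypic 0.67, gap bins neutral at 1,
  depth 1e7 (≈ 10 counts per 100-kb pixel at 1 Mb separation). Poisson
  rather than negative-binomial noise: the simplest model sufficient to
  exercise the estimators; over-dispersion is not claimed to match any real
  library. A mitotic mode sets all affinities to 1 and multiplies
  separations < 1 Mb by a boost factor (default 5), reproducing the
  diagonal-dominant, compartment-free look of metaphase maps.
* **Nuclear images** — segregated mode places L1 as a rim annulus plus an
  inner (nucleolar-shell) ring and B1 as interior puncta plus a diffuse
  component filling the L1-free interior; mixed mode draws both channels
  from one smooth Gaussian random field. Poisson–Gaussian noise at the
  stated SNR; the DNA channel is a filled disk.

What the generators do *not* emulate — and therefore what passing tests do
not show about real data: real repeat genomes have continuous density
gradients rather than two-level blocks, Hi-C has over-dispersion, mappability
structure and trans contacts, and microscopy has PSF blur, chromatic shift
and autofluorescence. The closure results demonstrate estimator correctness
under the stated model, not biological effect sizes; headline numbers from
real mouse data (overlap percentages, compartment counts, strengths) require
the real annotation and deposited matrices and are deliberately not asserted
anywhere in this repository.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; pipeline seeds are spawned
per stage from one top-level seed via `SeedSequence` and logged in the JSON
report. Test and acceptance problem sizes (5 × 40 Mb genomes, single 40-Mb
chromosomes at 100-kb bins, 10⁴-bin conservation panels, 256-px nuclei) were
chosen as the smallest scales at which the estimators' finite-size biases
are comfortably inside the stated tolerances.
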