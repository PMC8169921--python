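# repeatcomp

Repeat-density chromatin compartment calling and Hi-C/FISH segregation
statistics.

## The problem

Interphase genomes partition into megabase-scale A (euchromatic) and B
(heterochromatic) compartments, classically identified from Hi-C contact
maps. The two most abundant retrotransposon subclasses occupy largely
mutually exclusive territory along the linear genome: LINE-1 (L1; ~6–7 kb,
AT-rich) accumulates in B-compartment, heterochromatic regions, while SINE
B1 (mouse) / Alu (human; ~150–300 bp, GC-rich) accumulates in
A-compartment, euchromatic regions. `repeatcomp` is a tested, reusable
implementation of the computational analysis built on that observation, for
genomicists who want to call compartments from sequence alone, quantify
homotypic repeat clustering in Hi-C, or score L1/B1 spatial segregation in
microscopy — plus planted-truth simulators so every statistic can be
validated end to end without any external download.

## What it computes

* **De novo compartment calling from repeat density.** Per 100-kb bin,
  with d the coverage density, background fractions f_B1 = 0.03,
  f_L1 = 0.19 and pseudocount ε:

  r = log2[ ((d_B1 + ε)/f_B1) / ((d_L1 + ε)/f_L1) ]

  Maximal same-sign runs of r longer than 500 kb become B1-rich (r > 0,
  A-like) or L1-rich (r < 0, B-like) compartments. Calls are scored against
  reference A/B annotations by majority overlap.
* **Hi-C compartment statistics.** Observed/expected normalization, Pearson
  correlation matrix, leading-eigenvector compartment coordinate (sign
  anchored to B1 density), saddle plots with compartment strength
  CS = (AA + BB)/(AB + BA) from the corner means, and the segregation index
  S = mean homotypic / mean heterotypic interaction frequency, per
  chromosome with an autosome-only summary.
* **Cross-sample conservation** of compartment labels against a
  marginal-preserving permutation null.
* **FISH segregation index** for two-channel nuclear images:
  S_FISH = −Pearson(I_L1, I_B1) over nuclear pixels, with Otsu-based
  nuclear segmentation when no mask is given.
* **Synthetic data**: alternating-block repeat genomes, Poisson plaid
  contact matrices with tunable homotypic affinity (and a mitotic mode),
  and segregated/mixed synthetic nuclei.

See `docs/methods.md` for definitions, parameter defaults, and the design
rationale behind each statistic.

## Worked example

Run the whole pipeline on simulated defaults (5 chromosomes × 40 Mb,
planted compartment truth, Poisson plaid Hi-C):

```sh
repeatcomp run --simulate --seed 7 --out runs/demo
```

Output (abridged `report.json`):

```json
{
  "n_called_compartments": 114,
  "called_label_counts": {"B1-rich": 55, "L1-rich": 59},
  "median_compartment_size_bp": 1500000.0,
  "overlap_consistent_fraction": {"B1-rich": 1.0, "L1-rich": 1.0},
  "compartment_strength_mean": 2.5269255674378734,
  "segregation_index_mean": 2.143015159241652,
  "seed": 7
}
```

Reading the numbers: the caller recovered 114 compartments with median size
1.5 Mb (the generator's block-length median), every one of which lands in a
planted compartment of the matching class (`overlap_consistent_fraction`
1.0 for both labels). Compartment strength 2.53 > 1 and segregation index
2.14 > 1 both detect the planted homotypic affinity; the generator's
affinity ratio is a_hom/a_het = 1.5/0.67 ≈ 2.24, and the segregation index
lands close to it (small finite-size bias is expected; see
`docs/methods.md`).

The same steps are available piecemeal — `repeatcomp simulate`,
`call-compartments`, `score-overlap`, `hic-ev`, `saddle`, `seg-index`,
`conservation`, `fish-index` — and everything is importable as a library:

```python
import repeatcomp as rc

annotation, truth, genome = rc.simulate_repeat_genome(rc.SyntheticGenomeSpec(), seed=0)
b1 = rc.bin_coverage(annotation, genome, 100_000, "B1", prefix=True)
l1 = rc.bin_coverage(annotation, genome, 100_000, "L1", prefix=True)
called = rc.call_repeat_compartments(rc.log_ratio_track(b1, l1))
```

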