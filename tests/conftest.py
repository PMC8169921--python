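import numpy as np
import pandas as pd
import pytest

import repeatcomp as rc


@pytest.fixture
def toy_genome():
    return rc.GenomeTable(("chr1", "chr2"), (1_000_000, 600_000))


@pytest.fixture
def small_synthetic():
    """One 20-Mb chromosome with planted compartments; session-stable seed."""
    spec = rc.SyntheticGenomeSpec(n_chroms=1, chrom_length=20_000_000)
    annotation, truth, genome = rc.simulate_repeat_genome(spec, seed=101)
    return spec, annotation, truth, genome


def make_annotation(rows):
    """rows: (chrom, start, end, subfamily[, strand])"""
    out = []
    for r in rows:
        r = tuple(r)
        out.append(r if len(r) == 5 else r + ("+",))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "subfamily", "strand"])


def make_compartments(rows):
    """rows: (chrom, start, end, label[, score])"""
    out = []
    for r in rows:
        r = tuple(r)
        out.append(r if len(r) == 5 else r + (np.nan,))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "label", "score"])
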