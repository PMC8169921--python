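"""O/E, correlation, eigenvector, saddle, segregation, conservation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import repeatcomp as rc
from repeatcomp.compartments import compartments_to_bins

from conftest import make_compartments

BIN = 100_000


def block_labels(n_blocks=10, block=20):
    return np.repeat(np.resize([1, -1], n_blocks), block)


def labels_to_compartments(labels, bin_size=BIN, chrom="chr1"):
    rows = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            rows.append(
                (chrom, start * bin_size, i * bin_size,
                 "B1-rich" if labels[start] > 0 else "L1-rich")
            )
            start = i
    return make_compartments(rows)


class TestExpectedByDistance:
    def test_distance_function_identity(self):
        n = 50
        f = 10.0 / (1 + np.abs(np.subtract.outer(np.arange(n), np.arange(n))))
        m = rc.ContactMatrix("chr1", BIN, f)
        np.testing.assert_allclose(rc.expected_by_distance(m), f[0])

    def test_constant_matrix(self):
        m = rc.ContactMatrix("chr1", BIN, np.full((20, 20), 3.0))
        np.testing.assert_allclose(rc.expected_by_distance(m), 3.0)

    def test_poisson_sampled_decay_within_3_se(self):
        rng = np.random.default_rng(0)
        n = 300
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        mean = 50.0 / (1 + sep)
        counts = np.triu(rng.poisson(mean))
        counts = counts + np.triu(counts, 1).T
        m = rc.ContactMatrix("chr1", BIN, counts.astype(float))
        exp = rc.expected_by_distance(m)
        for s in (1, 5, 20, 100):
            n_pairs = n - s
            se = np.sqrt(mean[0, s] / n_pairs)
            assert abs(exp[s] - mean[0, s]) < 3 * se

    def test_all_bad_bins_errors(self):
        m = rc.ContactMatrix("chr1", BIN, np.ones((5, 5)), bad_bins=np.ones(5, bool))
        with pytest.raises(rc.InputError):
            rc.expected_by_distance(m)


class TestObservedOverExpected:
    def test_self_profile_gives_ones(self):
        n = 40
        f = 5.0 / (1 + np.abs(np.subtract.outer(np.arange(n), np.arange(n))))
        oe = rc.observed_over_expected(rc.ContactMatrix("chr1", BIN, f))
        np.testing.assert_allclose(oe.counts, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(10, (30, 30)).astype(float)
        c = (c + c.T) / 2
        a = rc.observed_over_expected(rc.ContactMatrix("chr1", BIN, c))
        b = rc.observed_over_expected(rc.ContactMatrix("chr1", BIN, 2 * c))
        np.testing.assert_allclose(a.counts, b.counts)

    def test_planted_affinity_ratio_recovered(self):
        """Mean O/E over homotypic vs heterotypic bin pairs matches the planted
        affinity ratio on an aperiodic planted-block genome at default scale."""
        _, truth, genome = rc.simulate_repeat_genome(
            rc.SyntheticGenomeSpec(n_chroms=1, chrom_length=40_000_000), 101
        )
        spec = rc.SyntheticHiCSpec(a_hom=1.5, a_het=0.67)
        m = rc.simulate_contact_matrix(truth, genome, "chr1", spec, seed=2)
        oe = rc.observed_over_expected(m)
        lab = compartments_to_bins(truth, "chr1", m.n_bins, m.bin_size)
        same = np.equal.outer(lab, lab)
        sep_ok = np.abs(np.subtract.outer(np.arange(m.n_bins), np.arange(m.n_bins))) >= 2
        hom = np.nanmean(oe.counts[same & sep_ok])
        het = np.nanmean(oe.counts[~same & sep_ok])
        assert hom / het == pytest.approx(1.5 / 0.67, rel=0.10)


class TestCorrelationMatrix:
    def test_checkerboard_two_block_signs(self):
        """Within-block correlations positive, cross-block negative, on an 8x8 toy."""
        lab = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        oe_vals = np.where(np.equal.outer(lab, lab), 2.0, 0.5)
        rng = np.random.default_rng(3)
        oe_vals = oe_vals * (1 + 0.01 * rng.normal(size=(8, 8)))
        oe_vals = (oe_vals + oe_vals.T) / 2
        corr = rc.correlation_matrix(rc.ContactMatrix("chr1", BIN, oe_vals, "oe"))
        same = np.equal.outer(lab, lab)
        off = ~np.eye(8, dtype=bool)
        assert (corr[same & off] > 0).all()
        assert (corr[~same] < 0).all()

    def test_diagonal_one_and_symmetry(self):
        rng = np.random.default_rng(4)
        c = rng.poisson(20, (30, 30)).astype(float)
        c = (c + c.T) / 2
        corr = rc.correlation_matrix(rc.observed_over_expected(rc.ContactMatrix("chr1", BIN, c)))
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)
        assert np.nanmax(np.abs(corr)) <= 1.0


class TestCompartmentEigenvector:
    def test_exact_two_block_recovery(self):
        """Closed-form: on a +/-1 two-block correlation matrix the leading
        eigenvector is constant within blocks with opposite signs."""
        lab = np.array([1] * 6 + [-1] * 6, dtype=float)
        corr = np.outer(lab, lab)  # rank one: eigenvector proportional to lab
        ev = rc.compartment_eigenvector(corr, anchor=lab)
        assert (np.sign(ev.values) == lab).all()
        assert ev.explained_variance == pytest.approx(1.0)

    def test_negating_anchor_flips_signs(self):
        lab = np.array([1] * 6 + [-1] * 6, dtype=float)
        corr = np.outer(lab, lab)
        a = rc.compartment_eigenvector(corr, anchor=lab)
        b = rc.compartment_eigenvector(corr, anchor=-lab)
        np.testing.assert_allclose(a.values, -b.values)

    def test_constant_matrix_errors(self):
        with pytest.raises(rc.DegenerateStatisticError):
            rc.compartment_eigenvector(np.ones((6, 6)), anchor=np.arange(6.0))

    def test_noiseless_plaid_full_recovery(self):
        """Deterministic plaid expectation: eigenvector labels all bins correctly."""
        labels = block_labels()
        truth = labels_to_compartments(labels)
        genome = rc.GenomeTable(("chr1",), (200 * BIN,))
        m = rc.simulate_contact_matrix(truth, genome, "chr1", rc.SyntheticHiCSpec(), 0, poisson=False)
        corr = rc.correlation_matrix(rc.observed_over_expected(m))
        ev = rc.compartment_eigenvector(corr, anchor=labels.astype(float))
        assert (np.sign(ev.values) == labels).mean() == 1.0

    def test_poisson_depth_recovery_at_least_90pct(self):
        labels = block_labels()
        truth = labels_to_compartments(labels)
        genome = rc.GenomeTable(("chr1",), (200 * BIN,))
        m = rc.simulate_contact_matrix(truth, genome, "chr1", rc.SyntheticHiCSpec(depth=1e7), 5)
        corr = rc.correlation_matrix(rc.observed_over_expected(m))
        ev = rc.compartment_eigenvector(corr, anchor=labels.astype(float))
        assert (np.sign(ev.values) == labels).mean() >= 0.90


class TestSaddleStrength:
    def test_uniform_oe_strength_one(self):
        oe = rc.ContactMatrix("chr1", BIN, np.ones((100, 100)), "oe")
        ev = rc.EigenTrack("chr1", BIN, np.linspace(-1, 1, 100))
        assert rc.saddle_strength(oe, ev, n_quantiles=10).strength == pytest.approx(1.0)

    def test_planted_corner_ratio(self):
        """Homotypic 2.0 / heterotypic 0.5 gives strength 4.0 on a 200-bin toy."""
        lab = block_labels()
        oe_vals = np.where(np.equal.outer(lab, lab), 2.0, 0.5)
        oe = rc.ContactMatrix("chr1", BIN, oe_vals, "oe")
        ev = rc.EigenTrack("chr1", BIN, lab.astype(float))
        res = rc.saddle_strength(oe, ev)
        assert res.strength == pytest.approx(4.0, rel=0.05)

    def test_scale_invariance(self):
        lab = block_labels()
        oe_vals = np.where(np.equal.outer(lab, lab), 2.0, 0.5)
        ev = rc.EigenTrack("chr1", BIN, lab.astype(float))
        s1 = rc.saddle_strength(rc.ContactMatrix("chr1", BIN, oe_vals, "oe"), ev).strength
        s2 = rc.saddle_strength(rc.ContactMatrix("chr1", BIN, 7.3 * oe_vals, "oe"), ev).strength
        assert s1 == pytest.approx(s2)

    def test_too_few_bins_reduces_quantiles(self):
        oe = rc.ContactMatrix("chr1", BIN, np.ones((20, 20)), "oe")
        ev = rc.EigenTrack("chr1", BIN, np.linspace(-1, 1, 20))
        with pytest.warns(UserWarning, match="quantiles"):
            res = rc.saddle_strength(oe, ev, n_quantiles=50)
        assert res.n_quantiles <= 10


class TestSegregationIndex:
    def test_uniform_matrix_gives_one(self):
        comp = labels_to_compartments(block_labels(4, 3), bin_size=BIN)
        m = rc.ContactMatrix("chr1", BIN, np.full((12, 12), 2.5))
        hom, het, s = rc.segregation_index_chrom(m, comp)
        assert s == pytest.approx(1.0)

    def test_block_matrix_brute_force(self):
        """Same-label pairs 2.0, cross-label 1.0 on 12 bins -> index 2.0,
        verified against explicit pair enumeration."""
        lab = block_labels(4, 3)
        comp = labels_to_compartments(lab, bin_size=BIN)
        vals = np.where(np.equal.outer(lab, lab), 2.0, 1.0)
        m = rc.ContactMatrix("chr1", BIN, vals)
        hom, het, s = rc.segregation_index_chrom(m, comp)
        # brute force over pairs
        hs, ts = [], []
        for i in range(12):
            for j in range(i + 2, 12):
                (hs if lab[i] == lab[j] else ts).append(vals[i, j])
        assert hom == pytest.approx(np.mean(hs))
        assert het == pytest.approx(np.mean(ts))
        assert s == pytest.approx(2.0)

    def test_label_swap_invariance(self):
        lab = block_labels(4, 3)
        comp = labels_to_compartments(lab, bin_size=BIN)
        swapped = comp.copy()
        swapped["label"] = swapped["label"].map({"B1-rich": "L1-rich", "L1-rich": "B1-rich"})
        rng = np.random.default_rng(6)
        vals = rng.poisson(5, (12, 12)).astype(float)
        vals = (vals + vals.T) / 2
        m = rc.ContactMatrix("chr1", BIN, vals)
        assert rc.segregation_index_chrom(m, comp)[2] == pytest.approx(
            rc.segregation_index_chrom(m, swapped)[2]
        )

    def test_single_class_chromosome_skipped(self):
        comp = make_compartments([("chr1", 0, 600_000, "B1-rich"),
                                  ("chr2", 0, 300_000, "B1-rich"),
                                  ("chr2", 300_000, 600_000, "L1-rich")])
        m1 = rc.ContactMatrix("chr1", BIN, np.ones((6, 6)))
        m2 = rc.ContactMatrix("chr2", BIN, np.ones((6, 6)))
        with pytest.warns(UserWarning, match="chr1"):
            res = rc.segregation_index([m1, m2], comp, exclude_chroms=())
        assert res.per_chrom["chrom"].tolist() == ["chr2"]

    def test_sex_chromosomes_excluded_from_summary(self):
        lab = block_labels(4, 3)
        comp = pd.concat(
            [labels_to_compartments(lab, chrom=c) for c in ("chr1", "chrX")],
            ignore_index=True,
        )
        strong = np.where(np.equal.outer(lab, lab), 3.0, 1.0)
        weak = np.where(np.equal.outer(lab, lab), 1.5, 1.0)
        ms = [rc.ContactMatrix("chr1", BIN, strong), rc.ContactMatrix("chrX", BIN, weak)]
        res = rc.segregation_index(ms, comp)
        assert res.summary_index == pytest.approx(res.per_chrom.set_index("chrom")["index"]["chr1"])

    def test_trans_block_means(self):
        rows = np.array(["B1-rich"] * 3 + ["L1-rich"] * 3, dtype=object)
        cols = np.array(["B1-rich", "L1-rich"] * 3, dtype=object)
        counts = np.where(np.equal.outer(rows, cols), 4.0, 2.0)
        from repeatcomp.hic import trans_segregation_index

        hom, het, s = trans_segregation_index(counts, rows, cols)
        assert (hom, het, s) == (4.0, 2.0, 2.0)


class TestBalancing:
    def test_row_sums_equalized(self):
        rng = np.random.default_rng(7)
        bias = rng.uniform(0.5, 2.0, 40)
        sep = np.abs(np.subtract.outer(np.arange(40), np.arange(40)))
        clean = 10.0 / (1 + sep)
        raw = clean * np.outer(bias, bias)
        m = rc.ContactMatrix("chr1", BIN, raw)
        bal = rc.balance_matrix(m)
        sums = np.nansum(bal.counts, axis=1)
        assert np.std(sums) / np.mean(sums) < 1e-3
        assert bal.normalization == "balanced"


class TestConservation:
    def test_identical_samples_fully_conserved(self):
        rng = np.random.default_rng(8)
        track = np.where(rng.random(500) < 0.5, 1.0, -1.0)
        res = rc.conservation_across_samples([track] * 5, k=4, n_permutations=10, seed=0)
        assert res.consistent_fraction == 1.0
        assert res.invariant_fraction == 1.0

    def test_fair_labels_match_binomial_tail(self):
        """21 independent fair-label samples: consistent-in->=16 fraction matches
        2*P(X>=16), X~Bin(21,1/2) ~= 0.0266, and invariant-in-all ~= 9.54e-7."""
        rng = np.random.default_rng(9)
        n_bins = 10_000
        tracks = [np.where(rng.random(n_bins) < 0.5, 1.0, -1.0) for _ in range(21)]
        res = rc.conservation_across_samples(tracks, k=16, n_permutations=100, seed=1)
        expected_consistent = 2 * stats.binom.sf(15, 21, 0.5)
        assert expected_consistent == pytest.approx(0.02660, abs=2e-4)
        se = np.sqrt(expected_consistent / n_bins)
        assert abs(res.consistent_fraction - expected_consistent) < 4 * se
        assert abs(res.null_consistent_fraction - expected_consistent) < 4 * se / np.sqrt(100)
        assert 2.0 ** -20 == pytest.approx(9.54e-7, rel=1e-3)
        assert res.invariant_fraction <= 2 / n_bins  # ~0 observed at this size
        assert res.null_invariant_fraction <= 2 / n_bins

    def test_mismatched_binning_errors(self):
        with pytest.raises(rc.InputError):
            rc.conservation_across_samples([np.ones(10), np.ones(11)], k=2)


class TestJointPermutationInvariance:
    def test_segregation_invariant_under_joint_bin_relabeling(self):
        rng = np.random.default_rng(10)
        lab = block_labels(4, 5)
        vals = np.where(np.equal.outer(lab, lab), 2.0, 1.0) * rng.uniform(0.9, 1.1, (20, 20))
        vals = (vals + vals.T) / 2
        comp = labels_to_compartments(lab)
        m = rc.ContactMatrix("chr1", BIN, vals)
        s0 = rc.segregation_index_chrom(m, comp, min_separation_bins=0)[2]
        perm = rng.permutation(20)
        comp_perm = labels_to_compartments(lab[perm])
        m_perm = rc.ContactMatrix("chr1", BIN, vals[np.ix_(perm, perm)])
        s1 = rc.segregation_index_chrom(m_perm, comp_perm, min_separation_bins=0)[2]
        assert s0 == pytest.approx(s1)
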