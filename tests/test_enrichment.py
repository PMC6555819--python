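import numpy as np
import pandas as pd
import pytest

from nrpbm.enrichment import (
    active_peak_filter,
    build_negatives,
    reciprocal_overlap,
    roc_auc,
    score_region,
    subtract_regions,
    read_bed,
    write_bed,
)
from nrpbm.motifs import PFM, HT29_BACKGROUND, pwm_from_pfm
from nrpbm.sequences import revcomp
from nrpbm.synthetic import random_dna


def regions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def random_regions(rng, n, chroms=("chr1", "chr2"), span=10_000):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, 400, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts,
        "end": starts + lengths,
    })


def overlap_oracle(a, b, frac):
    keep = []
    for i, ra in a.iterrows():
        for _, rb in b.iterrows():
            if ra.chrom != rb.chrom:
                continue
            ov = min(ra.end, rb.end) - max(ra.start, rb.start)
            if ov >= frac * (ra.end - ra.start) and ov >= frac * (rb.end - rb.start):
                keep.append(i)
                break
    return a.loc[keep].reset_index(drop=True)


class TestReciprocalOverlap:
    def test_identical_sets_fully_retained(self):
        a = regions([("chr1", 0, 100), ("chr2", 50, 80)])
        assert len(reciprocal_overlap(a, a)) == 2

    def test_boundary_half_overlap_counts(self):
        a = regions([("chr1", 0, 100)])
        b = regions([("chr1", 50, 150)])
        assert len(reciprocal_overlap(a, b, frac=0.5)) == 1

    def test_disjoint_sets_empty(self):
        a = regions([("chr1", 0, 100)])
        b = regions([("chr1", 200, 300)])
        assert reciprocal_overlap(a, b).empty

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            a = random_regions(rng, 150)
            b = random_regions(rng, 200)
            frac = float(rng.uniform(0.2, 0.9))
            ours = reciprocal_overlap(a, b, frac)
            oracle = overlap_oracle(a, b, frac)
            pd.testing.assert_frame_equal(ours, oracle)


class TestBuildNegatives:
    @pytest.fixture()
    def sets(self):
        rng = np.random.default_rng(4)
        dnase = regions([("chr1", i * 2000, i * 2000 + 1500) for i in range(30)])
        chip = regions([("chr1", i * 2000 + 200, i * 2000 + 500)
                        for i in range(0, 30, 3)])
        positives = random_regions(rng, 15, chroms=("chr1",), span=5_000)
        positives["end"] = positives["start"] + rng.integers(50, 300, size=15)
        return dnase, chip, positives

    def test_negatives_avoid_chip_and_match_sizes(self, sets):
        dnase, chip, positives = sets
        neg = build_negatives(dnase, chip, positives, rng_seed=5)
        assert len(neg) == len(positives)
        assert sorted(neg.end - neg.start) == sorted(positives.end - positives.start)
        assert reciprocal_overlap(neg, chip, frac=1e-9).empty  # no intersection

    def test_reproducible_under_seed(self, sets):
        dnase, chip, positives = sets
        a = build_negatives(dnase, chip, positives, rng_seed=6)
        b = build_negatives(dnase, chip, positives, rng_seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_positive_is_an_error(self, sets):
        dnase, chip, _ = sets
        big = regions([("chr1", 0, 50_000)])
        with pytest.raises(ValueError, match="size-match"):
            build_negatives(dnase, chip, big)


def test_subtract_regions_removes_covered_bases():
    a = regions([("chr1", 0, 100), ("chr1", 200, 300), ("chr2", 0, 50)])
    b = regions([("chr1", 20, 40), ("chr1", 90, 250)])
    out = subtract_regions(a, b)
    expected = regions([("chr1", 0, 20), ("chr1", 40, 90),
                        ("chr1", 250, 300), ("chr2", 0, 50)])
    pd.testing.assert_frame_equal(out, expected)


@pytest.fixture(scope="module")
def pwm():
    rng = np.random.default_rng(8)
    return pwm_from_pfm(PFM(rng.dirichlet(np.ones(4), size=9)),
                        background=HT29_BACKGROUND)


class TestScoreRegion:
    def test_consensus_scores_sum_of_per_position_maxima(self, pwm):
        consensus = "".join("ACGT"[i] for i in pwm.scores.argmax(axis=1))
        assert score_region(consensus, pwm) == pytest.approx(pwm.max_score())

    def test_reverse_complement_invariance(self, pwm):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_dna(60, rng)
            assert score_region(seq, pwm) == pytest.approx(
                score_region(revcomp(seq), pwm), abs=1e-9)

    def test_matches_exhaustive_window_enumeration(self, pwm):
        rng = np.random.default_rng(10)
        k = pwm.length
        for _ in range(100):
            seq = random_dna(100, rng)

            def window_score(s):
                return sum(pwm.scores[j, "ACGT".index(s[j])] for j in range(k))

            oracle = max(
                window_score(strand[off:off + k])
                for strand in (seq, revcomp(seq))
                for off in range(len(seq) - k + 1)
            )
            assert score_region(seq, pwm) == pytest.approx(oracle, abs=1e-9)

    def test_n_bases_score_at_background(self, pwm):
        k = pwm.length
        assert score_region("N" * k, pwm) == pytest.approx(0.0)

    def test_short_sequence_is_an_error(self, pwm):
        with pytest.raises(ValueError, match="shorter"):
            score_region("ACG", pwm)


class TestRocAuc:
    def test_separated_scores_give_unity(self):
        res = roc_auc([5, 6, 7], [1, 2, 3])
        assert res.auc == 1.0

    def test_null_case_near_half(self):
        rng = np.random.default_rng(11)
        res = roc_auc(rng.standard_normal(500), rng.standard_normal(500))
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_pos = int(rng.integers(1, 21))
            n_neg = int(rng.integers(1, 21))
            pos = rng.integers(0, 8, size=n_pos).astype(float)  # ties likely
            neg = rng.integers(0, 8, size=n_neg).astype(float)
            res = roc_auc(pos, neg)
            pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert res.auc == pytest.approx(pairs / (n_pos * n_neg), abs=1e-12)
            assert res.u_statistic == pytest.approx(res.auc * n_pos * n_neg)

    def test_complementarity_without_ties(self):
        rng = np.random.default_rng(13)
        pos = rng.standard_normal(40)
        neg = rng.standard_normal(30)
        assert roc_auc(pos, neg).auc + roc_auc(neg, pos).auc == pytest.approx(1.0)

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(14)
        res = roc_auc(rng.standard_normal(30), rng.standard_normal(30),
                      n_models_for_bonferroni=5)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_value * 5))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestActivePeakFilter:
    tss = pd.DataFrame({
        "gene": ["up_plus", "up_minus", "quiet"],
        "chrom": ["chr1", "chr1", "chr1"],
        "position": [50_000, 100_000, 200_000],
        "strand": ["+", "-", "+"],
    })
    de = ["up_plus", "up_minus"]

    def test_upstream_plus_strand_window(self):
        peaks = regions([("chr1", 44_800, 45_200),    # 5 kb upstream: keep
                         ("chr1", 34_800, 35_200),    # 15 kb upstream: drop
                         ("chr1", 50_100, 50_500)])   # downstream: drop
        out = active_peak_filter(peaks, self.tss, self.de, window=10_000)
        assert out.start.tolist() == [44_800]

    def test_upstream_minus_strand_window_is_rightward(self):
        # for a minus-strand gene at p, upstream is [p, p + window)
        peaks = regions([("chr1", 104_000, 104_300),  # inside [100k,110k): keep
                         ("chr1", 96_000, 96_500)])   # left of TSS: drop
        out = active_peak_filter(peaks, self.tss, self.de, window=10_000)
        assert out.start.tolist() == [104_000]

    def test_non_de_genes_do_not_rescue_peaks(self):
        peaks = regions([("chr1", 195_000, 195_400)])
        assert active_peak_filter(peaks, self.tss, self.de).empty

    def test_up_and_down_geometry(self):
        peaks = regions([("chr1", 50_100, 50_500)])
        out = active_peak_filter(peaks, self.tss, self.de, window=10_000,
                                 geometry="up_and_down")
        assert len(out) == 1

    def test_unknown_geometry_is_an_error(self):
        with pytest.raises(ValueError, match="geometry"):
            active_peak_filter(regions([("chr1", 0, 10)]), self.tss, self.de,
                               geometry="sideways")


def test_bed_round_trip(tmp_path):
    df = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 10],
                       "end": [5, 40], "name": ["a", "b"]})
    path = tmp_path / "x.bed"
    write_bed(df, path)
    back = read_bed(path)
    pd.testing.assert_frame_equal(back, df)
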