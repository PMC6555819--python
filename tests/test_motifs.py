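import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrpbm.motifs import (
    HT29_BACKGROUND,
    PFM,
    average_pfms,
    compute_beta,
    delta_z_matrix,
    information_content,
    pfm_from_zscores,
    probabilities_from_pwm,
    pwm_from_pfm,
    read_meme,
    read_pfm_tsv,
    write_meme,
    write_pfm_tsv,
)


def uniform_pfm(L=4):
    return PFM(np.full((L, 4), 0.25))


class TestPfmFromZscores:
    def test_equal_z_gives_uniform_column(self):
        pfm = pfm_from_zscores(np.full((3, 4), 2.5), beta=1.0)
        assert np.allclose(pfm.probs, 0.25)

    def test_beta_to_zero_limit_is_uniform(self):
        z = np.array([[5.0, -3.0, 0.0, 1.0]])
        pfm = pfm_from_zscores(z, beta=1e-12)
        assert np.allclose(pfm.probs, 0.25, atol=1e-9)

    def test_softmax_column_against_direct_arithmetic(self):
        pfm = pfm_from_zscores(np.array([[3.0, 0.0, 0.0, 0.0]]), beta=1.0)
        denom = math.exp(3) + 3
        assert pfm.probs[0, 0] == pytest.approx(math.exp(3) / denom, rel=1e-12)
        assert np.allclose(pfm.probs[0, 1:], 1 / denom, rtol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=4, max_size=4),
           st.floats(1e-3, 10), st.floats(-30, 30))
    def test_shift_invariance(self, zvals, beta, shift):
        z = np.array([zvals])
        a = pfm_from_zscores(z, beta).probs
        b = pfm_from_zscores(z + shift, beta).probs
        assert np.allclose(a, b, atol=1e-9)

    def test_non_finite_z_rejected(self):
        with pytest.raises(ValueError):
            pfm_from_zscores(np.array([[np.nan, 0, 0, 0]]), beta=1.0)

    def test_beta_is_numerator_over_zmax(self):
        assert compute_beta(30.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            compute_beta(0.0)


class TestPwmFromPfm:
    def test_background_column_maps_to_zero_scores(self):
        pfm = PFM(np.tile(HT29_BACKGROUND, (5, 1)))
        pwm = pwm_from_pfm(pfm, background=HT29_BACKGROUND)
        assert np.allclose(pwm.scores, 0.0, atol=1e-12)

    def test_extreme_columns_match_exact_arithmetic(self):
        # independent oracle: exact rationals for p, log2 at the end
        s = Fraction(1, 1000)
        bA = Fraction(6, 25)          # 0.24
        # column (1, 0, 0, 0) against uniform background
        pfm = PFM(np.array([[1.0, 0.0, 0.0, 0.0]]))
        pwm = pwm_from_pfm(pfm, background=np.array([0.25] * 4), pseudocount=0.001)
        pA = (Fraction(1) + s * Fraction(1, 4)) / (Fraction(1) + s)
        assert pwm.scores[0, 0] == pytest.approx(
            math.log2(float(pA / Fraction(1, 4))), abs=1e-12)
        # column with a zero frequency against the printed background
        pfm = PFM(np.array([[0.0, 0.5, 0.3, 0.2]]))
        pwm = pwm_from_pfm(pfm, background=HT29_BACKGROUND, pseudocount=0.001)
        pA = (Fraction(0) + s * bA) / (Fraction(1) + s)
        assert pwm.scores[0, 0] == pytest.approx(
            math.log2(float(pA / bA)), abs=1e-12)

    def test_round_trip_recovers_probabilities(self):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet(np.ones(4), size=8)
        pfm = PFM(mat)
        pwm = pwm_from_pfm(pfm, background=HT29_BACKGROUND)
        p = probabilities_from_pwm(pwm)
        expected = (mat + 0.001 * HT29_BACKGROUND) / (1 + 0.001)
        assert np.allclose(p, expected, atol=1e-12)

    def test_zero_background_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            pwm_from_pfm(uniform_pfm(), background=np.array([0.5, 0.5, 0.0, 0.0]))


class TestAveragePfms:
    def test_identical_inputs_are_returned(self):
        rng = np.random.default_rng(6)
        pfm = PFM(rng.dirichlet(np.ones(4), size=6))
        avg = average_pfms([pfm, pfm, pfm])
        assert np.allclose(avg.probs, pfm.probs)

    def test_two_column_toy_means(self):
        a = PFM(np.array([[1.0, 0.0, 0.0, 0.0], [0.5, 0.5, 0.0, 0.0]]))
        b = PFM(np.array([[0.0, 1.0, 0.0, 0.0], [0.5, 0.0, 0.5, 0.0]]))
        avg = average_pfms([a, b])
        assert np.allclose(avg.probs, [[0.5, 0.5, 0, 0], [0.5, 0.25, 0.25, 0]])
        assert np.allclose(avg.probs.sum(axis=1), 1.0)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            average_pfms([uniform_pfm(4), uniform_pfm(5)])


class TestInformationContent:
    def test_uniform_pfm_carries_no_information(self):
        assert np.allclose(information_content(uniform_pfm()), 0.0)

    def test_deterministic_column_against_closed_form(self):
        pfm = PFM(np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert information_content(pfm)[0] == pytest.approx(2.0)
        assert information_content(pfm, HT29_BACKGROUND)[0] == pytest.approx(
            -math.log2(0.24))


class TestDeltaZMatrix:
    def test_median_is_zero_and_planted_base_argmax(self, scenario_results):
        res = scenario_results["full"]
        sc = res["scenario"]
        for seed in sc.seeds[:10]:
            em = delta_z_matrix(res["profile"], seed)
            med = np.median(em.delta_z, axis=1)
            assert np.allclose(med, 0.0, atol=1e-9)

    def test_argmax_recovers_planted_base_at_informative_positions(
            self, scenario_results):
        res = scenario_results["full"]
        sc = res["scenario"]
        hits = total = 0
        for seed in sc.seeds:
            em = delta_z_matrix(res["profile"], seed)
            E = np.zeros((seed.context_len, 4))
            E[seed.flank_len:seed.flank_len + seed.site_len] = \
                sc.model.full_site_energy[seed.spacer_len]
            informative = (E.max(axis=1) - E.min(axis=1)) > 0.5
            planted = E.argmin(axis=1)
            inferred = em.delta_z.argmax(axis=1)
            hits += int((inferred[informative] == planted[informative]).sum())
            total += int(informative.sum())
        assert hits / total >= 0.95

    def test_missing_snv_is_an_error(self, scenario_results):
        res = scenario_results["full"]
        seed = res["scenario"].seeds[0]
        profile = res["profile"]
        import copy
        clipped = copy.copy(profile)
        mask = ~((clipped.data.seed_id == seed.seed_id)
                 & (clipped.data.variant_position == 0))
        clipped.data = clipped.data[mask]
        with pytest.raises(ValueError, match="missing"):
            delta_z_matrix(clipped, seed)


class TestMotifIO:
    def test_meme_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        pfms = [PFM(rng.dirichlet(np.ones(4), size=L), name=f"m{L}")
                for L in (5, 8)]
        path = tmp_path / "motifs.meme"
        write_meme(pfms, path, background=HT29_BACKGROUND)
        loaded = read_meme(path)
        assert [p.name for p in loaded] == ["m5", "m8"]
        for orig, back in zip(pfms, loaded):
            assert np.allclose(orig.probs, back.probs, atol=1e-5)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        pfm = PFM(rng.dirichlet(np.ones(4), size=6), name="t")
        path = tmp_path / "pfm.tsv"
        write_pfm_tsv(pfm, path)
        assert np.allclose(read_pfm_tsv(path).probs, pfm.probs, atol=1e-5)
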