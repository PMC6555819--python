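import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrpbm.probe_design import (
    DesignParams,
    ablate_half_site,
    build_library,
    enumerate_snv_probes,
    generate_seeds,
    sample_background,
)
from nrpbm.sequences import SeedSequence, has_long_run, random_dna

DR1 = SeedSequence("dr1", "AGGTCA", "A", "AGGTCA", "GTCTA", "TAGAC")


class TestEnumerateSnvProbes:
    @pytest.mark.parametrize(
        "spacer,expected",
        [("", 66), ("A", 69), ("ACGTA", 81)],  # 3 * (22 + S)
    )
    def test_variant_counts_by_spacer_length(self, spacer, expected):
        seed = SeedSequence("s", "AGGTCA", spacer, "AGTTCA", "GTCTA", "TAGAC")
        variants = enumerate_snv_probes(seed)
        assert len(variants) == expected
        assert len({v for _, _, v in variants}) == expected

    def test_each_variant_differs_at_exactly_one_position(self):
        region = DR1.variable_region()
        for pos, base, var in enumerate_snv_probes(DR1):
            diffs = [i for i, (a, b) in enumerate(zip(region, var)) if a != b]
            assert len(diffs) == 1
            assert var[diffs[0]] == base
            assert diffs[0] == DR1.context_offset() + pos

    def test_variants_cover_halves_spacer_and_flanks(self):
        positions = {pos for pos, _, _ in enumerate_snv_probes(DR1)}
        assert positions == set(range(DR1.context_len))

    def test_invalid_seed_characters_rejected(self):
        with pytest.raises(ValueError):
            SeedSequence("bad", "AGGTCN", "A", "AGGTCA")


class TestBuildLibrary:
    def test_full_design_unique_sequence_counts(self, full_design_library):
        lib = full_design_library
        # 24 seeds x sum over S of (3*(22+S) + 1)
        assert lib.seed_snv_count() == 10_728
        for spacer_len in range(6):
            assert lib.seed_snv_count(spacer_len) == 24 * (3 * (22 + spacer_len) + 1)

    def test_replicate_multiplicities(self, small_library):
        probes = small_library.probes
        snv = probes[probes.category == "snv"].groupby("sequence").size()
        assert (snv == 10).all()  # 5 per orientation
        for cat in ("seed", "background"):
            counts = probes[probes.category == cat].groupby("sequence").size()
            assert (counts == 8).all()  # 4 per orientation

    def test_probe_and_design_layout(self, small_library):
        probes = small_library.probes
        assert probes.probe_id.is_unique
        assert (probes.variable_region.str.len() == 34).all()
        assert (probes.primer_region.str.len() == 24).all()

    def test_snv_hamming_distance_to_seed_is_one(self, small_library):
        lib = small_library
        for seed_id, seed in lib.seeds.items():
            region = seed.variable_region()
            snvs = lib.probes[(lib.probes.seed_id == seed_id)
                              & (lib.probes.category == "snv")]
            for seq in snvs.sequence.unique():
                assert sum(a != b for a, b in zip(seq, region)) == 1

    def test_too_few_seeds_is_an_error(self):
        seeds = generate_seeds(3, (0, 0), rng_seed=0)
        with pytest.raises(ValueError, match="need 4 seeds"):
            build_library(seeds, DesignParams(seeds_per_spacer=4,
                                              spacer_range=(0, 0)),
                          background_sequences=[])

    def test_seed_collision_is_an_error_naming_the_pair(self):
        seeds = generate_seeds(2, (0, 0), rng_seed=0)
        clone = SeedSequence("clone", seeds[0].hs5, seeds[0].spacer,
                             seeds[0].hs3, seeds[0].flank5, seeds[0].flank3)
        with pytest.raises(ValueError, match="collision.*clone"):
            build_library([seeds[0], seeds[1], clone],
                          DesignParams(seeds_per_spacer=3, spacer_range=(0, 0)),
                          background_sequences=["ACGT" * 8 + "AC"])


class TestAblateHalfSite:
    def test_most_informative_position_is_mutated(self):
        model = np.zeros((DR1.context_len, 4))
        pos = DR1.hs5_slice.start + 2  # 5' half-site position 2
        model[pos, 0] = 5.0  # only informative entry: A preferred
        seed = DR1.with_context(
            DR1.context[:pos] + "A" + DR1.context[pos + 1:])
        ablated = ablate_half_site(seed, model, "5prime")
        diffs = [i for i, (a, b) in enumerate(zip(ablated.context, seed.context))
                 if a != b]
        assert diffs == [pos]

    def test_ablation_reduces_model_score_below_all_alternatives(self):
        rng = np.random.default_rng(7)
        model = rng.normal(size=(DR1.context_len, 4))
        for half, sl in (("5prime", DR1.hs5_slice), ("3prime", DR1.hs3_slice)):
            ablated = ablate_half_site(DR1, model, half)

            def score(ctx):
                return sum(model[i, "ACGT".index(b)] for i, b in enumerate(ctx))

            # exhaustive single-mutation scan within the half-site
            best_drop = min(
                score(DR1.context[:i] + b + DR1.context[i + 1:])
                for i in range(sl.start, sl.stop)
                for b in "ACGT" if b != DR1.context[i]
            )
            assert score(ablated.context) < score(DR1.context)
            assert score(ablated.context) == pytest.approx(best_drop)

    def test_tied_contributions_resolve_to_lowest_position(self):
        model = np.zeros((DR1.context_len, 4))
        for i, b in enumerate(DR1.context):
            model[i, "ACGT".index(b)] = 1.0  # every position ties
        ablated = ablate_half_site(DR1, model, "3prime")
        diffs = [i for i, (a, b) in enumerate(zip(ablated.context, DR1.context))
                 if a != b]
        assert diffs == [DR1.hs3_slice.start]

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="does not match"):
            ablate_half_site(DR1, np.zeros((5, 4)), "5prime")


class TestSampleBackground:
    def test_filters_runs_and_n(self):
        genome = {"chr": "AAAAA" + random_dna(5000, np.random.default_rng(0))
                  + "N" * 50}
        seqs = sample_background(genome, n=30, rng_seed=1)
        assert len(seqs) == 30
        for s in seqs:
            assert "N" not in s
            assert not has_long_run(s)

    def test_deterministic_and_filter_stable(self):
        genome = {"chr": random_dna(30_000, np.random.default_rng(0))}
        a = sample_background(genome, n=50, rng_seed=9)
        b = sample_background(genome, n=50, rng_seed=9)
        assert a == b
        assert [s for s in a if "N" not in s and not has_long_run(s)] == a

    def test_zero_requested_returns_empty(self):
        assert sample_background({"c": "ACGT" * 100}, n=0) == []

    def test_insufficient_genome_is_an_error(self):
        with pytest.raises(ValueError, match="genome too small"):
            sample_background({"c": "ACGTACGT"}, n=10, length=34)


@settings(max_examples=20, derandomize=True)
@given(st.integers(0, 5), st.integers(0, 2**16))
def test_generated_seeds_are_valid_and_distinct(spacer_len, rng_seed):
    seeds = generate_seeds(6, (spacer_len, spacer_len), rng_seed=rng_seed)
    contexts = [s.context for s in seeds]
    assert len(set(contexts)) == 6
    for a in contexts:
        for b in contexts:
            if a is not b:
                assert sum(x != y for x, y in zip(a, b)) >= 3
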