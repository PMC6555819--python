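import numpy as np
import pytest

from nrpbm.modes import classify_mode
from nrpbm.motifs import delta_z_matrix, pfm_for_seed
from nrpbm.normalization import compute_zscores
from nrpbm.probe_design import DesignParams, build_library, generate_seeds
from nrpbm.synthetic import make_scenario, random_dna, simulate_fluorescence


@pytest.fixture(scope="session")
def small_library():
    """A reduced probe library: 4 seeds per spacer at DR0-DR1."""
    params = DesignParams(seeds_per_spacer=4, spacer_range=(0, 1), n_background=40)
    seeds = generate_seeds(4, (0, 1), rng_seed=3)
    genome = {"chr1": random_dna(40_000, np.random.default_rng(4))}
    return build_library(seeds, params, genome=genome, rng_seed=5)


@pytest.fixture(scope="session")
def full_design_library():
    """The complete default design: 24 seeds per spacer, DR0-DR5."""
    seeds = generate_seeds(24, (0, 5), rng_seed=1)
    genome = {"chr1": random_dna(120_000, np.random.default_rng(2))}
    return build_library(seeds, genome=genome, rng_seed=3)


def _evaluate_scenario(kind: str, rng_seed: int = 11):
    """Simulate one scenario and run the inference pipeline over it."""
    sc = make_scenario(kind, rng_seed=rng_seed)
    fluor, truth = simulate_fluorescence(sc.library, sc.model, sc.noise,
                                         rng_seed=rng_seed + 1)
    profile = compute_zscores(fluor, sc.library)
    calls, inferred, planted = [], [], []
    for seed in sc.seeds:
        em = delta_z_matrix(profile, seed)
        if em.zmax < 3.0:
            continue
        calls.append(classify_mode(em, seed))
        inferred.append(pfm_for_seed(profile, seed).probs.ravel())
        planted.append(sc.model.planted_pfm(seed).probs.ravel())
    pooled_r = float(np.corrcoef(np.concatenate(inferred),
                                 np.concatenate(planted))[0, 1])
    return dict(scenario=sc, profile=profile, calls=calls, pooled_r=pooled_r,
                n_seeds=len(sc.seeds))


@pytest.fixture(scope="session")
def scenario_results():
    """Inference results for the three single-mode scenarios."""
    return {kind: _evaluate_scenario(kind) for kind in ("full", "half5", "half3")}


@pytest.fixture(scope="session")
def mutant_results():
    """Wild-type and DBD-mutant mode calls over a shared seed set."""
    sc = make_scenario("mutant", rng_seed=11)
    out = {}
    for label, model, rs in (("wt", sc.model, 111), ("mut", sc.mutant_model, 112)):
        fluor, _ = simulate_fluorescence(sc.library, model, sc.noise, rng_seed=rs)
        profile = compute_zscores(fluor, sc.library)
        out[label] = [classify_mode(delta_z_matrix(profile, s), s)
                      for s in sc.seeds]
    out["scenario"] = sc
    return out
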