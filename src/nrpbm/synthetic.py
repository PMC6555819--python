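"""Synthetic fluorescence and genomic benchmarks with known ground truth.

The generative model mirrors the dual binding-mode picture the analysis
is built to detect: a heterodimer can occupy a probe in full-site mode
(both half-sites engaged, a 12+S bp footprint including the spacer) or
in a half-site mode (one 6-bp half-site plus 5 bp of flank).  Probe
occupancy is a Boltzmann sum over all windows on both strands,

    occ(seq) = baseline + sum_modes w_mode * sum_windows exp(-E_mode(window)),

and measured fluorescence multiplies occupancy by per-probe lognormal
noise and an orientation bias factor.  Energies are additive
per-position penalties in natural-log units (0 for the preferred base),
so one mismatch costs a factor exp(-penalty) in occupancy; penalties
around 1-2 give the 2-7x per-base-change effects typical of
high-affinity transcription-factor sites.

A separate generator plants motif instances into random genomic regions
to benchmark PWM-based discrimination of bound versus unbound regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .motifs import PFM
from .probe_design import (
    DesignParams,
    ProbeLibrary,
    build_library,
    generate_seeds,
    sample_background,
)
from .sequences import (
    DNA_ALPHABET,
    HALF_SITE_LEN,
    SeedSequence,
    encode,
    random_dna,
    revcomp,
)

HALF_FOOTPRINT = HALF_SITE_LEN + 5  # 6-bp core plus 5 bp of flank


@dataclass
class GroundTruthModel:
    """Additive-energy ground truth for the dual-mode occupancy model.

    ``full_site_energy`` maps each spacer length S to a (12+S, 4) array
    (half-site cores informative, spacer positions neutral);
    ``hs5_energy`` is (11, 4) over flank+core, ``hs3_energy`` (11, 4)
    over core+flank.  ``mode_weights`` = (w_full, w_5, w_3) set the
    Boltzmann weight of a perfect site in each mode relative to the
    nonspecific ``baseline``; ``spacer_weights`` optionally rescales
    w_full per spacer length (a spacer-preference landscape).
    """

    full_site_energy: dict[int, np.ndarray]
    hs5_energy: np.ndarray
    hs3_energy: np.ndarray
    mode_weights: tuple[float, float, float] = (1.0, 0.0, 0.0)
    baseline: float = 1.0
    spacer_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if min(self.mode_weights) < 0:
            raise ValueError("mode weights must be non-negative")
        if max(self.mode_weights) <= 0:
            raise ValueError("at least one mode weight must be positive")
        for S, mat in self.full_site_energy.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (12 + S, 4) or not np.isfinite(mat).all():
                raise ValueError(f"full-site energy for spacer {S} must be ({12+S}, 4)")
            self.full_site_energy[S] = mat
        for name in ("hs5_energy", "hs3_energy"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (HALF_FOOTPRINT, 4) or not np.isfinite(mat).all():
                raise ValueError(f"{name} must be ({HALF_FOOTPRINT}, 4)")
            setattr(self, name, mat)

    def min_window(self) -> int:
        lens = [HALF_FOOTPRINT]
        lens += [12 + S for S in self.full_site_energy]
        return min(lens)

    def full_weight(self, spacer_len: int) -> float:
        w = self.mode_weights[0]
        if self.spacer_weights is not None:
            w *= self.spacer_weights.get(spacer_len, 1.0)
        return w

    def planted_pfm(self, seed: SeedSequence) -> PFM:
        """Boltzmann frequencies exp(-E)/Z over the seed context.

        Site positions take the dominant mode's energies; flank and
        spacer positions without planted preference are uniform.
        """
        L = seed.context_len
        E = np.zeros((L, 4))
        w_full, w5, w3 = self.mode_weights
        wf = self.full_weight(seed.spacer_len)
        dominant = np.argmax([wf, w5, w3])
        f = seed.flank_len
        if dominant == 0:
            E[f:f + seed.site_len] = self.full_site_energy[seed.spacer_len]
        elif dominant == 1:
            start = f - 5
            E[start:start + HALF_FOOTPRINT] = self.hs5_energy
        else:
            start = seed.hs3_slice.start
            E[start:start + HALF_FOOTPRINT] = self.hs3_energy
        w = np.exp(-E)
        return PFM(w / w.sum(axis=1, keepdims=True), name=f"truth_{seed.seed_id}")


@dataclass
class NoiseModel:
    """Multiplicative lognormal measurement noise and orientation bias."""

    lognormal_sigma: float = 0.1
    replicate_count: int = 5
    orientation_bias: float = 0.8  # multiplies o2-probe intensities

    def __post_init__(self) -> None:
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def build_truth_model(
    consensus5: str = "AGGTCA",
    consensus3: str = "AGGTCA",
    spacer_range: tuple[int, int] = (0, 5),
    mode_weights: tuple[float, float, float] = (30.0, 0.0, 0.0),
    baseline: float = 1.0,
    penalty_range: tuple[float, float] = (1.2, 2.2),
    flank_penalty_range: tuple[float, float] = (0.3, 0.7),
    flank5_consensus: str | None = None,
    flank3_consensus: str | None = None,
    spacer_weights: dict[int, float] | None = None,
    rng_seed: int = 0,
) -> GroundTruthModel:
    """Construct a ground-truth model around concrete half-site consensuses.

    Core positions prefer the consensus base (energy 0) and penalize
    the other three by independent draws from ``penalty_range``
    (natural-log units); spacer positions are neutral.  The 5 flank
    positions of the half-site modes carry mild preferences
    (``flank_penalty_range``, random preferred base): half-site
    binding in vitro depends on flanking contacts, which is also what
    keeps a lone 6-bp core from matching random sequence everywhere.
    """
    rng = np.random.default_rng(rng_seed)

    def block(consensus: str | None, n: int, rng_pen) -> np.ndarray:
        mat = rng.uniform(*rng_pen, size=(n, 4))
        for i in range(n):
            b = consensus[i] if consensus else DNA_ALPHABET[rng.integers(4)]
            mat[i, DNA_ALPHABET.index(b)] = 0.0
        return mat

    core5 = block(consensus5, HALF_SITE_LEN, penalty_range)
    core3 = block(consensus3, HALF_SITE_LEN, penalty_range)
    full = {
        S: np.vstack([core5, np.zeros((S, 4)), core3])
        for S in range(spacer_range[0], spacer_range[1] + 1)
    }
    hs5 = np.vstack([block(flank5_consensus, 5, flank_penalty_range), core5])
    hs3 = np.vstack([core3, block(flank3_consensus, 5, flank_penalty_range)])
    return GroundTruthModel(
        full_site_energy=full,
        hs5_energy=hs5,
        hs3_energy=hs3,
        mode_weights=mode_weights,
        baseline=baseline,
        spacer_weights=spacer_weights,
    )


# --------------------------------------------------------------------------
# Occupancy
# --------------------------------------------------------------------------

def _window_boltzmann(enc: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Sum of exp(-E) over all windows of each encoded sequence (one strand).

    ``enc`` is (N, L) integer-encoded; returns (N,) sums.
    """
    k = energy.shape[0]
    if enc.shape[1] < k:
        raise ValueError(
            f"sequence length {enc.shape[1]} shorter than model window {k}"
        )
    wins = sliding_window_view(enc, k, axis=1)          # (N, W, k)
    pos = np.arange(k)
    E = energy[pos, wins]                               # (N, W, k)
    return np.exp(-E.sum(axis=2)).sum(axis=1)


def occupancy_many(seqs: list[str], model: GroundTruthModel) -> np.ndarray:
    """Vectorized occupancy for equal-length sequences (both strands)."""
    if not seqs:
        return np.zeros(0)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("occupancy_many requires equal-length sequences")
    if L < model.min_window():
        raise ValueError("sequences shorter than the smallest model window")
    fwd = np.stack([encode(s) for s in seqs])
    rev = np.stack([encode(revcomp(s)) for s in seqs])
    total = np.zeros(len(seqs))
    w_full, w5, w3 = model.mode_weights
    for enc in (fwd, rev):
        if w_full > 0:
            for S, E in model.full_site_energy.items():
                wf = model.full_weight(S)
                if wf > 0 and enc.shape[1] >= E.shape[0]:
                    total += wf * _window_boltzmann(enc, E)
        if w5 > 0:
            total += w5 * _window_boltzmann(enc, model.hs5_energy)
        if w3 > 0:
            total += w3 * _window_boltzmann(enc, model.hs3_energy)
    return total + model.baseline


def occupancy(sequence: str, model: GroundTruthModel) -> float:
    """Dual-mode Boltzmann occupancy of one sequence (both strands)."""
    return float(occupancy_many([sequence], model)[0])


def simulate_fluorescence(
    library: ProbeLibrary,
    model: GroundTruthModel,
    noise: NoiseModel,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One intensity per probe record: occupancy x orientation x noise.

    Returns ``(fluorescence, truth)`` where truth holds the noise-free
    occupancy per unique sequence.  Deterministic under ``rng_seed``.
    """
    probes = library.probes
    uniq = probes["sequence"].unique()
    occ = occupancy_many(list(uniq), model)
    occ_map = dict(zip(uniq, occ))
    base = probes["sequence"].map(occ_map).to_numpy(dtype=float)
    bias = np.where(probes["orientation"] == "o2", noise.orientation_bias, 1.0)
    rng = np.random.default_rng(rng_seed)
    eps = np.exp(noise.lognormal_sigma * rng.standard_normal(len(probes)))
    fluor = pd.DataFrame(
        {"probe_id": probes["probe_id"], "intensity": base * bias * eps}
    )
    truth = pd.DataFrame({"sequence": uniq, "occupancy": occ})
    return fluor, truth


# --------------------------------------------------------------------------
# Named simulation scenarios
# --------------------------------------------------------------------------

@dataclass
class Scenario:
    """A seed set, ground-truth model and probe library ready to simulate."""

    library: ProbeLibrary
    model: GroundTruthModel
    noise: NoiseModel
    seeds: list[SeedSequence]
    mutant_model: GroundTruthModel | None = None


def make_scenario(
    kind: str,
    rng_seed: int = 0,
    n_per_spacer: int = 24,
    spacer_range: tuple[int, int] = (0, 5),
    sigma: float = 0.1,
    n_background: int = 500,
) -> Scenario:
    """Build one of the named simulation studies.

    * ``full`` - full-site binding only; both half-sites consensus-like.
    * ``half5`` / ``half3`` - one half-site mode only; the unengaged
      half is sequence-random so the half-site footprint has a unique
      best placement.
    * ``mutant`` - wild-type full-site binder (asymmetric seeds: strong
      5' half, degenerate 3' half) paired with a DNA-binding-domain
      mutant model that has lost full-site binding and retains weak
      5'-half-site binding (``mutant_model``).
    * ``dr1_preference`` - full-site weight concentrated on spacer
      length 1, with a weak 5'-half-site mode everywhere.
    """
    rng = np.random.default_rng(rng_seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    params = DesignParams(seeds_per_spacer=n_per_spacer, spacer_range=spacer_range,
                          n_background=n_background)
    noise = NoiseModel(lognormal_sigma=sigma, replicate_count=params.reps_snv)
    consensus = "AGGTCA"
    mutant_model = None

    if kind == "full":
        seeds = generate_seeds(n_per_spacer, spacer_range, rng_seed=sub(),
                               consensus5=consensus, consensus3=consensus,
                               mutation_counts=(0, 1), mutation_probs=(0.6, 0.4))
        model = build_truth_model(consensus, consensus, spacer_range,
                                  mode_weights=(30.0, 0.0, 0.0), rng_seed=sub())
    elif kind in ("half5", "half3"):
        c5 = consensus if kind == "half5" else None
        c3 = consensus if kind == "half3" else None
        # the unengaged half is random but kept >= 3 mismatches from the
        # consensus so the planted footprint is the unique binding site;
        # the engaged half's flank matches the model's flank preference
        # (seeds emulate real bound sites, flank contacts included)
        flank_cons = "GTCGA"
        seeds = generate_seeds(n_per_spacer, spacer_range, rng_seed=sub(),
                               consensus5=c5, consensus3=c3,
                               avoid5=None if c5 else consensus,
                               avoid3=None if c3 else consensus,
                               flank5_consensus=flank_cons if c5 else None,
                               flank3_consensus=flank_cons if c3 else None,
                               mutation_counts=(0, 1), mutation_probs=(0.6, 0.4))
        weights = (0.0, 30.0, 0.0) if kind == "half5" else (0.0, 0.0, 30.0)
        model = build_truth_model(consensus, consensus, spacer_range,
                                  mode_weights=weights,
                                  flank5_consensus=flank_cons if c5 else None,
                                  flank3_consensus=flank_cons if c3 else None,
                                  rng_seed=sub())
    elif kind == "mutant":
        # wild type binds genuine full sites (both halves consensus-like,
        # favorable 5' flank as at real bound sites); the DNA-binding-
        # domain mutant loses full-site binding and retains only weak
        # 5'-half-site binding anchored by the flank contacts
        flank_cons = "GTCGA"
        seeds = generate_seeds(n_per_spacer, spacer_range, rng_seed=sub(),
                               consensus5=consensus, consensus3=consensus,
                               flank5_consensus=flank_cons,
                               mutation_counts=(0, 1), mutation_probs=(0.7, 0.3))
        mseed = sub()
        model = build_truth_model(consensus, consensus, spacer_range,
                                  mode_weights=(30.0, 0.0, 0.0),
                                  rng_seed=mseed)
        # residual monomer binding leans heavily on flank contacts, which
        # anchors it to the 5' half rather than the equivalent 3' core
        mutant_model = build_truth_model(consensus, consensus, spacer_range,
                                         mode_weights=(0.0, 6.0, 0.0),
                                         flank_penalty_range=(0.6, 1.2),
                                         flank5_consensus=flank_cons,
                                         rng_seed=mseed)
    elif kind == "dr1_preference":
        seeds = generate_seeds(n_per_spacer, spacer_range, rng_seed=sub(),
                               consensus5=consensus, consensus3=consensus,
                               mutation_counts=(0, 1, 2, 3),
                               mutation_probs=(0.4, 0.3, 0.2, 0.1))
        spacer_weights = {S: (1.0 if S == 1 else 0.03)
                          for S in range(spacer_range[0], spacer_range[1] + 1)}
        model = build_truth_model(consensus, consensus, spacer_range,
                                  mode_weights=(60.0, 4.0, 0.3),
                                  spacer_weights=spacer_weights, rng_seed=sub())
    else:
        raise ValueError(f"unknown scenario {kind!r}")

    genome = {"synthchr": random_dna(120_000, np.random.default_rng(sub()))}
    background = sample_background(genome, n=n_background, rng_seed=sub())
    library = build_library(seeds, params, background_sequences=background)
    return Scenario(library=library, model=model, noise=noise, seeds=seeds,
                    mutant_model=mutant_model)


# --------------------------------------------------------------------------
# Genomic benchmark
# --------------------------------------------------------------------------

def simulate_genomic_benchmark(
    n_pos: int,
    n_neg: int,
    region_len: int,
    motif: PFM,
    planted_fraction: float,
    rng_seed: int = 0,
    tss_fraction: float = 0.5,
    upstream_window: int = 10_000,
    chrom: str = "synthchr",
):
    """Bound/unbound region sets with motif instances planted in positives.

    Regions tile one synthetic chromosome; each positive carries one
    motif instance sampled from the PFM (random strand) with
    probability ``planted_fraction``; negatives never do.  A TSS table
    and differentially-expressed (DE) gene list place ``tss_fraction``
    of the positives within ``upstream_window`` bp upstream of a DE
    gene.  Returns ``(positives, negatives, genome, tss, de_genes,
    truth)``.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    if region_len < motif.length:
        raise ValueError(
            f"region_len {region_len} shorter than motif length {motif.length}"
        )
    rng = np.random.default_rng(rng_seed)
    gap = max(upstream_window // 4, region_len)
    n_total = n_pos + n_neg
    chrom_len = (region_len + gap) * n_total + gap
    seq = list(random_dna(chrom_len, rng))

    rows = []
    truth_rows = []
    tss_rows = []
    de_genes = []
    order = rng.permutation(n_total)
    for slot, which in enumerate(order):
        start = gap + slot * (region_len + gap)
        end = start + region_len
        is_pos = which < n_pos
        name = f"pos_{which}" if is_pos else f"neg_{which - n_pos}"
        planted = bool(is_pos and rng.random() < planted_fraction)
        offset = -1
        if planted:
            inst = _sample_motif_instance(motif, rng)
            if rng.random() < 0.5:
                inst = revcomp(inst)
            offset = int(rng.integers(0, region_len - motif.length + 1))
            seq[start + offset:start + offset + motif.length] = list(inst)
        rows.append(dict(chrom=chrom, start=start, end=end, name=name,
                         is_positive=is_pos))
        truth_rows.append(dict(name=name, planted=planted, offset=offset))
        if is_pos and rng.random() < tss_fraction:
            gene = f"gene_{name}"
            strand = "+" if rng.random() < 0.5 else "-"
            slack = max(upstream_window - region_len, 1)
            if strand == "+":
                tss_pos = min(end + int(rng.integers(0, slack)), chrom_len - 1)
            else:
                tss_pos = max(start - int(rng.integers(0, slack)), 0)
            tss_rows.append(dict(gene=gene, chrom=chrom, position=tss_pos,
                                 strand=strand))
            de_genes.append(gene)

    # a few DE genes with no nearby peak, and non-DE genes, for realism
    for i in range(max(3, n_pos // 10)):
        p = int(rng.integers(0, chrom_len))
        tss_rows.append(dict(gene=f"distal_{i}", chrom=chrom, position=p,
                             strand="+" if rng.random() < 0.5 else "-"))
        if i % 2 == 0:
            de_genes.append(f"distal_{i}")

    regions = pd.DataFrame(rows)
    positives = regions[regions["is_positive"]].drop(columns="is_positive")
    negatives = regions[~regions["is_positive"]].drop(columns="is_positive")
    genome = {chrom: "".join(seq)}
    tss = pd.DataFrame(tss_rows)
    truth = pd.DataFrame(truth_rows)
    return (positives.reset_index(drop=True), negatives.reset_index(drop=True),
            genome, tss, de_genes, truth)


def _sample_motif_instance(motif: PFM, rng: np.random.Generator) -> str:
    out = []
    for row in motif.probs:
        out.append(DNA_ALPHABET[rng.choice(4, p=row / row.sum())])
    return "".join(out)
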