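"""Energy matrices, position frequency matrices and log-odds PWMs.

The central inference step converts per-variant binding z-scores into a
position frequency matrix (PFM).  At each context position the four
base variants (the seed base plus its three SNVs) define a column of
z-scores; the delta-z energy matrix subtracts the per-position median,
and the Boltzmann/softmax transform

    f_i = exp(beta * z_i) / sum_k exp(beta * z_k),  beta = 15 / z_max

turns z into base frequencies, where z_max is the maximum
replicate-averaged z over the seed and all its SNVs.  The log-odds PWM
follows the standard pseudocount construction

    p_ij = (f_ij + s * b_i) / (sum_i f_ij + s),  S_ij = log2(p_ij / b_i)

with pseudocount s = 0.001 against background base frequencies b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import DNA_ALPHABET, SeedSequence

#: Uniform background.
UNIFORM_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])
#: Background base frequencies of accessible chromatin in the HT29 cell
#: line (A, C, G, T order): the default for genomic enrichment scoring.
HT29_BACKGROUND = np.array([0.24, 0.26, 0.26, 0.24])

DEFAULT_PSEUDOCOUNT = 0.001
DEFAULT_BETA_NUMERATOR = 15.0


def _check_matrix(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError(f"{name} must be (L, 4), got {mat.shape}")
    if not np.isfinite(mat).all():
        raise ValueError(f"{name} contains non-finite entries")
    return mat


@dataclass
class EnergyMatrix:
    """Per-position, per-base delta-z perturbations for one seed.

    ``delta_z[pos, base]`` is the z-score of that base variant minus the
    median z of the four variants at the position; the per-position
    median of the four entries is therefore 0 by construction.
    """

    delta_z: np.ndarray
    seed: SeedSequence
    zmax: float

    def __post_init__(self) -> None:
        self.delta_z = _check_matrix(self.delta_z, "delta_z")
        if self.delta_z.shape[0] != self.seed.context_len:
            raise ValueError("delta_z length does not match seed context")

    @property
    def length(self) -> int:
        return self.delta_z.shape[0]


@dataclass
class PFM:
    """Position frequency matrix: rows are positions, columns A,C,G,T."""

    probs: np.ndarray
    source: str = "single_seed"
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = _check_matrix(self.probs, "probs")
        if (self.probs < -1e-12).any():
            raise ValueError("PFM entries must be non-negative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PFM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def slice(self, sl: slice, name: str | None = None) -> "PFM":
        return PFM(self.probs[sl], source=self.source, name=name or self.name)


@dataclass
class PWM:
    """Log-odds scoring matrix in bits, with its background and pseudocount."""

    scores: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    name: str = "motif"

    def __post_init__(self) -> None:
        self.scores = _check_matrix(self.scores, "scores")
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


def compute_beta(zmax: float, numerator: float = DEFAULT_BETA_NUMERATOR) -> float:
    """Softmax inverse temperature: ``numerator / zmax`` (default 15/z_max)."""
    if not np.isfinite(zmax) or zmax <= 0:
        raise ValueError(f"zmax must be positive and finite, got {zmax}")
    return numerator / zmax


def delta_z_matrix(profile, seed: SeedSequence) -> EnergyMatrix:
    """Delta-z energy matrix for one seed from a binding profile.

    At each context position the four variants are the seed probe (for
    the seed's own base) and the three SNVs; delta-z subtracts the
    median of those four z-scores.
    """
    z = variant_z_matrix(profile, seed)
    med = np.median(z, axis=1, keepdims=True)
    zmax = float(z.max())
    return EnergyMatrix(delta_z=z - med, seed=seed, zmax=zmax)


def variant_z_matrix(profile, seed: SeedSequence) -> np.ndarray:
    """(L, 4) matrix of replicate-averaged z per base variant of the seed."""
    df = profile.data
    rows = df[df["seed_id"] == seed.seed_id]
    seed_rows = rows[rows["category"] == "seed"]
    if seed_rows.empty:
        raise ValueError(f"profile lacks the seed probe for {seed.seed_id}")
    z_seed = float(seed_rows["mean_z"].iloc[0])
    snvs = rows[rows["category"] == "snv"]
    lut = {
        (int(p), b): float(z)
        for p, b, z in zip(snvs["variant_position"], snvs["variant_base"], snvs["mean_z"])
    }
    L = seed.context_len
    ctx = seed.context
    out = np.empty((L, 4))
    missing = []
    for pos in range(L):
        for bi, base in enumerate(DNA_ALPHABET):
            if base == ctx[pos]:
                out[pos, bi] = z_seed
            else:
                val = lut.get((pos, base))
                if val is None:
                    missing.append(f"{pos}{base}")
                else:
                    out[pos, bi] = val
    if missing:
        raise ValueError(
            f"profile is missing {len(missing)} SNV variants for seed "
            f"{seed.seed_id}: {', '.join(missing[:10])}"
        )
    return out


def pfm_from_zscores(z: np.ndarray, beta: float, name: str = "motif") -> PFM:
    """Softmax transform of per-position variant z-scores into a PFM."""
    z = _check_matrix(z, "z")
    if not np.isfinite(beta) or beta <= 0:
        raise ValueError(f"beta must be positive and finite, got {beta}")
    shifted = beta * (z - z.max(axis=1, keepdims=True))
    w = np.exp(shifted)
    return PFM(w / w.sum(axis=1, keepdims=True), name=name)


def pfm_for_seed(
    profile,
    seed: SeedSequence,
    beta_numerator: float = DEFAULT_BETA_NUMERATOR,
) -> PFM:
    """Seed-level PFM via the delta-z matrix and the 15/z_max softmax."""
    z = variant_z_matrix(profile, seed)
    beta = compute_beta(float(z.max()), beta_numerator)
    return pfm_from_zscores(z, beta, name=seed.seed_id)


def pwm_from_pfm(
    pfm: PFM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Log-odds PWM with the additive pseudocount construction."""
    b = np.asarray(background, dtype=float)
    if b.shape != (4,):
        raise ValueError("background must have 4 entries (A, C, G, T)")
    if (b <= 0).any():
        raise ValueError("background frequencies must all be positive")
    if not np.isclose(b.sum(), 1.0, atol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    f = pfm.probs
    p = (f + pseudocount * b) / (f.sum(axis=1, keepdims=True) + pseudocount)
    return PWM(np.log2(p / b), background=b, pseudocount=pseudocount, name=pfm.name)


def probabilities_from_pwm(pwm: PWM) -> np.ndarray:
    """Invert the log-odds transform back to pseudocounted probabilities."""
    return (2.0 ** pwm.scores) * pwm.background


def average_pfms(pfms: list[PFM], name: str = "averaged") -> PFM:
    """Element-wise mean of same-length PFMs, columns renormalized to 1."""
    if not pfms:
        raise ValueError("need at least one PFM")
    lengths = {p.length for p in pfms}
    if len(lengths) != 1:
        raise ValueError(f"PFM length mismatch: {sorted(lengths)}")
    mean = np.mean([p.probs for p in pfms], axis=0)
    mean /= mean.sum(axis=1, keepdims=True)
    return PFM(mean, source="averaged", name=name)


def information_content(
    pfm: PFM, background: np.ndarray = UNIFORM_BACKGROUND
) -> np.ndarray:
    """Per-position Kullback-Leibler information (bits) relative to background."""
    b = np.asarray(background, dtype=float)
    f = pfm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / b), 0.0)
    return terms.sum(axis=1)


# --------------------------------------------------------------------------
# MEME minimal motif format and 4-column TSV I/O
# --------------------------------------------------------------------------

def write_meme(pfms: list[PFM], path, background: np.ndarray = UNIFORM_BACKGROUND) -> None:
    b = np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {b[0]:.5f} C {b[1]:.5f} G {b[2]:.5f} T {b[3]:.5f}\n\n")
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in pfm.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PFM]:
    pfms = []
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1] if len(line.split()) > 1 else "motif"
            elif line.startswith("letter-probability matrix"):
                expecting = int(line.split("w=")[1].split()[0])
                rows = []
            elif expecting and line:
                rows.append([float(x) for x in line.split()[:4]])
                if len(rows) == expecting:
                    mat = np.asarray(rows)
                    mat /= mat.sum(axis=1, keepdims=True)
                    pfms.append(PFM(mat, name=name or "motif"))
                    expecting = 0
    return pfms


def write_pfm_tsv(pfm: PFM, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\n")
        for i, row in enumerate(pfm.probs):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def read_pfm_tsv(path, name: str = "motif") -> PFM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    mat = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    mat /= mat.sum(axis=1, keepdims=True)
    return PFM(mat, name=name)
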