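"""Combinatorial probe-library construction for SNV microarrays.

For every direct-repeat seed sequence the library contains the seed
itself, all single-nucleotide variants (SNVs) of the seed context
(half-sites, spacer and flanks), and two half-site ablation variants;
500 random genomic probes serve as the z-score background.  Each unique
SNV sequence is printed as 5 replicate probes in each of two
orientations (10 probes), every other unique sequence as 4 per
orientation (8 probes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .sequences import (
    DNA_ALPHABET,
    HALF_SITE_CONSENSUS,
    HALF_SITE_LEN,
    DOUBLE_STRANDING_PRIMER,
    SeedSequence,
    HalfSite,
    has_long_run,
    random_dna,
    revcomp,
    sample_from_consensus,
    validate_dna,
)

CATEGORIES = ("seed", "snv", "ablation_5", "ablation_3", "background")
ORIENTATIONS = ("o1", "o2")


@dataclass(frozen=True)
class DesignParams:
    """Replicate/orientation layout of the probe library."""

    seeds_per_spacer: int = 24
    spacer_range: tuple[int, int] = (0, 5)
    flank_len: int = 5
    reps_snv: int = 5       # per orientation -> 10 probes per unique SNV sequence
    reps_other: int = 4     # per orientation -> 8 probes per unique sequence
    n_background: int = 500

    @property
    def spacers(self) -> range:
        return range(self.spacer_range[0], self.spacer_range[1] + 1)


def enumerate_snv_probes(
    seed: SeedSequence, flank_len: int = 5
) -> list[tuple[int, str, str]]:
    """All single-nucleotide variants of a seed's context.

    Returns ``(position, base, variable_region)`` triples, one per
    variant: 3 alternative bases at each of the ``12 + spacer + 2*flank``
    context positions (69 for a DR1 seed with 5-bp flanks).  Positions
    are 0-based within the context, 5'->3' on the o1 strand.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    if seed.flank_len != flank_len:
        raise ValueError(
            f"seed {seed.seed_id} has {seed.flank_len}-bp flanks, expected {flank_len}"
        )
    ctx = seed.context
    off = seed.context_offset()
    region = seed.variable_region()
    out = []
    for pos, ref in enumerate(ctx):
        for base in DNA_ALPHABET:
            if base == ref:
                continue
            var = region[: off + pos] + base + region[off + pos + 1:]
            out.append((pos, base, var))
    return out


def ablate_half_site(seed: SeedSequence, model, half: str) -> SeedSequence:
    """Knock out one half-site with a single worst-case mutation.

    The position inside the chosen half-site contributing most to the
    model score is replaced by the base with the minimal score at that
    position.  Ties in contribution resolve to the lowest position
    index; ties in penalizing base resolve alphabetically.

    ``model`` is anything exposing a per-position, per-base score array
    aligned to the seed context: an ``EnergyMatrix`` (``delta_z``), a
    ``PWM`` (``scores``), or a bare ``(L, 4)`` array.
    """
    if half not in ("5prime", "3prime"):
        raise ValueError(f"half must be '5prime' or '3prime', got {half!r}")
    mat = getattr(model, "delta_z", None)
    if mat is None:
        mat = getattr(model, "scores", None)
    if mat is None:
        mat = np.asarray(model, dtype=float)
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (seed.context_len, 4):
        raise ValueError(
            f"model shape {mat.shape} does not match seed context "
            f"({seed.context_len} positions x 4 bases)"
        )
    sl = seed.hs5_slice if half == "5prime" else seed.hs3_slice
    ctx = seed.context
    # contribution of each half-site position = score of the seed base
    # there relative to the worst base (range to the minimum)
    contribs = []
    for pos in range(sl.start, sl.stop):
        ref_i = DNA_ALPHABET.index(ctx[pos])
        contribs.append(mat[pos, ref_i] - mat[pos].min())
    rel = int(np.argmax(contribs))  # argmax takes the first (lowest) index on ties
    pos = sl.start + rel
    ref = ctx[pos]
    scores = mat[pos]
    order = np.argsort(scores, kind="stable")  # alphabetical tie-break
    new_base = next(DNA_ALPHABET[i] for i in order if DNA_ALPHABET[i] != ref)
    new_ctx = ctx[:pos] + new_base + ctx[pos + 1:]
    return seed.with_context(new_ctx, seed_id=seed.seed_id)


def _seed_consensus_model(seed: SeedSequence) -> np.ndarray:
    """One-hot score matrix preferring the seed's own bases (ablation default)."""
    mat = np.zeros((seed.context_len, 4))
    for pos, base in enumerate(seed.context):
        mat[pos, DNA_ALPHABET.index(base)] = 1.0
    return mat


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    if isinstance(genome, str) and set(genome) <= set("ACGTNacgtn"):
        return {"seq": genome.upper()}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}


def sample_background(
    genome, n: int = 500, length: int = 34, rng_seed: int = 0
) -> list[str]:
    """Draw random genomic probe sequences for the z-score background.

    Candidates containing N or any single-base run longer than three
    nucleotides are rejected.  Deterministic under ``rng_seed``.
    """
    if n == 0:
        return []
    seqs = _load_genome(genome)
    rng = np.random.default_rng(rng_seed)
    names = sorted(seqs)
    lens = np.array([len(seqs[c]) for c in names])
    eligible = lens >= length
    if not eligible.any() or lens.sum() < n * length:
        raise ValueError(
            f"genome too small: need >= {n * length} bp for {n} probes of {length} bp"
        )
    weights = np.where(eligible, lens - length + 1, 0).astype(float)
    weights /= weights.sum()
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * n
    while len(out) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"insufficient eligible genome sequence: found {len(out)} of {n} "
                f"probes after {attempts} draws"
            )
        attempts += 1
        chrom = names[rng.choice(len(names), p=weights)]
        start = int(rng.integers(0, len(seqs[chrom]) - length + 1))
        cand = seqs[chrom][start:start + length]
        if "N" in cand or has_long_run(cand) or cand in seen:
            continue
        seen.add(cand)
        out.append(cand)
    return out


def generate_seeds(
    n_per_spacer: int = 24,
    spacer_range: tuple[int, int] = (0, 5),
    flank_len: int = 5,
    rng_seed: int = 0,
    consensus5: str | None = HALF_SITE_CONSENSUS,
    consensus3: str | None = HALF_SITE_CONSENSUS,
    mutation_counts: tuple[int, ...] = (0, 1, 2),
    mutation_probs: tuple[float, ...] = (0.4, 0.4, 0.2),
    min_hamming: int = 3,
    avoid5: str | None = None,
    avoid3: str | None = None,
    avoid_mismatch: int = 3,
    flank5_consensus: str | None = None,
    flank3_consensus: str | None = None,
) -> list[SeedSequence]:
    """Generate direct-repeat seeds spanning a range of degeneracy.

    Half-sites start from an IUPAC consensus (default RGKTCA) and
    receive 0-2 additional mutations; a consensus of ``None`` yields
    fully random half-sites.  A random half can be forced away from a
    given consensus (``avoid5``/``avoid3``, at least ``avoid_mismatch``
    mismatches) so that it cannot act as a binding site itself.  Within
    each spacer stratum, seed contexts are kept at pairwise Hamming
    distance >= ``min_hamming`` so that no SNV of one seed collides
    with another seed or its SNVs.
    """
    rng = np.random.default_rng(rng_seed)
    seeds: list[SeedSequence] = []
    for spacer_len in range(spacer_range[0], spacer_range[1] + 1):
        stratum: list[SeedSequence] = []
        tries = 0
        while len(stratum) < n_per_spacer:
            tries += 1
            if tries > 5000 * n_per_spacer:
                raise RuntimeError("could not generate enough distinct seeds")
            hs5 = _draw_half(consensus5, rng, mutation_counts, mutation_probs,
                             avoid=avoid5, avoid_mismatch=avoid_mismatch)
            hs3 = _draw_half(consensus3, rng, mutation_counts, mutation_probs,
                             avoid=avoid3, avoid_mismatch=avoid_mismatch)
            cand = SeedSequence(
                seed_id=f"DR{spacer_len}.{len(stratum) + 1}",
                hs5=hs5,
                hs3=hs3,
                spacer=random_dna(spacer_len, rng),
                flank5=_draw_flank(flank5_consensus, flank_len, rng),
                flank3=_draw_flank(flank3_consensus, flank_len, rng),
            )
            if all(_hamming(cand.context, s.context) >= min_hamming for s in stratum):
                stratum.append(cand)
        seeds.extend(stratum)
    return seeds


def _draw_half(consensus, rng, mut_counts, mut_probs,
               avoid=None, avoid_mismatch=3) -> HalfSite:
    if consensus is None:
        while True:
            cand = random_dna(HALF_SITE_LEN, rng)
            if avoid is None or (
                _hamming(cand, avoid) >= avoid_mismatch
                and _hamming(revcomp(cand), avoid) >= avoid_mismatch
            ):
                return HalfSite(cand)
    base = sample_from_consensus(consensus, rng)
    k = int(rng.choice(mut_counts, p=np.asarray(mut_probs) / np.sum(mut_probs)))
    positions = rng.choice(HALF_SITE_LEN, size=k, replace=False)
    chars = list(base)
    for p in positions:
        alt = [b for b in DNA_ALPHABET if b != chars[p]]
        chars[p] = alt[rng.integers(3)]
    return HalfSite("".join(chars))


def _draw_flank(consensus: str | None, flank_len: int, rng) -> str:
    """Flank drawn from a consensus with 0-1 mutations, or fully random."""
    if consensus is None:
        return random_dna(flank_len, rng)
    chars = list(sample_from_consensus(consensus, rng))
    if len(chars) != flank_len:
        raise ValueError("flank consensus length must equal flank_len")
    if rng.random() < 0.5:
        p = int(rng.integers(flank_len))
        alts = [b for b in DNA_ALPHABET if b != chars[p]]
        chars[p] = alts[rng.integers(3)]
    return "".join(chars)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ProbeLibrary:
    """The expanded probe set plus its seeds and design parameters.

    ``probes`` is one row per physical probe with columns:
    probe_id, seed_id, category, variant_position, variant_base,
    spacer_len, orientation, replicate_index, sequence (o1 frame, used
    as the unique-sequence key), variable_region (as printed; the
    reverse complement for o2), primer_region.
    """

    probes: pd.DataFrame
    seeds: dict[str, SeedSequence]
    params: DesignParams = field(default_factory=DesignParams)

    def unique_sequences(self, categories: tuple[str, ...] | None = None) -> pd.Index:
        df = self.probes
        if categories is not None:
            df = df[df["category"].isin(categories)]
        return pd.Index(df["sequence"].unique())

    def seed_snv_count(self, spacer_len: int | None = None) -> int:
        """Number of unique seed + SNV sequences (optionally one stratum)."""
        df = self.probes[self.probes["category"].isin(("seed", "snv"))]
        if spacer_len is not None:
            df = df[df["spacer_len"] == spacer_len]
        return df["sequence"].nunique()

    def category_counts(self) -> pd.DataFrame:
        return (
            self.probes.groupby("category")["sequence"]
            .nunique()
            .rename("unique_sequences")
            .to_frame()
        )

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.probes.to_csv(path, sep="\t", index=False)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            seen = set()
            for row in self.probes.itertuples():
                if row.sequence in seen:
                    continue
                seen.add(row.sequence)
                name = row.seed_id if isinstance(row.seed_id, str) else "background"
                fh.write(f">{name}|{row.category}|{len(seen)}\n{row.sequence}\n")


def build_library(
    seeds: list[SeedSequence],
    params: DesignParams = DesignParams(),
    background_sequences: list[str] | None = None,
    genome=None,
    ablation_model=None,
    rng_seed: int = 0,
) -> ProbeLibrary:
    """Assemble the full probe library from seeds.

    Requires ``params.seeds_per_spacer`` distinct seeds at every spacer
    length in ``params.spacer_range``; any SNV-sequence collision
    between two seeds is an error naming the pair.  Background probes
    come from ``background_sequences`` or are sampled from ``genome``.
    """
    by_spacer: dict[int, list[SeedSequence]] = {}
    for s in seeds:
        by_spacer.setdefault(s.spacer_len, []).append(s)
    for spacer_len in params.spacers:
        got = len(by_spacer.get(spacer_len, []))
        if got < params.seeds_per_spacer:
            raise ValueError(
                f"need {params.seeds_per_spacer} seeds at spacer length "
                f"{spacer_len}, got {got}"
            )
    ids = [s.seed_id for s in seeds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seed_id in seed list")

    if background_sequences is None:
        if genome is None:
            raise ValueError("provide background_sequences or a genome to sample from")
        background_sequences = sample_background(
            genome, n=params.n_background, rng_seed=rng_seed
        )

    # unique sequences per seed, with collision check across seeds
    owner: dict[str, str] = {}
    rows: list[dict] = []

    def claim(seq: str, seed_id: str):
        prev = owner.get(seq)
        if prev is not None and prev != seed_id:
            raise ValueError(
                f"probe sequence collision between seeds {prev!r} and {seed_id!r}"
            )
        owner[seq] = seed_id

    for seed in seeds:
        seq = seed.variable_region()
        claim(seq, seed.seed_id)
        rows.append(dict(seed_id=seed.seed_id, category="seed",
                         variant_position=None, variant_base=None,
                         spacer_len=seed.spacer_len, sequence=seq))
        for pos, base, var in enumerate_snv_probes(seed, params.flank_len):
            claim(var, seed.seed_id)
            rows.append(dict(seed_id=seed.seed_id, category="snv",
                             variant_position=pos, variant_base=base,
                             spacer_len=seed.spacer_len, sequence=var))
        model = ablation_model or _seed_consensus_model(seed)
        for half, cat in (("5prime", "ablation_5"), ("3prime", "ablation_3")):
            abl = ablate_half_site(seed, model, half)
            # single-base ablations coincide with one SNV sequence by
            # construction; they are carried as their own probe records
            diff = [i for i, (a, b) in enumerate(zip(abl.context, seed.context)) if a != b]
            rows.append(dict(seed_id=seed.seed_id, category=cat,
                             variant_position=diff[0],
                             variant_base=abl.context[diff[0]],
                             spacer_len=seed.spacer_len,
                             sequence=abl.variable_region()))
    for i, bg in enumerate(background_sequences):
        validate_dna(bg, f"background sequence {i}")
        rows.append(dict(seed_id=None, category="background",
                         variant_position=None, variant_base=None,
                         spacer_len=None, sequence=bg))

    base_df = pd.DataFrame(rows)
    # replicate / orientation expansion
    expanded = []
    for row in base_df.itertuples(index=False):
        reps = params.reps_snv if row.category == "snv" else params.reps_other
        for orientation in ORIENTATIONS:
            printed = row.sequence if orientation == "o1" else revcomp(row.sequence)
            for rep in range(1, reps + 1):
                expanded.append(row._asdict() | dict(
                    orientation=orientation,
                    replicate_index=rep,
                    variable_region=printed,
                ))
    probes = pd.DataFrame(expanded)
    bg_idx = probes.groupby("sequence", sort=False).ngroup()
    tag = probes["seed_id"].where(
        probes["seed_id"].notna(), "bg" + bg_idx.astype(str).str.zfill(4)
    )
    pos = probes["variant_position"].map(lambda v: "" if pd.isna(v) else f"_p{int(v)}")
    base = probes["variant_base"].fillna("")
    probes["probe_id"] = (
        tag
        + "_" + probes["category"]
        + pos + base
        + "_" + probes["orientation"]
        + "_r" + probes["replicate_index"].astype(str)
    )
    if probes["probe_id"].duplicated().any():
        dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"non-unique probe identifier generated: {dup}")
    probes["primer_region"] = DOUBLE_STRANDING_PRIMER
    cols = ["probe_id", "seed_id", "category", "variant_position", "variant_base",
            "spacer_len", "orientation", "replicate_index", "sequence",
            "variable_region", "primer_region"]
    return ProbeLibrary(
        probes=probes[cols].reset_index(drop=True),
        seeds={s.seed_id: s for s in seeds},
        params=params,
    )
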