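"""DNA sequence primitives for direct-repeat binding-site analysis.

Nuclear-receptor heterodimers bind direct repeats (DRs): two 6-bp
half-sites (consensus RGKTCA) separated by a 0-5 bp spacer.  A "seed"
is one concrete DR site with fixed flanking sequence, anchored inside
the 34-nt variable region of a microarray probe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

DNA_ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate nucleotide codes (used when sampling from a consensus).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

HALF_SITE_LEN = 6
#: Canonical nuclear-receptor half-site consensus.
HALF_SITE_CONSENSUS = "RGKTCA"

VARIABLE_REGION_LEN = 34
PRIMER_REGION_LEN = 24
#: Constant primer used for array double-stranding (fixture constant; the
#: primer never enters any analysis).
DOUBLE_STRANDING_PRIMER = "CCTTCATTCTACGCTGTCAATCGC"
#: 5' dinucleotide cap outside the variable region (excluded from analysis).
GC_CAP = "GC"

# Fixed neutral padding used to centre a DR context inside the 34-nt
# variable region.  Every 6-bp window is at least 3 mismatches from the
# RGKTCA half-site consensus on both strands, and there are no
# homopolymer runs.
_FILLER = "CTAGCCATTCTGCGCAACACTCAT"

_RUN_RE = re.compile(r"(.)\1{3,}")


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Check that ``seq`` is uppercase ACGT; return it unchanged."""
    if not isinstance(seq, str) or any(c not in BASE_INDEX for c in seq):
        raise ValueError(f"{name} must be an uppercase ACGT string, got {seq!r}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as integers A=0, C=1, G=2, T=3, other=4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def has_long_run(seq: str, max_run: int = 3) -> bool:
    """True if any single base repeats more than ``max_run`` times in a row."""
    if max_run != 3:
        return re.search(r"(.)\1{%d,}" % max_run, seq) is not None
    return _RUN_RE.search(seq) is not None


def sample_from_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Draw one concrete ACGT sequence from an IUPAC consensus."""
    out = []
    for c in consensus.upper():
        choices = IUPAC.get(c)
        if choices is None:
            raise ValueError(f"unknown IUPAC code {c!r}")
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1 else choices)
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


class HalfSite(str):
    """A 6-bp nuclear-receptor half-site (uppercase ACGT)."""

    def __new__(cls, bases: str) -> "HalfSite":
        validate_dna(bases, "half-site")
        if len(bases) != HALF_SITE_LEN:
            raise ValueError(f"half-site must be {HALF_SITE_LEN} bp, got {len(bases)}")
        return super().__new__(cls, bases)

    @property
    def bases(self) -> str:
        return str(self)


@dataclass(frozen=True)
class SeedSequence:
    """A direct-repeat seed: flank5 + hs5 + spacer + hs3 + flank3.

    Coordinates throughout the package are 0-based within this context,
    read 5'->3' on the primary (o1) probe strand.
    """

    seed_id: str
    hs5: HalfSite
    spacer: str
    hs3: HalfSite
    flank5: str = "GTCTA"
    flank3: str = "TAGAC"

    def __post_init__(self) -> None:
        object.__setattr__(self, "hs5", HalfSite(self.hs5))
        object.__setattr__(self, "hs3", HalfSite(self.hs3))
        validate_dna(self.spacer, "spacer")
        validate_dna(self.flank5, "flank5")
        validate_dna(self.flank3, "flank3")
        if not 0 <= len(self.spacer) <= 5:
            raise ValueError(f"spacer must be 0-5 bp, got {len(self.spacer)}")
        if len(self.flank5) != len(self.flank3):
            raise ValueError("flank5 and flank3 must have equal length")

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)

    @property
    def flank_len(self) -> int:
        return len(self.flank5)

    @property
    def site(self) -> str:
        """The 12+S bp direct-repeat site (no flanks)."""
        return self.hs5 + self.spacer + self.hs3

    @property
    def site_len(self) -> int:
        return 2 * HALF_SITE_LEN + self.spacer_len

    @property
    def context(self) -> str:
        """The full assayed context: flanks + site (22+S bp at flank_len=5)."""
        return self.flank5 + self.site + self.flank3

    @property
    def context_len(self) -> int:
        return self.site_len + 2 * self.flank_len

    # --- slices into ``context`` coordinates -------------------------------
    @property
    def hs5_slice(self) -> slice:
        return slice(self.flank_len, self.flank_len + HALF_SITE_LEN)

    @property
    def spacer_slice(self) -> slice:
        start = self.flank_len + HALF_SITE_LEN
        return slice(start, start + self.spacer_len)

    @property
    def hs3_slice(self) -> slice:
        start = self.flank_len + HALF_SITE_LEN + self.spacer_len
        return slice(start, start + HALF_SITE_LEN)

    def variable_region(self, total_len: int = VARIABLE_REGION_LEN) -> str:
        """Centre the context inside the probe variable region.

        Remaining positions are filled with a fixed neutral sequence so
        that two seeds differ only where their contexts differ.
        """
        ctx = self.context
        pad = total_len - len(ctx)
        if pad < 0:
            raise ValueError(
                f"context ({len(ctx)} bp) longer than variable region ({total_len} bp)"
            )
        left = pad // 2
        right = pad - left
        return _FILLER[:left] + ctx + _FILLER[len(_FILLER) - right:]

    def context_offset(self, total_len: int = VARIABLE_REGION_LEN) -> int:
        """Start of the context within the variable region."""
        return (total_len - self.context_len) // 2

    def with_context(self, new_context: str, seed_id: str | None = None) -> "SeedSequence":
        """Return a copy whose context string is replaced position-for-position."""
        if len(new_context) != self.context_len:
            raise ValueError("replacement context has wrong length")
        f = self.flank_len
        s = self.spacer_len
        return SeedSequence(
            seed_id=seed_id or self.seed_id,
            hs5=HalfSite(new_context[f:f + 6]),
            spacer=new_context[f + 6:f + 6 + s],
            hs3=HalfSite(new_context[f + 6 + s:f + 12 + s]),
            flank5=new_context[:f],
            flank3=new_context[f + 12 + s:],
        )
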