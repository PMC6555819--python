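"""PWM enrichment of binding sites in genomic regions (ROC analysis).

Bound (true-positive) regions and size-matched unbound (true-negative)
regions are each scored with a PWM (best window over both strands);
discrimination is summarized as the area under the ROC curve, with the
equivalent Wilcoxon-Mann-Whitney rank-sum test (continuity-corrected,
Bonferroni-adjusted across the motif models tested) for significance.
All interval coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from sklearn.metrics import roc_curve

from .motifs import PWM
from .sequences import encode, revcomp

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def validate_regions(df: pd.DataFrame) -> pd.DataFrame:
    if "chrom" not in df or "start" not in df or "end" not in df:
        raise ValueError("region table needs chrom/start/end columns")
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return validate_regions(df)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def reciprocal_overlap(
    a: pd.DataFrame, b: pd.DataFrame, frac: float = 0.5
) -> pd.DataFrame:
    """Intervals of ``a`` with a partner in ``b`` at reciprocal overlap.

    Retained when some b-interval overlaps by at least ``frac`` of the
    a-interval's length AND ``frac`` of the b-interval's length
    (boundary inclusive).
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    validate_regions(a)
    validate_regions(b)
    trees = _trees(b)
    keep = []
    for idx, row in enumerate(a.itertuples()):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        len_a = row.end - row.start
        for hit in tree.overlap(row.start, row.end):
            ov = min(row.end, hit.end) - max(row.start, hit.begin)
            if ov >= frac * len_a and ov >= frac * (hit.end - hit.begin):
                keep.append(idx)
                break
    return a.iloc[keep].reset_index(drop=True)


def subtract_regions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Remove every base covered by ``b`` from the intervals of ``a``."""
    validate_regions(a)
    validate_regions(b)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in b.itertuples():
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out = []
    for row in a.itertuples():
        pieces = [(row.start, row.end)]
        for bs, be in by_chrom.get(row.chrom, []):
            if bs >= row.end:
                break
            nxt = []
            for s, e in pieces:
                if be <= s or bs >= e:
                    nxt.append((s, e))
                    continue
                if s < bs:
                    nxt.append((s, bs))
                if be < e:
                    nxt.append((be, e))
            pieces = nxt
        for s, e in pieces:
            if e > s:
                out.append(dict(chrom=row.chrom, start=s, end=e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def build_negatives(
    dnase: pd.DataFrame,
    chip: pd.DataFrame,
    positives: pd.DataFrame,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Size-matched negative regions from ChIP-subtracted open chromatin.

    One negative per positive, of identical length, drawn uniformly
    over all eligible placements within ``dnase`` minus ``chip``.
    """
    eligible = subtract_regions(validate_regions(dnase), validate_regions(chip))
    validate_regions(positives)
    if eligible.empty:
        raise ValueError("no eligible sequence after ChIP subtraction")
    elig_len = (eligible["end"] - eligible["start"]).to_numpy()
    rng = np.random.default_rng(rng_seed)
    rows = []
    deficit = 0
    for row in positives.itertuples():
        L = row.end - row.start
        slots = elig_len - L + 1
        ok = slots > 0
        if not ok.any():
            deficit += 1
            continue
        w = np.where(ok, slots, 0).astype(float)
        pick = int(rng.choice(len(eligible), p=w / w.sum()))
        er = eligible.iloc[pick]
        start = int(er["start"] + rng.integers(0, elig_len[pick] - L + 1))
        rows.append(dict(chrom=er["chrom"], start=start, end=start + L,
                         name=f"neg_{len(rows)}"))
    if deficit:
        raise ValueError(
            f"could not size-match {deficit} positives: eligible regions too short"
        )
    return pd.DataFrame(rows)


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}


def extract_sequences(regions: pd.DataFrame, genome) -> list[str]:
    seqs = _load_genome(genome)
    out = []
    for row in regions.itertuples():
        if row.chrom not in seqs:
            raise KeyError(f"chromosome {row.chrom!r} not in genome")
        out.append(seqs[row.chrom][row.start:row.end])
    return out


def score_region(sequence: str, pwm: PWM, agg: str = "max") -> float:
    """PWM score of a region: best (or summed) window over both strands.

    Ambiguous bases (N) contribute a log-odds of 0, i.e. they are
    scored at background probability.
    """
    return float(score_sequences([sequence], pwm, agg=agg)[0])


def score_sequences(seqs: list[str], pwm: PWM, agg: str = "max") -> np.ndarray:
    if agg not in ("max", "sum"):
        raise ValueError(f"agg must be 'max' or 'sum', got {agg!r}")
    k = pwm.length
    S = np.vstack([pwm.scores.T, np.zeros(k)]).T  # 5th row: N -> 0 bits
    out = np.empty(len(seqs))
    for i, seq in enumerate(seqs):
        seq = seq.upper()
        if len(seq) < k:
            raise ValueError(
                f"sequence of length {len(seq)} shorter than motif ({k})"
            )
        best = []
        for strand_seq in (seq, revcomp(seq)):
            enc = encode(strand_seq)
            wins = sliding_window_view(enc, k)
            scores = S[np.arange(k), wins].sum(axis=1)
            best.append(scores)
        allw = np.concatenate(best)
        out[i] = allw.max() if agg == "max" else allw.sum()
    return out


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    u_statistic: float
    p_value: float
    p_adjusted: float
    curve: pd.DataFrame

    def to_dict(self) -> dict:
        return dict(auc=self.auc, n_pos=self.n_pos, n_neg=self.n_neg,
                    u_statistic=self.u_statistic, p_value=self.p_value,
                    p_adjusted=self.p_adjusted)


def roc_auc(
    pos_scores,
    neg_scores,
    n_models_for_bonferroni: int = 1,
) -> ROCResult:
    """AUC with rank-sum significance for bound vs unbound scores.

    AUC is the probability a positive outscores a negative (ties count
    half), identically U / (n_pos * n_neg); the two-sided
    Wilcoxon-Mann-Whitney p-value uses the normal approximation with
    continuity correction, Bonferroni-multiplied by the number of motif
    models tested in the run.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    auc = float(res.statistic) / (pos.size * neg.size)
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thr = roc_curve(labels, np.concatenate([pos, neg]))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return ROCResult(
        auc=auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_adjusted=float(min(1.0, res.pvalue * n_models_for_bonferroni)),
        curve=curve,
    )


GEOMETRIES = ("upstream_only", "up_and_down")


def active_peak_filter(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    de_genes,
    window: int = 10_000,
    geometry: str = "upstream_only",
) -> pd.DataFrame:
    """Peaks near differentially expressed genes ("active" regions).

    Retains peaks overlapping the strand-aware ``window`` upstream of
    any DE gene's TSS: for a +-strand gene at position p the window is
    [p - window, p); for a --strand gene it is [p, p + window).
    ``up_and_down`` uses [p - window, p + window) regardless of strand.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; choose from {GEOMETRIES}")
    validate_regions(peaks)
    de = set(de_genes)
    windows: dict[str, IntervalTree] = {}
    for row in tss.itertuples():
        if row.gene not in de:
            continue
        p = int(row.position)
        if geometry == "up_and_down":
            lo, hi = p - window, p + window
        elif row.strand == "+":
            lo, hi = p - window, p
        elif row.strand == "-":
            lo, hi = p, p + window
        else:
            raise ValueError(
                f"gene {row.gene!r} lacks a strand; required for upstream geometry"
            )
        lo = max(lo, 0)
        if hi > lo:
            windows.setdefault(row.chrom, IntervalTree()).addi(lo, hi)
    keep = []
    for idx, row in enumerate(peaks.itertuples()):
        tree = windows.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end):
            keep.append(idx)
    return peaks.iloc[keep].reset_index(drop=True)
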