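"""Fluorescence-to-z-score conversion for SNV microarray data.

Raw per-probe intensities are log-transformed, replicate-averaged per
unique probe sequence (one orientation by default), and standardized
against the mean and standard deviation of the 500 random genomic
background probes measured on the same array:

    z = (x - mu_bg) / sd_bg

so background sequences have mean z of about 0 and sd of about 1 by
construction.  Cross-array scaling uses a median-equalization stand-in
for the full microarray linear-regression normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_BACKGROUND_PROBES = 10


@dataclass
class BindingProfile:
    """Replicate-averaged z-scores per unique probe sequence.

    ``data`` columns: sequence, seed_id, category, variant_position,
    variant_base, spacer_len, mean_z, n_replicates.
    """

    data: pd.DataFrame
    bg_mean: float
    bg_sd: float
    orientation: tuple[str, ...] = ("o1",)
    scale: str = "log"

    def z_for_seed(self, seed_id: str) -> pd.DataFrame:
        return self.data[self.data["seed_id"] == seed_id]

    def zmax_for_seed(self, seed_id: str) -> float:
        """Maximum replicate-averaged z over the seed probe and its SNVs."""
        df = self.z_for_seed(seed_id)
        df = df[df["category"].isin(("seed", "snv"))]
        if df.empty:
            raise KeyError(f"no seed/SNV rows for {seed_id!r}")
        return float(df["mean_z"].max())

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# background_mean={self.bg_mean:.6g} "
                     f"background_sd={self.bg_sd:.6g} "
                     f"orientation={','.join(self.orientation)} scale={self.scale}\n")
            self.data.to_csv(fh, sep="\t", index=False)


def read_fluorescence(path) -> pd.DataFrame:
    """Read a (probe_id, intensity[, array_id]) tab-separated table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "probe_id" not in df or "intensity" not in df:
        raise ValueError("fluorescence table needs probe_id and intensity columns")
    return df


def scale_arrays(tables: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Equalize median log-intensities across arrays over shared probes.

    A simplified cross-array normalization: each array is rescaled by a
    single multiplicative factor so that its median log-intensity over
    the probes shared by all arrays matches the across-array mean.
    Rank order within each array is preserved exactly.
    """
    if not tables:
        raise ValueError("need at least one array")
    if len(tables) == 1:
        return [tables[0].copy()]
    shared = set(tables[0]["probe_id"])
    for t in tables[1:]:
        shared &= set(t["probe_id"])
    if not shared:
        raise ValueError("arrays share no probes; cannot scale")
    medians = []
    for t in tables:
        vals = t.loc[t["probe_id"].isin(shared), "intensity"].to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("intensities must be positive for log scaling")
        medians.append(np.median(np.log(vals)))
    target = float(np.mean(medians))
    out = []
    for t, m in zip(tables, medians):
        scaled = t.copy()
        scaled["intensity"] = scaled["intensity"] * np.exp(target - m)
        out.append(scaled)
    return out


def compute_zscores(
    table: pd.DataFrame,
    library,
    orientation: tuple[str, ...] = ("o1",),
    scale: str = "log",
    summary: str = "mean",
    min_background: int = MIN_BACKGROUND_PROBES,
) -> BindingProfile:
    """Convert raw probe intensities into a per-sequence binding profile.

    Intensities are log-transformed (``scale='linear'`` skips the log),
    replicate-averaged per unique sequence over the requested probe
    orientation(s), and z-scored against the background-probe mean/sd
    on the same scale.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"scale must be 'log' or 'linear', got {scale!r}")
    if summary not in ("mean", "median"):
        raise ValueError(f"summary must be 'mean' or 'median', got {summary!r}")
    probes = library.probes
    merged = table.merge(
        probes[["probe_id", "sequence", "seed_id", "category",
                "variant_position", "variant_base", "spacer_len", "orientation",
                "replicate_index"]],
        on="probe_id",
        how="inner",
    )
    if merged.empty:
        raise ValueError("no probe_ids in the table match the library")
    merged = merged[merged["orientation"].isin(orientation)]
    if merged.empty:
        raise ValueError(f"no probes with orientation {orientation}")
    x = merged["intensity"].to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative intensities")
    if scale == "log":
        if (x <= 0).any():
            raise ValueError("zero intensities cannot be log-transformed")
        merged = merged.assign(value=np.log(x))
    else:
        merged = merged.assign(value=x)

    agg = (
        merged.groupby("sequence", sort=False)
        .agg(
            value=("value", summary),
            n_replicates=("value", "size"),
            seed_id=("seed_id", "first"),
            category=("category", "first"),
            variant_position=("variant_position", "first"),
            variant_base=("variant_base", "first"),
            spacer_len=("spacer_len", "first"),
        )
        .reset_index()
    )
    exp_reps = np.where(agg["category"] == "snv",
                        library.params.reps_snv, library.params.reps_other)
    exp_reps = exp_reps * len(orientation)
    short = agg["n_replicates"] < exp_reps
    if short.any():
        warnings.warn(
            f"{int(short.sum())} unique sequences have fewer replicates than "
            "designed; averaging over those available",
            stacklevel=2,
        )
    bg = agg[agg["category"] == "background"]
    if len(bg) < min_background:
        raise ValueError(
            f"only {len(bg)} background sequences observed; need >= {min_background}"
        )
    mu = float(bg["value"].mean())
    sd = float(bg["value"].std(ddof=1))
    if sd <= 0:
        raise ValueError("background standard deviation is zero")
    agg["mean_z"] = (agg["value"] - mu) / sd
    cols = ["sequence", "seed_id", "category", "variant_position", "variant_base",
            "spacer_len", "mean_z", "n_replicates"]
    return BindingProfile(
        data=agg[cols],
        bg_mean=mu,
        bg_sd=sd,
        orientation=tuple(orientation),
        scale=scale,
    )


def concordance(a: BindingProfile, b: BindingProfile) -> float:
    """Squared Pearson correlation of mean z over shared sequences."""
    merged = a.data[["sequence", "mean_z"]].merge(
        b.data[["sequence", "mean_z"]], on="sequence", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared sequences; need >= 3")
    r, _ = stats.pearsonr(merged["mean_z_a"], merged["mean_z_b"])
    return float(r * r)
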