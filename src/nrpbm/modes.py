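"""Binding-mode classification and spacer-preference landscapes.

A heterodimer can engage a direct repeat through both half-sites
("full-site" mode) or through only one ("half-site" mode).  The
classifier reads this off the delta-z energy matrix: a half-site is
engaged when single-base changes inside it perturb binding.  The
engagement score of half h is

    perturbation_h = sum over h's six core positions of
                     (max_base delta_z - min_base delta_z),

and h counts as engaged when perturbation_h >= engage_abs (z-units)
and >= engage_frac of the two halves' summed perturbation.  Seeds whose
maximum z (over the seed and its SNVs) falls below ``z_threshold`` are
unbound ("none"); flank positions inform logos but not mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import EnergyMatrix
from .sequences import SeedSequence

MODES = ("full", "5prime_half", "3prime_half", "none")

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_ENGAGE_FRAC = 0.25
DEFAULT_ENGAGE_ABS = 2.0


@dataclass(frozen=True)
class ModeCall:
    seed_id: str
    spacer_len: int
    mode: str
    zmax: float
    perturbation_5: float
    perturbation_3: float


def classify_mode(
    em: EnergyMatrix,
    seed: SeedSequence | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    engage_frac: float = DEFAULT_ENGAGE_FRAC,
    engage_abs: float = DEFAULT_ENGAGE_ABS,
) -> ModeCall:
    """Classify one seed's binding mode from its delta-z matrix.

    Both-halves-engaged -> ``full``; exactly one -> that half's mode;
    zmax below ``z_threshold`` -> ``none``.  The degenerate case where
    neither half clears ``engage_abs`` despite above-threshold binding
    resolves to ``full`` (binding unperturbed by any single variant is
    treated as canonical engagement of the whole site).
    """
    seed = seed or em.seed
    if em.delta_z.shape[0] != seed.context_len:
        raise ValueError("energy matrix does not match seed geometry")
    ranges = em.delta_z.max(axis=1) - em.delta_z.min(axis=1)
    p5 = float(ranges[seed.hs5_slice].sum())
    p3 = float(ranges[seed.hs3_slice].sum())
    total = p5 + p3
    eng5 = p5 >= engage_abs and (total == 0 or p5 >= engage_frac * total)
    eng3 = p3 >= engage_abs and (total == 0 or p3 >= engage_frac * total)
    if em.zmax < z_threshold:
        mode = "none"
    elif eng5 and eng3:
        mode = "full"
    elif eng5:
        mode = "5prime_half"
    elif eng3:
        mode = "3prime_half"
    else:
        mode = "full"
    return ModeCall(seed_id=seed.seed_id, spacer_len=seed.spacer_len,
                    mode=mode, zmax=float(em.zmax),
                    perturbation_5=p5, perturbation_3=p3)


def spacer_landscape(
    calls: list[ModeCall],
    nr_id: str = "NR",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Spacer-preference landscape: one row per above-threshold seed.

    Columns: nr_id, spacer_len, seed_id, zmax, mode.  Seeds with
    zmax below the threshold are not represented.
    """
    rows = [
        dict(nr_id=nr_id, spacer_len=c.spacer_len, seed_id=c.seed_id,
             zmax=c.zmax, mode=c.mode)
        for c in calls
        if c.zmax >= z_threshold
    ]
    df = pd.DataFrame(rows, columns=["nr_id", "spacer_len", "seed_id", "zmax", "mode"])
    return df.sort_values(["spacer_len", "zmax"], ascending=[True, False],
                          ignore_index=True)


def landscape_summary(landscape: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics of zmax per (spacer_len, mode) stratum.

    Whiskers extend to the most extreme points within 1.5 x IQR of the
    quartiles.
    """
    out = []
    for (spacer, mode), grp in landscape.groupby(["spacer_len", "mode"]):
        z = grp["zmax"].to_numpy()
        q1, med, q3 = np.percentile(z, [25, 50, 75])
        iqr = q3 - q1
        lo = z[z >= q1 - 1.5 * iqr].min()
        hi = z[z <= q3 + 1.5 * iqr].max()
        out.append(dict(spacer_len=spacer, mode=mode, n=len(z), median=med,
                        q1=q1, q3=q3, whisker_low=lo, whisker_high=hi))
    return pd.DataFrame(out)


def mode_transitions(
    calls_a: list[ModeCall], calls_b: list[ModeCall]
) -> pd.DataFrame:
    """4x4 seed counts moving from mode in condition A to mode in B.

    Rows index the mode in A, columns the mode in B; the grand total
    equals the number of shared seeds.
    """
    a = {c.seed_id: c.mode for c in calls_a}
    b = {c.seed_id: c.mode for c in calls_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise ValueError(
            f"seed sets differ: only in A {only_a[:5]}, only in B {only_b[:5]}"
        )
    mat = pd.DataFrame(0, index=list(MODES), columns=list(MODES))
    for seed_id, mode_a in a.items():
        mat.loc[mode_a, b[seed_id]] += 1
    return mat
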