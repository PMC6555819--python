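"""End-to-end orchestration: config, staged runs, provenance, reports.

A run executes design -> simulate (or load) -> normalize -> motifs ->
modes (-> enrich) in order, writing each stage's tables into a run
directory.  Every table header carries the package version and a hash
of the configuration, so identical configs reproduce identical
non-stochastic outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import roc_auc, score_sequences, extract_sequences
from .modes import classify_mode, landscape_summary, spacer_landscape
from .motifs import (
    HT29_BACKGROUND,
    UNIFORM_BACKGROUND,
    average_pfms,
    delta_z_matrix,
    pfm_for_seed,
    pwm_from_pfm,
    write_meme,
)
from .normalization import compute_zscores
from .probe_design import DesignParams
from .synthetic import (
    NoiseModel,
    make_scenario,
    simulate_fluorescence,
    simulate_genomic_benchmark,
)

log = logging.getLogger("nrpbm")

_ALLOWED = {
    "run_name": None,
    "seed": None,
    "design": {"seeds_per_spacer", "spacer_range", "flank_len", "reps_snv",
               "reps_other", "n_background"},
    "simulate": {"scenario", "sigma", "orientation_bias"},
    "normalize": {"orientation", "scale", "summary"},
    "motifs": {"beta_numerator", "background", "pseudocount"},
    "modes": {"z_threshold", "engage_frac", "engage_abs"},
    "enrich": {"enabled", "n_pos", "n_neg", "region_len", "planted_fraction",
               "n_models"},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    raw: dict

    def __post_init__(self) -> None:
        for key, val in self.raw.items():
            if key not in _ALLOWED:
                raise ValueError(f"unknown config key {key!r}")
            allowed = _ALLOWED[key]
            if allowed is not None:
                if not isinstance(val, dict):
                    raise ValueError(f"config section {key!r} must be a mapping")
                extra = set(val) - allowed
                if extra:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(extra)}")
        if "seed" not in self.raw:
            raise ValueError("config requires an explicit top-level 'seed'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nrpbm {__version__} stage={stage} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    (out / "config.yaml").write_text(yaml.safe_dump(config.raw, sort_keys=True))
    rng = np.random.default_rng(config.seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    stage = "design"
    try:
        d = config.section("design")
        if "spacer_range" in d:
            d["spacer_range"] = tuple(d["spacer_range"])
        params = DesignParams(**d)
        sim_cfg = config.section("simulate")
        scenario = make_scenario(
            sim_cfg.get("scenario", "full"),
            rng_seed=sub(),
            n_per_spacer=params.seeds_per_spacer,
            spacer_range=params.spacer_range,
            sigma=float(sim_cfg.get("sigma", 0.1)),
            n_background=params.n_background,
        )
        library = scenario.library
        _write_table(library.probes, out / "library.tsv", cfg_hash, stage)
        library.to_fasta(out / "library.fasta")

        stage = "simulate"
        noise = scenario.noise
        if "orientation_bias" in sim_cfg:
            noise = NoiseModel(noise.lognormal_sigma, noise.replicate_count,
                               float(sim_cfg["orientation_bias"]))
        fluor, truth = simulate_fluorescence(library, scenario.model, noise,
                                             rng_seed=sub())
        _write_table(fluor, out / "fluorescence.tsv", cfg_hash, stage)
        _write_table(truth, out / "truth_occupancy.tsv", cfg_hash, stage)

        stage = "normalize"
        n = config.section("normalize")
        profile = compute_zscores(
            fluor, library,
            orientation=tuple(n.get("orientation", ("o1",))),
            scale=n.get("scale", "log"),
            summary=n.get("summary", "mean"),
        )
        profile.to_tsv(out / "zscores.tsv", [f"nrpbm {__version__} "
                                             f"stage=normalize config={cfg_hash}"])

        stage = "motifs"
        m = config.section("motifs")
        beta_num = float(m.get("beta_numerator", 15.0))
        z_thr = float(config.section("modes").get("z_threshold", 3.0))
        pfms, ems = {}, {}
        for seed_id, seed in library.seeds.items():
            if profile.zmax_for_seed(seed_id) < z_thr:
                continue
            pfms[seed_id] = pfm_for_seed(profile, seed, beta_num)
            ems[seed_id] = delta_z_matrix(profile, seed)
        if pfms:
            write_meme(list(pfms.values()), out / "seed_pfms.meme")

        stage = "modes"
        mo = config.section("modes")
        calls = [
            classify_mode(ems[sid], library.seeds[sid],
                          z_threshold=z_thr,
                          engage_frac=float(mo.get("engage_frac", 0.25)),
                          engage_abs=float(mo.get("engage_abs", 2.0)))
            for sid in ems
        ]
        all_calls = calls
        calls_df = pd.DataFrame([c.__dict__ for c in all_calls])
        _write_table(calls_df, out / "mode_calls.tsv", cfg_hash, stage)
        landscape = spacer_landscape(all_calls, z_threshold=z_thr)
        _write_table(landscape, out / "landscape.tsv", cfg_hash, stage)
        if not landscape.empty:
            _write_table(landscape_summary(landscape), out / "landscape_summary.tsv",
                         cfg_hash, stage)

        # averaged full-site PFMs per spacer length
        by_spacer: dict[int, list] = {}
        for c in all_calls:
            if c.mode == "full" and c.seed_id in pfms:
                seed = library.seeds[c.seed_id]
                site_pfm = pfms[c.seed_id].slice(
                    slice(seed.flank_len, seed.flank_len + seed.site_len))
                by_spacer.setdefault(c.spacer_len, []).append(site_pfm)
        averaged = [
            average_pfms(lst, name=f"full_site_DR{S}")
            for S, lst in sorted(by_spacer.items()) if lst
        ]
        if averaged:
            write_meme(averaged, out / "averaged_pfms.meme")

        stage = "enrich"
        e = config.section("enrich")
        if e.get("enabled", False) and averaged:
            bg_name = m.get("background", "ht29")
            bg = HT29_BACKGROUND if bg_name == "ht29" else UNIFORM_BACKGROUND
            pwm = pwm_from_pfm(averaged[0], background=bg,
                               pseudocount=float(m.get("pseudocount", 0.001)))
            pos, neg, genome, tss, de_genes, truth_g = simulate_genomic_benchmark(
                n_pos=int(e.get("n_pos", 200)),
                n_neg=int(e.get("n_neg", 200)),
                region_len=int(e.get("region_len", 150)),
                motif=averaged[0],
                planted_fraction=float(e.get("planted_fraction", 0.9)),
                rng_seed=sub(),
            )
            pos_scores = score_sequences(extract_sequences(pos, genome), pwm)
            neg_scores = score_sequences(extract_sequences(neg, genome), pwm)
            res = roc_auc(pos_scores, neg_scores,
                          n_models_for_bonferroni=int(e.get("n_models", 1)))
            (out / "roc.json").write_text(json.dumps(res.to_dict(), indent=2))
            _write_table(res.curve, out / "roc_curve.tsv", cfg_hash, stage)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    (out / "DONE").write_text(cfg_hash + "\n")
    return out


def render_reports(run_dir) -> Path:
    """Render figures and a markdown summary for a completed run."""
    import matplotlib.pyplot as plt

    from .motifs import read_meme
    from .plotting import plot_landscape, plot_logo, plot_roc

    run = Path(run_dir)
    figdir = run / "figures"
    figdir.mkdir(exist_ok=True)
    sections = []

    meme = run / "averaged_pfms.meme"
    if meme.exists():
        for pfm in read_meme(meme):
            ax = plot_logo(pfm, title=pfm.name)
            ax.figure.savefig(figdir / f"logo_{pfm.name}.png", dpi=120,
                              bbox_inches="tight")
            plt.close(ax.figure)
            sections.append(f"![{pfm.name}](figures/logo_{pfm.name}.png)")
    else:
        log.warning("no averaged PFMs found; skipping logo figures")

    landscape_path = run / "landscape.tsv"
    if landscape_path.exists():
        landscape = pd.read_csv(landscape_path, sep="\t", comment="#")
        if not landscape.empty:
            ax = plot_landscape(landscape, title="spacer-preference landscape")
            ax.figure.savefig(figdir / "landscape.png", dpi=120,
                              bbox_inches="tight")
            plt.close(ax.figure)
            sections.append("![landscape](figures/landscape.png)")
    else:
        log.warning("no landscape table found; skipping landscape figure")

    roc_path = run / "roc.json"
    if roc_path.exists():
        from .enrichment import ROCResult

        payload = json.loads(roc_path.read_text())
        curve = pd.read_csv(run / "roc_curve.tsv", sep="\t", comment="#")
        res = ROCResult(curve=curve, **payload)
        ax = plot_roc({"model": res}, title="bound vs unbound discrimination")
        ax.figure.savefig(figdir / "roc.png", dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        sections.append("![roc](figures/roc.png)")
    else:
        log.warning("no ROC results found; report omits the enrichment section")

    report = run / "report.md"
    report.write_text("# nrpbm run report\n\n" + "\n\n".join(sections) + "\n")
    return report
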