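"""End-to-end orchestration: synthesis -> calibration -> simulation -> report.

``run_pipeline`` executes the full analysis under one seeded configuration
and writes every artifact beneath an output directory::

    out/
      calibration/   accepted rate pairs per reaction + chosen RateSet
      signatures/    wild-type steady-state signatures
      scenarios/     per-scenario signatures and comparisons to wild type
      stats/         group comparison of synthetic binding samples
      report/        radar/heatmap/free-protein data files and figures
      manifest.json  config snapshot, version, per-file checksums

Re-running with an identical configuration reproduces identical checksums
(all randomness flows through the configured seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import WT_AFFINITIES, calibrate_all
from .niche import COMPLEX_SPECIES, heatmap_matrix, radar_data, simulate_niche
from .scenarios import compare_signatures, make_config, run_scenario, signature_flags
from .stats import dunn_bh, kruskal_wallis
from .synthetic import default_wt_abundance, sample_abundances, sample_binding

log = logging.getLogger("scncomplex")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "out"
    seed: int = 0
    affinities: dict[str, float] = field(default_factory=lambda: dict(WT_AFFINITIES))
    abundances_csv: str | None = None      # tidy cell_type,protein,total; None -> synthetic defaults
    scenarios: list[str] = field(default_factory=lambda: ["wt", "dprd"])
    grid_max: float = 0.5
    grid_step: float = 0.0002
    tol: float = 1e-5
    policy: str = "random"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_abundances(config: PipelineConfig) -> dict[str, dict[str, float]]:
    if config.abundances_csv:
        df = pd.read_csv(config.abundances_csv)
        value_col = "total" if "total" in df.columns else "mean"
        table: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            table.setdefault(row["cell_type"], {})[row["protein"]] = float(row[value_col])
        return table
    return default_wt_abundance(seed=config.seed).means


def render_report(out_dir: Path, signatures: dict[str, pd.DataFrame]) -> list[Path]:
    """Radar/heatmap/bar data files and figures for each scenario's signatures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = out_dir / "report"
    report.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, sig in signatures.items():
        radar = radar_data(sig)
        radar.to_csv(report / f"{name}_radar.csv")
        heat = heatmap_matrix(sig)
        heat.to_csv(report / f"{name}_heatmap.csv")
        free = sig.loc[["WOX5", "BRAVO", "PLT3"]]
        free.to_csv(report / f"{name}_free_protein.csv")
        written += [
            report / f"{name}_radar.csv",
            report / f"{name}_heatmap.csv",
            report / f"{name}_free_protein.csv",
        ]

        # radar figure: one polar axis per cell type, complexes as spokes
        angles = np.linspace(0, 2 * np.pi, len(COMPLEX_SPECIES), endpoint=False)
        fig, axes = plt.subplots(
            1, len(sig.columns), subplot_kw={"projection": "polar"}, figsize=(16, 4)
        )
        for ax, ct in zip(np.atleast_1d(axes), sig.columns):
            vals = radar[ct].to_numpy()
            ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]])
            ax.fill(np.r_[angles, angles[0]], np.r_[vals, vals[0]], alpha=0.25)
            ax.set_xticks(angles)
            ax.set_xticklabels(COMPLEX_SPECIES, fontsize=6)
            ax.set_title(ct)
        fig.suptitle(f"{name}: complex signatures")
        fig.savefig(report / f"{name}_radar.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(heat.to_numpy(), cmap="coolwarm", aspect="auto")
        ax.set_xticks(range(len(heat.columns)), heat.columns)
        ax.set_yticks(range(len(heat.index)), heat.index, fontsize=7)
        fig.colorbar(im, label="level / row max")
        ax.set_title(f"{name}: signature heatmap")
        fig.tight_layout()
        fig.savefig(report / f"{name}_heatmap.png", dpi=120)
        plt.close(fig)
        written += [report / f"{name}_radar.png", report / f"{name}_heatmap.png"]

    if {"wt", "dprd"} <= set(signatures):
        side = pd.concat(
            {name: heatmap_matrix(signatures[name]) for name in ("wt", "dprd")}, axis=1
        )
        side.to_csv(report / "wt_vs_dprd_heatmap.csv")
        written.append(report / "wt_vs_dprd_heatmap.csv")
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    t_start = time.time()
    out = Path(config.out_dir)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        stage: int(rng.integers(2**31 - 1))
        for stage in ("synth", "calibrate", "scenarios", "stats")
    }
    artifacts: list[Path] = []

    # synth
    log.info("stage synth: generating per-nucleus intensities")
    synth_dir = out / "synth"
    synth_dir.mkdir(parents=True, exist_ok=True)
    ab_config = default_wt_abundance(seed=stage_seeds["synth"])
    nuclei = sample_abundances(ab_config)
    nuclei.to_csv(synth_dir / "nuclei_intensities.csv", index=False)
    artifacts.append(synth_dir / "nuclei_intensities.csv")

    # calibrate
    log.info("stage calibrate: scanning rate grid per reaction")
    cal_dir = out / "calibration"
    cal_dir.mkdir(parents=True, exist_ok=True)
    rates, scans = calibrate_all(
        config.affinities,
        grid_max=config.grid_max,
        grid_step=config.grid_step,
        tol=config.tol,
        policy=config.policy,
        seed=stage_seeds["calibrate"],
    )
    for lab, scan in scans.items():
        scan.to_frame().to_csv(cal_dir / f"accepted_{lab}.csv", index=False)
        artifacts.append(cal_dir / f"accepted_{lab}.csv")
    (cal_dir / "rates.json").write_text(json.dumps(rates.to_dict(), indent=2))
    artifacts.append(cal_dir / "rates.json")

    # simulate wild type
    log.info("stage simulate: wild-type niche signatures")
    sig_dir = out / "signatures"
    sig_dir.mkdir(parents=True, exist_ok=True)
    abundances = _load_abundances(config)
    wt_sig = simulate_niche(abundances, rates)
    wt_sig.to_csv(sig_dir / "wt_signatures.csv")
    artifacts.append(sig_dir / "wt_signatures.csv")
    flags = signature_flags(wt_sig)
    (sig_dir / "wt_flags.json").write_text(json.dumps(flags, indent=2))
    artifacts.append(sig_dir / "wt_flags.json")

    # scenarios
    signatures: dict[str, pd.DataFrame] = {"wt": wt_sig}
    scen_dir = out / "scenarios"
    scen_dir.mkdir(parents=True, exist_ok=True)
    for name in config.scenarios:
        if name == "wt":
            continue
        log.info("stage scenarios: %s", name)
        sig = run_scenario(
            make_config(name, seed=stage_seeds["scenarios"]), abundances=abundances
        )
        signatures[name] = sig
        sig.to_csv(scen_dir / f"{name}_signatures.csv")
        comp = compare_signatures(wt_sig, sig)
        report = {
            "distance": comp.distance,
            "flags_wt": comp.flags_a,
            "flags_scenario": comp.flags_b,
        }
        (scen_dir / f"{name}_comparison.json").write_text(json.dumps(report, indent=2))
        artifacts += [scen_dir / f"{name}_signatures.csv", scen_dir / f"{name}_comparison.json"]

    # stats on synthetic binding groups (donor-only vs negative control vs pair)
    log.info("stage stats: group comparison of synthetic binding samples")
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    groups = {
        "donor_only": sample_binding(2.3, 7.4, 38, seed=stage_seeds["stats"]).samples,
        "negative_ctrl": sample_binding(8.8, 4.3, 38, seed=stage_seeds["stats"] + 1).samples,
        "BRAVO_PLT3": sample_binding(28.0, 11.7, 40, seed=stage_seeds["stats"] + 2).samples,
    }
    h, p = kruskal_wallis(groups)
    letters = dunn_bh(groups)
    letters.p_matrix.to_csv(stats_dir / "dunn_bh_pvalues.csv")
    (stats_dir / "kruskal_wallis.json").write_text(
        json.dumps({"H": h, "p": p, "letters": letters.letters}, indent=2)
    )
    artifacts += [stats_dir / "dunn_bh_pvalues.csv", stats_dir / "kruskal_wallis.json"]

    # report
    log.info("stage report")
    artifacts += render_report(out, signatures)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
        "elapsed_s": round(time.time() - t_start, 2),
        "checksums": {
            str(p.relative_to(out)): _sha256(p) for p in artifacts if p.suffix != ".png"
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
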