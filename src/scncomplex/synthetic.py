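"""Synthetic measurement generator.

Emulates, at the measurement level, the three kinds of data the analysis
consumes: per-nucleus fluorescence intensities of the WOX5/PLT3/BRAVO
translational reporters in the four niche cell types, per-nucleus FRET-FLIM
binding percentages, and TCSPC photon-arrival histograms.  No imaging is
emulated; values are drawn directly from the distributions at the level at
which a microscopist would tabulate them.

The default abundance means follow the qualitative pattern reported for the
niche: BRAVO highest in the stele initials (the global normalisation anchor,
mean 1.0) and falling towards the columella; WOX5 peaking in the quiescent
center and nearly absent in columella cells; PLT3 similar across SI/QC/CSC
and lower in CCs.  The numeric values are package defaults (the underlying
per-cell-type table is not published) and are user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .niche import CELL_TYPES, PROTEINS
from .flim import DecayHistogram

__all__ = [
    "DEFAULT_ABUNDANCE_MEANS",
    "AbundanceConfig",
    "BindingSampleSet",
    "DecayParams",
    "default_wt_abundance",
    "sample_abundances",
    "sample_binding",
    "simulate_decay",
]

#: default mean relative intensities, normalised to BRAVO in the stele initials
DEFAULT_ABUNDANCE_MEANS: dict[str, dict[str, float]] = {
    "SI": {"BRAVO": 1.00, "PLT3": 0.60, "WOX5": 0.30},
    "QC": {"BRAVO": 0.40, "PLT3": 0.55, "WOX5": 0.60},
    "CSC": {"BRAVO": 0.15, "PLT3": 0.65, "WOX5": 0.45},
    "CC": {"BRAVO": 0.02, "PLT3": 0.10, "WOX5": 0.01},
}


@dataclass
class AbundanceConfig:
    """Per-(cell type, protein) mean intensities and sampling noise.

    Exactly one (cell type, protein) pair must have mean 1.0 — the global
    normalisation anchor (BRAVO in SI by default).
    """

    means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            ct: dict(row) for ct, row in DEFAULT_ABUNDANCE_MEANS.items()
        }
    )
    sd: float = 0.05
    nuclei_per_root: int = 3
    n_roots: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            self.means[ct][p] for ct in self.means for p in self.means[ct]
        ]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("all means must lie in [0, 1]")
        if sum(1 for v in vals if v == 1.0) != 1:
            raise ValueError("exactly one (cell_type, protein) mean must equal 1.0")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not 1 <= self.nuclei_per_root <= 3:
            raise ValueError("nuclei_per_root must be 1..3")
        if self.n_roots < 1:
            raise ValueError("n_roots must be positive")

    def totals_frame(self) -> pd.DataFrame:
        """Tidy (cell_type, protein, total) table of the configured means."""
        rows = [
            {"cell_type": ct, "protein": p, "total": self.means[ct][p]}
            for ct in CELL_TYPES
            for p in PROTEINS
        ]
        return pd.DataFrame(rows)


@dataclass
class BindingSampleSet:
    """Per-nucleus binding percentages for one donor/acceptor combination."""

    label: str
    samples: np.ndarray
    mean_pct: float
    sd_pct: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValueError("need at least one sample")


@dataclass
class DecayParams:
    """Generative parameters for a TCSPC decay histogram.

    ``alpha_f`` is the photon-count amplitude of the FRET component: the
    probability that a detected photon is drawn from the fast exponential.
    Under equal brightness of the two donor states this equals the fraction
    of donor molecules undergoing FRET, which is how the fitted amplitude is
    read as "binding".
    """

    tau_d: float = 3.0          # donor-only lifetime, ns
    tau_f: float = 1.2          # FRET-quenched lifetime, ns
    alpha_f: float = 0.0        # photon fraction from the FRET component
    sigma_irf: float = 0.1      # Gaussian IRF width, ns
    background: float = 0.0     # uniform background, counts per bin
    window: float = 31.25       # repetition window (32 MHz), ns
    n_photons: int = 100_000
    bins: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau_f < self.tau_d:
            raise ValueError("require 0 < tau_f < tau_d")
        if not 0.0 <= self.alpha_f <= 1.0:
            raise ValueError("alpha_f must lie in [0, 1]")
        if self.sigma_irf < 0 or self.background < 0:
            raise ValueError("sigma_irf and background must be non-negative")
        if self.n_photons <= 0:
            raise ValueError("n_photons must be positive")
        if self.bins < 8:
            raise ValueError("need at least 8 bins")

    def to_json_dict(self) -> dict:
        return asdict(self)


def default_wt_abundance(seed: int = 0) -> AbundanceConfig:
    """The default wild-type abundance configuration (28 roots, 3 nuclei each)."""
    return AbundanceConfig(seed=seed)


def sample_abundances(config: AbundanceConfig) -> pd.DataFrame:
    """Draw per-nucleus intensities: max(0, Normal(mean, sd)) per nucleus.

    Returns one row per (root, cell_type, nucleus, protein) with the
    per-root per-cell-type mean (the quantity summarised per root in
    practice) in ``root_cell_mean``.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for root in range(1, config.n_roots + 1):
        for ct in CELL_TYPES:
            for protein in PROTEINS:
                mean = config.means[ct][protein]
                draws = np.maximum(
                    0.0,
                    rng.normal(mean, config.sd, size=config.nuclei_per_root),
                )
                root_mean = float(draws.mean())
                for nuc, val in enumerate(draws, start=1):
                    records.append(
                        {
                            "root_id": root,
                            "cell_type": ct,
                            "nucleus_id": nuc,
                            "protein": protein,
                            "intensity": float(val),
                            "root_cell_mean": root_mean,
                        }
                    )
    return pd.DataFrame.from_records(records)


def sample_binding(
    mean_pct: float, sd_pct: float, n: int, seed: int | None = None, label: str = ""
) -> BindingSampleSet:
    """Draw n per-nucleus binding percentages ~ Normal(mean, sd), untruncated.

    Negative values are legitimate: donor-only and negative-control samples
    scatter on both sides of zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd_pct < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    samples = rng.normal(mean_pct, sd_pct, size=n)
    return BindingSampleSet(label=label, samples=samples, mean_pct=mean_pct, sd_pct=sd_pct)


def simulate_decay(params: DecayParams) -> DecayHistogram:
    """Simulate a TCSPC histogram from a one- or two-exponential donor decay.

    Arrival times are a mixture alpha_f * Exp(tau_f) + (1-alpha_f) *
    Exp(tau_d), jittered by a Gaussian IRF of width sigma_irf and wrapped
    into the repetition window; a uniform Poisson background is added per
    bin.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_photons
    from_fret = rng.random(n) < params.alpha_f
    taus = np.where(from_fret, params.tau_f, params.tau_d)
    t = rng.exponential(taus)
    if params.sigma_irf > 0:
        t = t + rng.normal(0.0, params.sigma_irf, size=n)
    t = np.mod(t, params.window)
    edges = np.linspace(0.0, params.window, params.bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    if params.background > 0:
        counts = counts + rng.poisson(params.background, size=params.bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DecayHistogram(
        bin_centers=centers,
        counts=counts.astype(np.int64),
        window=params.window,
    )
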