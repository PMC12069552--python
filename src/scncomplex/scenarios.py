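"""Named experiments: wild type, the PLT3 PrD-deletion variant, and controls.

The PrD scenario replaces the two PLT3 dimer affinities by their measured
PrD-deletion values (WOX5-PLT3: 0.306 -> 0.185; BRAVO-PLT3: 0.280 -> 0.117)
while keeping the trimer-path rates at wild-type values — consistent with
the observation that trimer abundance in SI/QC is only mildly affected.  A
switch recalibrates both trimer paths to the re-measured split-donor value
instead.

Seven controls probe what drives the signatures: fixed uniform rates (equal,
association-biased, dissociation-biased) versus calibrated rates, crossed
with measured versus equal protein abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import (
    COMPLEX_LABELS,
    WT_AFFINITIES,
    RateSet,
    calibrate_all,
)
from .niche import CELL_TYPES, COMPLEX_SPECIES, PROTEINS, simulate_niche

__all__ = [
    "DPRD_WOX5PLT3",
    "DPRD_BRAVOPLT3",
    "REMEASURED_TRIMER",
    "SCENARIO_NAMES",
    "ScenarioConfig",
    "SignatureComparison",
    "delta_prd_affinities",
    "equal_abundances",
    "signature_flags",
    "run_scenario",
    "compare_signatures",
]

DPRD_WOX5PLT3 = 0.185
DPRD_BRAVOPLT3 = 0.117
#: split-donor trimer binding re-measured with PLT3 full length / PrD-deleted
REMEASURED_TRIMER = {"full": 0.315, "dprd": 0.289}

SCENARIO_NAMES = ("wt", "dprd", "c1", "c2", "c3", "c4", "c5", "c6", "c7")

#: fixed uniform rate pairs used by the controls
_CONTROL_RATES = {
    "equal": (0.1, 0.1),
    "assoc": (0.1, 0.05),
    "dissoc": (0.05, 0.1),
}

#: qualitative wild-type signature flags, in display order
FLAG_NAMES = (
    "trimer_max_in_SI_QC",
    "wox5plt3_max_in_CSC",
    "free_bravo_max_in_SI",
    "free_wox5_max_in_QC",
    "free_plt3_high_in_CSC_CC",
    "cc_complexes_negligible",
)


@dataclass
class ScenarioConfig:
    """One named simulation: a rate source plus an abundance source."""

    name: str
    affinities: dict[str, float] | None = None      # calibrated-rate source
    fixed_rates: tuple[float, float] | None = None  # uniform (a, d) source
    abundance_source: str = "measured"              # "measured" | "equal"
    equal_level: float = 0.5
    policy: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.affinities is None) == (self.fixed_rates is None):
            raise ValueError("exactly one of affinities / fixed_rates must be set")
        if self.abundance_source not in ("measured", "equal"):
            raise ValueError(f"unknown abundance source {self.abundance_source!r}")


def delta_prd_affinities(
    wt: Mapping[str, float] | None = None, trimer: str = "wt"
) -> dict[str, float]:
    """PrD-deletion affinity table: both PLT3 dimer affinities reduced.

    ``trimer='wt'`` keeps the trimer-path affinities at wild-type values;
    ``trimer='remeasured'`` sets both paths to the re-measured PrD-deletion
    split-donor binding.
    """
    table = dict(WT_AFFINITIES if wt is None else wt)
    table["WOX5PLT3"] = DPRD_WOX5PLT3
    table["BRAVOPLT3"] = DPRD_BRAVOPLT3
    if trimer == "remeasured":
        table["WOX5PLT3BRAVO1"] = REMEASURED_TRIMER["dprd"]
        table["WOX5PLT3BRAVO2"] = REMEASURED_TRIMER["dprd"]
    elif trimer != "wt":
        raise ValueError(f"unknown trimer mode {trimer!r}")
    return table


def equal_abundances(level: float = 0.5) -> dict[str, dict[str, float]]:
    """Every (cell type, protein) pool set to the same level (a.u.)."""
    return {ct: {p: level for p in PROTEINS} for ct in CELL_TYPES}


def make_config(name: str, seed: int = 0) -> ScenarioConfig:
    """Build one of the named scenario configurations (wt, dprd, c1..c7)."""
    name = name.lower()
    if name == "wt":
        return ScenarioConfig("wt", affinities=dict(WT_AFFINITIES), seed=seed)
    if name == "dprd":
        return ScenarioConfig("dprd", affinities=delta_prd_affinities(), seed=seed)
    if name == "c1":
        return ScenarioConfig("c1", fixed_rates=_CONTROL_RATES["equal"], seed=seed)
    if name == "c2":
        return ScenarioConfig("c2", fixed_rates=_CONTROL_RATES["assoc"], seed=seed)
    if name == "c3":
        return ScenarioConfig("c3", fixed_rates=_CONTROL_RATES["dissoc"], seed=seed)
    if name == "c4":
        return ScenarioConfig(
            "c4", affinities=dict(WT_AFFINITIES), abundance_source="equal", seed=seed
        )
    if name == "c5":
        return ScenarioConfig(
            "c5", fixed_rates=_CONTROL_RATES["equal"], abundance_source="equal", seed=seed
        )
    if name == "c6":
        return ScenarioConfig(
            "c6", fixed_rates=_CONTROL_RATES["assoc"], abundance_source="equal", seed=seed
        )
    if name == "c7":
        return ScenarioConfig(
            "c7", fixed_rates=_CONTROL_RATES["dissoc"], abundance_source="equal", seed=seed
        )
    raise ValueError(f"unknown scenario {name!r}")


def run_scenario(
    config: ScenarioConfig | str,
    abundances=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run one scenario end to end, returning the species x cell-type signatures.

    ``abundances`` overrides the measured abundance table (defaults to the
    package's wild-type configuration); it is ignored when the scenario
    prescribes equal abundances.
    """
    if isinstance(config, str):
        config = make_config(config, seed=seed if seed is not None else 0)
    if config.fixed_rates is not None:
        rates = RateSet.uniform(*config.fixed_rates)
    else:
        rates, _ = calibrate_all(
            config.affinities, policy=config.policy, seed=config.seed
        )
    if config.abundance_source == "equal":
        table = equal_abundances(config.equal_level)
    else:
        if abundances is None:
            from .synthetic import default_wt_abundance

            abundances = default_wt_abundance().means
        table = abundances
    return simulate_niche(table, rates)


def _free_fraction(sig: pd.DataFrame, protein: str) -> pd.Series:
    """Free / total fraction of one protein per cell type (0 where absent)."""
    contributions = {
        "WOX5": ["WOX5", "WOX5PLT3", "BRAVOWOX5", "WOX5PLT3BRAVO"],
        "BRAVO": ["BRAVO", "BRAVOPLT3", "BRAVOWOX5", "WOX5PLT3BRAVO"],
        "PLT3": ["PLT3", "WOX5PLT3", "BRAVOPLT3", "WOX5PLT3BRAVO"],
    }[protein]
    total = sig.loc[contributions].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = sig.loc[protein] / total
    return frac.fillna(0.0)


def signature_flags(sig: pd.DataFrame) -> dict[str, bool]:
    """The six qualitative wild-type pattern flags of a niche signature.

    "Free PLT3 high in CSC and CC" is evaluated on the free *fraction* of
    the PLT3 pool (CC pools are small, so absolute levels would hide the
    pattern the bar plots show per cell).
    """
    trimer = sig.loc["WOX5PLT3BRAVO"]
    top2 = set(trimer.sort_values(ascending=False).index[:2])
    plt3_free_frac = _free_fraction(sig, "PLT3")
    cmax = sig.loc[list(COMPLEX_SPECIES)].max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc_rel = sig.loc[list(COMPLEX_SPECIES), "CC"] / cmax
    cc_rel = cc_rel.fillna(0.0)
    return {
        "trimer_max_in_SI_QC": top2 == {"SI", "QC"},
        "wox5plt3_max_in_CSC": sig.loc["WOX5PLT3"].idxmax() == "CSC",
        "free_bravo_max_in_SI": sig.loc["BRAVO"].idxmax() == "SI",
        "free_wox5_max_in_QC": sig.loc["WOX5"].idxmax() == "QC",
        "free_plt3_high_in_CSC_CC": set(
            plt3_free_frac.sort_values(ascending=False).index[:2]
        )
        == {"CSC", "CC"},
        "cc_complexes_negligible": bool((cc_rel < 0.05).all()),
    }


@dataclass
class SignatureComparison:
    """Entry-wise and qualitative comparison of two niche signatures."""

    abs_diff: pd.DataFrame
    rel_diff: pd.DataFrame
    flags_a: dict[str, bool]
    flags_b: dict[str, bool]
    distance: float

    @property
    def flags_equal(self) -> bool:
        return self.flags_a == self.flags_b


def compare_signatures(a: pd.DataFrame, b: pd.DataFrame) -> SignatureComparison:
    """Differences (B - A) plus pattern flags and an L1 distance.

    The scalar distance is the L1 norm over entries of both signatures after
    per-entry max-normalisation (each entry divided by the larger of the two
    values, zero where both vanish): scale-free, zero iff identical.
    """
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("signatures must share species and cell types")
    abs_diff = b - a
    denom = pd.concat([a.abs(), b.abs()]).groupby(level=0).max().reindex(a.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = abs_diff / denom
    rel_diff = rel.fillna(0.0)
    return SignatureComparison(
        abs_diff=abs_diff,
        rel_diff=rel_diff,
        flags_a=signature_flags(a),
        flags_b=signature_flags(b),
        distance=float(rel_diff.abs().to_numpy().sum()),
    )
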