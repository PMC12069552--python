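"""Steady-state simulation of the seven-species complex-formation model.

Each cell type of the root stem cell niche (stele initials SI, quiescent
center QC, columella stem cells CSC, columella cells CC) holds fixed total
pools of the transcription factors WOX5, BRAVO and PLT3.  Mass-action
kinetics partition those pools into three heterodimers (WOX5-PLT3,
BRAVO-PLT3, BRAVO-WOX5) and the trimer WOX5-PLT3-BRAVO, which forms along
two paths: BRAVO binding the WOX5-PLT3 dimer (path 1) or WOX5 binding the
BRAVO-PLT3 dimer (path 2).  Free PLT3 exchanges with the trimer only
through the dimers.  The steady state of this system — the cell's complex
"signature" — is the model output.

The dynamics conserve the three totals

    total_WOX5  = WOX5  + WOX5PLT3 + BRAVOWOX5 + WOX5PLT3BRAVO
    total_BRAVO = BRAVO + BRAVOPLT3 + BRAVOWOX5 + WOX5PLT3BRAVO
    total_PLT3  = PLT3  + WOX5PLT3 + BRAVOPLT3 + WOX5PLT3BRAVO

which is both a model statement (protein amounts are held constant while
being repartitioned) and the main numerical invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator, TransformerMixin

from .calibration import RateSet, SteadyStateError

__all__ = [
    "CELL_TYPES",
    "PROTEINS",
    "SPECIES",
    "COMPLEX_SPECIES",
    "SignatureProfile",
    "scn_rhs",
    "conservation_totals",
    "simulate_cell",
    "simulate_niche",
    "heatmap_matrix",
    "radar_data",
    "NicheSimulator",
]

CELL_TYPES = ("SI", "QC", "CSC", "CC")
PROTEINS = ("WOX5", "BRAVO", "PLT3")
#: state vector order used throughout
SPECIES = (
    "WOX5",
    "BRAVO",
    "PLT3",
    "WOX5PLT3",
    "BRAVOPLT3",
    "BRAVOWOX5",
    "WOX5PLT3BRAVO",
)
COMPLEX_SPECIES = SPECIES[3:]

_IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclass
class SignatureProfile:
    """Steady-state free-protein and complex levels for one cell type."""

    cell_type: str
    levels: dict[str, float]
    totals: dict[str, float]
    converged: bool = True
    residual: float = 0.0
    time: float = 0.0

    def __getitem__(self, species: str) -> float:
        return self.levels[species]

    def as_series(self) -> pd.Series:
        return pd.Series({s: self.levels[s] for s in SPECIES}, name=self.cell_type)


def scn_rhs(t: float, y: Sequence[float], rates: RateSet) -> np.ndarray:
    """Time derivatives of (WOX5, BRAVO, PLT3, WOX5PLT3, BRAVOPLT3, BRAVOWOX5, WOX5PLT3BRAVO)."""
    W, B, P, WP, BP, BW, T = y
    r = rates
    a_bw, d_bw = r["BRAVOWOX5"].a, r["BRAVOWOX5"].d
    a_wp, d_wp = r["WOX5PLT3"].a, r["WOX5PLT3"].d
    a_bp, d_bp = r["BRAVOPLT3"].a, r["BRAVOPLT3"].d
    a_t1, d_t1 = r["WOX5PLT3BRAVO1"].a, r["WOX5PLT3BRAVO1"].d
    a_t2, d_t2 = r["WOX5PLT3BRAVO2"].a, r["WOX5PLT3BRAVO2"].d

    f_bw = a_bw * B * W - d_bw * BW        # B + W <-> BW
    f_wp = a_wp * W * P - d_wp * WP        # W + P <-> WP
    f_bp = a_bp * B * P - d_bp * BP        # B + P <-> BP
    f_t1 = a_t1 * WP * B - d_t1 * T        # WP + B <-> T  (path 1)
    f_t2 = a_t2 * BP * W - d_t2 * T        # BP + W <-> T  (path 2)

    return np.array(
        [
            -f_bw - f_wp - f_t2,           # dWOX5/dt
            -f_bw - f_bp - f_t1,           # dBRAVO/dt
            -f_wp - f_bp,                  # dPLT3/dt (no direct trimer term)
            f_wp - f_t1,                   # dWOX5PLT3/dt
            f_bp - f_t2,                   # dBRAVOPLT3/dt
            f_bw,                          # dBRAVOWOX5/dt
            f_t1 + f_t2,                   # dWOX5PLT3BRAVO/dt
        ]
    )


def conservation_totals(y: Sequence[float]) -> dict[str, float]:
    """The three conserved protein totals of a state vector."""
    W, B, P, WP, BP, BW, T = y
    return {
        "WOX5": W + WP + BW + T,
        "BRAVO": B + BP + BW + T,
        "PLT3": P + WP + BP + T,
    }


def simulate_cell(
    totals: Mapping[str, float] | Sequence[float],
    rates: RateSet,
    *,
    cell_type: str = "",
    criterion: float = 1e-10,
    time_cap: float = 1e6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    initial_complexes: Sequence[float] | None = None,
) -> SignatureProfile:
    """Integrate one cell from an all-free initial condition to steady state.

    ``totals`` gives the WOX5/BRAVO/PLT3 pools (a.u.).  All protein starts
    free (complexes zero) unless ``initial_complexes`` supplies a feasible
    pre-bound partition (used by the multistability check); steady state is
    declared at max|dX/dt| < ``criterion``.
    """
    if not isinstance(totals, Mapping):
        totals = dict(zip(PROTEINS, totals))
    tot = {p: float(totals[p]) for p in PROTEINS}
    if any(v < 0 for v in tot.values()):
        raise ValueError("protein totals must be non-negative")

    y = np.zeros(7)
    if initial_complexes is not None:
        y[3:] = np.asarray(initial_complexes, dtype=float)
        W, B, P = tot["WOX5"], tot["BRAVO"], tot["PLT3"]
        y[0] = W - y[3] - y[5] - y[6]
        y[1] = B - y[4] - y[5] - y[6]
        y[2] = P - y[3] - y[4] - y[6]
        if np.any(y < -1e-12):
            raise ValueError("initial complexes exceed protein totals")
        y = np.clip(y, 0.0, None)
    else:
        y[0], y[1], y[2] = tot["WOX5"], tot["BRAVO"], tot["PLT3"]

    rate_scale = max(
        max(rates[lab].a for lab in rates.rates),
        max(rates[lab].d for lab in rates.rates),
        1e-6,
    )
    t_chunk = 10.0 / rate_scale
    t_total = 0.0
    while True:
        if np.max(np.abs(scn_rhs(t_total, y, rates))) < criterion:
            break
        if t_total >= time_cap:
            raise SteadyStateError(
                f"cell {cell_type or totals}: no steady state within t={time_cap:g}"
            )
        t_chunk = min(t_chunk, time_cap - t_total)
        sol = solve_ivp(
            scn_rhs,
            (0.0, t_chunk),
            y,
            args=(rates,),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise SteadyStateError(f"integrator failed: {sol.message}")
        y = sol.y[:, -1]
        t_total += t_chunk
        t_chunk *= 2.0

    # the integrator may leave tiny negative excursions; clamp and warn loudly
    if np.any(y < -1e-12):
        raise SteadyStateError(f"negative concentrations beyond tolerance: {y}")
    y = np.clip(y, 0.0, None)
    residual = float(np.max(np.abs(scn_rhs(t_total, y, rates))))
    levels = {s: float(y[_IDX[s]]) for s in SPECIES}
    return SignatureProfile(
        cell_type=cell_type,
        levels=levels,
        totals=tot,
        converged=True,
        residual=residual,
        time=t_total,
    )


def _coerce_abundance_table(abundances) -> dict[str, dict[str, float]]:
    """Accept a tidy DataFrame (cell_type, protein, total) or nested mapping."""
    if isinstance(abundances, pd.DataFrame):
        value_col = "total" if "total" in abundances.columns else "mean"
        out: dict[str, dict[str, float]] = {}
        for _, row in abundances.iterrows():
            out.setdefault(str(row["cell_type"]), {})[str(row["protein"])] = float(
                row[value_col]
            )
        return out
    return {ct: {p: float(v) for p, v in row.items()} for ct, row in abundances.items()}


def simulate_niche(abundances, rates: RateSet, **kwargs) -> pd.DataFrame:
    """Simulate all four cell types; rows = species, columns = cell types."""
    table = _coerce_abundance_table(abundances)
    missing = [ct for ct in CELL_TYPES if ct not in table]
    if missing:
        raise ValueError(f"missing cell types: {missing}")
    profiles = {
        ct: simulate_cell(table[ct], rates, cell_type=ct, **kwargs)
        for ct in CELL_TYPES
    }
    return pd.DataFrame({ct: profiles[ct].as_series() for ct in CELL_TYPES})


def heatmap_matrix(signatures: pd.DataFrame, normalize: str = "row_max") -> pd.DataFrame:
    """Signature matrix for display; default normalisation is per-row maximum."""
    if normalize == "none":
        return signatures.copy()
    if normalize == "row_max":
        denom = signatures.max(axis=1).replace(0.0, np.nan)
        return signatures.div(denom, axis=0).fillna(0.0)
    raise ValueError(f"unknown normalisation {normalize!r}")


def radar_data(signatures: pd.DataFrame) -> pd.DataFrame:
    """Complex levels per cell type (the radial axes of the radar display)."""
    return signatures.loc[list(COMPLEX_SPECIES)].copy()


class NicheSimulator(BaseEstimator, TransformerMixin):
    """Transformer mapping per-cell-type protein totals to steady-state signatures.

    Parameters
    ----------
    rates : RateSet
        Calibrated association/dissociation rates for the five reactions.
    criterion, time_cap, rtol, atol : float
        Steady-state declaration threshold and integrator controls.

    After :meth:`transform`, ``signatures_`` holds the species x cell-type
    steady-state matrix of the most recent call.
    """

    def __init__(
        self,
        rates: RateSet,
        criterion: float = 1e-10,
        time_cap: float = 1e6,
        rtol: float = 1e-10,
        atol: float = 1e-12,
    ):
        self.rates = rates
        self.criterion = criterion
        self.time_cap = time_cap
        self.rtol = rtol
        self.atol = atol

    def fit(self, X=None, y=None) -> "NicheSimulator":
        return self

    def transform(self, X) -> pd.DataFrame:
        self.signatures_ = simulate_niche(
            X,
            self.rates,
            criterion=self.criterion,
            time_cap=self.time_cap,
            rtol=self.rtol,
            atol=self.atol,
        )
        return self.signatures_
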