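"""Calibration of relative association/dissociation rates from binding affinities.

A FRET-FLIM "binding" value gives the fraction of donor molecules in complex
at steady state.  For each measured protein pair that fraction is mapped back
onto mass-action rate constants by simulating the reversible dimerisation

    D + A  <-> DA         dDA/dt = a*A*D - d*DA

from equal unit donor/acceptor pools (D0 = A0 = 1 a.u., DA0 = 0) until steady
state, and accepting every (a, d) pair on a regular grid whose steady-state
bound fraction DA_ss/D0 matches the measured affinity within a tolerance.

With D0 = A0 = 1 the steady state has the closed form: the bound fraction x
is the smaller root of a*(1-x)^2 = d*x.  The scan exploits this: candidate
grid pairs are pre-filtered by the closed form (accepted pairs lie on the
line d = a*(1-b)^2/b) and every candidate is then verified by integrating
the ODE, so the accepted set is identical to the brute-force grid scan at a
fraction of the cost.  ``scan_rates_exhaustive`` retains the plain
integrate-every-grid-point scan for small sub-ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator

__all__ = [
    "RateConstants",
    "RateSet",
    "ScanResult",
    "SteadyStateError",
    "COMPLEX_LABELS",
    "WT_AFFINITIES",
    "dimer_rhs",
    "closed_form_bound_fraction",
    "steady_state_bound_fraction",
    "scan_rates",
    "scan_rates_exhaustive",
    "select_rate",
    "calibrate_all",
    "RateCalibrator",
]

#: the five reactions of the niche model, in canonical order.
#: WOX5PLT3BRAVO1 = trimer via WOX5-PLT3 dimer + BRAVO,
#: WOX5PLT3BRAVO2 = trimer via BRAVO-PLT3 dimer + WOX5.
COMPLEX_LABELS = (
    "BRAVOWOX5",
    "WOX5PLT3",
    "BRAVOPLT3",
    "WOX5PLT3BRAVO1",
    "WOX5PLT3BRAVO2",
)

#: wild-type binding fractions (FRET-FLIM binding percentage / 100)
WT_AFFINITIES: dict[str, float] = {
    "BRAVOWOX5": 0.224,
    "WOX5PLT3": 0.306,
    "BRAVOPLT3": 0.280,
    "WOX5PLT3BRAVO1": 0.363,
    "WOX5PLT3BRAVO2": 0.298,
}

GRID_MAX = 0.5
GRID_STEP = 0.0002
TOLERANCE = 1e-5


class SteadyStateError(RuntimeError):
    """Integration reached the time cap without satisfying the steady-state criterion."""


@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rate pair (arbitrary units)."""

    a: float
    d: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.d < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class RateSet:
    """The ten rate constants of the seven-species niche model."""

    rates: dict[str, RateConstants]

    def __post_init__(self) -> None:
        missing = [lab for lab in COMPLEX_LABELS if lab not in self.rates]
        if missing:
            raise ValueError(f"missing rate constants for: {missing}")

    def __getitem__(self, label: str) -> RateConstants:
        return self.rates[label]

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for lab in COMPLEX_LABELS:
            out[f"a_{lab}"] = self.rates[lab].a
            out[f"d_{lab}"] = self.rates[lab].d
        return out

    @classmethod
    def from_dict(cls, flat: Mapping[str, float]) -> "RateSet":
        rates = {
            lab: RateConstants(float(flat[f"a_{lab}"]), float(flat[f"d_{lab}"]))
            for lab in COMPLEX_LABELS
        }
        return cls(rates)

    @classmethod
    def uniform(cls, a: float, d: float) -> "RateSet":
        """Same (a, d) for all five reactions (used by the control scenarios)."""
        return cls({lab: RateConstants(a, d) for lab in COMPLEX_LABELS})


@dataclass
class ScanResult:
    """Accepted (a, d) grid pairs for one binding affinity."""

    label: str
    target: float
    pairs: list[RateConstants]
    tolerance: float
    grid_max: float
    grid_step: float
    #: ODE-verified bound fraction for each accepted pair
    bound_fractions: list[float] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.pairs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "a": [p.a for p in self.pairs],
                "d": [p.d for p in self.pairs],
                "bound_fraction": self.bound_fractions
                if self.bound_fractions
                else [np.nan] * len(self.pairs),
            }
        )


def dimer_rhs(t: float, y: Sequence[float], a: float, d: float) -> np.ndarray:
    """Right-hand side of the reversible dimerisation ODE, state y = (D, A, DA)."""
    D, A, DA = y
    flux = a * A * D - d * DA
    return np.array([-flux, -flux, flux])


def closed_form_bound_fraction(a, d, d0: float = 1.0):
    """Steady-state bound fraction for equal donor/acceptor pools D0 = A0 = d0.

    The bound fraction x = DA_ss/D0 solves a*d0*(1-x)^2 = d*x; the physical
    solution is the smaller quadratic root, evaluated in the numerically
    stable conjugate form (exact at a = 0 and d = 0).
    """
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    ad0 = a * d0
    disc = (2.0 * ad0 + d) ** 2 - 4.0 * ad0**2
    denom = 2.0 * ad0 + d + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(denom > 0, 2.0 * ad0 / denom, 0.0)
    return x if x.ndim else float(x)


def steady_state_bound_fraction(
    rates: RateConstants,
    initial: Sequence[float] = (1.0, 1.0, 0.0),
    *,
    criterion: float = 1e-10,
    time_cap: float = 1e6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """Integrate the dimer ODE to steady state and return DA_ss / D0.

    Steady state is declared when max|dX/dt| < ``criterion``; integration
    proceeds in doubling time chunks up to ``time_cap`` (raises
    :class:`SteadyStateError` beyond).
    """
    a, d = rates.a, rates.d
    y = np.asarray(initial, dtype=float)
    if np.any(y < 0):
        raise ValueError("initial concentrations must be non-negative")
    D0 = y[0] + y[2]
    if D0 == 0:
        return 0.0
    if a == 0 and d == 0:
        return y[2] / D0
    if d == 0 and a > 0:
        # irreversible limit: the complex absorbs the limiting pool exactly;
        # the ODE approaches it only algebraically, so return the limit
        return (y[2] + min(y[0], y[1])) / D0
    if np.max(np.abs(dimer_rhs(0.0, y, a, d))) < criterion:
        return y[2] / D0

    # characteristic relaxation rate sets the first chunk length
    scale = max(a * (y[0] + y[1]), d, 1e-6)
    t_chunk = 10.0 / scale
    t_total = 0.0
    while t_total < time_cap:
        t_chunk = min(t_chunk, time_cap - t_total)
        sol = solve_ivp(
            dimer_rhs,
            (0.0, t_chunk),
            y,
            args=(a, d),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - LSODA failure is pathological here
            raise SteadyStateError(f"integrator failed: {sol.message}")
        y = sol.y[:, -1]
        t_total += t_chunk
        if np.max(np.abs(dimer_rhs(t_total, y, a, d))) < criterion:
            return float(y[2] / D0)
        t_chunk *= 2.0
    raise SteadyStateError(
        f"no steady state within t={time_cap:g} for a={a}, d={d} "
        f"(residual {np.max(np.abs(dimer_rhs(t_total, y, a, d))):.2e})"
    )


def _grid(grid_max: float, grid_step: float) -> np.ndarray:
    n = int(round(grid_max / grid_step))
    return np.arange(n + 1) * grid_step


def scan_rates(
    target: float,
    label: str = "",
    *,
    grid_max: float = GRID_MAX,
    grid_step: float = GRID_STEP,
    tol: float = TOLERANCE,
    verify: bool = True,
) -> ScanResult:
    """Find all grid (a, d) pairs whose steady-state bound fraction matches ``target``.

    Candidates are pre-filtered with the closed-form steady state (they must
    lie on the line d = a*(1-b)^2/b within the tolerance window) and, when
    ``verify`` is set, each survivor is confirmed by integrating the ODE; the
    accepted set equals the brute-force grid scan.  The degenerate origin
    (a = 0, d = 0) is excluded.
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("target binding fraction must lie in [0, 1]")
    grid = _grid(grid_max, grid_step)

    pairs: list[RateConstants] = []
    fractions: list[float] = []

    if target == 0.0:
        # only a = 0 yields exactly zero complex; any d > 0
        for d in grid[1:]:
            pairs.append(RateConstants(0.0, float(d)))
            fractions.append(0.0)
    elif target == 1.0:
        # irreversible limit: d = 0, any a > 0
        for a in grid[1:]:
            pairs.append(RateConstants(float(a), 0.0))
            fractions.append(1.0)
    else:
        a_pos = grid[1:]
        ratio = (1.0 - target) ** 2 / target  # d = ratio * a
        d_star = ratio * a_pos
        j0 = np.round(d_star / grid_step).astype(int)
        cand_a: list[float] = []
        cand_d: list[float] = []
        n_d = len(grid) - 1
        for off in (-2, -1, 0, 1, 2):
            j = j0 + off
            ok = (j >= 0) & (j <= n_d)
            cand_a.extend(a_pos[ok])
            cand_d.extend(grid[j[ok]])
        cand_a_arr = np.asarray(cand_a)
        cand_d_arr = np.asarray(cand_d)
        approx = closed_form_bound_fraction(cand_a_arr, cand_d_arr)
        keep = np.abs(approx - target) <= tol + 1e-7
        order = np.lexsort((cand_d_arr[keep], cand_a_arr[keep]))
        for a, d in zip(cand_a_arr[keep][order], cand_d_arr[keep][order]):
            if verify:
                b = steady_state_bound_fraction(RateConstants(float(a), float(d)))
            else:
                b = float(closed_form_bound_fraction(a, d))
            if abs(b - target) <= tol:
                pairs.append(RateConstants(float(a), float(d)))
                fractions.append(b)

    return ScanResult(
        label=label,
        target=target,
        pairs=pairs,
        tolerance=tol,
        grid_max=grid_max,
        grid_step=grid_step,
        bound_fractions=fractions,
    )


def scan_rates_exhaustive(
    target: float,
    a_values: Iterable[float],
    d_values: Iterable[float],
    *,
    tol: float = TOLERANCE,
    label: str = "",
) -> ScanResult:
    """Brute-force scan: integrate the ODE at every (a, d) in the given sub-range.

    Intended for small sub-grids (cross-checks, exploration); the full
    2501 x 2501 grid is handled by :func:`scan_rates`.
    """
    pairs: list[RateConstants] = []
    fractions: list[float] = []
    a_values = list(a_values)
    d_values = list(d_values)
    for a in a_values:
        for d in d_values:
            if a == 0.0 and d == 0.0:
                continue
            b = steady_state_bound_fraction(RateConstants(float(a), float(d)))
            if abs(b - target) <= tol:
                pairs.append(RateConstants(float(a), float(d)))
                fractions.append(b)
    step = float(a_values[1] - a_values[0]) if len(a_values) > 1 else np.nan
    return ScanResult(
        label=label,
        target=target,
        pairs=pairs,
        tolerance=tol,
        grid_max=float(max(list(a_values) + list(d_values))),
        grid_step=step,
        bound_fractions=fractions,
    )


def select_rate(
    result: ScanResult,
    policy: str = "random",
    seed: int | None = None,
) -> RateConstants:
    """Pick one accepted (a, d) pair.

    Policies: ``random`` (seeded draw, the default treatment of parameter
    degeneracy), ``fastest`` (largest association rate) and ``slowest``
    (smallest positive association rate) for speed-robustness checks.
    """
    if not result.pairs:
        raise ValueError(f"no accepted rate pairs for {result.label!r}")
    if policy == "random":
        rng = np.random.default_rng(seed)
        return result.pairs[int(rng.integers(len(result.pairs)))]
    if policy == "fastest":
        return max(result.pairs, key=lambda p: (p.a, p.d))
    if policy == "slowest":
        positive = [p for p in result.pairs if p.a > 0] or result.pairs
        return min(positive, key=lambda p: (p.a, p.d))
    raise ValueError(f"unknown policy {policy!r}")


def calibrate_all(
    affinities: Mapping[str, float],
    *,
    grid_max: float = GRID_MAX,
    grid_step: float = GRID_STEP,
    tol: float = TOLERANCE,
    policy: str = "random",
    seed: int | None = None,
) -> tuple[RateSet, dict[str, ScanResult]]:
    """Calibrate one rate pair per reaction and assemble the full RateSet.

    ``affinities`` must map every label in :data:`COMPLEX_LABELS` to a
    binding fraction in [0, 1].
    """
    missing = [lab for lab in COMPLEX_LABELS if lab not in affinities]
    if missing:
        raise KeyError(f"missing affinity for: {missing}")
    scans: dict[str, ScanResult] = {}
    chosen: dict[str, RateConstants] = {}
    rng = np.random.default_rng(seed)
    for lab in COMPLEX_LABELS:
        scan = scan_rates(
            float(affinities[lab]), lab, grid_max=grid_max, grid_step=grid_step, tol=tol
        )
        scans[lab] = scan
        sub_seed = int(rng.integers(2**31 - 1))
        chosen[lab] = select_rate(scan, policy=policy, seed=sub_seed)
    return RateSet(chosen), scans


class RateCalibrator(BaseEstimator):
    """Estimator mapping a binding-affinity table to mass-action rate constants.

    Parameters
    ----------
    grid_max, grid_step : float
        The (a, d) candidate grid, 0 to ``grid_max`` inclusive in steps of
        ``grid_step`` on both axes.
    tol : float
        Acceptance tolerance on |steady-state bound fraction - target|.
    policy : {"random", "fastest", "slowest"}
        How to pick one pair from the accepted set of each reaction.
    seed : int or None
        Seed for the ``random`` policy.

    Attributes
    ----------
    rates_ : RateSet
        One (a, d) pair per reaction.
    scans_ : dict[str, ScanResult]
        Full accepted sets per reaction.
    """

    def __init__(
        self,
        grid_max: float = GRID_MAX,
        grid_step: float = GRID_STEP,
        tol: float = TOLERANCE,
        policy: str = "random",
        seed: int | None = None,
    ):
        self.grid_max = grid_max
        self.grid_step = grid_step
        self.tol = tol
        self.policy = policy
        self.seed = seed

    def fit(self, affinities: Mapping[str, float], y=None) -> "RateCalibrator":
        if hasattr(affinities, "set_index") and not isinstance(affinities, dict):
            # a DataFrame with label/binding_fraction columns
            affinities = dict(
                zip(affinities["label"], affinities["binding_fraction"])
            )
        self.rates_, self.scans_ = calibrate_all(
            affinities,
            grid_max=self.grid_max,
            grid_step=self.grid_step,
            tol=self.tol,
            policy=self.policy,
            seed=self.seed,
        )
        return self
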