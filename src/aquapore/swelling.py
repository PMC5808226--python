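"""Oocyte swelling-assay kinetics: forward simulation and Pf/Psol estimation.

The osmotic water permeability coefficient Pf (cm/s) of a *Xenopus* oocyte
is obtained from the initial rate of relative-volume change after transfer
to a hypotonic bath::

    Pf = V0 * d(V/V0)/dt / [S * Vw * (Osm_in - Osm_out)]

where V0 is the initial oocyte volume (cm^3), S its surface area (cm^2),
Vw the molar volume of water (cm^3/mol) and Osm_in/Osm_out the internal
and bath osmolalities (mmol/kg).  Relative volume is inferred from the
projected silhouette area assuming a sphere, V/V0 = (A/A0)^(3/2).

The apparent solute permeability in an isotonic solute bath is::

    Psol = d(V/V0)/dt * (V0/S)

Osmolalities are bridged to molar concentrations taking 1 kg of water as
1000 cm^3, i.e. 1 mmol/kg == 1e-6 mol/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AssayConstants",
    "SwellingTrace",
    "PermeabilityEstimate",
    "GroupComparison",
    "IntegrationError",
    "InsufficientDataError",
    "relative_volume",
    "fit_initial_slope",
    "pf_from_slope",
    "psol_from_slope",
    "estimate_permeability",
    "simulate_swelling",
    "simulate_solute_uptake",
    "compare_groups",
]

#: 1 mmol/kg of water expressed in mol/cm^3 (1 kg water == 1000 cm^3).
OSMOLAL_TO_MOL_PER_CM3 = 1e-6

#: Default window (s) for the initial-slope fit: the first five frames of a
#: 15-s acquisition.  Pf is defined from the initial gradient, before the
#: shrinking osmotic gradient flattens the swelling curve.
DEFAULT_WINDOW_S = 60.0


class IntegrationError(RuntimeError):
    """The fixed-step integrator produced a non-physical trajectory."""


class InsufficientDataError(ValueError):
    """Fewer than two sample points available for a fit."""


@dataclass(frozen=True)
class AssayConstants:
    """Physical constants of the oocyte swelling assay.

    Defaults are the standard stage V/VI *Xenopus* oocyte values: volume
    9e-4 cm^3, surface area 0.045 cm^2, molar volume of water 18 cm^3/mol,
    internal osmolality 202 mmol/kg and a 3-fold-diluted Ringer bath of
    59 mmol/kg.
    """

    v0: float = 9e-4
    s: float = 0.045
    vw: float = 18.0
    osm_in: float = 202.0
    osm_out: float = 59.0

    def __post_init__(self) -> None:
        for name in ("v0", "s", "vw", "osm_in", "osm_out"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AssayConstants.{name} must be strictly positive")

    @property
    def delta_c(self) -> float:
        """Osmotic gradient Osm_in - Osm_out in mol/cm^3."""
        return (self.osm_in - self.osm_out) * OSMOLAL_TO_MOL_PER_CM3

    @property
    def c_in0(self) -> float:
        """Initial internal concentration in mol/cm^3."""
        return self.osm_in * OSMOLAL_TO_MOL_PER_CM3

    @property
    def c_out(self) -> float:
        """Bath concentration in mol/cm^3."""
        return self.osm_out * OSMOLAL_TO_MOL_PER_CM3


def relative_volume(rel_area: Sequence[float] | np.ndarray) -> np.ndarray:
    """Relative volume V/V0 from relative silhouette area, (A/A0)^(3/2).

    Raises ValueError naming the offending index if any area ratio is
    non-positive.
    """
    a = np.asarray(rel_area, dtype=float)
    bad = np.flatnonzero(~(a > 0))
    if bad.size:
        raise ValueError(f"non-positive relative area at index {bad[0]}: {a[bad[0]]!r}")
    return a ** 1.5


@dataclass
class SwellingTrace:
    """One oocyte's silhouette-area time series and derived relative volume."""

    oocyte_id: str
    group: str  # "expressing" | "control"
    condition: str  # "water" | "glycerol" | "trehalose" | "urea" | ...
    times: np.ndarray  # seconds from transfer, strictly increasing, first == 0
    rel_area: np.ndarray  # A/A0, rel_area[0] == 1
    rel_volume: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_area = np.asarray(self.rel_area, dtype=float)
        if self.times.size != self.rel_area.size:
            raise ValueError("times and rel_area must have equal length")
        if self.times.size and self.times[0] != 0.0:
            raise ValueError("trace must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.rel_area.size and self.rel_area[0] != 1.0:
            raise ValueError("rel_area[0] must be exactly 1 (areas are self-normalized)")
        if self.rel_volume is None:
            self.rel_volume = relative_volume(self.rel_area)
        else:
            self.rel_volume = np.asarray(self.rel_volume, dtype=float)
            if not np.allclose(self.rel_volume, relative_volume(self.rel_area)):
                raise ValueError("rel_volume inconsistent with rel_area^(3/2)")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Fitted initial slope of V/V0 and the derived permeability."""

    slope: float  # d(V/V0)/dt, 1/s
    kind: Literal["pf", "psol"]
    value: float  # cm/s
    window_s: float
    fit_r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.kind not in ("pf", "psol"):
            raise ValueError(f"kind must be 'pf' or 'psol', got {self.kind!r}")
        if self.n_points < 2:
            raise ValueError("a permeability estimate needs at least 2 points")
        if self.slope * self.value < 0:
            raise ValueError("permeability must have the sign of the fitted slope")


def fit_initial_slope(
    trace: SwellingTrace, window_s: float = DEFAULT_WINDOW_S
) -> tuple[float, float, int]:
    """Ordinary least-squares slope of V/V0 against time over [0, window_s].

    Returns ``(slope, r2, n_points)``.  A perfectly constant series has
    slope 0 and, by convention, r2 = 1 (the fit is exact).
    """
    mask = trace.times <= window_s
    t = trace.times[mask]
    v = trace.rel_volume[mask]
    if t.size < 2:
        raise InsufficientDataError(
            f"only {t.size} point(s) within [0, {window_s}] s; need at least 2"
        )
    slope, intercept = np.polyfit(t, v, 1)
    resid = v - (slope * t + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(v - v.mean(), v - v.mean()))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(r2), int(t.size)


def pf_from_slope(slope: float, constants: AssayConstants = AssayConstants()) -> float:
    """Osmotic water permeability Pf (cm/s) from d(V/V0)/dt."""
    if constants.osm_in == constants.osm_out:
        raise ZeroDivisionError(
            "Pf is undefined without an osmotic gradient (osm_in == osm_out)"
        )
    return constants.v0 * slope / (constants.s * constants.vw * constants.delta_c)


def psol_from_slope(slope: float, constants: AssayConstants = AssayConstants()) -> float:
    """Apparent solute permeability Psol (cm/s) = slope * V0/S."""
    return slope * constants.v0 / constants.s


def estimate_permeability(
    trace: SwellingTrace,
    kind: Literal["pf", "psol"],
    constants: AssayConstants = AssayConstants(),
    window_s: float = DEFAULT_WINDOW_S,
) -> PermeabilityEstimate:
    """Fit the initial slope of a trace and convert it to Pf or Psol."""
    slope, r2, n = fit_initial_slope(trace, window_s)
    value = pf_from_slope(slope, constants) if kind == "pf" else psol_from_slope(slope, constants)
    return PermeabilityEstimate(
        slope=slope, kind=kind, value=value, window_s=window_s, fit_r2=r2, n_points=n
    )


def _apply_area_noise(
    rel_area: np.ndarray, noise_sd: float, seed: int | None
) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return rel_area
    rng = np.random.default_rng(seed)
    noisy = rel_area.copy()
    noisy[1:] *= rng.normal(1.0, noise_sd, size=rel_area.size - 1)
    if np.any(noisy <= 0):
        raise ValueError("area noise produced a non-positive area; lower noise_sd")
    return noisy


def simulate_swelling(
    pf: float,
    constants: AssayConstants = AssayConstants(),
    dt: float = 15.0,
    duration: float = 300.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    oocyte_id: str = "sim",
    group: str = "expressing",
    condition: str = "water",
    internal_dt: float = 1.0,
) -> SwellingTrace:
    """Simulate hypotonic swelling of a single oocyte.

    Integrates dV/dt = Pf * S * Vw * (c_in(t) - c_out) with conserved
    internal solute, c_in(t) = c_in(0) * V0 / V(t), and constant surface
    area, by classical fixed-step 4th-order Runge-Kutta with an internal
    step of at most ``internal_dt`` seconds, resampled onto the ``dt``
    output grid.  Silhouette area follows as (V/V0)^(2/3); multiplicative
    Gaussian noise of standard deviation ``noise_sd`` is applied to every
    area except the t=0 frame, which is pinned to 1 by the normalization.
    """
    if pf < 0:
        raise ValueError("pf must be non-negative")
    if dt <= 0 or internal_dt <= 0:
        raise ValueError("time steps must be positive")
    if duration < dt:
        raise ValueError("duration must cover at least one step")

    n_out = int(np.floor(duration / dt + 1e-9)) + 1
    n_sub = max(1, int(np.ceil(dt / internal_dt - 1e-9)))
    h = dt / n_sub
    amount_in = constants.c_in0 * constants.v0  # conserved mol of internal solute

    def dv_dt(v: float) -> float:
        return pf * constants.s * constants.vw * (amount_in / v - constants.c_out)

    v = constants.v0
    rel_vol = np.empty(n_out)
    rel_vol[0] = 1.0
    increasing = constants.osm_in > constants.osm_out
    for i in range(1, n_out):
        for _ in range(n_sub):
            k1 = dv_dt(v)
            k2 = dv_dt(v + 0.5 * h * k1)
            k3 = dv_dt(v + 0.5 * h * k2)
            k4 = dv_dt(v + h * k3)
            v_new = v + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if pf > 0 and increasing and v_new < v:
                raise IntegrationError(
                    "noiseless volume decreased under a hypotonic gradient; "
                    "reduce internal_dt"
                )
            if v_new <= 0:
                raise IntegrationError("volume went non-positive; reduce internal_dt")
            v = v_new
        rel_vol[i] = v / constants.v0

    rel_area = rel_vol ** (2.0 / 3.0)
    rel_area = _apply_area_noise(rel_area, noise_sd, seed)
    return SwellingTrace(
        oocyte_id=oocyte_id,
        group=group,
        condition=condition,
        times=np.arange(n_out) * dt,
        rel_area=rel_area,
    )


def simulate_solute_uptake(
    psol: float,
    constants: AssayConstants = AssayConstants(),
    dt: float = 15.0,
    duration: float = 300.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    oocyte_id: str = "sim",
    group: str = "expressing",
    condition: str = "glycerol",
) -> SwellingTrace:
    """Simulate isotonic solute uptake: V/V0 grows linearly at psol*S/V0.

    In an isotonic solute bath the water influx tracks solute entry, so the
    apparent-permeability definition Psol = d(V/V0)/dt * V0/S inverts to a
    constant relative-volume growth rate.  Noise handling matches
    :func:`simulate_swelling`.
    """
    if psol < 0:
        raise ValueError("psol must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must cover at least one step")
    times = np.arange(int(np.floor(duration / dt + 1e-9)) + 1) * dt
    rel_vol = 1.0 + psol * constants.s / constants.v0 * times
    rel_area = rel_vol ** (2.0 / 3.0)
    rel_area = _apply_area_noise(rel_area, noise_sd, seed)
    return SwellingTrace(
        oocyte_id=oocyte_id,
        group=group,
        condition=condition,
        times=times,
        rel_area=rel_area,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of permeability estimates (mean ± SEM, t-test)."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    fold: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_groups(
    estimates_a: Sequence[PermeabilityEstimate],
    estimates_b: Sequence[PermeabilityEstimate],
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided Student's t comparison of two groups of permeabilities.

    Both groups must hold estimates of the same kind (pf with pf, psol with
    psol).  When both groups are degenerate (zero variance) with equal
    means, p = 1 by convention.
    """
    if len(estimates_a) < 2 or len(estimates_b) < 2:
        raise ValueError("each group needs at least 2 estimates")
    kinds = {e.kind for e in estimates_a} | {e.kind for e in estimates_b}
    if len(kinds) != 1:
        raise ValueError(f"cannot compare mixed permeability kinds: {sorted(kinds)}")
    a = np.array([e.value for e in estimates_a], dtype=float)
    b = np.array([e.value for e in estimates_b], dtype=float)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sem_a = float(stats.sem(a))
    sem_b = float(stats.sem(b))
    if a.std() == 0.0 and b.std() == 0.0:
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    fold = mean_a / mean_b if mean_b != 0 else np.inf
    return GroupComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        n_a=a.size,
        n_b=b.size,
        fold=float(fold),
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )
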