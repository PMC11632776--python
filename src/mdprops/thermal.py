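"""Cooling-curve assembly, glass-transition estimation, thermal expansion.

The glass-transition temperature of an amorphous polymer shows up as a change
of slope in the specific volume V(T) = 1/rho(T) recorded along a slow cooling
schedule.  Broken-stick regression fits one ordinary least-squares line to
the points clearly below Tg and one to the points clearly above; the
abscissa of their intersection estimates Tg.  The volumetric thermal
expansion coefficient is the relative finite-difference slope of V over a
narrow temperature interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AnalysisError, PropertyResult, TimeSeriesTable

#: below this slope difference (cm^3/(g K)) the two fitted lines are treated
#: as parallel and Tg is undefined
PARALLEL_SLOPE_TOL = 1e-12


@dataclass
class VTSeries:
    """Temperature-indexed density / specific-volume points from cooling."""

    temperatures: np.ndarray  # K, strictly increasing
    densities: np.ndarray  # g/cm^3
    specific_volumes: np.ndarray  # cm^3/g, = 1/density
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        self.specific_volumes = np.asarray(self.specific_volumes, dtype=float)
        if not np.all(np.diff(self.temperatures) > 0):
            raise AnalysisError("temperatures must be strictly increasing")
        if np.any(self.densities <= 0):
            raise AnalysisError("densities must be positive")
        rel = np.abs(self.specific_volumes * self.densities - 1.0)
        if np.any(rel > 1e-12):
            raise AnalysisError("specific volume must equal 1/density")

    @property
    def n_points(self) -> int:
        return len(self.temperatures)


@dataclass
class TgResult:
    """Broken-stick fit: two lines, their windows, and the intersection."""

    tg: float  # K
    low_fit: tuple[float, float]  # (slope, intercept) of the glassy branch
    high_fit: tuple[float, float]  # (slope, intercept) of the rubbery branch
    low_residual_se: float
    high_residual_se: float
    low_window: tuple[float, float]
    high_window: tuple[float, float]


def average_density(series: TimeSeriesTable, window: float) -> PropertyResult:
    """Mean +/- sd of density over the final ``window`` ns of a run.

    Mirrors the convention of averaging an NPT production run over its last
    0.5 ns, after the box has stabilised.
    """
    t = series.values[:, 0]
    rho = series.values[:, 1]
    span = t[-1] - t[0]
    if span < window:
        raise AnalysisError(
            f"window {window} ns exceeds series span {span} ns"
        )
    mask = t >= t[-1] - window
    mean = float(np.mean(rho[mask]))
    sd = float(np.std(rho[mask]))
    return PropertyResult(
        name="density",
        value=mean,
        unit="g/cm^3",
        error=sd,
        provenance={"window_ns": window, "n_samples": int(mask.sum())},
    )


def build_vt_series(per_temperature: list[tuple[float, PropertyResult]],
                    metadata: dict | None = None) -> VTSeries:
    """Assemble per-temperature density averages into a V(T) series."""
    temps = np.array([T for T, _ in per_temperature], dtype=float)
    if len(np.unique(temps)) != len(temps):
        raise AnalysisError("duplicate temperatures in cooling curve")
    rhos = np.array([r.value for _, r in per_temperature], dtype=float)
    if np.any(rhos <= 0):
        raise AnalysisError("density must be positive")
    order = np.argsort(temps)
    temps, rhos = temps[order], rhos[order]
    return VTSeries(
        temperatures=temps,
        densities=rhos,
        specific_volumes=1.0 / rhos,
        metadata=metadata or {},
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, residual se)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(len(x) - 2, 1)
    return float(slope), float(intercept), float(np.sqrt(np.sum(resid**2) / dof))


def broken_stick_tg(
    vt: VTSeries,
    low_window: tuple[float, float] = (150.0, 275.0),
    high_window: tuple[float, float] = (475.0, 600.0),
) -> TgResult:
    """Estimate Tg as the intersection of two OLS lines on V(T).

    ``low_window`` and ``high_window`` are inclusive temperature ranges
    selecting the points clearly below and clearly above the transition.
    """
    T, V = vt.temperatures, vt.specific_volumes
    lo = (T >= low_window[0]) & (T <= low_window[1])
    hi = (T >= high_window[0]) & (T <= high_window[1])
    if lo.sum() < 2 or hi.sum() < 2:
        raise AnalysisError(
            f"need >= 2 points per window, got {int(lo.sum())} low / {int(hi.sum())} high"
        )
    m1, b1, se1 = _ols_line(T[lo], V[lo])
    m2, b2, se2 = _ols_line(T[hi], V[hi])
    if abs(m2 - m1) < PARALLEL_SLOPE_TOL:
        raise AnalysisError("parallel fits, Tg undefined")
    tg = (b1 - b2) / (m2 - m1)
    return TgResult(
        tg=float(tg),
        low_fit=(m1, b1),
        high_fit=(m2, b2),
        low_residual_se=se1,
        high_residual_se=se2,
        low_window=tuple(low_window),
        high_window=tuple(high_window),
    )


def thermal_expansion(
    vt: VTSeries, t1: float, t2: float, normalization: str = "low"
) -> PropertyResult:
    """Volumetric thermal expansion alpha_V over [t1, t2].

    alpha_V = (V(T2) - V(T1)) / ((T2 - T1) * V_ref) in 1/K, with V_ref the
    lower-temperature volume by default ("low") or the midpoint volume
    ("mid").  A narrow interval (25 K) is recommended because alpha_V(T) is
    strongly nonlinear.
    """
    if t2 <= t1:
        raise AnalysisError(f"require T2 > T1, got {t1} >= {t2}")

    def _v(T: float) -> float:
        i = np.where(np.isclose(vt.temperatures, T, rtol=0, atol=1e-9))[0]
        if len(i) == 0:
            raise AnalysisError(f"temperature {T} K not in series")
        return float(vt.specific_volumes[i[0]])

    v1, v2 = _v(t1), _v(t2)
    if normalization == "low":
        vref = v1
    elif normalization == "mid":
        vref = 0.5 * (v1 + v2)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    alpha = (v2 - v1) / ((t2 - t1) * vref)
    return PropertyResult(
        name="alpha_V",
        value=float(alpha),
        unit="1/K",
        provenance={"T1_K": t1, "T2_K": t2, "normalization": normalization},
    )
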