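"""Stress-strain processing and elastic constants from deformation runs.

Uniaxial deformation of a periodic box gives engineering strain
eps = (L_t - L0)/L0 and stress sigma(eps) = -P_z(eps) (pressure tensor
component along the pull direction, bar -> GPa).  The raw curve is smoothed
by averaging over a +/-2.5% strain window; to pin the curve to zero stress
at zero strain, the data is first reflected with a negative sign around
eps = 0.  Young's modulus is the Hooke's-law slope over 0.3-3% strain,
maximum tensile strength the largest smoothed stress between 3% and 97%.
Poisson's ratio comes from the transverse box response over 1-2% strain,
and the bulk modulus from Lame's relation K = E / (3 (1 - 2 nu)), which
degenerates as nu -> 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BAR_TO_GPA
from .types import AnalysisError, PropertyResult, TimeSeriesTable

#: |1 - 2 nu| below this marks the bulk modulus as unreliable
NEAR_INCOMPRESSIBLE_TOL = 1e-3


@dataclass
class StressStrainCurve:
    strains: np.ndarray  # dimensionless, in [0, 1], increasing
    stress: np.ndarray  # GPa, raw
    smoothed: np.ndarray | None = None  # GPa, on the same strain grid
    half_width: float | None = None
    reflected: bool = False

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if np.any(self.strains < 0) or np.any(self.strains > 1):
            raise AnalysisError("raw strains must lie in [0, 1]")
        if not np.all(np.diff(self.strains) > 0):
            raise AnalysisError("strains must be strictly increasing")


@dataclass
class ElasticConstants:
    """Per-direction or aggregated elastic constants (GPa except nu)."""

    E: float
    sigma_max: float
    nu: float
    K: float
    E_err: float | None = None
    sigma_max_err: float | None = None
    nu_err: float | None = None
    K_err: float | None = None
    flags: list[str] = field(default_factory=list)


def stress_from_pressure(pz: TimeSeriesTable) -> StressStrainCurve:
    """sigma = -P_z converted from bar to GPa, on the strain grid."""
    if "strain" not in pz.names:
        raise AnalysisError(f"missing strain column; have {pz.names}")
    strain = pz.column("strain")
    pcol = [n for n in pz.names if n != "strain"][0]
    unit = pz.unit(pcol)
    p = pz.column(pcol)
    if unit == "bar":
        sigma = -p * BAR_TO_GPA
    elif unit == "GPa":
        sigma = -p
    else:
        raise AnalysisError(f"pressure column must be flagged bar or GPa, got {unit!r}")
    return StressStrainCurve(strains=strain, stress=sigma)


def strain_series(lengths: TimeSeriesTable, L0: float) -> np.ndarray:
    """Engineering strain (L_t - L0)/L0 for each record."""
    if L0 <= 0:
        raise AnalysisError("reference length L0 must be positive")
    return (lengths.values[:, 1] - L0) / L0


def smooth_reflect(
    curve: StressStrainCurve, half_width: float = 0.025, reflect: bool = True
) -> StressStrainCurve:
    """Window-average the stress over +/-``half_width`` strain.

    With ``reflect`` the odd-reflected points (-eps, -sigma) participate in
    windows that dip below zero strain, which forces the smoothed curve
    through (0, 0).  Near the upper data edge the half-width shrinks to
    keep every window centred on its grid point, so a linear curve maps to
    itself exactly on the whole grid.
    """
    if half_width <= 0:
        raise AnalysisError("half_width must be positive")
    eps, sig = curve.strains, curve.stress
    span = eps[-1] - eps[0]
    if half_width >= span:
        raise AnalysisError(
            f"half_width {half_width} >= data span {span}"
        )
    if reflect:
        # odd reflection: a sample at exactly eps = 0 must carry zero stress
        # to be consistent with sigma(-0) = -sigma(0)
        sig0 = np.where(eps == 0.0, 0.0, sig)
        pos = eps > 0
        aug_e = np.concatenate([-eps[pos][::-1], eps])
        aug_s = np.concatenate([-sig0[pos][::-1], sig0])
    else:
        aug_e, aug_s = eps, sig
    smoothed = np.empty_like(sig)
    tol = 1e-12
    for i, e in enumerate(eps):
        h = min(half_width, eps[-1] - e)
        mask = np.abs(aug_e - e) <= h + tol
        smoothed[i] = aug_s[mask].mean()
    if reflect:
        smoothed[eps == 0.0] = 0.0  # window is antisymmetric there
    return StressStrainCurve(
        strains=eps, stress=sig, smoothed=smoothed,
        half_width=half_width, reflected=reflect,
    )


def _require_smoothed(curve: StressStrainCurve) -> np.ndarray:
    if curve.smoothed is None:
        raise AnalysisError("curve has no smoothed stress; run smooth_reflect first")
    return curve.smoothed


def youngs_modulus(
    curve: StressStrainCurve, fit_lo: float = 0.003, fit_hi: float = 0.03
) -> PropertyResult:
    """Hooke's-law modulus: zero-intercept OLS slope of sigma vs eps.

    The reflection step already pins the smoothed curve to the origin, so
    the fit carries no free intercept.
    """
    sig = _require_smoothed(curve)
    mask = (curve.strains >= fit_lo) & (curve.strains <= fit_hi)
    if mask.sum() < 2:
        raise AnalysisError(
            f"need >= 2 smoothed points in [{fit_lo}, {fit_hi}], got {int(mask.sum())}"
        )
    e, s = curve.strains[mask], sig[mask]
    denom = float(np.sum(e * e))
    slope = float(np.sum(s * e) / denom) if denom > 0 else 0.0
    return PropertyResult(
        name="youngs_modulus", value=slope, unit="GPa",
        provenance={"fit_window": [fit_lo, fit_hi], "n_points": int(mask.sum()),
                    "intercept": "zero", "half_width": curve.half_width},
    )


def max_stress(
    curve: StressStrainCurve, lo: float = 0.03, hi: float = 0.97
) -> PropertyResult:
    """Largest smoothed stress on [lo, hi]; ties break to the smaller strain."""
    sig = _require_smoothed(curve)
    mask = (curve.strains >= lo) & (curve.strains <= hi)
    if not np.any(mask):
        raise AnalysisError(f"no smoothed points in [{lo}, {hi}]")
    seg_e, seg_s = curve.strains[mask], sig[mask]
    i = int(np.argmax(seg_s))  # first occurrence == smallest strain
    return PropertyResult(
        name="max_stress", value=float(seg_s[i]), unit="GPa",
        provenance={"strain_at_max": float(seg_e[i]), "window": [lo, hi]},
    )


def poisson_ratio(
    deformation: TimeSeriesTable, fit_lo: float = 0.01, fit_hi: float = 0.02
) -> PropertyResult:
    """nu = -(slope of transverse strain vs axial strain) over the window.

    The deformation table holds the axial strain followed by one or two
    transverse box lengths (semi-isotropic coupling makes the two
    transverse directions equal); with a single column a warning flag is
    recorded.  The transverse reference length is the length at zero axial
    strain.
    """
    ea = deformation.values[:, 0]
    trans_idx = [
        i for i, (name, _) in enumerate(deformation.columns)
        if i > 0 and name != "L_axial"
    ]
    if not trans_idx:
        raise AnalysisError("no transverse length columns")
    flags = [] if len(trans_idx) >= 2 else ["single transverse direction"]
    trans = deformation.values[:, trans_idx]
    i0 = np.where(np.isclose(ea, 0.0, atol=1e-12))[0]
    ref_row = i0[0] if len(i0) else 0
    if not len(i0):
        flags.append("no zero-strain record; first row used as reference")
    et = trans / trans[ref_row] - 1.0
    et_mean = et.mean(axis=1)
    mask = (ea >= fit_lo) & (ea <= fit_hi)
    if mask.sum() < 2:
        raise AnalysisError(f"need >= 2 points in [{fit_lo}, {fit_hi}]")
    slope = np.polyfit(ea[mask], et_mean[mask], 1)[0]
    nu = -float(slope)
    prov = {"fit_window": [fit_lo, fit_hi], "n_points": int(mask.sum()),
            "reference": "length at zero axial strain"}
    if flags:
        prov["flags"] = flags
    return PropertyResult(name="poisson_ratio", value=nu,
                          unit="dimensionless", provenance=prov)


def bulk_modulus(E: float, nu: float) -> PropertyResult:
    """Lame's relation K = E / (3 (1 - 2 nu)) for an isotropic solid.

    As nu approaches 0.5 the denominator vanishes and small fluctuations in
    nu blow up K; within ``NEAR_INCOMPRESSIBLE_TOL`` of that point the
    result is flagged rather than reported as a bare number.
    """
    if E < 0:
        raise AnalysisError("E must be non-negative")
    if nu > 0.5:
        raise AnalysisError(f"nu = {nu} > 0.5 is non-physical for Lame's relation")
    denom = 3.0 * (1.0 - 2.0 * nu)
    prov: dict = {"relation": "K = E / (3 (1 - 2 nu))", "nu": nu}
    if abs(1.0 - 2.0 * nu) < NEAR_INCOMPRESSIBLE_TOL:
        prov["flags"] = ["near-incompressible: K unreliable"]
        value = float("inf") if denom == 0 else E / denom
    else:
        value = E / denom
    return PropertyResult(name="bulk_modulus", value=float(value),
                          unit="GPa", provenance=prov)


def aggregate_directions(per_direction: list[ElasticConstants]) -> ElasticConstants:
    """Mean +/- population std of each constant over the three pull axes."""
    if len(per_direction) != 3:
        raise AnalysisError(f"need exactly 3 directions, got {len(per_direction)}")

    def agg(vals):
        a = np.array(vals, dtype=float)
        return float(a.mean()), float(a.std())

    E, E_err = agg([d.E for d in per_direction])
    s, s_err = agg([d.sigma_max for d in per_direction])
    nu, nu_err = agg([d.nu for d in per_direction])
    K, K_err = agg([d.K for d in per_direction])
    flags = sorted({f for d in per_direction for f in d.flags})
    return ElasticConstants(E=E, sigma_max=s, nu=nu, K=K, E_err=E_err,
                            sigma_max_err=s_err, nu_err=nu_err, K_err=K_err,
                            flags=flags)


def delta_energy(energies: TimeSeriesTable) -> TimeSeriesTable:
    """Subtract the first-row value from every energy column (E - E0)."""
    if energies.n_rows < 1:
        raise AnalysisError("empty energy table")
    values = energies.values.copy()
    values[:, 1:] -= values[0, 1:]
    return TimeSeriesTable(columns=list(energies.columns), values=values)
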