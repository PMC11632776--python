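"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its arguments and a
:class:`GeneratorSpec` (seed + noise level): identical inputs give
bit-identical output.  The generators emulate the statistical structure of
the MD series the pipeline consumes — a piecewise-linear specific-volume
cooling curve, two-state bond-event series, elastic-plastic stress-strain
sweeps, semi-isotropic transverse box response, Brownian trajectories and
non-overlapping periodic sphere packings — so each analyzer can be tested by
parameter recovery without an MD engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image
from .hbond import BondEventMatrix
from .thermal import VTSeries
from .types import AnalysisError, ConfigurationFrame, TimeSeriesTable
from .dynamics import DisplacementTrajectory


@dataclass
class GeneratorSpec:
    seed: int = 0
    noise_sd: float = 0.0  # units of the generated observable

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_vt_curve(
    tg: float = 400.0,
    slope_low: float = 1.0e-4,
    slope_high: float = 3.0e-4,
    v_at_tg: float = 0.54,
    temps=np.arange(150.0, 601.0, 25.0),
    spec: GeneratorSpec = GeneratorSpec(),
) -> VTSeries:
    """Two-line hinge V(T) meeting at (tg, v_at_tg), plus Gaussian noise.

    slope_high > slope_low > 0 (glassy branch expands less than the rubbery
    branch).  Noise is i.i.d. on the specific volume, sd = ``spec.noise_sd``
    in cm^3/g.
    """
    temps = np.asarray(temps, dtype=float)
    if not np.all(np.diff(temps) > 0):
        raise AnalysisError("temperatures must be strictly increasing")
    if not (slope_low > 0 and slope_high > 0):
        raise AnalysisError("slopes must be positive for a physical transition")
    v = np.where(
        temps <= tg,
        v_at_tg + slope_low * (temps - tg),
        v_at_tg + slope_high * (temps - tg),
    )
    if spec.noise_sd > 0:
        v = v + spec.rng().normal(0.0, spec.noise_sd, size=v.shape)
    meta = {"tg_true_K": tg, "slope_low": slope_low, "slope_high": slope_high,
            "noise_sd": spec.noise_sd, "seed": spec.seed}
    if slope_high == slope_low:
        meta["warnings"] = ["Tg unidentifiable"]
    return VTSeries(
        temperatures=temps, densities=1.0 / v, specific_volumes=v, metadata=meta
    )


def gen_bond_events(
    n_bonds: int,
    n_frames: int,
    dt: float,
    k_break: float,
    k_reform: float,
    spec: GeneratorSpec = GeneratorSpec(),
) -> BondEventMatrix:
    """Two-state Markov bond histories; all bonds start formed.

    Per step: P(break) = 1 - exp(-k_break dt), P(reform) = 1 - exp(-k_reform
    dt), with rates in 1/ns and dt in ns.
    """
    if k_break < 0 or k_reform < 0 or dt <= 0:
        raise AnalysisError("rates must be >= 0 and dt > 0")
    p_break = 1.0 - np.exp(-k_break * dt)
    p_reform = 1.0 - np.exp(-k_reform * dt)
    rng = spec.rng()
    ind = np.empty((n_bonds, n_frames), dtype=np.int8)
    state = np.ones(n_bonds, dtype=bool)
    ind[:, 0] = 1
    for k in range(1, n_frames):
        u = rng.random(n_bonds)
        state = np.where(state, u >= p_break, u < p_reform)
        ind[:, k] = state
    bonds = [(3 * i, 3 * i + 1, 3 * i + 2) for i in range(n_bonds)]
    return BondEventMatrix(bonds=bonds, times=np.arange(n_frames) * dt,
                           indicators=ind)


def gen_stress_strain(
    E_true: float,
    strain_yield: float,
    sigma_plateau: float,
    strains,
    spec: GeneratorSpec = GeneratorSpec(),
    knee_halfwidth: float | None = None,
) -> TimeSeriesTable:
    """Elastic-plastic stress sweep: linear at slope E, plateau beyond yield.

    The knee is a cubic Hermite blend over ``strain_yield`` +/-
    ``knee_halfwidth`` (default 20% of the yield strain), so the curve is
    exactly linear below the knee and exactly the plateau above it.  When
    sigma_plateau exceeds E * max(strain) the whole sweep is linear.
    Gaussian noise (sd in GPa) is added to the stress.
    """
    strains = np.asarray(strains, dtype=float)
    if np.any(strains < 0) or np.any(strains > 1):
        raise AnalysisError("strains must lie in [0, 1]")
    if E_true < 0:
        raise AnalysisError("E must be non-negative")
    w = knee_halfwidth if knee_halfwidth is not None else 0.2 * strain_yield
    a, b = strain_yield - w, strain_yield + w
    sigma = np.where(strains <= a, E_true * strains, sigma_plateau)
    if w > 0:
        mid = (strains > a) & (strains < b)
        s = (strains[mid] - a) / (b - a)
        h00 = 2 * s**3 - 3 * s**2 + 1
        h10 = s**3 - 2 * s**2 + s
        h01 = -2 * s**3 + 3 * s**2
        sigma[mid] = h00 * (E_true * a) + h10 * (b - a) * E_true + h01 * sigma_plateau
    sigma = np.minimum(sigma, np.maximum(E_true * strains, sigma_plateau))
    if spec.noise_sd > 0:
        sigma = sigma + spec.rng().normal(0.0, spec.noise_sd, size=sigma.shape)
    return TimeSeriesTable(
        columns=[("strain", "dimensionless"), ("stress", "GPa")],
        values=np.column_stack([strains, sigma]),
    )


def gen_box_deformation(
    nu_true: float,
    L0: float,
    strains,
    spec: GeneratorSpec = GeneratorSpec(),
    volume_preserving: bool = False,
) -> TimeSeriesTable:
    """Axial and (coupled, equal) transverse box lengths under uniaxial pull.

    Default linear convention: transverse strain = -nu_true * axial strain.
    With ``volume_preserving`` the finite-strain incompressible response
    L_trans = L0 (1+eps)^(-1/2) is emitted instead (nu_true is ignored).
    Optional Gaussian noise (sd in nm) applies to the transverse lengths.
    """
    strains = np.asarray(strains, dtype=float)
    if not (-1.0 <= nu_true <= 0.5):
        raise AnalysisError("nu must lie in [-1, 0.5]")
    if L0 <= 0:
        raise AnalysisError("L0 must be positive")
    L_axial = L0 * (1.0 + strains)
    if volume_preserving:
        L_trans = L0 * (1.0 + strains) ** -0.5
    else:
        L_trans = L0 * (1.0 - nu_true * strains)
    rng = spec.rng()
    cols = [("strain", "dimensionless"), ("L_axial", "nm"),
            ("L_trans_x", "nm"), ("L_trans_y", "nm")]
    tx = L_trans.copy()
    ty = L_trans.copy()
    if spec.noise_sd > 0:
        tx = tx + rng.normal(0.0, spec.noise_sd, size=tx.shape)
        ty = ty + rng.normal(0.0, spec.noise_sd, size=ty.shape)
    return TimeSeriesTable(
        columns=cols, values=np.column_stack([strains, L_axial, tx, ty])
    )


def gen_random_walk(
    D_true: float,
    n_particles: int,
    n_frames: int,
    dt: float,
    spec: GeneratorSpec = GeneratorSpec(),
) -> DisplacementTrajectory:
    """Brownian trajectories: per-coordinate step variance 2 D dt (unwrapped).

    D_true in nm^2/ns, dt in ns; all particles start at the origin.
    """
    if D_true < 0 or dt <= 0:
        raise AnalysisError("need D >= 0 and dt > 0")
    rng = spec.rng()
    steps = rng.normal(
        0.0, np.sqrt(2.0 * D_true * dt), size=(n_frames - 1, n_particles, 3)
    ) if D_true > 0 else np.zeros((n_frames - 1, n_particles, 3))
    pos = np.concatenate(
        [np.zeros((1, n_particles, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    return DisplacementTrajectory(times=np.arange(n_frames) * dt, positions=pos)


def gen_packing(
    n_atoms: int,
    radius: float,
    box,
    spec: GeneratorSpec = GeneratorSpec(),
    element: str = "C",
    max_attempts_per_atom: int = 1000,
) -> ConfigurationFrame:
    """Uniform non-overlapping sphere packing (min-image separation >= 2r).

    Rejection sampling; raises "packing too dense" once the per-atom
    placement budget is exhausted.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    rng = spec.rng()
    placed: list[np.ndarray] = []
    attempts = 0
    budget = max(1, n_atoms) * max_attempts_per_atom
    while len(placed) < n_atoms:
        if attempts >= budget:
            raise AnalysisError("packing too dense: placement budget exhausted")
        attempts += 1
        cand = rng.uniform(0.0, box)
        if placed:
            d = minimum_image(np.array(placed) - cand, box)
            if np.min(np.sqrt((d * d).sum(axis=1))) < 2.0 * radius:
                continue
        placed.append(cand)
    pos = np.array(placed).reshape(n_atoms, 3)
    return ConfigurationFrame(
        elements=np.array([element] * n_atoms, dtype=object),
        names=np.array([f"{element}{i + 1}" for i in range(n_atoms)], dtype=object),
        mol_index=np.arange(n_atoms),
        positions=pos,
        box=box,
    )


def gen_hbond_geometry(d_OO: float, theta: float, box) -> ConfigurationFrame:
    """One donor O-H pair plus one acceptor O at a prescribed geometry.

    The acceptor sits at distance ``d_OO`` nm along +x from the donor; the
    hydrogen is placed (0.1 nm bond) so the H-donor-acceptor angle equals
    ``theta`` degrees.
    """
    if d_OO <= 0 or not (0 <= theta <= 180):
        raise AnalysisError("need d_OO > 0 and theta in [0, 180]")
    box = np.asarray(box, dtype=float).reshape(3)
    center = box / 2.0
    th = np.radians(theta)
    oh = 0.1
    h = center + oh * np.array([np.cos(th), np.sin(th), 0.0])
    acceptor = center + np.array([d_OO, 0.0, 0.0])
    return ConfigurationFrame(
        elements=np.array(["O", "H", "O"], dtype=object),
        names=np.array(["OD", "HD", "OA"], dtype=object),
        mol_index=np.array([0, 0, 1]),
        positions=np.stack([center, h, acceptor]),
        box=box,
    )
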