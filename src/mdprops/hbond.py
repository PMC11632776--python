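"""Hydrogen-bond detection and kinetics.

A hydrogen bond is declared when the donor-oxygen to acceptor-oxygen
minimum-image distance is below ``r_max`` (default 0.35 nm) and the angle at
the donor oxygen, between its hydrogen and the acceptor oxygen, is below
``theta_max`` (default 30 degrees); both inequalities are strict.

Kinetics follow the intermittent existence function C_HB(t): the indicator
autocorrelation over multiple time origins, normalised per lag.  Because in
rigid glasses many bonds never break within the sampled window, C_HB is
extrapolated by fitting a two-term weighted exponential decay

    C(t) = K1 exp(-t/tau1) + K2 exp(-t/tau2),

whose full integral K1*tau1 + K2*tau2 is the bond lifetime and whose
0.5-crossing time is the half-life.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .geometry import minimum_image
from .types import AnalysisError, ConfigurationFrame, TimeSeriesTable


@dataclass
class HBondCriterion:
    r_max: float = 0.35  # nm, donor O -- acceptor O
    theta_max: float = 30.0  # degrees, H - donorO - acceptorO

    def __post_init__(self) -> None:
        if self.r_max <= 0 or not (0 < self.theta_max < 180):
            raise ValueError("invalid hydrogen-bond criterion")


@dataclass
class HBondSelection:
    """Atom-name patterns identifying donors, hydrogens and acceptors.

    By default every oxygen with an attached hydrogen (same molecule, O-H
    distance < ``oh_bond_max``) is a donor and every oxygen an acceptor.
    When ``donor_names`` lists explicit atoms, each must have an attached
    hydrogen or detection fails.
    """

    donor_pattern: str = "O*"
    hydrogen_pattern: str = "H*"
    acceptor_pattern: str = "O*"
    oh_bond_max: float = 0.12  # nm
    donor_names: list[str] | None = None


Bond = tuple[int, int, int]  # donor O index, H index, acceptor O index


def _match(names: np.ndarray, pattern: str) -> np.ndarray:
    return np.array([fnmatch.fnmatch(str(n), pattern) for n in names], dtype=bool)


def _donor_pairs(
    frame: ConfigurationFrame, selection: HBondSelection
) -> list[tuple[int, int]]:
    names = frame.names
    if selection.donor_names is not None:
        donor_idx = [i for i, n in enumerate(names) if str(n) in selection.donor_names]
        strict = True
    else:
        donor_idx = list(np.where(_match(names, selection.donor_pattern))[0])
        strict = False
    h_idx = np.where(_match(names, selection.hydrogen_pattern))[0]
    pairs: list[tuple[int, int]] = []
    for d in donor_idx:
        found = False
        same_mol = h_idx[frame.mol_index[h_idx] == frame.mol_index[d]]
        if len(same_mol):
            dvec = minimum_image(
                frame.positions[same_mol] - frame.positions[d], frame.box
            )
            dist = np.linalg.norm(dvec, axis=1)
            for h, r in zip(same_mol, dist):
                if r < selection.oh_bond_max:
                    pairs.append((int(d), int(h)))
                    found = True
        if strict and not found:
            raise AnalysisError(
                f"donor atom {names[d]!r} (index {d}) has no attached hydrogen"
            )
    return pairs


def detect_hbonds(
    frame: ConfigurationFrame,
    criterion: HBondCriterion = HBondCriterion(),
    selection: HBondSelection = HBondSelection(),
) -> list[Bond]:
    """Geometric hydrogen bonds in one frame (minimum-image convention)."""
    acceptors = np.where(_match(frame.names, selection.acceptor_pattern))[0]
    bonds: list[Bond] = []
    for d, h in _donor_pairs(frame, selection):
        acc = acceptors[acceptors != d]
        if not len(acc):
            continue
        doo = minimum_image(frame.positions[acc] - frame.positions[d], frame.box)
        r = np.linalg.norm(doo, axis=1)
        close = r < criterion.r_max
        if not np.any(close):
            continue
        dh = minimum_image(frame.positions[h] - frame.positions[d], frame.box)
        dh_norm = np.linalg.norm(dh)
        for a, vec, dist in zip(acc[close], doo[close], r[close]):
            cosang = np.dot(dh, vec) / (dh_norm * dist)
            theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if theta < criterion.theta_max:
                bonds.append((int(d), int(h), int(a)))
    return bonds


@dataclass
class BondEventMatrix:
    """0/1 bond-existence indicators per bond per frame."""

    bonds: list[Bond]
    times: np.ndarray  # ns, strictly increasing
    indicators: np.ndarray  # (n_bonds, n_frames) of {0, 1}
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.indicators = np.asarray(self.indicators)
        if self.indicators.ndim != 2 or self.indicators.shape != (
            len(self.bonds),
            len(self.times),
        ):
            raise AnalysisError("indicator matrix shape mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise AnalysisError("frame times must be strictly increasing")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_frames(self) -> int:
        return len(self.times)


def track_bonds(
    frames: list[ConfigurationFrame],
    times,
    criterion: HBondCriterion = HBondCriterion(),
    selection: HBondSelection = HBondSelection(),
    mol_kind: dict[int, str] | None = None,
) -> BondEventMatrix:
    """Follow every bond ever observed across a frame sequence.

    ``mol_kind`` optionally maps molecule index to a label (e.g. "polymer",
    "water"); each bond then gets a sorted "kind-kind" group label.
    """
    n_atoms = frames[0].n_atoms
    universe: dict[Bond, int] = {}
    per_frame: list[set[Bond]] = []
    for k, frame in enumerate(frames):
        if frame.n_atoms != n_atoms:
            raise AnalysisError(
                f"frame {k} has {frame.n_atoms} atoms, expected {n_atoms}"
            )
        found = set(detect_hbonds(frame, criterion, selection))
        for b in sorted(found):
            universe.setdefault(b, len(universe))
        per_frame.append(found)
    bonds = sorted(universe, key=universe.get)
    ind = np.zeros((len(bonds), len(frames)), dtype=np.int8)
    for k, found in enumerate(per_frame):
        for b in found:
            ind[universe[b], k] = 1
    groups = []
    if mol_kind is not None:
        for d, _, a in bonds:
            kinds = sorted(
                [mol_kind.get(int(frames[0].mol_index[d]), "other"),
                 mol_kind.get(int(frames[0].mol_index[a]), "other")]
            )
            groups.append("-".join(kinds))
    return BondEventMatrix(bonds=bonds, times=np.asarray(times, float),
                           indicators=ind, groups=groups)


def bonds_per_monomer(events: BondEventMatrix, n_monomers: int) -> float:
    """Time-averaged bond count divided by the monomer count."""
    if n_monomers <= 0:
        raise AnalysisError("monomer count must be positive")
    return float(events.indicators.sum(axis=0).mean() / n_monomers)


def existence_function(events: BondEventMatrix) -> TimeSeriesTable:
    """Intermittent autocorrelation C_HB(t) over multiple time origins.

    C(t) = sum_bonds sum_t0 h(t0) h(t0+t) / sum_bonds sum_t0 h(t0)^2, with
    t0 ranging over all origins that leave room for lag t.  C(0) = 1
    whenever any bond exists.
    """
    if events.n_frames < 2:
        raise AnalysisError("need >= 2 frames for a correlation")
    h = events.indicators.astype(np.float64)
    if not np.any(h):
        raise AnalysisError("empty bond population")
    n = events.n_frames
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    num = np.zeros(n)
    denom_prefix = np.zeros(n)
    for start in range(0, h.shape[0], 512):  # chunk to bound FFT memory
        block = h[start:start + 512]
        f = np.fft.rfft(block, nfft, axis=1)
        acf = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n]
        num += acf.sum(axis=0)
        denom_prefix += np.cumsum(block, axis=1).sum(axis=0)  # h^2 == h
    # denominator at lag t sums h over origins 0..n-1-t
    denom = denom_prefix[n - 1 - np.arange(n)]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    c = np.clip(c, 0.0, None)
    lags = events.times - events.times[0]
    return TimeSeriesTable(columns=[("time", "ns"), ("C_HB", "dimensionless")],
                           values=np.column_stack([lags, c]))


@dataclass
class DecayFit:
    """Two-term exponential fit of the existence function."""

    K1: float
    tau1: float  # ns
    K2: float
    tau2: float  # ns
    residual_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.K1 * np.exp(-t / self.tau1) + self.K2 * np.exp(-t / self.tau2)


def fit_decay(c: TimeSeriesTable, tau_bounds: tuple[float, float] | None = None,
              k_max: float = 2.0) -> DecayFit:
    """Bounded nonlinear least squares of C(t) = K1 e^{-t/tau1} + K2 e^{-t/tau2}.

    Deterministic multi-start initialisation over decade-spaced time scales;
    the best converged start wins.  K1, K2 >= 0 and tau1, tau2 > 0 are
    enforced through bounds; the returned fit has tau1 <= tau2.
    """
    t = c.values[:, 0]
    y = c.values[:, 1]
    if len(t) < 8:
        raise AnalysisError("need >= 8 points to fit a two-term decay")
    if np.any(y < -1e-9) or np.any(y > 1 + 1e-6):
        raise AnalysisError("C values must lie in [0, 1]")
    t_max = t[-1] if t[-1] > 0 else 1.0
    if tau_bounds is None:
        tau_bounds = (1e-6 * t_max, 1e4 * t_max)

    below = np.where(y < np.exp(-1.0) * y[0])[0] if y[0] > 0 else []
    tau0 = t[below[0]] if len(below) else t_max

    def resid(p):
        k1, k2, tau1, tau2 = p
        return k1 * np.exp(-t / tau1) + k2 * np.exp(-t / tau2) - y

    lb = [0.0, 0.0, tau_bounds[0], tau_bounds[0]]
    ub = [k_max, k_max, tau_bounds[1], tau_bounds[1]]
    best = None
    for f1, f2 in [(0.3, 3.0), (1.0, 10.0), (0.1, 1.0), (1.0, 100.0)]:
        for k1 in (0.5, 0.8, 0.2):
            p0 = [
                np.clip(k1 * max(y[0], 0.1), lb[0], ub[0]),
                np.clip((1 - k1) * max(y[0], 0.1), lb[1], ub[1]),
                np.clip(f1 * tau0, *tau_bounds),
                np.clip(f2 * tau0, *tau_bounds),
            ]
            res = least_squares(resid, p0, bounds=(lb, ub), method="trf")
            if res.success and (best is None or res.cost < best.cost):
                best = res
    flags: list[str] = []
    if best is None:
        return DecayFit(np.nan, 1.0, np.nan, 1.0, np.inf, False, ["no-convergence"])
    k1, k2, tau1, tau2 = best.x
    if tau2 < tau1:
        k1, k2, tau1, tau2 = k2, k1, tau2, tau1
    fit_end = k1 * np.exp(-t_max / tau1) + k2 * np.exp(-t_max / tau2)
    if fit_end > 0.99 * max(y[0], 1e-12):
        flags.append("no-decay: tau -> infinity")
    return DecayFit(
        K1=float(k1), tau1=float(tau1), K2=float(k2), tau2=float(tau2),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=not flags, flags=flags,
    )


@dataclass
class LifetimeResult:
    lifetime: float  # ns, full integral of the fitted decay
    half_life: float  # ns
    flags: list[str] = field(default_factory=list)


def lifetime_halflife(fit: DecayFit, mode: str = "crossing") -> LifetimeResult:
    """Lifetime and half-life of a fitted existence-function decay.

    lifetime = K1 tau1 + K2 tau2 (the integral of the fit to zero).  The
    half-life is by default the time where the fitted C crosses 0.5
    ("crossing"); mode "partial_integral" instead integrates C up to that
    crossing.  If C(0) < 0.5 the half-life is 0, flagged.
    """
    if not fit.converged:
        raise AnalysisError(f"decay fit not converged: {fit.flags}")
    lifetime = fit.K1 * fit.tau1 + fit.K2 * fit.tau2
    c0 = fit.K1 + fit.K2
    if c0 < 0.5:
        return LifetimeResult(float(lifetime), 0.0, ["C(0)<0.5"])
    t_hi = max(fit.tau1, fit.tau2)
    while fit(t_hi) >= 0.5:
        t_hi *= 2.0
        if t_hi > 1e12:
            return LifetimeResult(float(lifetime), np.inf, ["no 0.5 crossing"])
    t_cross = brentq(lambda t: fit(t) - 0.5, 0.0, t_hi, xtol=1e-12)
    if mode == "crossing":
        half = t_cross
    elif mode == "partial_integral":
        half = fit.K1 * fit.tau1 * (1 - np.exp(-t_cross / fit.tau1)) + \
            fit.K2 * fit.tau2 * (1 - np.exp(-t_cross / fit.tau2))
    else:
        raise ValueError(f"unknown half-life mode {mode!r}")
    return LifetimeResult(float(lifetime), float(half), [])
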