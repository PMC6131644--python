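"""Parameter containers shared across the package.

All quantities are SI internally: metres, seconds, mol/m^3.  The reporting
layer (:mod:`zincleft.reporting`) converts to the human-facing units
(micrometres, milliseconds, micromolar) used in tables and figures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """Raised when a parameter violates its physical or contractual bounds."""


class CalibrationRangeError(ValueError):
    """Raised when a fluorescence reading sits at or beyond a calibration asymptote.

    ``bound`` names which asymptote was hit (``"lower"`` or ``"upper"``).
    """

    def __init__(self, message: str, bound: str):
        super().__init__(message)
        self.bound = bound


@dataclass(frozen=True)
class SynapseGeometry:
    """Disc-shaped synaptic cleft geometry.

    Parameters
    ----------
    R : float
        Radius of the transmissive (active) zone where vesicular release
        occurs, in metres.
    S : float
        Outer synapse radius, in metres.  Beyond ``S`` the concentration is
        clamped to the far-field baseline (extracellular matrix / glial sink).
    h : float
        Cleft height (pre- to postsynaptic membrane distance), in metres.
        Enters only through volume and source-rate conversions; the model is
        depth-averaged.
    """

    R: float
    S: float
    h: float

    def __post_init__(self):
        if not (0.0 < self.R < self.S):
            raise ParameterError(
                f"require 0 < R < S, got R={self.R!r}, S={self.S!r}")
        if self.h <= 0.0:
            raise ParameterError(f"cleft height must be positive, got {self.h!r}")

    @property
    def cleft_volume(self) -> float:
        """Volume of the full cleft disc, pi*S^2*h (m^3)."""
        return np.pi * self.S**2 * self.h

    @property
    def source_volume(self) -> float:
        """Volume of the transmissive-zone cylinder, pi*R^2*h (m^3)."""
        return np.pi * self.R**2 * self.h


@dataclass(frozen=True)
class BufferModel:
    """Fast immobile buffer, reduced to a single binding ratio.

    A buffer with concentration ``c_B`` and rates ``k_on``/``k_off`` that is
    slow-moving relative to the free ion and fast-binding acts, to first
    order, as a scaling of the diffusion coefficient by ``1/(1+G)`` with
    ``G`` the equilibrium bound:free ratio ``[B] * k_on / k_off``.

    Units follow the field's conventions: ``c_B`` in SI mol/m^3 but
    ``k_on`` in 1/(M s) as association constants are tabulated, so G
    carries a factor 1e-3 converting mol/m^3 to M.
    """

    c_B: float = 0.0   # mol/m^3
    k_on: float = 0.0  # 1/(M s)
    k_off: float = 1.0  # 1/s

    def __post_init__(self):
        if self.c_B < 0 or self.k_on < 0 or self.k_off < 0:
            raise ParameterError("buffer parameters must be non-negative")
        if self.c_B > 0 and self.k_off == 0:
            raise ParameterError(
                "k_off must be positive when buffer is present (c_B > 0)")

    @property
    def G(self) -> float:
        """Buffering ratio (dimensionless): (c_B in M) * k_on / k_off."""
        if self.c_B == 0.0:
            return 0.0
        return (self.c_B * 1e-3) * self.k_on / self.k_off


#: a no-op buffer (G = 0)
NO_BUFFER = BufferModel()


@dataclass(frozen=True)
class TransportParams:
    """Diffusion coefficient plus optional buffering.

    ``D`` is the free diffusion coefficient (m^2/s); ``D_eff = D/(1+G)`` is
    the buffered effective coefficient actually used by the model.
    """

    D: float
    buffer: BufferModel = NO_BUFFER

    def __post_init__(self):
        if self.D <= 0:
            raise ParameterError(f"diffusion coefficient must be positive, got {self.D!r}")

    @property
    def D_eff(self) -> float:
        return self.D / (1.0 + self.buffer.G)


@dataclass(frozen=True)
class SourceSpec:
    """Volumetric release rate ``k`` inside the transmissive zone (r <= R).

    ``k`` is in mol/(m^3 s).  The stationary solution depends on the ratio
    ``K = k / D_eff``, exposed here as a method because it ties a source to a
    transport parameter set.
    """

    k: float

    def __post_init__(self):
        if self.k < 0:
            raise ParameterError(f"release rate must be non-negative, got {self.k!r}")

    def K(self, D_eff: float) -> float:
        """Poisson constant k/D_eff (mol/m^5)."""
        if D_eff <= 0:
            raise ParameterError("D_eff must be positive")
        return self.k / D_eff


@dataclass(frozen=True)
class RadialField:
    """A concentration profile on a radial grid spanning [0, S].

    ``baseline`` is the constant far-field concentration; the release
    component is ``c - baseline``.
    """

    r: np.ndarray
    c: np.ndarray
    baseline: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "c", c)
        if r.ndim != 1 or c.shape != r.shape:
            raise ParameterError("r and c must be 1-D arrays of equal length")
        if r.size < 2 or np.any(np.diff(r) <= 0):
            raise ParameterError("r must be strictly increasing with >= 2 points")
        if not np.all(np.isfinite(c)):
            raise ParameterError("concentration values must be finite")

    def interpolate(self, radii) -> np.ndarray:
        """Linear interpolation of the profile at arbitrary radii."""
        return np.interp(np.asarray(radii, dtype=float), self.r, self.c)

    @property
    def c_max(self) -> float:
        return float(self.c.max())


@dataclass(frozen=True)
class TimeConstantResult:
    """Slowest relaxation mode of the cleft: tau_max = 1/lambda_min."""

    tau_max: float
    lambda_min: float
    bessel_root: float

    def __post_init__(self):
        if self.tau_max <= 0:
            raise ParameterError("tau_max must be positive")


@dataclass(frozen=True)
class PulseSchedule:
    """Pulsed release protocol: action potentials at ``frequency`` each opening
    the source for ``pulse_duration`` until ``train_duration`` has elapsed.

    ``release_probability`` is the per-event fusion probability.  In
    ``expected`` mode the source rate is scaled by it; in ``stochastic`` mode
    each event fires as a seeded Bernoulli trial.
    """

    frequency: float          # events/s
    pulse_duration: float     # s
    train_duration: float     # s
    release_probability: float = 1.0
    mode: str = "expected"    # "expected" | "stochastic"
    seed: int | None = None

    def __post_init__(self):
        if self.frequency <= 0 or self.pulse_duration <= 0 or self.train_duration <= 0:
            raise ParameterError("frequency and durations must be positive")
        if self.pulse_duration > 1.0 / self.frequency + 1e-15:
            raise ParameterError(
                "pulse_duration must not exceed the inter-event period 1/frequency")
        if not (0.0 <= self.release_probability <= 1.0):
            raise ParameterError("release_probability must lie in [0, 1]")
        if self.mode not in ("expected", "stochastic"):
            raise ParameterError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "stochastic" and self.seed is None:
            raise ParameterError("stochastic mode requires a seed")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def n_events(self) -> int:
        """Number of events whose onsets fall inside the train."""
        return int(np.ceil(self.frequency * self.train_duration - 1e-9))

    def fired(self) -> np.ndarray:
        """Boolean fusion decision per event.

        Deterministic function of (seed, n_events, release_probability); in
        expected mode every event "fires" (probability enters as a rate
        scaling instead).
        """
        if self.mode == "expected":
            return np.ones(self.n_events, dtype=bool)
        rng = np.random.default_rng(self.seed)
        return rng.random(self.n_events) < self.release_probability


@dataclass(frozen=True)
class UptakeModel:
    """Saturable (Michaelis-Menten) transmembrane uptake.

    Areal flux J(c) = J_max * c / (K_m + c), applied on both the pre- and
    postsynaptic membrane (the grid's membrane area counts both faces).
    For c << K_m this reduces to a linear uptake with conductance J_max/K_m.
    """

    J_max: float = 3e-6   # mol/(m^2 s)
    K_m: float = 1e-2     # mol/m^3 (10 uM)
    enabled: bool = True

    def __post_init__(self):
        if self.J_max < 0:
            raise ParameterError("J_max must be non-negative")
        if self.K_m <= 0:
            raise ParameterError("K_m must be positive")

    def areal_flux(self, c) -> np.ndarray:
        """Uptake flux per unit membrane area at concentration c."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ParameterError("uptake requires non-negative concentrations")
        if not self.enabled:
            return np.zeros_like(c)
        return self.J_max * c / (self.K_m + c)


NO_UPTAKE = UptakeModel(J_max=0.0, enabled=False)


@dataclass(frozen=True)
class VesicleSpec:
    """A synaptic vesicle: diameter (m) and luminal free-zinc concentration (mol/L)."""

    diameter: float = 40e-9
    luminal_concentration: float = 1.25e-3

    def __post_init__(self):
        if self.diameter <= 0 or self.luminal_concentration <= 0:
            raise ParameterError("vesicle diameter and concentration must be positive")


@dataclass(frozen=True)
class TrainBudget:
    """Ion bookkeeping for a stimulation train."""

    n_events: int
    expected_fusions: float
    ions_total: float
    mean_rate: float  # ions/s

    def __post_init__(self):
        if self.ions_total < 0:
            raise ParameterError("ions_total must be non-negative")
        if self.expected_fusions > self.n_events + 1e-9:
            raise ParameterError("expected_fusions cannot exceed n_events")


@dataclass(frozen=True)
class CalibrationParams:
    """Six-parameter sigmoid calibration of indicator fluorescence vs free zinc.

    F([Zn]) = a / (b + c*exp(-d*([Zn] - f))) + t

    with ``d`` in 1/M, ``f`` in M and ``a, b, c`` dimensionless shape/amplitude
    factors; ``t`` is the fluorescence offset.  Only the combinations a/b,
    (c/b)*exp(d*f), d and t are identifiable from data, so fits normalise
    b = 1 (and by default f = 0).
    """

    a: float
    b: float
    c: float
    d: float
    f: float
    t: float

    def __post_init__(self):
        if self.c <= 0:
            raise ParameterError("c must be positive")
        if self.d <= 0:
            raise ParameterError("d must be positive")


@dataclass(frozen=True)
class CalibrationSeries:
    """A calibration ladder: free-zinc concentrations (M) vs fluorescence (a.u.)."""

    zn: np.ndarray
    fluorescence: np.ndarray
    condition: str = "control"

    def __post_init__(self):
        zn = np.asarray(self.zn, dtype=float)
        fl = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "zn", zn)
        object.__setattr__(self, "fluorescence", fl)
        if zn.ndim != 1 or fl.shape != zn.shape:
            raise ParameterError("zn and fluorescence must be 1-D arrays of equal length")
        if zn.size < 6:
            raise ParameterError(
                "calibration needs at least 6 points (one per free parameter)")
        if np.any(zn < 0):
            raise ParameterError("zinc concentrations must be non-negative")
        if np.any(np.diff(zn) < 0):
            raise ParameterError("zinc concentrations must be sorted ascending")
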