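"""Closed-form model of release-diffusion in a thin disc-shaped cleft.

The cleft is a flat cylinder of outer radius ``S`` with a central
transmissive zone of radius ``R`` acting as a uniform volumetric source
``k`` while the far field at ``r >= S`` is clamped to a baseline.  Because
the cleft is much thinner than it is wide, the problem is depth-averaged
and rotationally symmetric; everything reduces to the radial coordinate.

Three closed-form results are implemented:

* the stationary profile — parabolic inside the source disc, logarithmic
  outside, continuously differentiable at ``r = R``;
* the slowest relaxation time constant ``tau_max = (S/rho_1)^2 / D_eff``
  where ``rho_1 ~ 2.4048`` is the first positive zero of the Bessel
  function J0 (the slowest decaying radial eigenmode under a clamped rim);
* a first-order space-time approximation: the stationary profile scaled by
  ``1 - exp(-t/tau_max)`` (rise) or ``exp(-t/tau_max)`` (decay), valid when
  the source varies slowly compared to ``tau_max``.

The exact time-dependent solution with pulsed release and uptake is the
job of :mod:`zincleft.fv`.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special

from .params import (
    ParameterError,
    BufferModel,
    RadialField,
    SourceSpec,
    SynapseGeometry,
    TimeConstantResult,
    TransportParams,
)

__all__ = [
    "effective_diffusion",
    "stationary_profile",
    "bessel_j0_root",
    "slowest_time_constant",
    "approx_time_course",
    "stationary_flux_balance",
]


def effective_diffusion(D: float, buffer: BufferModel) -> float:
    """Buffered effective diffusion coefficient D_eff = D / (1 + G).

    ``G = c_B * k_on / k_off`` is the equilibrium bound:free ratio of a fast
    immobile buffer.  With no buffer (``c_B = 0``) the free coefficient is
    returned unchanged.
    """
    if D <= 0:
        raise ParameterError(f"diffusion coefficient must be positive, got {D!r}")
    return D / (1.0 + buffer.G)


def stationary_profile(
    geom: SynapseGeometry,
    source: SourceSpec,
    transport: TransportParams,
    n_points: int = 512,
    baseline: float = 0.0,
) -> RadialField:
    """Stationary concentration profile of the constant-release problem.

    With ``K = k / D_eff``::

        c(r) = K/4 (R^2 - r^2) + (R^2 K / 2) ln(S/R)   for r <= R
        c(r) = (R^2 K / 2) ln(S/r)                     for R <= r <= S

    plus the additive far-field ``baseline``.  The two branches match in
    value and slope at ``r = R`` and the profile vanishes (to baseline) at
    the rim ``r = S``.

    Returns the profile sampled on a uniform grid of ``n_points`` radii
    including 0 and S; the closed form is exact, the grid only sets output
    resolution.
    """
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    K = source.K(transport.D_eff)
    r = np.linspace(0.0, geom.S, n_points)
    c = evaluate_stationary(r, geom, K) + baseline
    return RadialField(r=r, c=c, baseline=baseline)


def evaluate_stationary(r, geom: SynapseGeometry, K: float) -> np.ndarray:
    """Evaluate the stationary release component at arbitrary radii.

    Exposed separately so the finite-volume comparison can sample the
    closed form exactly at its cell centres.
    """
    r = np.asarray(r, dtype=float)
    R, S = geom.R, geom.S
    inner = K / 4.0 * (R**2 - r**2) + R**2 * K / 2.0 * np.log(S / R)
    with np.errstate(divide="ignore"):
        outer = R**2 * K / 2.0 * np.log(S / np.maximum(r, np.finfo(float).tiny))
    return np.where(r <= R, inner, outer)


def bessel_j0_root(n: int) -> float:
    """n-th positive zero of the Bessel function J0, by bracketing + Brent.

    J0's zeros cannot be written in closed form; they are found numerically
    by bracketing each sign change (consecutive zeros are asymptotically pi
    apart, starting near 3pi/4) and polishing with Brent's method.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"root index must be an integer >= 1, got {n!r}")
    # McMahon asymptotic guess: rho_n ~ (n - 1/4) * pi
    guess = (n - 0.25) * np.pi
    lo, hi = guess - 0.5 * np.pi, guess + 0.5 * np.pi
    # widen conservatively if the bracket misses a sign change
    while special.j0(lo) * special.j0(hi) > 0:
        lo -= 0.1
        hi += 0.1
    return float(optimize.brentq(special.j0, lo, hi, xtol=1e-14, rtol=8.9e-16))


def slowest_time_constant(geom: SynapseGeometry, D_eff: float) -> TimeConstantResult:
    """Slowest relaxation time of the clamped-rim disc.

    The slowest radial eigenmode is J0(rho_1 r / S), giving

        lambda_min = 1 / tau_max = D_eff * (rho_1 / S)^2

    with rho_1 the first positive J0 zero (~2.4048).  tau_max grows
    quadratically with the synapse radius S and inversely with D_eff.
    """
    if D_eff <= 0:
        raise ParameterError("D_eff must be positive")
    rho1 = bessel_j0_root(1)
    lam = D_eff * (rho1 / geom.S) ** 2
    return TimeConstantResult(tau_max=1.0 / lam, lambda_min=lam, bessel_root=rho1)


def approx_time_course(
    profile: RadialField,
    tau: float,
    times,
    mode: str = "rise",
) -> pd.DataFrame:
    """First-order space-time approximation around the stationary profile.

    rise:  c(r, t) = baseline + (c_stat(r) - baseline) * (1 - exp(-t/tau))
    decay: c(r, t) = baseline + (c_stat(r) - baseline) * exp(-t/tau)

    Valid when the source turns on/off abruptly but otherwise changes slowly
    compared to ``tau``.  Returns a tidy table with columns
    ``t_s, r_m, c_mol_per_m3``.
    """
    if tau <= 0:
        raise ParameterError("tau must be positive")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ParameterError("times must be non-negative")
    if mode not in ("rise", "decay"):
        raise ParameterError(f"mode must be 'rise' or 'decay', got {mode!r}")

    release = profile.c - profile.baseline
    if mode == "rise":
        factors = 1.0 - np.exp(-times / tau)
    else:
        factors = np.exp(-times / tau)
    frames = []
    for t, fac in zip(times, factors):
        frames.append(pd.DataFrame({
            "t_s": t,
            "r_m": profile.r,
            "c_mol_per_m3": profile.baseline + fac * release,
        }))
    return pd.concat(frames, ignore_index=True)


def stationary_flux_balance(
    profile: RadialField,
    geom: SynapseGeometry,
    transport: TransportParams,
    source: SourceSpec,
) -> float:
    """Relative mismatch between rim outflow and total release.

    At steady state every mole released in the transmissive zone
    (pi R^2 h k) must leave by diffusion through the rim ring at S.  In the
    logarithmic outer branch c = alpha*ln(S/r) + baseline the rim flux is
    D_eff * 2 pi h * alpha, with alpha read off the profile at a single
    interior radius.  Exact (machine precision) for the analytic profile;
    O(dr^2) for a finite-volume steady state.
    """
    total_release = geom.source_volume * source.k  # mol/s
    if total_release == 0.0:
        return 0.0
    # sample the log branch at the grid point nearest the geometric mean of
    # R and S: safely inside (R, S), away from the rim where c -> baseline
    # makes alpha 0/0, and exactly on the grid (no interpolation error)
    target = np.sqrt(geom.R * geom.S)
    interior = np.flatnonzero((profile.r > geom.R) & (profile.r < geom.S))
    if interior.size == 0:
        raise ParameterError("profile has no grid point strictly between R and S")
    j = interior[np.argmin(np.abs(profile.r[interior] - target))]
    alpha = (profile.c[j] - profile.baseline) / np.log(geom.S / profile.r[j])
    outflow = transport.D_eff * 2.0 * np.pi * geom.h * alpha
    return abs(outflow - total_release) / total_release
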