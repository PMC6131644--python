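"""Fluorescence-indicator calibration for free-zinc quantification.

A high-affinity indicator (FluoZin-3 class, K_D ~ 15 nM) reports free Zn2+
through a sigmoid intensity curve

    F([Zn]) = a / (b + c * exp(-d*([Zn] - f))) + t

which is fitted per measurement condition (calcium level, UV exposure) with
a seeded population-based global optimizer, then inverted to read free-zinc
concentrations off sample wells.  The curve is over-parameterised: only
a/b, (c/b)*exp(d*f), d and t are identifiable, so the fit normalises b = 1
and f = 0 and reports curve-level (not parameter-level) agreement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .params import (
    CalibrationParams,
    CalibrationRangeError,
    CalibrationSeries,
    ParameterError,
)

__all__ = [
    "DEFAULT_CALIBRATION",
    "default_zn_ladder",
    "forward_fluorescence",
    "invert_fluorescence",
    "fit_calibration",
    "FitDiagnostics",
    "free_zinc_from_measurement",
    "synthesize_calibration_series",
    "read_series_csv",
    "write_series_csv",
]

#: plausible defaults for the synthetic dilution series: upper/lower
#: asymptote gap ~1000 a.u., half-rise slope ~ (50 nM)^-1, small offset.
DEFAULT_CALIBRATION = CalibrationParams(a=1000.0, b=1.0, c=9.0, d=2e7, f=0.0, t=50.0)


def default_zn_ladder() -> np.ndarray:
    """Plate-reader dilution ladder: a blank plus 50 pM .. 250 nM (M).

    Twelve wells as in a 96-well plate row: the zero blank and eleven
    log-spaced standards spanning the 5000-fold range.
    """
    return np.concatenate([[0.0], np.geomspace(50e-12, 250e-9, 11)])


def _denominator(params: CalibrationParams, zn) -> np.ndarray:
    return params.b + params.c * np.exp(-params.d * (np.asarray(zn, dtype=float) - params.f))


def forward_fluorescence(params: CalibrationParams, zn) -> np.ndarray | float:
    """Fluorescence intensity at free-zinc concentration ``zn`` (M)."""
    den = _denominator(params, zn)
    if np.any(den <= 0):
        raise ParameterError(
            "calibration denominator b + c*exp(-d([Zn]-f)) is non-positive")
    out = params.a / den + params.t
    return float(out) if np.isscalar(zn) else out


def invert_fluorescence(params: CalibrationParams, F: float) -> float:
    """Free-zinc concentration (M) from a fluorescence reading.

    [Zn] = f - (1/d) * ln((a/(F - t) - b) / c)

    Valid only strictly between the asymptotes t (no zinc) and a/b + t
    (indicator saturation); readings at or beyond an asymptote raise
    :class:`CalibrationRangeError` naming the bound.
    """
    if params.a <= 0 or params.b <= 0:
        raise ParameterError("inversion requires a > 0 and b > 0")
    lower = params.t
    upper = params.a / params.b + params.t
    if F <= lower:
        raise CalibrationRangeError(
            f"reading {F!r} at or below the zero-zinc asymptote t={lower!r}",
            bound="lower")
    if F >= upper:
        raise CalibrationRangeError(
            f"reading {F!r} at or above the saturation asymptote a/b+t={upper!r}"
            " (indicator saturated)", bound="upper")
    return params.f - np.log((params.a / (F - params.t) - params.b) / params.c) / params.d


@dataclass(frozen=True)
class FitDiagnostics:
    sse: float
    residual_norm: float
    converged: bool
    restarts: int
    seed: int


def _default_bounds(series: CalibrationSeries) -> dict:
    """Data-driven box for the (a, c, d, t) fit, b=1 and f=0 pinned.

    Log-scale boxes for the positive shape parameters; the amplitude box is
    anchored on the observed intensity range, the slope box spans half-rise
    scales from ~10 pM to ~100 uM.
    """
    F = series.fluorescence
    frange = float(F.max() - F.min())
    if frange <= 0:
        raise ParameterError("fluorescence values are constant; nothing to fit")
    return {
        "a": (1e-2 * frange, 1e3 * frange),
        "c": (1e-4, 1e6),
        "d": (1e4, 1e11),  # 1/M
        "t": (float(F.min()) - 3 * frange, float(F.min()) + frange),
    }


def fit_calibration(
    series: CalibrationSeries,
    bounds: dict | None = None,
    seed: int = 0,
    restarts: int = 3,
) -> tuple[CalibrationParams, FitDiagnostics]:
    """Seeded global least-squares fit of the sigmoid calibration curve.

    Runs differential evolution (population-based, deterministic for a given
    seed) over log-amplitude/log-slope coordinates, polishes the best of
    ``restarts`` runs with a trust-region least-squares pass, and returns the
    fitted parameters with diagnostics.  Non-convergence is flagged (and
    warned about), never silent.
    """
    box = dict(_default_bounds(series))
    if bounds:
        box.update(bounds)
    zn_nm = series.zn * 1e9  # condition the slope parameter
    F = series.fluorescence

    # optimisation coordinates: log10 a, log10 c, log10 d[1/nM], t
    lo = np.array([np.log10(box["a"][0]), np.log10(box["c"][0]),
                   np.log10(box["d"][0] * 1e-9), box["t"][0]])
    hi = np.array([np.log10(box["a"][1]), np.log10(box["c"][1]),
                   np.log10(box["d"][1] * 1e-9), box["t"][1]])

    def model(x):
        a, c, d = 10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2]
        return a / (1.0 + c * np.exp(-d * zn_nm)) + x[3]

    def sse(x):
        r = model(x) - F
        return float(r @ r)

    rng_seeds = np.random.SeedSequence(seed).generate_state(restarts)
    best_x, best_sse = None, np.inf
    for rs in rng_seeds:
        res = optimize.differential_evolution(
            sse, bounds=list(zip(lo, hi)), seed=int(rs % 2**31), tol=1e-12,
            maxiter=400, popsize=20, polish=True)
        if res.fun < best_sse:
            best_x, best_sse = res.x, res.fun

    polish = optimize.least_squares(
        lambda x: model(x) - F, best_x, bounds=(lo, hi),
        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    x = polish.x if float(polish.cost * 2) <= best_sse else best_x
    final_sse = min(float(polish.cost * 2), best_sse)

    converged = polish.status > 0
    if not converged:
        warnings.warn("calibration fit did not converge after all restarts; "
                      "result flagged", RuntimeWarning, stacklevel=2)
    params = CalibrationParams(
        a=10.0 ** x[0], b=1.0, c=10.0 ** x[1], d=10.0 ** x[2] * 1e9,
        f=0.0, t=x[3])
    diag = FitDiagnostics(
        sse=final_sse, residual_norm=float(np.sqrt(final_sse)),
        converged=converged, restarts=restarts, seed=seed)
    return params, diag


def free_zinc_from_measurement(
    sample_F: float,
    params: CalibrationParams,
    total_chelator_zn: float,
) -> tuple[float, float]:
    """Free-zinc concentration and released fraction for a sample well.

    ``total_chelator_zn`` is the total zinc loaded on the caged chelator (M);
    the released fraction is free/total (e.g. 30 pM free out of 1 uM loaded
    is a fraction of 3e-5, i.e. 0.003%).
    """
    if total_chelator_zn <= 0:
        raise ParameterError("total loaded zinc must be positive")
    free = invert_fluorescence(params, sample_F)
    return free, free / total_chelator_zn


def synthesize_calibration_series(
    params: CalibrationParams = DEFAULT_CALIBRATION,
    zn_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    condition: str = "control",
) -> CalibrationSeries:
    """Synthetic dilution series: the forward curve plus Gaussian read noise.

    Emulates a plate-reader calibration row; with ``noise_sd=0`` the points
    are exact forward-model values.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    zn = default_zn_ladder() if zn_grid is None else np.asarray(zn_grid, dtype=float)
    F = np.asarray(forward_fluorescence(params, zn), dtype=float)
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, size=zn.shape)
    return CalibrationSeries(zn=zn, fluorescence=F, condition=condition)


def read_series_csv(path) -> list[CalibrationSeries]:
    """Read calibration series from CSV columns zn_molar, fluorescence[, condition]."""
    df = pd.read_csv(path)
    required = {"zn_molar", "fluorescence"}
    if not required.issubset(df.columns):
        raise ParameterError(f"calibration CSV needs columns {sorted(required)}")
    if "condition" not in df.columns:
        df["condition"] = "control"
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("zn_molar")
        out.append(CalibrationSeries(
            zn=grp["zn_molar"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            condition=str(cond)))
    return out


def write_series_csv(series_list, path) -> None:
    frames = [pd.DataFrame({
        "zn_molar": s.zn, "fluorescence": s.fluorescence, "condition": s.condition,
    }) for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
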