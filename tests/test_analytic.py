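"""Closed-form model: stationary profile, Bessel eigenvalue, time course."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.linalg import solve_banded

import zincleft as z
from zincleft import analytic, fv
from zincleft.params import ParameterError


# ---------------------------------------------------------------- diffusion

@pytest.mark.parametrize("D, buffer, expected", [
    # no buffer: identity
    (7e-10, z.BufferModel(), 7e-10),
    # G = 9 (c_B = 9 mol/m^3 = 9 mM, k_on/k_off = 1e3 per M): D/10
    (7e-10, z.BufferModel(c_B=9.0, k_on=1e3, k_off=1.0), 7e-11),
    # hand evaluation: c_B = 1 mM, k_on = 1e8 /(M s), k_off = 1e5 /s -> G=1
    (2e-10, z.BufferModel(c_B=1.0, k_on=1e8, k_off=1e5), 1e-10),
])
def test_effective_diffusion_values(D, buffer, expected):
    assert z.effective_diffusion(D, buffer) == pytest.approx(expected, rel=1e-12)


def test_effective_diffusion_rejects_bad_parameters():
    with pytest.raises(ParameterError):
        z.effective_diffusion(0.0, z.BufferModel())
    with pytest.raises(ParameterError):
        z.BufferModel(c_B=1.0, k_on=1e8, k_off=0.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(c_B=st.floats(1e-6, 1e3), k_on=st.floats(1.0, 1e9),
       k_off=st.floats(1e-3, 1e6), scale=st.floats(1.1, 10.0))
def test_effective_diffusion_monotonicity(c_B, k_on, k_off, scale):
    """More buffer or faster binding slows diffusion; faster unbinding
    restores it; D_eff never exceeds D."""
    D = 7e-10
    base = z.effective_diffusion(D, z.BufferModel(c_B, k_on, k_off))
    assert base <= D
    assert z.effective_diffusion(D, z.BufferModel(c_B * scale, k_on, k_off)) < base
    assert z.effective_diffusion(D, z.BufferModel(c_B, k_on * scale, k_off)) < base
    assert z.effective_diffusion(D, z.BufferModel(c_B, k_on, k_off * scale)) > base


# ---------------------------------------------------------- stationary profile

def test_profile_branches_match_at_zone_edge(geom, transport, source):
    """Value and slope of the parabolic and logarithmic branches agree at R."""
    K = source.K(transport.D_eff)
    R, S = geom.R, geom.S
    inner_at_R = K / 4 * (R**2 - R**2) + R**2 * K / 2 * np.log(S / R)
    outer_at_R = R**2 * K / 2 * np.log(S / R)
    assert inner_at_R == pytest.approx(outer_at_R, rel=1e-15)
    # one-sided slopes, numerically: both -K*R/2
    eps = 1e-13
    f = lambda r: float(analytic.evaluate_stationary(np.array([r]), geom, K)[0])
    left = (f(R) - f(R - eps)) / eps
    right = (f(R + eps) - f(R)) / eps
    assert left == pytest.approx(-K * R / 2, rel=1e-5)
    assert right == pytest.approx(-K * R / 2, rel=1e-5)


def test_profile_boundary_and_degenerate_cases(geom, transport):
    prof = z.stationary_profile(geom, z.SourceSpec(k=0.2), transport,
                                baseline=1e-6)
    assert prof.c[-1] == pytest.approx(1e-6, rel=1e-12)      # c(S) = baseline
    assert np.all(np.diff(prof.c) <= 1e-30)                  # non-increasing
    assert np.all(prof.c >= prof.baseline - 1e-30)
    flat = z.stationary_profile(geom, z.SourceSpec(k=0.0), transport)
    assert np.all(flat.c == 0.0)                             # zero source
    with pytest.raises(ParameterError):
        z.stationary_profile(geom, z.SourceSpec(k=0.2), transport, n_points=2)


def _poisson_oracle(geom, K, n):
    """Independent steady-state oracle: direct banded solve of the discrete
    cylindrical Poisson problem with Dirichlet rim."""
    grid = fv.build_grid(geom, n)
    dr = grid.dr
    gf = 2 * np.pi * grid.faces[1:-1] * geom.h / dr
    grim = 2 * np.pi * geom.S * geom.h / dr
    rhs = -K * (grid.centers <= geom.R) * grid.cell_volumes
    main = np.empty(n)
    for i in range(n):
        gi = gf[i - 1] if i > 0 else 0.0
        go = gf[i] if i < n - 1 else 2 * grim
        main[i] = -(gi + go)
    ab = np.zeros((3, n))
    ab[0, 1:] = gf
    ab[1] = main
    ab[2, :-1] = gf
    c = solve_banded((1, 1), ab, rhs)
    return grid.centers, c


def test_center_to_edge_ratio_and_poisson_oracle(transport):
    """With R = 300 nm, S = 3 um the ratio c(0)/c(R) is 1 + 1/(2 ln 10),
    independent of the release rate; the whole profile agrees with a direct
    numerical Poisson solve."""
    geom = z.SynapseGeometry(R=300e-9, S=3e-6, h=40e-9)
    K = z.SourceSpec(k=0.37).K(transport.D_eff)  # arbitrary rate
    c0, cR = analytic.evaluate_stationary(np.array([0.0, geom.R]), geom, K)
    assert c0 / cR == pytest.approx(1 + 1 / (2 * np.log(10)), rel=1e-12)

    r, c_num = _poisson_oracle(geom, K, 4000)
    c_ana = analytic.evaluate_stationary(r, geom, K)
    mask = c_ana > 0.01 * c_ana.max()  # rim cells: relative error ill-posed
    assert np.max(np.abs(c_num[mask] - c_ana[mask]) / c_ana[mask]) < 5e-3
    # the oracle reproduces the rate-independent centre/edge ratio too
    ratio_num = np.interp(0.0, r, c_num) / np.interp(geom.R, r, c_num)
    assert ratio_num == pytest.approx(1 + 1 / (2 * np.log(10)), rel=1e-3)


# ------------------------------------------------------------- Bessel roots

def _j0_quadrature(x):
    """Independent J0 via its integral representation."""
    val, _ = integrate.quad(lambda th: np.cos(x * np.sin(th)), 0, np.pi,
                            epsabs=1e-12, epsrel=1e-12, limit=200)
    return val / np.pi


def test_bessel_roots():
    roots = [z.bessel_j0_root(n) for n in range(1, 6)]
    assert roots[0] == pytest.approx(2.4048, abs=5e-5)
    assert np.all(np.diff(roots) > 0)
    for rho in roots:
        assert abs(_j0_quadrature(rho)) < 1e-10
    from scipy.special import jn_zeros  # library cross-check
    assert roots == pytest.approx(jn_zeros(0, 5), rel=1e-12)
    with pytest.raises(ParameterError):
        z.bessel_j0_root(0)


# ------------------------------------------------------------ time constant

def test_time_constant_value_and_scaling(geom):
    tc = z.slowest_time_constant(geom, 2e-10)
    # (S/rho_1)^2 / D with S = 3 um, D = 2e-10 m^2/s
    assert tc.tau_max == pytest.approx(7.781e-3, rel=1e-3)
    assert tc.lambda_min * tc.tau_max == pytest.approx(1.0, rel=1e-15)
    big = z.SynapseGeometry(R=geom.R, S=2 * geom.S, h=geom.h)
    assert z.slowest_time_constant(big, 2e-10).tau_max \
        == pytest.approx(4 * tc.tau_max, rel=1e-12)       # quadratic in S
    assert z.slowest_time_constant(geom, 2e-11).tau_max \
        == pytest.approx(10 * tc.tau_max, rel=1e-12)      # inverse in D


def test_time_constant_matches_discrete_eigenvalue(geom):
    """Slowest decay rate of a finely discretised radial diffusion operator
    (Dirichlet rim, reflecting centre) agrees with the J0-eigenvalue formula
    within 1% at 2000 cells."""
    from scipy.linalg import eigh_tridiagonal

    D = 2e-10
    n = 2000
    grid = fv.build_grid(geom, n)
    dr = grid.dr
    gf = D * 2 * np.pi * grid.faces[1:-1] * geom.h / dr
    grim = D * 2 * np.pi * geom.S * geom.h / dr
    V = grid.cell_volumes
    diag = np.empty(n)
    for i in range(n):
        gi = gf[i - 1] if i > 0 else 0.0
        go = gf[i] if i < n - 1 else 2 * grim
        diag[i] = -(gi + go) / V[i]
    # similarity transform by sqrt(V) symmetrises the operator
    off = gf / np.sqrt(V[:-1] * V[1:])
    eigvals = eigh_tridiagonal(diag, off, select="i",
                               select_range=(n - 1, n - 1))[0]
    tau_discrete = -1.0 / eigvals[-1]
    tau_formula = z.slowest_time_constant(geom, D).tau_max
    assert tau_discrete == pytest.approx(tau_formula, rel=0.01)


# ------------------------------------------------------- approximate course

def test_approx_time_course(geom, transport, source, tau):
    prof = z.stationary_profile(geom, source, transport, n_points=64)
    t = tau.tau_max
    rise = z.approx_time_course(prof, t, [0.0, t, 20 * t], mode="rise")
    at = lambda df, ti: df[np.isclose(df.t_s, ti)].c_mol_per_m3.to_numpy()
    assert np.all(at(rise, 0.0) == 0.0)
    assert at(rise, t) == pytest.approx((1 - np.exp(-1)) * prof.c, rel=1e-12)
    assert at(rise, 20 * t) == pytest.approx(prof.c, rel=1e-8, abs=1e-30)
    # rise + decay at equal t reconstruct the stationary profile
    decay = z.approx_time_course(prof, t, [0.4 * t], mode="decay")
    rise04 = z.approx_time_course(prof, t, [0.4 * t], mode="rise")
    assert (rise04.c_mol_per_m3 + decay.c_mol_per_m3).to_numpy() \
        == pytest.approx(prof.c, rel=1e-12)
    with pytest.raises(ParameterError):
        z.approx_time_course(prof, t, [-1e-3])
    with pytest.raises(ParameterError):
        z.approx_time_course(prof, 0.0, [1e-3])


# ------------------------------------------------------------- flux balance

def test_flux_balance_identity(geom, transport, source):
    prof = z.stationary_profile(geom, source, transport)
    assert z.stationary_flux_balance(prof, geom, transport, source) < 1e-10
    zero = z.SourceSpec(k=0.0)
    flat = z.stationary_profile(geom, zero, transport)
    assert z.stationary_flux_balance(flat, geom, transport, zero) == 0.0


def test_flux_balance_on_fv_steady_state(geom, transport, source, steady_runs):
    """The finite-volume steady state satisfies the global balance up to
    discretisation error."""
    res = steady_runs[150]
    field = z.RadialField(r=res.grid.centers, c=res.fields[-1])
    assert z.stationary_flux_balance(field, geom, transport, source) < 1e-2
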