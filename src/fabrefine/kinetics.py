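"""Bivalent-analyte SPR kinetics: simulator, global fitter, K_D.

An IgG is a two-armed (bivalent) analyte: it first attaches to one
immobilized ligand site and can then bridge to a second.  With ``L`` the
free-site signal (RU), ``AB`` singly bound and ``AB2`` doubly bound
complexes, the model integrated here is

    d[AB]/dt  = 2·k_on·C·L − k_off·[AB] − k_on2·[AB]·L + 2·k_off2·[AB2]
    d[AB2]/dt = k_on2·[AB]·L − 2·k_off2·[AB2],      L = R_max − [AB] − [AB2]

with analyte concentration C held at the injected value during association
and 0 afterwards; the measured response is [AB] + [AB2].  The statistical
factors (2·k_on for the first attachment, 2·k_off2 for release of either
arm) follow the conventional instrument-software formulation.  The apparent
first-step rate constants define the reported affinity, K_D = k_off/k_on.

Fitting is global: one parameter set across a dilution series, nonlinear
least squares in log-parameter space with positivity implied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares


class KineticsError(ValueError):
    pass


class FitError(RuntimeError):
    """Non-convergence; carries the last iterate and RSS."""

    def __init__(self, message: str, last_params=None, rss: float | None = None):
        super().__init__(message)
        self.last_params = last_params
        self.rss = rss


@dataclass(frozen=True)
class KineticParams:
    """Apparent rate constants of the bivalent analyte model."""

    k_on: float      # 1/(M·s), first attachment
    k_off: float     # 1/s, first release
    k_on2: float     # 1/(RU·s), second attachment
    k_off2: float    # 1/s, second release
    r_max: float     # RU

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.k_on2, self.k_off2) < 0:
            raise KineticsError("rate constants must be >= 0")
        if self.r_max <= 0:
            raise KineticsError("R_max must be > 0")


@dataclass(frozen=True)
class Sensorgram:
    """One SPR trace: response vs time at a known analyte concentration."""

    time: np.ndarray          # s, strictly increasing
    response: np.ndarray      # RU
    concentration: float      # M
    t_assoc_end: float        # s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise KineticsError("time grid must be strictly increasing")
        if not np.all(np.isfinite(np.asarray(self.response, float))):
            raise KineticsError("non-finite response values")
        if not (0 < self.t_assoc_end < t[-1]):
            raise KineticsError("t_assoc_end must lie inside the time grid")


def _rhs_factory(p: KineticParams, concentrations: np.ndarray):
    """Vectorized right-hand side for m sensorgrams stacked as 2m states."""
    def rhs(t, y, conc_active):
        ab = y[0::2]
        ab2 = y[1::2]
        free = p.r_max - ab - ab2
        d_ab = (2.0 * p.k_on * conc_active * free - p.k_off * ab
                - p.k_on2 * ab * free + 2.0 * p.k_off2 * ab2)
        d_ab2 = p.k_on2 * ab * free - 2.0 * p.k_off2 * ab2
        out = np.empty_like(y)
        out[0::2] = d_ab
        out[1::2] = d_ab2
        return out
    return rhs


def _integrate(p: KineticParams, concentrations: np.ndarray,
               grid: np.ndarray, t_assoc_end: float,
               rtol: float = 1e-8) -> np.ndarray:
    """Responses, shape (m, len(grid)); association then dissociation."""
    m = len(concentrations)
    rhs = _rhs_factory(p, concentrations)
    y0 = np.zeros(2 * m)
    t_a = grid[grid <= t_assoc_end]
    t_d = grid[grid > t_assoc_end]
    resp = np.empty((m, len(grid)))
    sol_a = solve_ivp(rhs, (0.0, t_assoc_end),
                      y0, t_eval=t_a, args=(concentrations,),
                      method="LSODA", rtol=rtol, atol=1e-10)
    if not sol_a.success:
        raise KineticsError(f"association integration failed: {sol_a.message}")
    y_end = sol_a.y[:, -1] if t_a.size and np.isclose(t_a[-1], t_assoc_end) \
        else solve_ivp(rhs, (0.0, t_assoc_end), y0, args=(concentrations,),
                       method="LSODA", rtol=rtol, atol=1e-10).y[:, -1]
    resp[:, :len(t_a)] = sol_a.y[0::2, :] + sol_a.y[1::2, :]
    if len(t_d):
        sol_d = solve_ivp(rhs, (t_assoc_end, grid[-1]), y_end, t_eval=t_d,
                          args=(np.zeros(m),), method="LSODA",
                          rtol=rtol, atol=1e-10)
        if not sol_d.success:
            raise KineticsError(f"dissociation integration failed: {sol_d.message}")
        resp[:, len(t_a):] = sol_d.y[0::2, :] + sol_d.y[1::2, :]
    return resp


def simulate_bivalent(p: KineticParams, conc: float, grid: np.ndarray,
                      t_assoc_end: float, rtol: float = 1e-8) -> Sensorgram:
    """Integrate the model for one analyte concentration."""
    if conc < 0:
        raise KineticsError("concentration must be >= 0")
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise KineticsError("time grid must be strictly increasing")
    resp = _integrate(p, np.array([conc]), grid, t_assoc_end, rtol)[0]
    return Sensorgram(time=grid, response=resp, concentration=conc,
                      t_assoc_end=t_assoc_end)


def langmuir_1to1(k_a: float, k_d: float, r_max: float, conc: float,
                  grid: np.ndarray, t_assoc_end: float) -> np.ndarray:
    """Closed-form 1:1 Langmuir response (the k_on2 = 0 reduction of the
    model, with k_a the same apparent association constant, i.e. 2·k_on)."""
    grid = np.asarray(grid, float)
    kobs = k_a * conc + k_d
    req = r_max * k_a * conc / kobs if kobs > 0 else 0.0
    resp = np.where(grid <= t_assoc_end,
                    req * (1.0 - np.exp(-kobs * grid)),
                    0.0)
    r_end = req * (1.0 - np.exp(-kobs * t_assoc_end))
    diss = grid > t_assoc_end
    resp[diss] = r_end * np.exp(-k_d * (grid[diss] - t_assoc_end))
    return resp


DEFAULT_INIT = KineticParams(k_on=1e5, k_off=1e-3, k_on2=1e-4, k_off2=1e-3,
                             r_max=100.0)


@dataclass(frozen=True)
class FitDiagnostics:
    rss: float
    n_points: int
    stderr: dict[str, float]
    n_iterations: int


def fit_bivalent(curves: list[Sensorgram],
                 init: KineticParams | None = None,
                 rtol: float = 1e-8) -> tuple[KineticParams, FitDiagnostics]:
    """Global nonlinear least squares over a multi-concentration series.

    All five parameters are shared across curves.  R_max is initialized at
    1.1 × the maximum observed response unless an init is supplied.
    Raises :class:`FitError` on non-convergence or degenerate input.
    """
    if len(curves) < 2:
        raise KineticsError("need >= 2 concentrations for a global fit")
    concs = np.array([c.concentration for c in curves])
    if concs.max() < 4 * concs.min():
        raise KineticsError("concentration series must span >= 4-fold")
    max_resp = max(float(np.max(c.response)) for c in curves)
    if max_resp <= 0:
        raise FitError("degenerate input: no positive response")
    if init is None:
        init = replace(DEFAULT_INIT, r_max=1.1 * max_resp)
    grid = curves[0].time
    t_assoc = curves[0].t_assoc_end
    for c in curves[1:]:
        if len(c.time) != len(grid) or not np.allclose(c.time, grid) \
                or c.t_assoc_end != t_assoc:
            raise KineticsError("curves must share one time grid and phase split")
    obs = np.stack([c.response for c in curves])

    def unpack(x):
        return KineticParams(*np.exp(x))

    def residuals(x):
        p = unpack(x)
        try:
            model = _integrate(p, concs, grid, t_assoc, rtol)
        except KineticsError:
            return np.full(obs.size, 1e3)
        return (model - obs).ravel()

    x0 = np.log([init.k_on, init.k_off, init.k_on2, init.k_off2, init.r_max])
    res = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    rss = float(res.cost * 2)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitError(f"fit did not converge: {res.message}",
                       last_params=unpack(res.x), rss=rss)
    params = unpack(res.x)
    # a fit that never left a flat model is non-convergence in disguise
    model = _integrate(params, concs, grid, t_assoc, rtol)
    if float(np.max(np.abs(model))) < 1e-9 * max_resp:
        raise FitError("degenerate fit: model identically zero",
                       last_params=params, rss=rss)
    # standard errors from the Jacobian at the optimum (log-scale chain rule)
    dof = max(obs.size - len(res.x), 1)
    sigma2 = rss / dof
    try:
        cov_log = sigma2 * np.linalg.inv(res.jac.T @ res.jac)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        vals = np.exp(res.x)
        se = vals * se_log
    except np.linalg.LinAlgError:
        se = np.full(5, np.nan)
    names = ("k_on", "k_off", "k_on2", "k_off2", "r_max")
    diags = FitDiagnostics(rss=rss, n_points=obs.size,
                           stderr=dict(zip(names, se.tolist())),
                           n_iterations=int(res.nfev))
    return params, diags


def equilibrium_kd(p: KineticParams) -> float:
    """K_D = k_off/k_on in nM, 3 significant figures."""
    if p.k_on <= 0:
        raise KineticsError("k_on must be > 0 to define K_D")
    kd_nm = p.k_off / p.k_on * 1e9
    if kd_nm == 0:
        return 0.0
    return float(np.format_float_positional(
        kd_nm, precision=3, unique=False, fractional=False))
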