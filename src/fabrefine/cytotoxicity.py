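"""ADCC dose-response analysis: specific lysis, variable-slope 4PL fits,
EC50 comparison by the extra-sum-of-squares F-test, relative potency.

Cytotoxicity from a chromium-release assay is expressed as percent specific
lysis, 100·(sample − spontaneous)/(maximal − spontaneous), and modeled as a
four-parameter logistic (variable-slope sigmoid) of antibody concentration:

    y = bottom + (top − bottom) / (1 + 10^((log10 EC50 − log10 x) · hill))

Two samples' potencies are compared by refitting with a single shared
log10 EC50 (top/bottom/hill stay per-curve) and testing the RSS increase
with the extra-sum-of-squares F-test.  Relative potency is EC50_ref /
EC50_test — above 1 means the test article is more potent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .design_engine import round_half_away


class CytotoxError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class DoseResponse:
    """Replicated lysis measurements over a concentration series (μg/mL)."""

    concentration: np.ndarray
    lysis: np.ndarray
    replicate_id: np.ndarray | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, float)
        if np.any(c <= 0):
            raise CytotoxError("concentrations must be > 0")
        if len(c) != len(np.asarray(self.lysis, float)):
            raise CytotoxError("concentration and lysis lengths differ")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample: str) -> "DoseResponse":
        sub = df[df["sample"] == sample]
        return cls(concentration=sub["concentration"].to_numpy(float),
                   lysis=sub["lysis"].to_numpy(float),
                   replicate_id=sub.get("replicate", None),
                   sample=sample)


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    log_ec50: float      # log10 μg/mL
    hill: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.top < self.bottom:
            raise CytotoxError("top must be >= bottom")

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.log_ec50)


def specific_lysis(sample_cpm: float, spontaneous_cpm: float,
                   maximal_cpm: float) -> float:
    """Percent specific release of a chromium-release well."""
    if maximal_cpm <= spontaneous_cpm:
        raise CytotoxError("maximal release must exceed spontaneous release")
    return 100.0 * (sample_cpm - spontaneous_cpm) / (maximal_cpm - spontaneous_cpm)


def four_pl(x: np.ndarray, bottom: float, top: float, log_ec50: float,
            hill: float) -> np.ndarray:
    logx = np.log10(np.asarray(x, float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logx) * hill))


def _init_from_data(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    bottom = float(np.min(y))
    top = float(np.max(y))
    mid = 0.5 * (top + bottom)
    log_ec50 = float(np.log10(x[np.argmin(np.abs(y - mid))]))
    return np.array([bottom, top, log_ec50, 1.0])


def fit_4pl(dr: DoseResponse, max_nfev: int = 2000) -> FourPLFit:
    """Least-squares variable-slope sigmoid fit; raises on degenerate data."""
    x = np.asarray(dr.concentration, float)
    y = np.asarray(dr.lysis, float)
    if len(np.unique(x)) < 5:
        raise CytotoxError("need >= 5 distinct concentrations")
    if np.ptp(y) < 1e-9:
        raise FitError("degenerate data: constant response")
    p0 = _init_from_data(x, y)

    def resid(p):
        return four_pl(x, *p) - y

    res = least_squares(resid, p0, method="lm", max_nfev=max_nfev,
                        xtol=1e-12, ftol=1e-12)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitError(f"4PL fit did not converge: {res.message}")
    bottom, top, log_ec50, hill = res.x
    if hill < 0:           # equivalent parameterization; report rising form
        bottom, top, hill = top, bottom, -hill
    if not (np.log10(x.min()) - 3 < log_ec50 < np.log10(x.max()) + 3):
        raise FitError("EC50 unbounded: outside the tested range by >1000x")
    rss = float(np.sum(res.fun ** 2))
    return FourPLFit(bottom=float(bottom), top=float(top),
                     log_ec50=float(log_ec50), hill=float(hill),
                     rss=rss, n_points=len(y))


def _fit_shared(dr_a: DoseResponse, dr_b: DoseResponse,
                fa: FourPLFit, fb: FourPLFit) -> float:
    """RSS of the joint fit with one common log_ec50 (top/bottom/hill per
    curve) — the null model of the EC50 comparison."""
    xa, ya = np.asarray(dr_a.concentration, float), np.asarray(dr_a.lysis, float)
    xb, yb = np.asarray(dr_b.concentration, float), np.asarray(dr_b.lysis, float)

    def resid(p):
        ba, ta, ha, bb, tb, hb, lec = p
        return np.concatenate([four_pl(xa, ba, ta, lec, ha) - ya,
                               four_pl(xb, bb, tb, lec, hb) - yb])

    p0 = np.array([fa.bottom, fa.top, fa.hill, fb.bottom, fb.top, fb.hill,
                   0.5 * (fa.log_ec50 + fb.log_ec50)])
    res = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise FitError(f"shared fit did not converge: {res.message}")
    return float(np.sum(res.fun ** 2))


def compare_ec50(dr_a: DoseResponse, dr_b: DoseResponse,
                 fit_a: FourPLFit | None = None,
                 fit_b: FourPLFit | None = None) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of EC50_a = EC50_b.

    Separate fits (8 parameters) vs a shared-EC50 fit (7 parameters):
    F = [(RSS_shared − RSS_sep)/1] / [RSS_sep/df_sep].  Returns (F, p);
    a shared fit that happens to beat the separate fits clips F at 0, p = 1.
    """
    fa = fit_a or fit_4pl(dr_a)
    fb = fit_b or fit_4pl(dr_b)
    rss_sep = fa.rss + fb.rss
    rss_shared = _fit_shared(dr_a, dr_b, fa, fb)
    n = fa.n_points + fb.n_points
    df_sep = n - 8
    df_shared = n - 7
    if df_sep <= 0:
        raise CytotoxError("not enough points for the F-test")
    num = (rss_shared - rss_sep) / (df_shared - df_sep)
    if num <= 0 or rss_sep <= 0:
        return 0.0, 1.0
    f_stat = num / (rss_sep / df_sep)
    p = float(stats.f.sf(f_stat, df_shared - df_sep, df_sep))
    return float(f_stat), p


def relative_potency(ec50_ref: float, ec50_test: float) -> float:
    """EC50_ref / EC50_test, 1 decimal, half away from zero."""
    if ec50_ref <= 0 or ec50_test <= 0:
        raise CytotoxError("EC50 values must be > 0")
    return round_half_away(ec50_ref / ec50_test, 1)
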