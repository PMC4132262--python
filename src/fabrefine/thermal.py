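"""Differential scanning fluorimetry: melt curves, derivative-method Tm,
ΔTm with Student's t-test.

A thermal-shift experiment follows a hydrophobic dye's fluorescence as a
protein unfolds over a temperature ramp (here 25–99 °C).  Each unfolding
transition appears as a sigmoidal rise; the melting temperature Tm is read
off as the peak of the smoothed first derivative dF/dT ("derivative
method"), with parabolic refinement of the peak vertex.  Antibody samples
typically show two transitions (Fab and CH2/Fc); the Fab peak is selected
by an expected-temperature window rather than guessed from peak order.

ΔTm between constructs is the difference of replicate means; significance
uses a two-tailed pooled-variance Student's t-test, also available directly
from (n, mean, SD) summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design_engine import round_half_away


class ThermalError(ValueError):
    pass


@dataclass(frozen=True)
class MeltCurve:
    temperature: np.ndarray   # °C, strictly increasing
    fluorescence: np.ndarray  # a.u.
    replicate_id: int = 0
    sample: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, float)
        if np.any(np.diff(t) <= 0):
            raise ThermalError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(np.asarray(self.fluorescence, float))):
            raise ThermalError("non-finite fluorescence")


@dataclass(frozen=True)
class TmResult:
    tm: float            # °C
    peak_height: float   # dF/dT units
    peak_rank: int       # 1 = tallest peak

    def __post_init__(self) -> None:
        if self.peak_height <= 0:
            raise ThermalError("peak height must be > 0")


def simulate_melt(tm_list: list[tuple[float, float, float]],
                  baselines: tuple[float, float] = (0.0, 0.0),
                  noise_sd: float = 0.0, seed: int = 0,
                  grid: np.ndarray | None = None,
                  quench: float = 0.0,
                  replicate_id: int = 0, sample: str = "") -> MeltCurve:
    """Synthetic melt curve: a sum of two-state sigmoids plus baseline.

    ``tm_list`` holds (Tm °C, amplitude, slope s) per transition; each
    contributes A / (1 + exp((Tm − T)/s)), so the analytic inflection sits
    exactly at Tm.  ``baselines`` = (intercept, slope per °C).  ``quench``
    optionally subtracts a linear post-transition decay.  Noise is Gaussian
    with SD ``noise_sd``, seeded.
    """
    if grid is None:
        grid = np.arange(25.0, 99.0 + 1e-9, 0.74)   # 1% ramp, ~100 points
    t = np.asarray(grid, float)
    f = np.full_like(t, float(baselines[0])) + baselines[1] * (t - t[0])
    for tm, amp, slope in tm_list:
        if not (t[0] <= tm <= t[-1]):
            raise ThermalError(f"Tm {tm} outside grid [{t[0]}, {t[-1]}]")
        if slope <= 0:
            raise ThermalError("sigmoid slope must be > 0")
        f = f + amp / (1.0 + np.exp((tm - t) / slope))
    if quench > 0 and tm_list:
        last_tm = max(tm for tm, _, _ in tm_list)
        post = t > last_tm + 5.0
        f[post] -= quench * (t[post] - (last_tm + 5.0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=len(t))
    return MeltCurve(temperature=t, fluorescence=f,
                     replicate_id=replicate_id, sample=sample)


def tm_derivative(curve: MeltCurve, smoothing_window: int = 5,
                  prominence_frac: float = 0.05) -> list[TmResult]:
    """Tm of each transition by the derivative method.

    The fluorescence is smoothed with a centered moving average
    (``smoothing_window`` points), differentiated by central differences,
    and local maxima of dF/dT above ``prominence_frac`` × the global maximum
    are returned tallest-first, each with a parabolic-vertex refinement.
    An empty list (no peak above the floor) is not an error.
    """
    t = np.asarray(curve.temperature, float)
    f = np.asarray(curve.fluorescence, float)
    if len(t) < 20:
        raise ThermalError("need >= 20 grid points for the derivative method")
    w = max(1, int(smoothing_window))
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        fpad = np.pad(f, pad, mode="edge")
        f = np.convolve(fpad, kernel, mode="valid")[: len(t)]
    if np.ptp(f) <= 1e-12 * max(1.0, float(np.max(np.abs(f)))):
        return []                         # flat to numerical precision
    dfdt = np.gradient(f, t)
    floor = prominence_frac * float(np.max(dfdt)) if np.max(dfdt) > 0 else np.inf
    peaks = []
    for i in range(1, len(t) - 1):
        if dfdt[i] > dfdt[i - 1] and dfdt[i] >= dfdt[i + 1] and dfdt[i] > floor \
                and dfdt[i] > 0:
            # parabola through the three points around the vertex
            y0, y1, y2 = dfdt[i - 1], dfdt[i], dfdt[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            tm = t[i] + shift * (t[min(i + 1, len(t) - 1)] - t[i]) if shift >= 0 \
                else t[i] + shift * (t[i] - t[i - 1])
            height = y1 - 0.25 * (y0 - y2) * shift
            peaks.append((float(tm), float(height)))
    peaks.sort(key=lambda p: -p[1])
    return [TmResult(tm=tm, peak_height=h, peak_rank=rank + 1)
            for rank, (tm, h) in enumerate(peaks)]


def pick_fab_peak(results: list[TmResult],
                  window: tuple[float, float] = (60.0, 85.0)) -> TmResult | None:
    """Tallest peak inside the expected Fab-transition window."""
    inside = [r for r in results if window[0] <= r.tm <= window[1]]
    return min(inside, key=lambda r: r.peak_rank) if inside else None


def delta_tm(test: list[float], ref: list[float]) -> tuple[float, float]:
    """ΔTm = mean(test) − mean(ref) (1 decimal, half away from zero) and the
    two-tailed pooled-variance Student's t p-value."""
    if len(test) < 2 or len(ref) < 2:
        raise ThermalError("need >= 2 replicates per group")
    dtm = round_half_away(float(np.mean(test)) - float(np.mean(ref)), 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # identical groups
        t_stat, p = stats.ttest_ind(test, ref, equal_var=True)
    if np.isnan(p):           # zero pooled variance, identical groups
        p = 1.0 if np.mean(test) == np.mean(ref) else 0.0
    return dtm, float(p)


def delta_tm_from_stats(n_test: int, mean_test: float, sd_test: float,
                        n_ref: int, mean_ref: float, sd_ref: float
                        ) -> tuple[float, float]:
    """Same as :func:`delta_tm` but from (n, mean, SD) summaries."""
    if n_test < 2 or n_ref < 2:
        raise ThermalError("need >= 2 replicates per group")
    dtm = round_half_away(mean_test - mean_ref, 1)
    t_stat, p = stats.ttest_ind_from_stats(mean_test, sd_test, n_test,
                                           mean_ref, sd_ref, n_ref,
                                           equal_var=True)
    if np.isnan(p):
        p = 1.0 if mean_test == mean_ref else 0.0
    return dtm, float(p)
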