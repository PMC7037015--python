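"""Mono-exponential relaxation fits with asymptotic standard errors.

Inversion recovery: ``I(tau) = I0 * (1 - (1 + w) * exp(-tau / T1))`` with
the inversion efficiency ``w`` floated by default (w = 1 is a perfect pi
pulse) or fixed on request.  CPMG: ``I(Delta) = I0 * exp(-Delta / T2)``.
Both are nonlinear least squares via lmfit; reported uncertainties are the
Jacobian-covariance standard errors scaled by the residual variance.  A
residual-resampling bootstrap is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

from .recon import pick_peaks, series_reference_index, track_intensities, fid_to_spectrum
from .sequence import RelaxationSeries

__all__ = [
    "FitResult",
    "fit_ir",
    "fit_cpmg",
    "bootstrap_stderr",
    "relaxation_table",
    "fit_series",
]


@dataclass
class FitResult:
    model: str  # "IR" | "CPMG"
    t_fit_s: float
    t_stderr_s: float
    amplitude: float
    residual_rms: float
    n_points: int
    converged: bool
    efficiency_fit: float | None = None
    efficiency_stderr: float | None = None


def _ir_model(tau, i0, t1, w):
    return i0 * (1.0 - (1.0 + w) * np.exp(-tau / t1))


def _cpmg_model(delta, i0, t2):
    return i0 * np.exp(-delta / t2)


def _failed(model: str, n: int) -> FitResult:
    return FitResult(
        model=model, t_fit_s=float("nan"), t_stderr_s=float("nan"),
        amplitude=float("nan"), residual_rms=float("nan"),
        n_points=n, converged=False,
        efficiency_fit=float("nan") if model == "IR" else None,
    )


def _null_point_t1_guess(delays: np.ndarray, intensities: np.ndarray) -> float:
    """T1 guess from the IR zero crossing: tau_null / ln 2.

    The crossing is linearly interpolated between the delays bracketing the
    sign change; an exact-zero datum is taken as the null directly.  With
    no sign change the guess falls back to the delay span / 3.
    """
    zero = np.where(intensities == 0)[0]
    if zero.size:
        return delays[zero[0]] / math.log(2.0)
    sign = np.sign(intensities)
    flips = np.where(sign[:-1] * sign[1:] < 0)[0]
    if flips.size:
        i = flips[0]
        y0, y1 = intensities[i], intensities[i + 1]
        tau_null = delays[i] + (delays[i + 1] - delays[i]) * (-y0) / (y1 - y0)
        return tau_null / math.log(2.0)
    return max(delays.max() / 3.0, 1e-6)


def fit_ir(
    delays,
    intensities,
    fixed_efficiency: float | None = None,
) -> FitResult:
    """Fit the inversion-recovery model to signed peak heights.

    Requires >= 3 points for the 3-parameter fit (>= 2 with the efficiency
    fixed).  Degenerate data (all intensities equal) or solver failure
    yields ``converged=False``, never an exception.
    """
    tau = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    n_free = 2 if fixed_efficiency is not None else 3
    if tau.size != y.size:
        raise ValueError("delays and intensities must have equal length")
    if tau.size < n_free:
        raise ValueError(f"need at least {n_free} points for the IR fit")
    if np.allclose(y, y[0]):
        return _failed("IR", tau.size)
    model = Model(_ir_model, independent_vars=["tau"])
    params = model.make_params(
        i0=y[-1] if y[-1] != 0 else (np.max(np.abs(y)) or 1.0),
        t1=dict(value=_null_point_t1_guess(tau, y), min=1e-9),
        w=dict(value=1.0 if fixed_efficiency is None else fixed_efficiency,
               min=0.0, max=2.0, vary=fixed_efficiency is None),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(y, params, tau=tau)
    except Exception:
        return _failed("IR", tau.size)
    if not res.success or not (res.params["t1"].value > 0):
        return _failed("IR", tau.size)
    return FitResult(
        model="IR",
        t_fit_s=float(res.params["t1"].value),
        t_stderr_s=float(res.params["t1"].stderr or 0.0),
        amplitude=float(res.params["i0"].value),
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        n_points=int(tau.size),
        converged=True,
        efficiency_fit=float(res.params["w"].value),
        efficiency_stderr=float(res.params["w"].stderr or 0.0),
    )


def fit_cpmg(delays, intensities) -> FitResult:
    """Fit the CPMG decay model to peak heights.

    The initial T2 comes from a log-linear regression over the points above
    5% of the maximum; requires >= 2 points.
    """
    delta = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if delta.size != y.size:
        raise ValueError("delays and intensities must have equal length")
    if delta.size < 2:
        raise ValueError("need at least 2 points for the CPMG fit")
    if np.allclose(y, y[0]) or np.max(y) <= 0:
        return _failed("CPMG", delta.size)
    strong = y > 0.05 * np.max(y)
    if np.count_nonzero(strong) >= 2:
        slope, intercept = np.polyfit(delta[strong], np.log(y[strong]), 1)
        t2_guess = -1.0 / slope if slope < 0 else delta.max()
        i0_guess = math.exp(intercept)
    else:
        t2_guess, i0_guess = max(delta.max() / 3.0, 1e-6), float(np.max(y))
    model = Model(_cpmg_model, independent_vars=["delta"])
    params = model.make_params(
        i0=i0_guess, t2=dict(value=max(t2_guess, 1e-9), min=1e-9)
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(y, params, delta=delta)
    except Exception:
        return _failed("CPMG", delta.size)
    if not res.success or not (res.params["t2"].value > 0):
        return _failed("CPMG", delta.size)
    return FitResult(
        model="CPMG",
        t_fit_s=float(res.params["t2"].value),
        t_stderr_s=float(res.params["t2"].stderr or 0.0),
        amplitude=float(res.params["i0"].value),
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        n_points=int(delta.size),
        converged=True,
    )


def bootstrap_stderr(
    fit_func,
    delays,
    intensities,
    n_boot: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Residual-resampling bootstrap SD of the fitted relaxation time."""
    delays = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    base = fit_func(delays, y, **fit_kwargs)
    if not base.converged:
        return float("nan")
    if base.model == "IR":
        fitted = _ir_model(delays, base.amplitude, base.t_fit_s, base.efficiency_fit)
    else:
        fitted = _cpmg_model(delays, base.amplitude, base.t_fit_s)
    resid = y - fitted
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
        r = fit_func(delays, y_star, **fit_kwargs)
        if r.converged:
            draws.append(r.t_fit_s)
    return float(np.std(draws, ddof=1)) if len(draws) > 1 else float("nan")


def fit_series(
    series: RelaxationSeries,
    reference_peaks=None,
    min_height_fraction: float = 0.2,
    apodization_hz: float = 0.0,
    zero_fill_factor: int = 2,
    fixed_efficiency: float | None = None,
) -> pd.DataFrame:
    """Pick peaks, track their heights across the array, and fit each one.

    Returns a DataFrame with one row per tracked peak: position_ppm,
    fitted relaxation time, standard error, amplitude, convergence flag.
    """
    if reference_peaks is None:
        ref = series_reference_index(series)
        spec = fid_to_spectrum(
            series.fids[ref], series.spectral_width_hz, series.spectrometer_mhz,
            apodization_hz=apodization_hz, zero_fill_factor=zero_fill_factor,
            carrier_ppm=series.carrier_ppm,
        )
        reference_peaks = pick_peaks(spec, min_height_fraction=min_height_fraction)
    table = track_intensities(
        series, reference_peaks,
        apodization_hz=apodization_hz, zero_fill_factor=zero_fill_factor,
    )
    rows = []
    for col in table.columns[1:]:
        if series.experiment == "IR":
            r = fit_ir(table["delay_s"], table[col], fixed_efficiency=fixed_efficiency)
        else:
            r = fit_cpmg(table["delay_s"], table[col])
        rows.append(
            {
                "position_ppm": float(col),
                "t_fit_s": r.t_fit_s,
                "t_stderr_s": r.t_stderr_s,
                "amplitude": r.amplitude,
                "converged": r.converged,
                "model": r.model,
            }
        )
    return pd.DataFrame(rows)


def relaxation_table(
    ir_series: RelaxationSeries,
    cpmg_series: RelaxationSeries,
    match_tol_ppm: float = 0.02,
    **fit_kwargs,
) -> pd.DataFrame:
    """Joined per-peak T1/T2 table from paired IR and CPMG series.

    Peaks are fitted independently per experiment and joined by position
    within ``match_tol_ppm``; unmatched peaks are kept as rows with NaN on
    the missing side and flagged in the ``matched`` column.
    """
    ir = fit_series(ir_series, **fit_kwargs)
    cpmg = fit_series(cpmg_series, **fit_kwargs)
    rows = []
    used_cpmg: set[int] = set()
    for _, r1 in ir.iterrows():
        best_j, best_d = None, match_tol_ppm
        for j, r2 in cpmg.iterrows():
            d = abs(r1["position_ppm"] - r2["position_ppm"])
            if j not in used_cpmg and d <= best_d:
                best_j, best_d = j, d
        row = {
            "position_ppm": r1["position_ppm"],
            "t1_s": r1["t_fit_s"], "t1_stderr_s": r1["t_stderr_s"],
            "t2_s": float("nan"), "t2_stderr_s": float("nan"),
            "matched": best_j is not None,
        }
        if best_j is not None:
            used_cpmg.add(best_j)
            row["t2_s"] = cpmg.loc[best_j, "t_fit_s"]
            row["t2_stderr_s"] = cpmg.loc[best_j, "t_stderr_s"]
        rows.append(row)
    unmatched = [j for j in cpmg.index if j not in used_cpmg]
    for j in unmatched:
        rows.append(
            {
                "position_ppm": cpmg.loc[j, "position_ppm"],
                "t1_s": float("nan"), "t1_stderr_s": float("nan"),
                "t2_s": cpmg.loc[j, "t_fit_s"], "t2_stderr_s": cpmg.loc[j, "t_stderr_s"],
                "matched": False,
            }
        )
    if unmatched or not all(r["matched"] for r in rows[: len(ir)]):
        warnings.warn("some peaks could not be matched across the IR/CPMG pair", stacklevel=2)
    out = pd.DataFrame(rows).sort_values("position_ppm", ascending=False).reset_index(drop=True)
    return out
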