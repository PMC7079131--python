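"""Whole-cell Na+ current analysis: peaks, I/V, Boltzmann and kinetic fits.

The pipeline mirrors the standard voltage-clamp workflow: extract peak
currents per sweep, build the I/V relation and estimate the reversal
potential, convert to chord conductance, fit steady-state Boltzmann curves,
derive the m3h gating endpoints from those curves (m from the cube root of
the normalized activation conductance), fit per-voltage tau_m/tau_h with the
endpoints held fixed, fit the current decay with a double exponential, fit
the two-pulse recovery time course, and convert slope factors to effective
gating charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import uniform_filter1d as ndi_uniform

from .model import (
    BoltzmannParams,
    DecayParams,
    HHState,
    Sense,
    boltzmann_curve,
    charge_from_slope,
    conductance_from_current,
    double_exp_decay,
    hh_m3h_timecourse,
    recovery_fraction,
)
from .traces import Sweep, TraceSet

__all__ = [
    "FitError",
    "BoltzmannFit",
    "RecoveryFit",
    "DecayFit",
    "GatingFitResult",
    "extract_peak_currents",
    "estimate_reversal",
    "fit_steady_state_boltzmann",
    "derive_gating_endpoints",
    "fit_hh_time_constants",
    "fit_inactivation_double_exp",
    "fit_recovery_timecourse",
    "recovery_ratios",
    "activation_conductance_curve",
    "availability_curve",
    "apply_voltage_shift",
    "charge_from_slope",
    "compare_conditions",
    "analyze_condition",
]

# capacitive-transient guard: peak search skips this much after the step
PEAK_BLANK_MS = 0.3
K_BOUNDS = (0.5, 30.0)      # mV, Boltzmann slope
TAU_BOUNDS = (0.05, 100.0)  # ms, all kinetic time constants


class FitError(RuntimeError):
    """A nonlinear fit failed or was degenerate; carries diagnostics."""


@dataclass
class BoltzmannFit:
    params: BoltzmannParams
    stderr_vhalf: float
    stderr_k: float
    rss: float

    @property
    def vhalf(self) -> float:
        return self.params.vhalf

    @property
    def k(self) -> float:
        return self.params.k


@dataclass
class RecoveryFit:
    tau: float
    t_half: float
    stderr_tau: float
    rss: float


@dataclass
class DecayFit:
    params: DecayParams
    rss_double: float
    rss_single: float
    tau_single: float
    aicc_double: float
    aicc_single: float

    @property
    def prefers_double(self) -> bool:
        return self.aicc_double < self.aicc_single


@dataclass
class GatingFitResult:
    """Per-cell gating summary mirroring the standard report columns."""

    act: Optional[BoltzmannFit] = None
    inact: Optional[BoltzmannFit] = None
    gmax: float = float("nan")
    e_na_fit: float = float("nan")
    peak_density: float = float("nan")          # pA/pF, largest magnitude
    tau_table: Optional[pd.DataFrame] = None    # voltage, tau_m, tau_h, offset, ok
    decay: dict = field(default_factory=dict)   # voltage -> DecayFit
    recovery: Optional[RecoveryFit] = None
    z_act: float = float("nan")
    z_inact: float = float("nan")

    @property
    def recovery_tau(self) -> float:
        return self.recovery.tau if self.recovery else float("nan")

    @property
    def recovery_t_half(self) -> float:
        return self.recovery.t_half if self.recovery else float("nan")


# --------------------------------------------------------------------------
# peaks, I/V, reversal
# --------------------------------------------------------------------------

def extract_peak_currents(
    ts: TraceSet, window: tuple[float, float] = (PEAK_BLANK_MS, 50.0),
    smooth_ms: float = 0.0,
) -> pd.DataFrame:
    """Per-sweep peak current (largest-magnitude extremum in the window).

    Inward currents are negative; the peak keeps its sign.  ``smooth_ms``
    applies a boxcar of that width before the extremum search — useful when
    all sweeps share identical kinetics (availability protocols), where the
    smoothing bias cancels in normalization but the noise-extremum floor
    does not.  Returns columns voltage, peak_pa, density_pa_pf (and
    interval_ms for recovery sweeps).
    """
    lo, hi = window
    rows = []
    for sw in ts.sweeps:
        sel = (sw.time_ms >= lo) & (sw.time_ms <= hi)
        if not sel.any():
            raise ValueError(f"empty peak window {window} for sweep at {sw.voltage} mV")
        seg = sw.current_pa[sel]
        if smooth_ms > 0 and sw.time_ms.size > 1:
            n = max(int(round(smooth_ms / sw.dt_ms)) | 1, 1)
            seg = ndi_uniform(seg, n)
        peak = float(seg[np.argmax(np.abs(seg))])
        rows.append({"voltage": sw.voltage, "peak_pa": peak,
                     "density_pa_pf": peak / ts.c_m, "interval_ms": sw.interval_ms})
    return pd.DataFrame(rows)


def estimate_reversal(iv: pd.DataFrame) -> float:
    """Reversal potential (mV) by linear interpolation of the I/V zero crossing.

    Searches the limb depolarized of the peak inward current for a sign
    change from inward (negative) to outward (positive).
    """
    df = iv.sort_values("voltage").reset_index(drop=True)
    v = df["voltage"].to_numpy(dtype=float)
    i = df["peak_pa"].to_numpy(dtype=float)
    start = int(np.argmin(i))  # peak inward current
    for j in range(start, len(v) - 1):
        if i[j] < 0 <= i[j + 1]:
            if i[j + 1] == 0:
                return float(v[j + 1])
            return float(v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j]))
    raise FitError("I/V relation has no inward-to-outward zero crossing; "
                   "cannot estimate the reversal potential")


def activation_conductance_curve(
    ts: TraceSet, e_na: float, window: tuple[float, float] = (PEAK_BLANK_MS, 50.0),
    reversal_margin_mv: float = 10.0, smooth_ms: float = 0.5,
) -> pd.DataFrame:
    """Normalized peak-conductance curve G/Gmax(V) from an activation family.

    Peak currents are divided by the driving force (V - E_Na) and normalized
    to the per-cell maximum.  Sweeps within ``reversal_margin_mv`` of the
    reversal are excluded: the driving force there is so small that the
    chord conductance amplifies current noise without bound.  A short boxcar
    (``smooth_ms``) suppresses the noise-extremum floor on sub-threshold
    sweeps; its attenuation of the true peak is nearly voltage-independent
    and cancels in the normalization.
    """
    iv = extract_peak_currents(ts, window, smooth_ms=smooth_ms)
    rows = []
    for _, r in iv.iterrows():
        if abs(r["voltage"] - e_na) < reversal_margin_mv:
            continue
        g = conductance_from_current(r["peak_pa"], r["voltage"], e_na)
        rows.append({"voltage": r["voltage"], "g_ns": g})
    df = pd.DataFrame(rows)
    gmax = df["g_ns"].max()
    if gmax <= 0:
        raise FitError("non-positive peak conductance; check sweep polarity")
    df["g_over_gmax"] = df["g_ns"] / gmax
    return df


def availability_curve(
    ts: TraceSet, window: tuple[float, float] = (PEAK_BLANK_MS, 50.0),
    smooth_ms: float = 1.0,
) -> pd.DataFrame:
    """Normalized availability (peak test current / max) vs pre-pulse voltage.

    All sweeps respond to the same test pulse, so a 1 ms boxcar before the
    peak search suppresses the noise-extremum floor on fully inactivated
    sweeps without biasing the normalized curve.
    """
    iv = extract_peak_currents(ts, window, smooth_ms=smooth_ms)
    peak_mag = iv["peak_pa"].abs()
    iv = iv.assign(g_over_gmax=peak_mag / peak_mag.max())
    return iv[["voltage", "g_over_gmax"]]


# --------------------------------------------------------------------------
# Boltzmann and endpoint machinery
# --------------------------------------------------------------------------

def fit_steady_state_boltzmann(
    voltage, g_over_gmax, sense: Sense = Sense.ACTIVATION
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized G/Gmax(V) table.

    Initial V1/2 at the half-maximum crossing, k = 8 mV, k bounded to
    (0.5, 30) mV.  Raises FitError on degenerate input or non-convergence.
    """
    v = np.asarray(voltage, dtype=float)
    y = np.asarray(g_over_gmax, dtype=float)
    if v.size < 4:
        raise FitError(f"need >= 4 points to fit a Boltzmann curve, got {v.size}")
    if np.ptp(y) < 1e-6:
        raise FitError("degenerate input: G/Gmax does not span a transition "
                       f"(range {np.ptp(y):.2g}); slope factor unbounded")

    order = np.argsort(v)
    vs, ys = v[order], y[order]
    half = 0.5 * (ys.min() + ys.max())
    crossings = np.nonzero(np.diff(np.sign(ys - half)))[0]
    v0 = float(vs[crossings[0]]) if crossings.size else float(np.median(vs))

    def f(vv, vhalf, k):
        return boltzmann_curve(vv, BoltzmannParams(vhalf, k, sense))

    try:
        popt, pcov = optimize.curve_fit(
            f, v, y, p0=[v0, 8.0],
            bounds=([-200.0, K_BOUNDS[0]], [100.0, K_BOUNDS[1]]), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    resid = y - f(v, *popt)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [float("nan")] * 2
    return BoltzmannFit(BoltzmannParams(float(popt[0]), float(popt[1]), sense),
                        float(stderr[0]), float(stderr[1]), float(resid @ resid))


def derive_gating_endpoints(
    act: BoltzmannParams, inact: BoltzmannParams, v_before: float, v_after: float
) -> dict:
    """m3h endpoints for a step v_before -> v_after.

    m is the cube root of the activation-curve value (so that m^3 reproduces
    the fitted normalized conductance); h is the inactivation-curve value
    directly.
    """
    return {
        "m0": float(boltzmann_curve(v_before, act)) ** (1.0 / 3.0),
        "m_inf": float(boltzmann_curve(v_after, act)) ** (1.0 / 3.0),
        "h0": float(boltzmann_curve(v_before, inact)),
        "h_inf": float(boltzmann_curve(v_after, inact)),
    }


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

def fit_hh_time_constants(
    ts: TraceSet,
    act: BoltzmannParams,
    inact: BoltzmannParams,
    gmax: float,
    e_na: float,
    v_holding: Optional[float] = None,
    min_peak_g_frac: float = 0.02,
    fit_gmax: bool = False,
) -> pd.DataFrame:
    """Per-voltage tau_m/tau_h from endpoint-fixed m3h fits of G(t).

    Each sweep's current is converted to conductance via G = I/(V - E_Na)
    (sweeps within 0.5 mV of the reversal are skipped: the driving force is
    singular there); the m3h transient is fitted with only tau_m, tau_h and
    the offset free, endpoints and gmax held fixed.  With ``fit_gmax`` the
    conductance scale is freed as well — useful when ``gmax`` is the
    measured peak conductance, which understates the full-activation scale
    whenever inactivation overlaps the rising phase.  Sweeps whose expected
    steady-state amplitude is below ``min_peak_g_frac`` of gmax, or whose
    fit fails, are flagged ok=False and the pipeline continues.
    """
    v_hold = ts.meta.get("holding_mv", -120.0) if v_holding is None else v_holding
    rows = []
    for sw in ts.sweeps:
        v = sw.voltage
        row = {"voltage": v, "tau_m": np.nan, "tau_h": np.nan,
               "offset": np.nan, "rss": np.nan, "ok": False}
        if abs(v - e_na) < 0.5:
            rows.append(row)
            continue
        ep = derive_gating_endpoints(act, inact, v_hold, v)
        if ep["m_inf"] ** 3 * max(ep["h0"], ep["h_inf"]) < min_peak_g_frac:
            rows.append(row)
            continue
        g = conductance_from_current(sw.current_pa, v, e_na)
        t = sw.time_ms

        def f(tt, tau_m, tau_h, offset, scale=1.0):
            s = HHState(m0=ep["m0"], m_inf=ep["m_inf"], h0=ep["h0"], h_inf=ep["h_inf"],
                        tau_m=tau_m, tau_h=tau_h, gmax=scale * gmax, offset=offset)
            return hh_m3h_timecourse(tt, s)

        try:
            if fit_gmax:
                popt, _ = optimize.curve_fit(
                    f, t, g, p0=[0.5, 3.0, 0.0, 1.0],
                    bounds=([TAU_BOUNDS[0]] * 2 + [-abs(gmax), 1e-3],
                            [TAU_BOUNDS[1]] * 2 + [abs(gmax), 1e3]), maxfev=5000)
            else:
                popt, _ = optimize.curve_fit(
                    f, t, g, p0=[0.5, 3.0, 0.0],
                    bounds=([TAU_BOUNDS[0]] * 2 + [-abs(gmax)],
                            [TAU_BOUNDS[1]] * 2 + [abs(gmax)]), maxfev=5000)
            resid = g - f(t, *popt)
            row.update(tau_m=float(popt[0]), tau_h=float(popt[1]),
                       offset=float(popt[2]), rss=float(resid @ resid), ok=True)
        except RuntimeError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def _aicc(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        rss = 1e-300
    aic = n * math.log(rss / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else float("inf"))


def fit_inactivation_double_exp(sweep: Sweep, peak_window: tuple[float, float] = (PEAK_BLANK_MS, 50.0)) -> DecayFit:
    """Double-exponential fit of the post-peak current decay.

    tau1 < tau2 is enforced by relabeling; a single-exponential fit of the
    same segment is reported alongside with small-sample AIC for the model
    comparison.
    """
    lo, hi = peak_window
    sel = (sweep.time_ms >= lo) & (sweep.time_ms <= hi)
    t_all, i_all = sweep.time_ms[sel], sweep.current_pa[sel]
    pk = int(np.argmax(np.abs(i_all)))
    t = t_all[pk:] - t_all[pk]
    y = i_all[pk:]
    if t.size < 8:
        raise FitError("decay segment too short for a double-exponential fit")
    a_tot = abs(float(y[0]))

    # log-linear tail regression seeds the slow component
    tail = slice(t.size // 3, None)
    mag = np.abs(y[tail])
    good = mag > max(1e-12, 1e-6 * a_tot)
    if good.sum() >= 4:
        slope, inter = np.polyfit(t[tail][good], np.log(mag[good]), 1)
        tau2_0 = float(np.clip(-1.0 / slope if slope < 0 else 10.0,
                               2 * TAU_BOUNDS[0], TAU_BOUNDS[1] * 0.9))
    else:
        tau2_0 = 10.0
    tau1_0 = max(tau2_0 / 8.0, 2 * TAU_BOUNDS[0])

    def f2(tt, a1, a2, tau1, tau2):
        return double_exp_decay(tt, DecayParams(a1, a2, tau1, tau2))

    def f1(tt, a, tau):
        return -a * np.exp(-tt / tau)

    try:
        popt2, _ = optimize.curve_fit(
            f2, t, y, p0=[0.7 * a_tot, 0.3 * a_tot, tau1_0, tau2_0],
            bounds=([0.0, 0.0, TAU_BOUNDS[0], TAU_BOUNDS[0]],
                    [np.inf, np.inf, TAU_BOUNDS[1], TAU_BOUNDS[1]]), maxfev=3000)
        popt1, _ = optimize.curve_fit(
            f1, t, y, p0=[a_tot, tau2_0],
            bounds=([0.0, TAU_BOUNDS[0]], [np.inf, TAU_BOUNDS[1]]), maxfev=3000)
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    r2 = y - f2(t, *popt2)
    r1 = y - f1(t, *popt1)
    rss2, rss1 = float(r2 @ r2), float(r1 @ r1)
    params = DecayParams(float(popt2[0]), float(popt2[1]),
                         float(popt2[2]), float(popt2[3])).ordered()
    return DecayFit(params, rss2, rss1, float(popt1[1]),
                    _aicc(rss2, t.size, 4), _aicc(rss1, t.size, 2))


def recovery_ratios(ts: TraceSet, window: tuple[float, float] = (PEAK_BLANK_MS, 50.0),
                    smooth_ms: float = 1.0) -> pd.DataFrame:
    """P2/P1 peak-current ratios from a recovery-protocol trace set.

    P1 and P2 share the same pulse kinetics, so the boxcar bias cancels in
    the ratio.
    """
    if ts.protocol != "recovery":
        raise ValueError(f"expected a recovery trace set, got {ts.protocol!r}")
    t1 = np.asarray(ts.meta["p1_time_ms"])
    i1 = np.asarray(ts.meta["p1_current_pa"])
    sel = (t1 >= window[0]) & (t1 <= window[1])
    seg1 = i1[sel]
    if smooth_ms > 0 and t1.size > 1:
        n = max(int(round(smooth_ms / float(t1[1] - t1[0]))) | 1, 1)
        seg1 = ndi_uniform(seg1, n)
    p1 = float(seg1[np.argmax(np.abs(seg1))])
    iv = extract_peak_currents(ts, window, smooth_ms=smooth_ms)
    return pd.DataFrame({"interval_ms": iv["interval_ms"],
                         "ratio": iv["peak_pa"] / p1})


def fit_recovery_timecourse(intervals, ratios) -> RecoveryFit:
    """Mono-exponential recovery fit, I_P2/I_P1 = 1 - exp(-t/tau); t1/2 = tau ln2."""
    t = np.asarray(intervals, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if t.size < 5:
        raise FitError(f"need >= 5 recovery intervals, got {t.size}")
    half_idx = np.argmin(np.abs(y - 0.5))
    p0 = max(float(t[half_idx]) / math.log(2), 0.5)
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, tau: recovery_fraction(tt, tau), t, y,
            p0=[p0], bounds=([TAU_BOUNDS[0]], [500.0]), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}") from exc
    tau = float(popt[0])
    resid = y - recovery_fraction(t, tau)
    return RecoveryFit(tau=tau, t_half=tau * math.log(2),
                       stderr_tau=float(np.sqrt(pcov[0, 0])), rss=float(resid @ resid))


# --------------------------------------------------------------------------
# small utilities and the per-cell orchestrator
# --------------------------------------------------------------------------

def apply_voltage_shift(table, shift: float):
    """Translate the voltage axis of a (voltage, value) table by ``shift`` mV.

    Accepts a DataFrame with a ``voltage`` column or an (N, 2) array whose
    first column is voltage; values are untouched.
    """
    if isinstance(table, pd.DataFrame):
        out = table.copy()
        out["voltage"] = out["voltage"] + shift
        return out
    arr = np.array(table, dtype=float, copy=True)
    arr[:, 0] += shift
    return arr


def compare_conditions(a, b) -> tuple[float, float]:
    """Unpaired two-sample t test; returns (t statistic, p value)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def analyze_condition(
    act_ts: TraceSet,
    inact_ts: Optional[TraceSet] = None,
    rec_ts: Optional[TraceSet] = None,
    e_na: Optional[float] = None,
    temperature: float = 295.15,
) -> GatingFitResult:
    """Full per-cell pipeline over the available protocol families."""
    res = GatingFitResult()
    iv = extract_peak_currents(act_ts)
    res.peak_density = float(iv["density_pa_pf"].abs().max()) * np.sign(
        iv.loc[iv["density_pa_pf"].abs().idxmax(), "density_pa_pf"])
    res.e_na_fit = estimate_reversal(iv) if e_na is None else e_na
    gdf = activation_conductance_curve(act_ts, res.e_na_fit)
    res.act = fit_steady_state_boltzmann(gdf["voltage"], gdf["g_over_gmax"],
                                         Sense.ACTIVATION)
    res.gmax = float(gdf["g_ns"].max())
    res.z_act = charge_from_slope(res.act.k, temperature)

    if inact_ts is not None:
        av = availability_curve(inact_ts)
        res.inact = fit_steady_state_boltzmann(av["voltage"], av["g_over_gmax"],
                                               Sense.INACTIVATION)
        res.z_inact = charge_from_slope(res.inact.k, temperature)
        # res.gmax is the measured peak conductance; free the scale so the
        # tau fits are not forced through an understated full-activation gmax
        res.tau_table = fit_hh_time_constants(
            act_ts, res.act.params, res.inact.params, res.gmax, res.e_na_fit,
            fit_gmax=True)
        for sw in act_ts.sweeps:
            if -40.0 <= sw.voltage <= -20.0:
                try:
                    res.decay[sw.voltage] = fit_inactivation_double_exp(sw)
                except FitError:
                    pass

    if rec_ts is not None:
        rr = recovery_ratios(rec_ts)
        res.recovery = fit_recovery_timecourse(rr["interval_ms"], rr["ratio"])
    return res
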