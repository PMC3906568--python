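"""Electrophysiology analyses: frame timing, membrane test, IV metrics,
synaptic event detection, charge transfer, photostimulation map statistics.

All quantities are SI (volts, amperes, ohms, farads, seconds, coulombs).
"""

from __future__ import annotations

import csv
import sqlite3
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from neurorig.signals import Trace

__all__ = [
    "MembraneProps",
    "EventRecord",
    "IVMetrics",
    "MapSite",
    "frame_times_from_exposure",
    "membrane_properties",
    "iv_metrics",
    "detect_spikes",
    "detect_events",
    "charge_transfer",
    "classify_map_sites",
    "export_map_csv",
    "export_map_sqlite",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MembraneProps:
    """Passive membrane/electrode properties from a test pulse."""

    Rin: float | None = None          # total input resistance, ohms
    Raccess: float | None = None      # access (series) resistance, ohms
    Rm: float | None = None           # membrane resistance, ohms
    Cm: float | None = None           # membrane capacitance, farads
    tau: float | None = None          # charging time constant, seconds
    holding_current: float | None = None
    resting_potential: float | None = None
    fit_residual: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class EventRecord:
    """One detected synaptic-like event."""

    onset_time: float
    amplitude: float
    decay_tau: float | None = None
    rise_time: float | None = None
    baseline: float = 0.0


@dataclass
class IVMetrics:
    resting_potential: float | None = None
    input_resistance: float | None = None
    tau_m: float | None = None
    sag_ratio: float | None = None
    isis: list = field(default_factory=list)
    first_spike_latency: float | None = None
    adaptation_ratio: float | None = None


@dataclass
class MapSite:
    """One photostimulation site: position, per-trial counts, statistics."""

    position: tuple  # global (x, y), meters
    n_trials: int = 1
    spontaneous_count: int = 0   # events in baseline windows, summed over trials
    test_count: int = 0          # events in post-stimulus test windows
    trials: list = field(default_factory=list)  # optional per-trial EventRecord lists
    metric_value: float | None = None
    p_value: float | None = None
    evoked_flag: bool = False

    def __post_init__(self):
        if self.spontaneous_count < 0 or self.test_count < 0:
            raise ValueError("event counts cannot be negative")


# ---------------------------------------------------------------------------
# frame timing


def frame_times_from_exposure(ttl: Trace):
    """Frame (start, duration) pairs from a camera exposure TTL trace.

    Thresholds at the midpoint of the trace's dynamic range with a +-10%
    amplitude hysteresis band, so noise up to the band width cannot produce
    spurious edges.  Returns an empty list (with a warning) for a trace with
    no dynamic range.
    """
    y = ttl.samples
    if y.size == 0:
        raise ValueError("empty trace")
    lo_v, hi_v = float(y.min()), float(y.max())
    amp = hi_v - lo_v
    if amp <= 0:
        warnings.warn("exposure trace has no dynamic range; no frames found")
        return []
    mid = 0.5 * (lo_v + hi_v)
    hi_th, lo_th = mid + 0.1 * amp, mid - 0.1 * amp
    state = y[0] > mid
    # an exposure already in progress at the first sample starts there
    starts = [0] if state else []
    out = []
    for i in range(y.size):
        if not state and y[i] > hi_th:
            state = True
            starts.append(i)
        elif state and y[i] < lo_th:
            state = False
            if starts:
                i0 = starts[-1]
                out.append((ttl.t0 + i0 / ttl.rate, (i - i0) / ttl.rate))
                starts.pop()
    for i0 in starts:  # exposure still high at the end of the trace
        out.append((ttl.t0 + i0 / ttl.rate, (y.size - i0) / ttl.rate))
    return out


# ---------------------------------------------------------------------------
# membrane test pulse


def _find_step(command: Trace):
    """Indices (onset, offset) and amplitude of the single step in a command."""
    d = np.diff(command.samples)
    idx = np.nonzero(np.abs(d) > 0)[0]
    if len(idx) == 0:
        raise ValueError("command contains no step (zero-amplitude pulse)")
    i_on = int(idx[0]) + 1
    amp = float(command.samples[i_on] - command.samples[i_on - 1])
    i_off = int(idx[1]) + 1 if len(idx) > 1 else command.n
    return i_on, i_off, amp


def _fit_exponential(t, y, y_inf):
    """Fit y(t) = y_inf + A·exp(-t/tau); returns (A, tau, rms residual)."""
    dev = y - y_inf
    sgn = np.sign(dev[0]) or 1.0
    pos = sgn * dev
    ok = pos > max(1e-30, 1e-6 * pos.max())
    if ok.sum() < 3:
        raise RuntimeError("too few samples above baseline for exponential fit")
    # log-linear initial guess, then refine
    coef = np.polyfit(t[ok], np.log(pos[ok]), 1)
    tau0 = -1.0 / coef[0] if coef[0] < 0 else (t[-1] - t[0]) / 3
    A0 = sgn * np.exp(coef[1])
    popt, _ = optimize.curve_fit(
        lambda tt, A, tau: y_inf + A * np.exp(-tt / tau), t, y,
        p0=[A0, max(tau0, 1e-9)], maxfev=5000)
    A, tau = popt
    rms = float(np.sqrt(np.mean((y_inf + A * np.exp(-t / tau) - y) ** 2)))
    return float(A), float(tau), rms


def membrane_properties(response: Trace, command: Trace, mode: str) -> MembraneProps:
    """Membrane/electrode properties from a single test-pulse response.

    Voltage clamp: the command step dV drives a capacitive transient; the
    peak current (extrapolated to pulse onset from a single-exponential fit
    of the decay) gives the access resistance Raccess = dV/(Ipeak - I0), the
    steady-state current gives the total input resistance
    Rin = dV/(Iss - I0), the membrane resistance is Rm = Rin - Raccess and
    the capacitance follows from the fitted time constant,
    Cm = tau·Rin/(Raccess·Rm).  Current clamp: Rin = dVss/dI and the resting
    potential is the pre-pulse baseline mean.
    """
    if mode not in ("vc", "ic"):
        raise ValueError(f"mode must be vc|ic, got {mode!r}")
    i_on, i_off, amp = _find_step(command)
    rate = response.rate
    if i_on < max(2, int(0.001 * rate)):
        raise ValueError("need baseline before the pulse")
    y = response.samples
    base = float(np.mean(y[:i_on]))
    # steady state: last quarter of the pulse
    i_ss = i_on + max(1, int(0.75 * (i_off - i_on)))
    ss = float(np.mean(y[i_ss:i_off]))

    if mode == "ic":
        rin = (ss - base) / amp
        return MembraneProps(Rin=rin, resting_potential=base)

    # voltage clamp: fit the decay, extrapolate the peak back to onset
    t_rel = (np.arange(i_on, i_off) - i_on) / rate
    A, tau, rms = _fit_exponential(t_rel, y[i_on:i_off], ss)
    i_peak = ss + A
    raccess = amp / (i_peak - base)
    rin = amp / (ss - base)
    rm = rin - raccess
    if raccess <= 0 or rm <= 0:
        raise ValueError("non-physical fit: resistances must be positive")
    cm = tau * rin / (raccess * rm)
    return MembraneProps(Rin=rin, Raccess=raccess, Rm=rm, Cm=cm, tau=tau,
                         holding_current=base, fit_residual=rms)


# ---------------------------------------------------------------------------
# IV curve metrics


def detect_spikes(trace: Trace, threshold: float = -20e-3,
                  refractory: float = 2e-3) -> np.ndarray:
    """Spike times: upward threshold crossings with an absolute refractory."""
    y = trace.samples
    up = np.nonzero((y[1:] >= threshold) & (y[:-1] < threshold))[0] + 1
    times = trace.t0 + up / trace.rate
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            kept.append(t)
            last = t
    return np.asarray(kept)


def iv_metrics(traces: list[Trace], steps, step_window,
               spike_threshold: float = -20e-3) -> IVMetrics:
    """Standard current-clamp IV protocol metrics.

    ``traces`` are the voltage responses (one per current step amplitude in
    ``steps``, amps), ``step_window`` is the (t_on, t_off) of the current
    pulse.  Input resistance is the least-squares slope through
    (dI, dV_steady) over subthreshold steps; the membrane time constant is
    fitted on the smallest hyperpolarizing step; sag ratio
    (Vmin - Vss)/(Vmin - Vbaseline) on the largest one; spike-train metrics
    (ISIs, latency, adaptation = mean of last two ISIs / first ISI) come
    from the step with the most spikes.
    """
    if len(traces) != len(steps):
        raise ValueError("one trace per current step required")
    t_on, t_off = step_window
    steps = np.asarray(steps, dtype=float)
    baselines, vss, spikes_per = [], [], []
    for tr in traces:
        pre = tr.time_slice(tr.t0, t_on).samples
        baselines.append(float(np.mean(pre)))
        ss_start = t_on + 0.75 * (t_off - t_on)
        vss.append(float(np.mean(tr.time_slice(ss_start, t_off).samples)))
        spikes_per.append(detect_spikes(tr.time_slice(t_on, t_off),
                                        threshold=spike_threshold))
    rmp = float(np.mean(baselines))
    sub = [i for i in range(len(steps)) if len(spikes_per[i]) == 0]

    rin = None
    if len(sub) >= 2:
        di = steps[sub]
        dv = np.array(vss)[sub] - np.array(baselines)[sub]
        rin = float(np.polyfit(di, dv, 1)[0])

    m = IVMetrics(resting_potential=rmp, input_resistance=rin)

    hyp = [i for i in range(len(steps)) if steps[i] < 0]
    if hyp:
        # tau on the smallest-magnitude hyperpolarizing step
        i_small = min(hyp, key=lambda i: abs(steps[i]))
        tr = traces[i_small].time_slice(t_on, t_off)
        t_rel = tr.times - tr.t0
        try:
            _, tau, _ = _fit_exponential(t_rel, tr.samples, vss[i_small])
            m.tau_m = tau
        except RuntimeError:
            pass
        # sag on the largest-magnitude hyperpolarizing step
        i_big = max(hyp, key=lambda i: abs(steps[i]))
        seg = traces[i_big].time_slice(t_on, t_off).samples
        vmin = float(seg.min())
        denom = vmin - baselines[i_big]
        if abs(denom) > 0:
            m.sag_ratio = float(np.clip((vmin - vss[i_big]) / denom, 0.0, 1.0))

    i_spiky = int(np.argmax([len(s) for s in spikes_per]))
    sp = spikes_per[i_spiky]
    if len(sp) >= 1:
        m.first_spike_latency = float(sp[0] - t_on)
    if len(sp) >= 2:
        m.isis = list(np.diff(sp))
    if len(sp) >= 3:
        isis = np.diff(sp)
        m.adaptation_ratio = float(np.mean(isis[-2:]) / isis[0])
    return m


# ---------------------------------------------------------------------------
# event detection


def _deconvolve_exp(y: np.ndarray, rate: float, tau: float) -> np.ndarray:
    """Frequency-domain deconvolution of a single-exponential decay kernel.

    The spectrum is divided by the kernel spectrum, regularized by adding
    1e-6 of its peak magnitude, turning each exponential event into a narrow
    pulse at its onset with height ~ event amplitude.
    """
    n = y.size
    t = np.arange(n) / rate
    kernel = np.exp(-t / tau)
    Y = np.fft.rfft(y)
    K = np.fft.rfft(kernel)
    eps = 1e-6 * np.abs(K).max()
    return np.fft.irfft(Y / (K + eps), n=n)


def detect_events(trace: Trace, decay_tau_guess: float, threshold_k: float = 5.0,
                  min_interval: float = 5e-3, polarity: str = "negative",
                  lowpass_frac: float = 0.4) -> list[EventRecord]:
    """Detect stereotyped exponential-decay events (PSCs/PSPs) in a trace.

    Pipeline: zero-phase Butterworth low-pass at ``lowpass_frac`` of Nyquist
    -> exponential deconvolution with ``decay_tau_guess`` -> 1 ms boxcar
    smoothing of the deconvolved signal (deconvolution amplifies
    high-frequency noise; each event remains a pulse wider than 1 ms) ->
    robust threshold at ``threshold_k`` x 1.4826·MAD of the smoothed signal
    (floored at 1e-3 of its peak to reject deconvolution ringing on
    noise-free data) -> onsets at threshold crossings separated by at least
    ``min_interval``.
    Each event is then measured on the filtered trace: baseline (median of
    the preceding 5 ms), amplitude (extremum - baseline), 10-90% rise time,
    and a single-exponential decay fit from the peak.
    """
    if decay_tau_guess <= 0:
        raise ValueError("decay_tau_guess must be positive")
    if polarity not in ("negative", "positive"):
        raise ValueError(f"polarity must be negative|positive, got {polarity!r}")
    if trace.duration < 10 * decay_tau_guess:
        raise ValueError("trace shorter than 10x the decay time constant")

    rate = trace.rate
    sign = -1.0 if polarity == "negative" else 1.0
    b, a = signal.butter(4, lowpass_frac)
    yf = signal.filtfilt(b, a, trace.samples)
    d = _deconvolve_exp(sign * (yf - np.median(yf)), rate, decay_tau_guess)
    # deconvolution whitens the noise upward; a 1 ms boxcar restores the
    # event pulses (>= rise-time wide) above the amplified noise floor
    w = max(1, int(round(1e-3 * rate)))
    d = np.convolve(d, np.ones(w) / w, mode="same")

    mad = np.median(np.abs(d - np.median(d)))
    thresh = threshold_k * 1.4826 * mad
    peak = float(d.max())
    if peak <= 0:
        return []
    thresh = max(thresh, 1e-3 * peak)
    above = d > thresh
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1

    min_gap = int(round(min_interval * rate))
    onsets = []
    for i in crossings:
        if not onsets or i - onsets[-1] >= min_gap:
            onsets.append(int(i))

    events = []
    n = trace.n
    base_n = max(1, int(round(0.005 * rate)))
    for j, i0 in enumerate(onsets):
        i_end = onsets[j + 1] if j + 1 < len(onsets) else n
        i_end = min(i_end, i0 + max(min_gap, int(round(8 * decay_tau_guess * rate))))
        baseline = float(np.median(yf[max(0, i0 - base_n):max(1, i0)]))
        seg = yf[i0:i_end]
        if seg.size < 3:
            continue
        i_peak = i0 + int(np.argmax(sign * (seg - baseline)))
        amplitude = float(yf[i_peak] - baseline)
        rise = _rise_time(yf, i0, i_peak, baseline, rate, sign)
        tau_fit = None
        dec = yf[i_peak:i_end]
        if dec.size >= 4:
            try:
                t_rel = np.arange(dec.size) / rate
                _, tau_fit, _ = _fit_exponential(t_rel, dec, baseline)
            except (RuntimeError, ValueError):
                tau_fit = None
        events.append(EventRecord(
            onset_time=trace.t0 + i0 / rate, amplitude=amplitude,
            decay_tau=tau_fit, rise_time=rise, baseline=baseline))
    return events


def _rise_time(y, i0, i_peak, baseline, rate, sign):
    if i_peak <= i0:
        return None
    seg = sign * (y[i0:i_peak + 1] - baseline)
    peak = seg[-1]
    if peak <= 0:
        return None
    above10 = np.nonzero(seg >= 0.1 * peak)[0]
    above90 = np.nonzero(seg >= 0.9 * peak)[0]
    if len(above10) == 0 or len(above90) == 0:
        return None
    return float((above90[0] - above10[0]) / rate)


# ---------------------------------------------------------------------------
# charge transfer


def charge_transfer(trace: Trace, window, baseline_window) -> float:
    """Baseline-subtracted charge (coulombs) in a time window.

    Trapezoidal integral of (I - mean baseline current) over ``window``.
    """
    base = float(np.mean(trace.time_slice(*baseline_window).samples))
    seg = trace.time_slice(*window)
    return float(np.trapezoid(seg.samples - base, dx=1.0 / seg.rate))


# ---------------------------------------------------------------------------
# photostimulation map classification


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean rejections under the Benjamini-Hochberg step-up procedure."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order]
    crit = alpha * (np.arange(1, n + 1) / n)
    below = np.nonzero(ranked <= crit)[0]
    reject = np.zeros(n, dtype=bool)
    if len(below):
        reject[order[:below[-1] + 1]] = True
    return reject


def classify_map_sites(sites: list[MapSite], test_window: float,
                       baseline_window: float, alpha: float = 0.05,
                       metric: str = "count") -> list[MapSite]:
    """Flag photostimulation sites whose responses exceed spontaneous activity.

    The spontaneous event rate is pooled across all sites and trials,
    lambda = (total baseline events)/(total baseline time).  Each site's
    test-window event count is compared against a Poisson null with mean
    lambda x test_window x n_trials (upper-tail probability of at least the
    observed count); sites are flagged by Benjamini-Hochberg control of the
    false discovery rate at ``alpha``.
    """
    if not sites:
        raise ValueError("empty site list")
    if test_window <= 0 or baseline_window <= 0:
        raise ValueError("windows must be positive")
    total_base_time = sum(s.n_trials * baseline_window for s in sites)
    if total_base_time <= 0:
        raise ValueError("zero total baseline time")
    lam = sum(s.spontaneous_count for s in sites) / total_base_time

    pvals = np.empty(len(sites))
    for i, s in enumerate(sites):
        mu = lam * test_window * s.n_trials
        if mu == 0:
            pvals[i] = 0.0 if s.test_count > 0 else 1.0
        else:
            pvals[i] = stats.poisson.sf(s.test_count - 1, mu)
        s.p_value = float(pvals[i])
        if metric == "count":
            s.metric_value = float(s.test_count)
        elif metric == "mean_count":
            s.metric_value = s.test_count / s.n_trials
        # charge / decay-tau metrics need per-trial event records
        elif metric in ("charge", "decay_tau") and s.trials:
            vals = []
            for trial_events in s.trials:
                for ev in trial_events:
                    if metric == "charge" and ev.decay_tau:
                        vals.append(ev.amplitude * ev.decay_tau)
                    elif metric == "decay_tau" and ev.decay_tau:
                        vals.append(ev.decay_tau)
            s.metric_value = float(np.sum(vals)) if metric == "charge" else \
                (float(np.mean(vals)) if vals else None)
    flags = _benjamini_hochberg(pvals, alpha)
    for s, f in zip(sites, flags):
        s.evoked_flag = bool(f)
    return sites


_MAP_COLUMNS = ["x", "y", "n_trials", "spontaneous_count", "test_count",
                "p_value", "evoked", "metric_value"]


def _site_row(s: MapSite):
    return [s.position[0], s.position[1], s.n_trials, s.spontaneous_count,
            s.test_count, s.p_value, int(s.evoked_flag), s.metric_value]


def export_map_csv(sites: list[MapSite], path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MAP_COLUMNS)
        for s in sites:
            w.writerow(_site_row(s))


def export_map_sqlite(sites: list[MapSite], path, table: str = "map_sites"):
    con = sqlite3.connect(path)
    try:
        con.execute(f"DROP TABLE IF EXISTS {table}")
        con.execute(f"CREATE TABLE {table} ({', '.join(_MAP_COLUMNS)})")
        con.executemany(
            f"INSERT INTO {table} VALUES ({', '.join('?' * len(_MAP_COLUMNS))})",
            [_site_row(s) for s in sites])
        con.commit()
    finally:
        con.close()
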