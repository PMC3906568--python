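"""Imaging analyses: running-background subtraction, bleaching correction,
frame registration, ROI dF/F, event-triggered averages, mosaic composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from neurorig.rig import Transform3D
from neurorig.signals import Frame, FrameSeries, Trace

__all__ = [
    "ROI",
    "AlignmentAdjustment",
    "rolling_background_subtract",
    "bleach_correct",
    "register_frames",
    "roi_dff_series",
    "ratiometric_dff_series",
    "event_triggered_average",
    "compose_mosaic",
]


@dataclass
class ROI:
    """A rectangular or elliptic region of interest in global coordinates.

    ``bounds`` is (x0, y0, width, height) in meters; ``shape`` selects
    ``rectangle`` (the full bounds) or ``ellipse`` (inscribed).
    """

    bounds: tuple
    shape: str = "rectangle"
    label: str = ""

    def __post_init__(self):
        x0, y0, w, h = self.bounds
        if w <= 0 or h <= 0:
            raise ValueError("ROI must have nonzero area")
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")

    def mask(self, frame: Frame) -> np.ndarray:
        """Boolean pixel mask of this ROI in a frame, via its transform."""
        rows, cols = frame.pixels.shape
        cgrid, rgrid = np.meshgrid(np.arange(cols), np.arange(rows))
        pix = np.column_stack([cgrid.ravel(), rgrid.ravel(),
                               np.zeros(cgrid.size)])
        gpts = frame.transform.map(pix)
        x0, y0, w, h = self.bounds
        if self.shape == "rectangle":
            m = ((gpts[:, 0] >= x0) & (gpts[:, 0] < x0 + w)
                 & (gpts[:, 1] >= y0) & (gpts[:, 1] < y0 + h))
        else:
            cx, cy = x0 + w / 2, y0 + h / 2
            m = (((gpts[:, 0] - cx) / (w / 2)) ** 2
                 + ((gpts[:, 1] - cy) / (h / 2)) ** 2) <= 1.0
        return m.reshape(rows, cols)


@dataclass
class AlignmentAdjustment:
    """A manual alignment correction stored as metadata, never baked into data.

    The adjustment transform is composed on top of each target frame's
    original pixel-to-global transform at evaluation time; the original
    transforms are left untouched.
    """

    transform: Transform3D
    applies_to: set = field(default_factory=set)  # frame indices/ids

    def effective_transform(self, frame: Frame, frame_id) -> Transform3D:
        if frame_id in self.applies_to:
            return self.transform @ frame.transform
        return frame.transform


# ---------------------------------------------------------------------------
# continuous background subtraction


def rolling_background_subtract(frames: FrameSeries, time_constant: float) -> FrameSeries:
    """High-pass filter a video with an exponentially updating background.

    background_t = (1-alpha)·background_{t-1} + alpha·frame_t with
    alpha = dt/time_constant (clamped to 1); output_t = frame_t -
    background_{t-1}.  Static structure decays out of the output while fast
    fluorescence transients pass through.
    """
    if time_constant <= 0:
        raise ValueError("time constant must be positive")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = frames.times
    dts = np.diff(times)
    mean_dt = float(np.mean(dts))
    if mean_dt > 0 and np.any(np.abs(dts - mean_dt) > 0.1 * mean_dt):
        warnings.warn("non-uniform frame intervals; using per-frame alpha")
    out = []
    background = frames[0].pixels.astype(float)
    for i, f in enumerate(frames):
        diff = f.pixels - (background if i > 0 else frames[0].pixels)
        if i > 0:
            alpha = min(1.0, dts[i - 1] / time_constant) if dts[i - 1] > 0 else 1.0
            background = (1 - alpha) * background + alpha * f.pixels
        out.append(Frame(pixels=diff, transform=f.transform,
                         objective=f.objective, t_start=f.t_start,
                         exposure=f.exposure))
    return FrameSeries(out)


# ---------------------------------------------------------------------------
# bleaching correction


def bleach_correct(series: Trace):
    """Correct slow photobleaching in an ROI fluorescence time series.

    Fits F_hat(t) = A·exp(-t/tau_b) + C by least squares and rescales the
    series multiplicatively, corrected(t) = F(t)·F_hat(0)/F_hat(t), which
    flattens the baseline while preserving fractional (dF/F) transient
    amplitudes.  Returns ``(corrected Trace, fit_ok flag)``; on fit failure
    the series is returned unchanged with ``fit_ok=False``.
    """
    if series.n < 10:
        raise ValueError("need at least 10 samples to fit a bleach curve")
    t = series.times - series.t0
    y = series.samples
    c0 = float(y[-len(y) // 5:].mean())
    a0 = float(y[:max(1, len(y) // 10)].mean() - c0)
    if abs(a0) < 1e-12 * max(abs(c0), 1.0):
        return series.copy(), True  # already flat
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, A, tau, C: A * np.exp(-tt / tau) + C, t, y,
            p0=[a0, max(t[-1] / 3, 1e-6), c0], maxfev=5000)
        A, tau, C = popt
        fhat = A * np.exp(-t / tau) + C
        if np.any(fhat <= 0):
            raise RuntimeError("fitted bleach curve crosses zero")
    except (RuntimeError, ValueError):
        return series.copy(), False
    corrected = y * (fhat[0] / fhat)
    return Trace(corrected, series.rate, series.t0, series.units,
                 series.channel), True


# ---------------------------------------------------------------------------
# frame registration


def _xcorr_shift(img: np.ndarray, ref: np.ndarray):
    """Integer (dy, dx) maximizing the circular cross-correlation with ref."""
    a = img - img.mean()
    b = ref - ref.mean()
    corr = np.fft.irfft2(np.fft.rfft2(b).conj() * np.fft.rfft2(a),
                         s=img.shape)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    ny, nx = img.shape
    if iy > ny // 2:
        iy -= ny
    if ix > nx // 2:
        ix -= nx
    return -iy, -ix  # correction shift to align img onto ref


def register_frames(frames: FrameSeries, reference: str = "first"):
    """Estimate and correct integer-pixel translation between frames.

    The per-frame shift is the argmax of the 2D cross-correlation with the
    reference (``first`` frame or the ``mean`` image); frames are shifted
    back with zero padding.  Returns ``(shifts, registered FrameSeries)``
    where ``shifts[i] = (dx, dy)`` is the detected displacement of frame i
    relative to the reference.
    """
    if reference not in ("first", "mean"):
        raise ValueError("reference must be first|mean")
    stack = frames.stack()
    ref = stack[0] if reference == "first" else stack.mean(axis=0)
    if np.ptp(ref) == 0:
        warnings.warn("flat reference frame; registration returns zero shifts")
        return [(0, 0)] * len(frames), FrameSeries([f for f in frames])
    shifts, out = [], []
    for f in frames:
        if np.ptp(f.pixels) == 0:
            dy, dx = 0, 0
        else:
            dy, dx = _xcorr_shift(f.pixels, ref)
        shifts.append((-dx, -dy))  # displacement of the frame vs reference
        # apply the correction shift, zeroing the wrapped margin
        reg = np.roll(f.pixels, (dy, dx), axis=(0, 1))
        if dy > 0:
            reg[:dy, :] = 0
        elif dy < 0:
            reg[dy:, :] = 0
        if dx > 0:
            reg[:, :dx] = 0
        elif dx < 0:
            reg[:, dx:] = 0
        out.append(Frame(pixels=reg, transform=f.transform,
                         objective=f.objective, t_start=f.t_start,
                         exposure=f.exposure))
    return shifts, FrameSeries(out)


# ---------------------------------------------------------------------------
# ROI series


def roi_dff_series(frames: FrameSeries, roi: ROI, baseline_window) -> Trace:
    """Fractional fluorescence change (dF/F) of an ROI over a video.

    F(t) is the mean pixel value inside the ROI (mapped through each frame's
    transform); F0 is the mean of F over the baseline time window; the
    output is (F - F0)/F0 sampled at the (assumed uniform) frame rate.
    """
    times = frames.times
    f_vals = []
    for f in frames:
        m = roi.mask(f)
        if not m.any():
            raise ValueError(f"ROI {roi.label!r} does not intersect the frames")
        f_vals.append(float(f.pixels[m].mean()))
    f_vals = np.asarray(f_vals)
    b0, b1 = baseline_window
    in_base = (times >= b0) & (times < b1)
    if not in_base.any():
        raise ValueError("baseline window contains no frames")
    f0 = float(f_vals[in_base].mean())
    if f0 == 0:
        raise ValueError("baseline fluorescence is zero")
    dts = np.diff(times)
    rate = 1.0 / float(np.mean(dts)) if len(dts) else 1.0
    return Trace((f_vals - f0) / f0, rate, t0=float(times[0]),
                 units="dF/F", channel=roi.label)


def ratiometric_dff_series(frames_num: FrameSeries, frames_den: FrameSeries,
                           roi: ROI, baseline_window) -> Trace:
    """dF/F of the ratio of two simultaneously acquired channels.

    The per-frame ROI means of the two channels are divided elementwise
    before the fractional change is computed, cancelling signals common to
    both channels (illumination fluctuation, focal drift).
    """
    def roi_means(fr):
        vals = []
        for f in fr:
            m = roi.mask(f)
            if not m.any():
                raise ValueError("ROI does not intersect the frames")
            vals.append(float(f.pixels[m].mean()))
        return np.asarray(vals)

    num, den = roi_means(frames_num), roi_means(frames_den)
    if np.any(den == 0):
        raise ValueError("denominator channel contains zero ROI means")
    ratio = num / den
    times = frames_num.times
    b0, b1 = baseline_window
    in_base = (times >= b0) & (times < b1)
    if not in_base.any():
        raise ValueError("baseline window contains no frames")
    f0 = float(ratio[in_base].mean())
    if f0 == 0:
        raise ValueError("baseline ratio is zero")
    dts = np.diff(times)
    rate = 1.0 / float(np.mean(dts)) if len(dts) else 1.0
    return Trace((ratio - f0) / f0, rate, t0=float(times[0]),
                 units="dF/F", channel=roi.label)


# ---------------------------------------------------------------------------
# event-triggered average


def event_triggered_average(series: Trace, event_times, window):
    """Average of signal windows aligned on event times.

    ``window`` is (pre, post) in seconds around each event.  Events whose
    window falls partly outside the series are skipped.  Returns
    ``(averaged Trace with t0 = -pre, n_used)``.
    """
    pre, post = window
    n_pre = int(round(pre * series.rate))
    n_post = int(round(post * series.rate))
    segs = []
    for et in event_times:
        i = int(round((et - series.t0) * series.rate))
        if i - n_pre < 0 or i + n_post > series.n:
            continue
        segs.append(series.samples[i - n_pre:i + n_post])
    if not segs:
        raise ValueError("no events with a complete window inside the series")
    avg = np.mean(segs, axis=0)
    return (Trace(avg, series.rate, t0=-pre, units=series.units,
                  channel=series.channel),
            len(segs))


# ---------------------------------------------------------------------------
# mosaic composition


def compose_mosaic(frames: list[Frame], adjustments=None,
                   resolution: float = None, overlap: str = "last",
                   frame_ids=None):
    """Stitch positioned frames into one image in global coordinates.

    Each frame is placed through ``adjustment ∘ transform`` (adjustments are
    metadata; the frames' own transforms are not modified) and resampled
    nearest-neighbor onto an output grid spanning the union of footprints at
    ``resolution`` meters/pixel.  Overlaps resolve ``last`` (later frame on
    top) or ``mean``.  Returns ``(mosaic array, mosaic Transform3D)``.
    """
    if not frames:
        raise ValueError("empty frame list")
    if resolution is None or resolution <= 0:
        raise ValueError("resolution must be a positive pixel size in meters")
    if overlap not in ("last", "mean"):
        raise ValueError("overlap policy must be last|mean")
    adjustments = adjustments or []
    frame_ids = frame_ids if frame_ids is not None else list(range(len(frames)))

    def eff_transform(f, fid):
        t = f.transform
        for adj in adjustments:
            if fid in adj.applies_to:
                t = adj.transform @ t
        return t

    # global bounding box over frame corner points
    corners_g = []
    for f, fid in zip(frames, frame_ids):
        ny, nx = f.pixels.shape
        t = eff_transform(f, fid)
        cs = np.array([[-0.5, -0.5, 0], [nx - 0.5, -0.5, 0],
                       [-0.5, ny - 0.5, 0], [nx - 0.5, ny - 0.5, 0]])
        corners_g.append(t.map(cs))
    corners_g = np.vstack(corners_g)
    xmin, ymin = corners_g[:, 0].min(), corners_g[:, 1].min()
    xmax, ymax = corners_g[:, 0].max(), corners_g[:, 1].max()
    ncols = max(1, int(np.ceil((xmax - xmin) / resolution)))
    nrows = max(1, int(np.ceil((ymax - ymin) / resolution)))

    # mosaic pixel (c, r) center -> global (x, y)
    mosaic_t = Transform3D.from_parts(
        offset=(xmin + 0.5 * resolution, ymin + 0.5 * resolution, 0.0),
        scale=(resolution, resolution, 1.0))

    out = np.zeros((nrows, ncols))
    if overlap == "mean":
        acc = np.zeros((nrows, ncols))
        cnt = np.zeros((nrows, ncols))

    cgrid, rgrid = np.meshgrid(np.arange(ncols), np.arange(nrows))
    mos_pix = np.column_stack([cgrid.ravel(), rgrid.ravel(),
                               np.zeros(cgrid.size)])
    mos_global = mosaic_t.map(mos_pix)

    for f, fid in zip(frames, frame_ids):
        t = eff_transform(f, fid)
        src = t.inverse().map(mos_global)
        cs = np.rint(src[:, 0]).astype(int)
        rs = np.rint(src[:, 1]).astype(int)
        ny, nx = f.pixels.shape
        ok = (cs >= 0) & (cs < nx) & (rs >= 0) & (rs < ny)
        vals = f.pixels[rs[ok], cs[ok]]
        rr = rgrid.ravel()[ok]
        cc = cgrid.ravel()[ok]
        if overlap == "last":
            out[rr, cc] = vals
        else:
            acc[rr, cc] += vals
            cnt[rr, cc] += 1
    if overlap == "mean":
        nzero = cnt > 0
        out[nzero] = acc[nzero] / cnt[nzero]
    return out, mosaic_t
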