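"""Calcium event detection and event-shape metrics.

Event onsets are found as abrupt changes in the low-frequency spectral
power of the trace: a multitaper short-time power estimate (1-s windows,
50-ms steps) is averaged below 2 Hz, outliers in its first difference mark
candidate rises, and an iterative amplitude threshold — starting at 7 SDs
of the preceding 10 s of trace and relaxing by 40% per iteration while the
lookback grows by 75% — separates true events from noise.  Samples of
already-accepted events are excluded from the threshold window so closely
spaced events do not inflate the local SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal.windows import dpss

from .behavior import BoutSegmentation

FWHM_OK = "none"
FWHM_NEXT_EVENT = "next_event_overlap"
FWHM_MULTI_PEAK = "multi_peak"


@dataclass
class DetectorParams:
    power_band_hz: float = 2.0
    window_s: float = 1.0
    step_s: float = 0.05
    mad_k: float = 3.0
    sd0: float = 7.0  # iteration-1 amplitude threshold, in local SD units
    sd_decay: float = 0.40  # threshold shrinks by this fraction each iteration
    win0_s: float = 10.0  # iteration-1 lookback window
    win_growth: float = 0.75  # lookback grows by this fraction each iteration
    min_rise_samples: int = 3  # rise time > 150 ms at 20 Hz
    min_window_samples: int = 20  # usable lookback needed to test a candidate
    min_outlier_run: int = 3  # consecutive power-rise steps (= min rise time)
    base_win_s: float = 0.75  # pre-peak span searched for the event baseline

    def __post_init__(self) -> None:
        if min(self.power_band_hz, self.window_s, self.step_s, self.sd0,
               self.win0_s) <= 0:
            raise ValueError("detector parameters must be positive")
        if not (0 < self.sd_decay <= 1 and 0 < self.win_growth <= 1):
            raise ValueError("sd_decay and win_growth must lie in (0, 1]")


@dataclass
class CalciumEvent:
    t_on: int  # sample index of onset
    t_peak: int  # sample index of peak
    amplitude: float  # trace[t_peak] - trace[t_on]
    rise_time_s: float
    fwhm_s: float | None = None
    fwhm_excluded_reason: str = FWHM_OK
    t_fall: int | None = None  # end of fall (first return to onset level)


def lowfreq_power(
    trace: np.ndarray,
    fs: float = 20.0,
    params: DetectorParams | None = None,
    multitaper: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time power below ``power_band_hz``, and window-start indices.

    The trace is pre-smoothed with a 1-s moving average (for power
    estimation only), split into ``window_s`` windows advanced by
    ``step_s``, each window mean-removed and tapered (3 DPSS tapers of
    time-bandwidth 2, or a single boxcar when ``multitaper=False``), and
    the periodogram power is averaged over frequencies below the band
    limit.
    """
    p = params or DetectorParams()
    trace = np.asarray(trace, dtype=float)
    w = int(round(p.window_s * fs))
    if trace.size < w:
        raise ValueError("trace shorter than the spectrogram window")
    step = max(int(round(p.step_s * fs)), 1)
    smooth = uniform_filter1d(trace, size=max(int(round(1.0 * fs)), 1), mode="nearest")
    wins = np.lib.stride_tricks.sliding_window_view(smooth, w)[::step]
    wins = wins - wins.mean(axis=1, keepdims=True)
    if multitaper:
        tapers = dpss(w, NW=2, Kmax=3)
        tapers = tapers * np.sqrt(w)  # unit mean-square per taper
    else:
        tapers = np.ones((1, w))
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    band = freqs < p.power_band_hz
    spec = np.zeros(wins.shape[0])
    for tap in tapers:
        ft = np.fft.rfft(wins * tap, axis=1)
        spec += (np.abs(ft[:, band]) ** 2).mean(axis=1)
    spec /= tapers.shape[0] * w
    starts = np.arange(wins.shape[0]) * step
    return spec, starts


def mad_outliers(x: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean mask of samples more than ``k`` scaled MADs from the median.

    Uses the SD-consistent scaling 1.4826 * MAD.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    # absolute floor guards against flagging pure floating-point jitter
    # around an exactly constant series
    floor = 1e-9 * max(1.0, float(np.max(np.abs(x), initial=0.0)))
    return np.abs(x - med) > max(k * mad, floor)


def candidate_events(power: np.ndarray, mad_k: float = 3.0) -> list[tuple[int, int]]:
    """Groups of consecutive outlier samples in the power first-difference.

    Returns half-open ``[start, end)`` index ranges into ``diff(power)``;
    only positive power changes (rises) are kept as candidates.
    """
    power = np.asarray(power, dtype=float)
    if power.size < 2:
        raise ValueError("need at least 2 power samples")
    d = np.diff(power)
    out = mad_outliers(d, k=mad_k) & (d > 0)
    groups: list[tuple[int, int]] = []
    idx = np.flatnonzero(out)
    if idx.size == 0:
        return groups
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            groups.append((start, prev + 1))
            start = i
        prev = i
    groups.append((start, prev + 1))
    return groups


def _localize(trace: np.ndarray, smooth: np.ndarray, lo: int, hi: int,
              fs: float, base_win_s: float = 1.0) -> tuple[int, int] | None:
    """Find (t_on, t_peak) for a candidate region [lo, hi) of the trace.

    The peak is the maximum of the lightly smoothed trace in the region,
    extended forward while still rising; the onset is the last pre-peak
    sample at which the smoothed trace sits within 10% of event height
    above the minimum of the ``base_win_s`` seconds before the peak.  The
    baseline search is kept short so that noise-driven candidates are not
    credited with amplitude they accumulate over a long window.
    """
    n = trace.size
    lo = max(lo, 0)
    hi = min(hi, n)
    if hi - lo < 2:
        return None
    pk = lo + int(np.argmax(smooth[lo:hi]))
    # extend forward while still rising (peak may sit past the window)
    while pk + 1 < n and smooth[pk + 1] > smooth[pk]:
        pk += 1
    t_peak = pk
    pre_lo = max(t_peak - int(round(base_win_s * fs)), 0)
    if t_peak - pre_lo < 1:
        return None
    base_idx = pre_lo + int(np.argmin(smooth[pre_lo:t_peak]))
    base = smooth[base_idx]
    height = smooth[t_peak] - base
    if height <= 0:
        return None
    thresh = base + 0.1 * height
    below = np.flatnonzero(smooth[base_idx:t_peak] <= thresh)
    t_on = base_idx + (int(below[-1]) if below.size else 0)
    if t_on >= t_peak:
        return None
    return t_on, t_peak


def detect_events(
    trace: np.ndarray,
    fs: float = 20.0,
    params: DetectorParams | None = None,
    multitaper: bool = True,
) -> list[CalciumEvent]:
    """Detect calcium events in one normalized trace.

    Candidates come from :func:`candidate_events` on the low-frequency
    power; each is localized to an onset/peak on the raw trace; the
    iterative amplitude threshold then accepts candidates whose amplitude
    exceeds ``sd0 * (1 - sd_decay)^k`` times the SD of the non-event trace
    in the ``win0_s * (1 + win_growth)^k`` seconds before onset, with rise
    time of at least ``min_rise_samples``.  Iteration stops when nothing
    new is accepted.
    """
    p = params or DetectorParams()
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    power, starts = lowfreq_power(trace, fs=fs, params=p, multitaper=multitaper)
    groups = candidate_events(power, mad_k=p.mad_k)
    w = int(round(p.window_s * fs))
    step = max(int(round(p.step_s * fs)), 1)
    smooth = uniform_filter1d(trace, size=5, mode="nearest")

    candidates: dict[int, tuple[int, int]] = {}
    for g0, g1 in groups:
        if g1 - g0 < p.min_outlier_run:
            continue  # an event's rise spans several consecutive power steps
        # power sample k spans trace samples [k*step, k*step + w)
        lo = starts[g0]
        hi = min(starts[min(g1, starts.size - 1)] + 2 * w, n)
        loc = _localize(trace, smooth, lo, hi, fs, base_win_s=p.base_win_s)
        if loc is None:
            continue
        t_on, t_peak = loc
        candidates[t_peak] = (t_on, t_peak)  # dedupe by peak

    # merge candidates whose rising phases overlap, keeping the larger rise
    merged: list[tuple[int, int]] = []
    for on, pk in sorted(candidates.values()):
        if merged and on <= merged[-1][1]:
            prev_on, prev_pk = merged[-1]
            if trace[pk] - trace[on] > trace[prev_pk] - trace[prev_on]:
                merged[-1] = (on, pk)
        else:
            merged.append((on, pk))
    pending = [(on, pk) for on, pk in merged if pk - on >= p.min_rise_samples]
    accepted: list[CalciumEvent] = []
    removed = np.zeros(n, dtype=bool)
    k = 0
    max_iter = 200
    while pending and k < max_iter:
        factor = p.sd0 * (1.0 - p.sd_decay) ** k
        win = int(round(p.win0_s * (1.0 + p.win_growth) ** k * fs))
        newly: list[tuple[int, int]] = []
        for on, pk in pending:
            lo = max(on - win, 0)
            usable = ~removed[lo:on]
            if usable.sum() < p.min_window_samples:
                continue  # deferred: window grows next iteration
            # amplitude on the lightly smoothed trace against the median
            # of the pre-onset baseline: smoothing suppresses single-sample
            # noise peaks and the median baseline does not chase noise
            # dips, so noise-driven candidates get no spurious amplitude;
            # the threshold scale is a robust SD of the raw trace, immune
            # to not-yet-removed neighboring events
            win_vals = trace[lo:on][usable]
            sd = 1.4826 * np.median(np.abs(win_vals - np.median(win_vals)))
            if sd == 0:
                sd = win_vals.std()
            b0 = max(on - 15, 0)
            base = np.median(smooth[b0:on]) if on > b0 else smooth[on]
            amp = smooth[pk] - base
            if amp > factor * sd and amp > 0:
                newly.append((on, pk))
        if not newly:
            break
        for on, pk in newly:
            fall = _fall_end(trace, on, pk, n)
            removed[on : fall + 1] = True
            accepted.append(
                CalciumEvent(
                    t_on=on,
                    t_peak=pk,
                    amplitude=float(trace[pk] - trace[on]),
                    rise_time_s=(pk - on) / fs,
                    t_fall=fall,
                )
            )
        newset = set(newly)
        # candidates whose rise lies inside a removed event span are part
        # of that event, not separate events
        pending = [c for c in pending
                   if c not in newset and not (removed[c[0]] or removed[c[1]])]
        k += 1
    accepted.sort(key=lambda e: e.t_on)
    # clip falls at the next event's onset (used only for sample removal)
    for a, b in zip(accepted, accepted[1:]):
        if a.t_fall is not None and a.t_fall >= b.t_on:
            a.t_fall = b.t_on - 1
    return accepted


def _fall_end(trace: np.ndarray, t_on: int, t_peak: int, n: int) -> int:
    """First sample after the peak back at or below the onset level."""
    level = trace[t_on]
    idx = np.flatnonzero(trace[t_peak:] <= level)
    return int(t_peak + idx[0]) if idx.size else n - 1


def event_metrics(
    event: CalciumEvent,
    trace: np.ndarray,
    fs: float = 20.0,
    next_onset: int | None = None,
) -> CalciumEvent:
    """Fill in FWHM (seconds) or an exclusion reason for one event.

    FWHM is the time between the 50%-height crossings on the rise and the
    decay (linearly interpolated between samples).  The event is excluded
    when the next event's onset precedes the decay crossing, or when more
    than one local peak exceeds 75% of event height between the crossings.
    """
    trace = np.asarray(trace, dtype=float)
    on, pk = event.t_on, event.t_peak
    base = trace[on]
    height = trace[pk] - base
    half = base + 0.5 * height
    # rising crossing: last sample at/below half before the peak
    seg = trace[on : pk + 1]
    below = np.flatnonzero(seg <= half)
    i = on + (int(below[-1]) if below.size else 0)
    t_rise = i + (half - trace[i]) / (trace[i + 1] - trace[i]) if i + 1 <= pk and trace[i + 1] != trace[i] else float(i)
    # decay crossing: first sample at/below half after the peak
    after = np.flatnonzero(trace[pk:] <= half)
    if after.size == 0:
        event.fwhm_s = None
        event.fwhm_excluded_reason = FWHM_NEXT_EVENT
        return event
    j = pk + int(after[0])
    t_decay = (j - 1) + (trace[j - 1] - half) / (trace[j - 1] - trace[j]) if j > pk and trace[j - 1] != trace[j] else float(j)
    if next_onset is not None and next_onset < t_decay:
        event.fwhm_s = None
        event.fwhm_excluded_reason = FWHM_NEXT_EVENT
        return event
    # count local peaks above 75% height between the two crossings
    lo, hi = int(np.floor(t_rise)), int(np.ceil(t_decay)) + 1
    seg = trace[lo:hi]
    thresh75 = base + 0.75 * height
    peaks = 0
    for m in range(1, seg.size - 1):
        if seg[m] > thresh75 and seg[m] >= seg[m - 1] and seg[m] > seg[m + 1]:
            peaks += 1
    if seg.size and seg[np.argmax(seg)] > thresh75 and peaks == 0:
        peaks = 1  # peak at segment edge
    if peaks > 1:
        event.fwhm_s = None
        event.fwhm_excluded_reason = FWHM_MULTI_PEAK
        return event
    event.fwhm_s = (t_decay - t_rise) / fs
    event.fwhm_excluded_reason = FWHM_OK
    return event


def annotate_metrics(events: list[CalciumEvent], trace: np.ndarray,
                     fs: float = 20.0) -> list[CalciumEvent]:
    """Run :func:`event_metrics` over a sorted event list in place."""
    for k, ev in enumerate(events):
        nxt = events[k + 1].t_on if k + 1 < len(events) else None
        event_metrics(ev, trace, fs=fs, next_onset=nxt)
    return events


def event_rate(
    events: list[CalciumEvent],
    seg: BoutSegmentation | None = None,
    state: str = "session",
    n_samples: int | None = None,
    fs: float = 20.0,
) -> float:
    """Events per minute, optionally restricted to one behavioral state.

    State-conditioned rates count events whose onset falls inside bouts of
    the state and divide by the total time spent in that state.
    """
    if state == "session":
        if n_samples is None:
            if seg is None:
                raise ValueError("session rate needs n_samples or a segmentation")
            n_samples = seg.n_samples
        total_s = n_samples / fs
        count = len(events)
    else:
        if seg is None:
            raise ValueError("state-conditioned rate needs a segmentation")
        total_s = seg.state_time_s(state)
        if total_s <= 0:
            raise ValueError(f"zero time spent in state {state!r}")
        mask = seg.mask(state)
        count = sum(1 for ev in events if mask[ev.t_on])
    return count / total_s * 60.0
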