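"""Autonomic feature signals and event-locked summaries.

The five wristband feature signals are high- and low-frequency heart-rate
variability (band power of the cubic-spline-interpolated RR series in
0.15-0.4 Hz and 0.04-0.15 Hz), tonic and phasic skin conductance, and skin
temperature. Per stimulus-on event the mean amplitude and peak-to-peak of
each signal are extracted and averaged over a task's events.

Spectral HRV cannot be estimated from 1 s stimulus windows (the LF band
edge at 0.04 Hz alone needs tens of seconds of signal), so the HF/LF
"signal value" at time t is the band power of a symmetric window
(default 64 s) of the RR series centred on t. This windowing choice is
documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

logger = logging.getLogger("affectpipe.ans")

__all__ = [
    "HF_BAND",
    "LF_BAND",
    "ANS_SIGNALS",
    "interpolate_rr",
    "hrv_band_power",
    "decompose_gsr",
    "extract_event_ans_features",
]

HF_BAND = (0.15, 0.40)
LF_BAND = (0.04, 0.15)

ANS_SIGNALS = ("hf_hrv", "lf_hrv", "gsr_tonic", "gsr_phasic", "temperature")


def interpolate_rr(
    beat_times: np.ndarray, rr_ms: np.ndarray, rate: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline of (beat time, RR) on a uniform grid.

    The grid spans the observed beats only (no extrapolation). Returns
    (grid times s, RR ms).
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rr_ms = np.asarray(rr_ms, dtype=float)
    if len(beat_times) < 4:
        raise ValueError("need at least 4 beats for spline interpolation")
    if not np.all(np.diff(beat_times) > 0):
        raise ValueError("beat times must be strictly increasing")
    spline = CubicSpline(beat_times, rr_ms, bc_type="natural")
    t0 = np.ceil(beat_times[0] * rate) / rate
    t1 = np.floor(beat_times[-1] * rate) / rate
    grid = np.arange(t0, t1 + 0.5 / rate, 1.0 / rate)
    grid = grid[(grid >= beat_times[0]) & (grid <= beat_times[-1])]
    return grid, spline(grid)


def hrv_band_power(
    series: np.ndarray, band: tuple[float, float], rate: float = 4.0
) -> float:
    """Integrated PSD (ms^2) of a uniform RR series over [lo, hi).

    The series is linearly detrended; the spectrum is an averaged
    periodogram (Welch, Hann, 50% overlap, segment length min(n, 64 s)).
    Adjacent bands add exactly because the integral is a rectangle sum on
    half-open frequency intervals.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = band
    if hi > rate / 2.0 + 1e-12:
        raise ValueError(f"band edge {hi} Hz exceeds Nyquist {rate / 2.0} Hz")
    if len(series) < 64:
        raise ValueError("series too short for spectral estimation (need >= 64 samples)")
    nperseg = min(len(series), int(64 * rate))
    f, psd = signal.welch(
        signal.detrend(series), fs=rate, nperseg=nperseg, noverlap=nperseg // 2
    )
    df = f[1] - f[0]
    m = (f >= lo) & (f < hi)
    return float(psd[m].sum() * df)


def decompose_gsr(
    raw: np.ndarray, rate: float = 20.0, tonic_window_s: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split raw skin conductance into tonic baseline and phasic residual.

    The tonic component is a running median (window ``tonic_window_s``);
    the phasic component is the residual, so tonic + phasic reconstructs
    the input exactly. A simple documented stand-in for device-side
    decompositions.
    """
    raw = np.asarray(raw, dtype=float)
    k = int(tonic_window_s * rate) // 2 * 2 + 1
    tonic = signal.medfilt(raw, kernel_size=min(k, len(raw) // 2 * 2 - 1 if len(raw) > 2 else 1))
    return tonic, raw - tonic


def _window_stats(t: np.ndarray, x: np.ndarray, on: float, off: float):
    m = (t >= on) & (t < off)
    if not m.any():
        return None
    seg = x[m]
    return float(seg.mean()), float(seg.max() - seg.min())


def extract_event_ans_features(
    streams,
    events,
    task: str | None = None,
    *,
    hrv_window_s: float = 64.0,
    hrv_rate: float = 4.0,
) -> dict[str, float]:
    """Mean amplitude and peak-to-peak of each feature signal over a task's
    stimulus-on windows, averaged across events.

    ``streams`` is a ``synthetic.WristbandStreams``; ``events`` an
    ``EventTimeline`` or events frame (onset/duration/trial_type). When
    ``task`` is given only that trial_type's events are used. For HF/LF the
    per-event signal is the band power of the RR series in a
    ``hrv_window_s`` window sliding across the event; events whose windows
    contain no samples are skipped and logged.
    """
    ev = events.events if hasattr(events, "events") else events
    if task is not None:
        ev = ev[ev["trial_type"] == task]
    if ev.empty:
        raise ValueError(f"no events for task {task!r}")

    grid_t, rr = interpolate_rr(streams.beat_times, streams.rr_ms, rate=hrv_rate)
    half = hrv_window_s / 2.0

    per_event: dict[str, list[tuple[float, float]]] = {s: [] for s in ANS_SIGNALS}
    for _, e in ev.iterrows():
        on, off = float(e["onset"]), float(e["onset"] + e["duration"])
        # HF/LF: band power of the RR window centred on each in-event grid
        # time (clamped to the recording).
        centres = grid_t[(grid_t >= on) & (grid_t < off)]
        if len(centres) == 0:
            centres = np.array([(on + off) / 2.0])
        hf_vals, lf_vals = [], []
        for c in centres:
            m = (grid_t >= c - half) & (grid_t <= c + half)
            if m.sum() >= 64:
                seg = rr[m]
                hf_vals.append(hrv_band_power(seg, HF_BAND, hrv_rate))
                lf_vals.append(hrv_band_power(seg, LF_BAND, hrv_rate))
        if hf_vals:
            per_event["hf_hrv"].append(
                (float(np.mean(hf_vals)), float(np.max(hf_vals) - np.min(hf_vals)))
            )
            per_event["lf_hrv"].append(
                (float(np.mean(lf_vals)), float(np.max(lf_vals) - np.min(lf_vals)))
            )
        else:
            logger.info("event at %.1fs: RR window too short; HRV skipped", on)

        for name, (t, x) in {
            "gsr_tonic": (streams.gsr_time, streams.gsr_tonic),
            "gsr_phasic": (streams.gsr_time, streams.gsr_phasic),
            "temperature": (streams.temp_time, streams.temperature),
        }.items():
            stats = _window_stats(np.asarray(t), np.asarray(x), on, off)
            if stats is None:
                logger.info("event at %.1fs: no %s samples; skipped", on, name)
            else:
                per_event[name].append(stats)

    row: dict[str, float] = {}
    for name, vals in per_event.items():
        if not vals:
            logger.warning("no usable events for signal %s", name)
            continue
        arr = np.asarray(vals)
        row[f"{name}_mean"] = float(arr[:, 0].mean())
        row[f"{name}_p2p"] = float(arr[:, 1].mean())
    return row
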