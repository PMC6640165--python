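"""EEG preprocessing, artifact rejection, and event-locked features.

The processing chain mirrors a low-density (12-channel, 128 Hz) consumer
EEG workflow: zero-phase 0.1-60 Hz band-pass, bad-channel removal, ICA
eyeblink removal, average re-referencing, three-rule sliding-window
artifact masking, then per-event band-power RMS and complexity features
averaged into four scalp channel groups, with left/right alpha asymmetry
kept separate and the grouped features reduced by PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.special import gammaln
from sklearn.decomposition import PCA, FastICA

logger = logging.getLogger("affectpipe.eeg")

__all__ = [
    "BANDS",
    "DEFAULT_GROUPS",
    "DEFAULT_PAIRS",
    "SCALAR_FEATURES",
    "EEGRecording",
    "PCAResult",
    "detect_sync_events",
    "preprocess",
    "mark_artifacts",
    "band_rms",
    "hurst_rs",
    "petrosian_fd",
    "hjorth_params",
    "extract_event_features",
    "reduce_pca",
]

#: Analysis bands (Hz). Delta is used only for artifact envelopes.
BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 7.0), "alpha": (8.0, 15.0), "beta": (16.0, 31.0)}

DEFAULT_GROUPS = {
    "F": ["F7", "F8", "Fz"],
    "C": ["Cz", "C3", "C4"],
    "P": ["P3", "P4", "P7", "P8", "Pz"],
    "O": ["Oz"],
}

#: (left, right) homologous electrode pairs for alpha asymmetry.
DEFAULT_PAIRS = [("F7", "F8"), ("P3", "P4"), ("P7", "P8")]

#: Scalar features computed per channel group; 6 features x 4 groups = the
#: 24 variables entering PCA.
SCALAR_FEATURES = ("theta_rms", "alpha_rms", "beta_rms", "hurst", "petrosian_fd", "hjorth_fd")


@dataclass
class EEGRecording:
    """Multichannel EEG in uV with an optional photodiode sync channel."""

    data: np.ndarray               # (n_channels, n_samples)
    channels: list[str]
    sfreq: float = 128.0
    sync: np.ndarray | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples) matching channels")
        if self.sync is not None and len(self.sync) != self.data.shape[1]:
            raise ValueError("sync channel length must match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


# ---------------------------------------------------------------------------
# Sync events
# ---------------------------------------------------------------------------


def detect_sync_events(
    sync: np.ndarray, sampling_rate: float, threshold: float | None = None
) -> list[int]:
    """Locate pulse onsets on the photodiode sync channel.

    Each stimulus flashes one rectangular pulse; the onset is the sample at
    which |sync| first crosses the threshold (default: half the peak
    excursion). Returns strictly increasing sample indices; an empty list
    (with a warning) if no edge is found.
    """
    sync = np.asarray(sync, dtype=float)
    peak = np.abs(sync).max()
    if peak <= 0:
        logger.warning("sync channel contains no edges")
        return []
    thr = threshold if threshold is not None else peak / 2.0
    above = np.abs(sync) > thr
    if not above.any():
        logger.warning("sync channel contains no edges above threshold")
        return []
    starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    return [int(s) for s in starts]


# ---------------------------------------------------------------------------
# Filtering helpers
# ---------------------------------------------------------------------------


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    return signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")


def _filt(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    return signal.sosfiltfilt(_bandpass_sos(lo, hi, fs), x, axis=-1)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _find_blink_component(sources, mixing, channels, fs):
    """Index of the ICA component matching an eyeblink pattern, or None.

    A blink component loads dominantly on frontal channels (mean absolute
    mixing weight on F* channels > 1.2x the all-channel mean) and carries
    most (> 50%) of its power below 4 Hz.
    """
    frontal = [i for i, ch in enumerate(channels) if ch.upper().startswith("F")]
    if not frontal:
        return None, []
    report = []
    best, best_score = None, 0.0
    for j in range(sources.shape[1]):
        w = np.abs(mixing[:, j])
        frontal_ratio = w[frontal].mean() / (w.mean() + 1e-12)
        f, psd = signal.welch(sources[:, j], fs=fs, nperseg=min(len(sources), 512))
        total = psd.sum()
        low_frac = psd[f < 4.0].sum() / total if total > 0 else 0.0
        report.append((j, float(frontal_ratio), float(low_frac)))
        if frontal_ratio > 1.2 and low_frac > 0.5:
            score = frontal_ratio * low_frac
            if score > best_score:
                best, best_score = j, score
    return best, report


def preprocess(
    rec: EEGRecording,
    bad_channels: list[str] | tuple[str, ...] = (),
    *,
    l_freq: float = 0.1,
    h_freq: float = 60.0,
    remove_blinks: bool = True,
    random_state: int = 97,
) -> EEGRecording:
    """Band-pass, drop bad channels, remove the eyeblink component, re-reference.

    The blink component is found by spatial ICA (FastICA) using a
    frontal-dominant-loading + sub-4 Hz power criterion and removed before
    the average re-reference, so the cleaned output has an exactly zero
    channel mean at every sample. The criterion values and the removal (or
    its failure) are recorded in ``history``.
    """
    keep = [ch for ch in rec.channels if ch not in set(bad_channels)]
    if len(keep) < 4:
        raise ValueError(f"fewer than 4 good channels remain ({len(keep)})")
    idx = [rec.channels.index(ch) for ch in keep]
    data = _filt(rec.data[idx], l_freq, h_freq, rec.sfreq)
    history = list(rec.history)
    history.append(f"bandpass {l_freq}-{h_freq} Hz; kept {len(keep)} channels")

    if remove_blinks:
        try:
            import warnings

            ica = FastICA(
                n_components=len(keep), random_state=random_state, max_iter=2000, tol=1e-3
            )
            with warnings.catch_warnings():
                # partial convergence is fine for the blink criterion
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                sources = ica.fit_transform(data.T)
            j, report = _find_blink_component(sources, ica.mixing_, keep, rec.sfreq)
            if j is not None:
                fr, lf = next((r[1], r[2]) for r in report if r[0] == j)
                sources[:, j] = 0.0
                data = ica.inverse_transform(sources).T
                history.append(
                    f"removed blink ICA component {j} "
                    f"(frontal ratio {fr:.2f}, low-freq fraction {lf:.2f})"
                )
            else:
                history.append("no ICA component met the blink criterion")
        except Exception as exc:  # decomposition failure -> pass through
            logger.warning("ICA failed (%s); blink removal skipped", exc)
            history.append(f"ICA failed: {exc}; blink removal skipped")

    data = data - data.mean(axis=0, keepdims=True)
    history.append("average re-reference")
    return EEGRecording(data=data, channels=keep, sfreq=rec.sfreq, sync=rec.sync, history=history)


# ---------------------------------------------------------------------------
# Artifact masking
# ---------------------------------------------------------------------------


def mark_artifacts(
    rec: EEGRecording,
    *,
    abs_threshold: float = 400.0,
    p2p_threshold: float = 400.0,
    envelope_threshold: float = 40.0,
    window_s: float = 0.3,
) -> np.ndarray:
    """Boolean (n_channels, n_samples) mask of contaminated samples.

    A 0.3 s sliding window on a channel is marked if (1) any absolute
    sample value exceeds ``abs_threshold`` uV, (2) the window peak-to-peak
    amplitude exceeds ``p2p_threshold`` uV, or (3) the Hilbert envelope of
    any band-filtered copy (delta/theta/alpha/beta) exceeds
    ``envelope_threshold`` uV. The mask is the union over rules and bands.
    """
    w = max(int(round(window_s * rec.sfreq)), 1)
    n_ch, n = rec.data.shape
    mask = np.zeros((n_ch, n), dtype=bool)
    envelopes = []
    for lo, hi in BANDS.values():
        filt = _filt(rec.data, lo, hi, rec.sfreq)
        envelopes.append(np.abs(signal.hilbert(filt, axis=-1)))
    for ci in range(n_ch):
        x = rec.data[ci]
        viol = np.abs(x) > abs_threshold
        p2p = (
            ndimage.maximum_filter1d(x, size=w, mode="nearest")
            - ndimage.minimum_filter1d(x, size=w, mode="nearest")
        )
        viol |= p2p > p2p_threshold
        for env in envelopes:
            viol |= env[ci] > envelope_threshold
        # Mark every sample of any violating window.
        mask[ci] = ndimage.maximum_filter1d(viol.astype(np.uint8), size=w, mode="nearest") > 0
    return mask


# ---------------------------------------------------------------------------
# Scalar features
# ---------------------------------------------------------------------------


def band_rms(x: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """RMS amplitude of the band-filtered signal (a pure in-band sine of
    amplitude A gives A/sqrt(2))."""
    return float(np.sqrt(np.mean(_filt(np.asarray(x, float), band[0], band[1], fs) ** 2)))


def _expected_rs(m: int) -> float:
    """Small-sample expectation of the rescaled range of white noise
    (Anis-Lloyd with the Peters finite-sample factor)."""
    i = np.arange(1, m)
    s = np.sum(np.sqrt((m - i) / i))
    if m <= 340:
        g = np.exp(gammaln((m - 1) / 2.0) - gammaln(m / 2.0)) / np.sqrt(np.pi)
    else:
        g = 1.0 / np.sqrt(m * np.pi / 2.0)
    return (m - 0.5) / m * g * s


def hurst_rs(x: np.ndarray) -> float:
    """Hurst exponent by bias-corrected rescaled-range analysis.

    Averages R/S over non-overlapping blocks at dyadic block sizes and
    regresses log2(R/S) - log2(E[R/S]) on log2(size); the fitted slope is
    added to the white-noise value 0.5. Clipped to [0, 1]. Short windows
    (~1 s at 128 Hz) make this a coarse estimator; see the methods note.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 16:
        return 0.5
    sizes = [m for m in (8, 16, 32, 64, 128, 256, 512) if m <= n]
    log_rs, log_exp, log_m = [], [], []
    for m in sizes:
        rs_vals = []
        for start in range(0, n - m + 1, m):
            block = x[start : start + m]
            sd = block.std()
            if sd == 0:
                continue
            z = np.cumsum(block - block.mean())
            rs_vals.append((z.max() - z.min()) / sd)
        if rs_vals:
            log_rs.append(np.log2(np.mean(rs_vals)))
            log_exp.append(np.log2(_expected_rs(m)))
            log_m.append(np.log2(m))
    if len(log_m) < 2:
        return 0.5
    slope = np.polyfit(log_m, np.array(log_rs) - np.array(log_exp), 1)[0]
    return float(np.clip(0.5 + slope, 0.0, 1.0))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from the sign changes of the first
    difference."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = np.diff(x)
    n_delta = int(np.sum(d[1:] * d[:-1] < 0))
    if n_delta == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def hjorth_params(x: np.ndarray) -> tuple[float, float]:
    """Hjorth (mobility, complexity) of a window.

    Complexity -- the ratio of the mobility of the first difference to the
    mobility of the signal -- serves as the fractal-dimension-like
    complexity descriptor exposed as ``hjorth_fd``.
    """
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    var_x = np.var(x)
    if var_x == 0 or len(dx) < 2:
        return 0.0, 0.0
    mob = np.sqrt(np.var(dx) / var_x)
    var_dx = np.var(dx)
    ddx = np.diff(dx)
    mob_dx = np.sqrt(np.var(ddx) / var_dx) if var_dx > 0 else 0.0
    comp = mob_dx / mob if mob > 0 else 0.0
    return float(mob), float(comp)


# ---------------------------------------------------------------------------
# Event-locked feature extraction
# ---------------------------------------------------------------------------


def _event_windows(events, sfreq: float, n_samples: int) -> list[tuple[int, int]]:
    if hasattr(events, "events"):
        events = events.events
    wins = []
    for _, ev in events.iterrows():
        i0 = int(round(ev["onset"] * sfreq))
        i1 = int(round((ev["onset"] + ev["duration"]) * sfreq))
        if 0 <= i0 < i1 <= n_samples:
            wins.append((i0, i1))
    return wins


def extract_event_features(
    rec: EEGRecording,
    mask: np.ndarray,
    events,
    groups: dict[str, list[str]] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    *,
    max_masked_frac: float = 0.5,
) -> dict[str, float]:
    """Stimulus-locked features averaged over events and channel groups.

    For every event window and channel: theta/alpha/beta band RMS, Hurst
    exponent, Petrosian FD and the Hjorth complexity descriptor. Windows
    with more than ``max_masked_frac`` masked samples are dropped. Features
    are averaged over events, then over channels within group, yielding the
    ``{group}_{feature}`` scalars; ``asym_{L}_{R}`` is the mean over events
    of alpha RMS(right) - alpha RMS(left).
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    pairs = DEFAULT_PAIRS if pairs is None else pairs
    wins = _event_windows(events, rec.sfreq, rec.n_samples)
    if not wins:
        raise ValueError("no usable events within the recording")

    band_sig = {
        b: _filt(rec.data, *BANDS[b], rec.sfreq) for b in ("theta", "alpha", "beta")
    }

    # per channel: feature -> list of per-event values
    per_channel: dict[str, dict[str, list[float]]] = {
        ch: {f: [] for f in SCALAR_FEATURES} for ch in rec.channels
    }
    alpha_by_event: dict[str, list[float]] = {ch: [] for ch in rec.channels}

    for i0, i1 in wins:
        for ci, ch in enumerate(rec.channels):
            if mask[ci, i0:i1].mean() > max_masked_frac:
                alpha_by_event[ch].append(np.nan)
                continue
            seg = rec.data[ci, i0:i1]
            feats = per_channel[ch]
            for b in ("theta", "alpha", "beta"):
                feats[f"{b}_rms"].append(
                    float(np.sqrt(np.mean(band_sig[b][ci, i0:i1] ** 2)))
                )
            feats["hurst"].append(hurst_rs(seg))
            feats["petrosian_fd"].append(petrosian_fd(seg))
            feats["hjorth_fd"].append(hjorth_params(seg)[1])
            alpha_by_event[ch].append(feats["alpha_rms"][-1])

    row: dict[str, float] = {}
    for gname, chans in groups.items():
        chans = [ch for ch in chans if ch in rec.channels]
        for fname in SCALAR_FEATURES:
            vals = [
                np.mean(per_channel[ch][fname])
                for ch in chans
                if per_channel[ch][fname]
            ]
            if vals:
                row[f"{gname}_{fname}"] = float(np.mean(vals))
            else:
                logger.warning(
                    "group %s: all event windows masked; feature %s absent", gname, fname
                )
    for left, right in pairs:
        if left in rec.channels and right in rec.channels:
            lv = np.asarray(alpha_by_event[left], dtype=float)
            rv = np.asarray(alpha_by_event[right], dtype=float)
            ok = ~(np.isnan(lv) | np.isnan(rv))
            if ok.any():
                row[f"asym_{left}_{right}"] = float(np.mean(rv[ok] - lv[ok]))
    return row


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Component scores (participants x k), loadings (features x k,
    orthonormal columns), and explained-variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def reduce_pca(table: pd.DataFrame, k: int = 5) -> PCAResult:
    """Standardize columns and project onto the first k principal components.

    Fitted across participants (rows). If k exceeds what the data can
    support, fewer components are returned with a warning.
    """
    table = table.dropna()
    if len(table) < k + 1:
        raise ValueError(f"need at least {k + 1} complete rows, got {len(table)}")
    X = table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n_max = min(Z.shape)
    k_eff = min(k, n_max)
    if k_eff < k:
        logger.warning("requested %d components, data supports %d", k, k_eff)
    pca = PCA(n_components=k_eff, svd_solver="full")
    scores = pca.fit_transform(Z)
    comp_names = [f"PC{i + 1}" for i in range(k_eff)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=table.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
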