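"""Minute-wise HRV quantifiers: NPSD and LVM, plus the KS feature screen.

NPSD (normalized band-limited power spectral density) is the fraction of
the RR-tachogram's spectral power falling in the sympathetic
low-frequency band 0.04–0.12 Hz, which is elevated during apneic
episodes.  LVM (longest vertical line of the recurrence plot) measures
laminarity/intermittency of the reconstructed RR dynamics.  Both are
computed per minute, aligned with minute-wise apnea annotations, and the
two-sample Kolmogorov–Smirnov screen that selects discriminative
features between apneic and non-apneic minutes is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal, spatial, stats

from .errors import InsufficientDataError, OsaprogError
from .io_formats import APNEA, RRSeries

logger = logging.getLogger(__name__)

#: Apneic low-frequency band edges (Hz).
BAND_LO = 0.04
BAND_HI = 0.12
#: Band over which total spectral power is accumulated (Hz).
TOTAL_BAND = (0.003, 0.5)
#: Uniform resampling rate of the tachogram (Hz).
RESAMPLE_HZ = 4.0


@dataclass
class RecurrenceParams:
    """Parameters of the recurrence-plot computation.

    ``threshold_mode='fixed_recurrence_rate'`` solves for the distance
    threshold ε so the off-diagonal recurrence rate equals
    ``epsilon_or_rate``; ``'fixed_epsilon'`` uses the value directly.
    """

    embed_dim: int = 3
    delay: int = 1
    threshold_mode: str = "fixed_recurrence_rate"
    epsilon_or_rate: float = 0.10
    min_line: int = 2
    exclude_loi: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise OsaprogError("embed_dim must be >= 1")
        if self.threshold_mode not in ("fixed_epsilon", "fixed_recurrence_rate"):
            raise OsaprogError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed_recurrence_rate" and not (0 < self.epsilon_or_rate < 1):
            raise OsaprogError("recurrence rate must lie in (0, 1)")


@dataclass
class FeatureSeries:
    """Per-minute HRV feature vectors aligned to apnea annotations."""

    minutes: np.ndarray          # 0-based minute indices (may have gaps)
    npsd: np.ndarray             # fraction in [0, 1]
    lvm: np.ndarray              # integer line length (resampled-grid samples)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=int)
        self.npsd = np.asarray(self.npsd, dtype=float)
        self.lvm = np.asarray(self.lvm, dtype=float)
        if not (len(self.minutes) == len(self.npsd) == len(self.lvm)):
            raise OsaprogError("minutes/npsd/lvm lengths differ")
        if self.labels is not None and len(self.labels) != len(self.minutes):
            raise OsaprogError("labels length differs from minutes")
        if len(self.npsd) and (np.nanmin(self.npsd) < -1e-12 or np.nanmax(self.npsd) > 1 + 1e-12):
            raise OsaprogError("npsd outside [0, 1]")

    @property
    def feature_names(self) -> list[str]:
        return ["npsd", "lvm"]

    def matrix(self) -> np.ndarray:
        """(n_minutes, 2) array of [npsd, lvm]."""
        return np.column_stack([self.npsd, self.lvm])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"minute": self.minutes, "npsd": self.npsd, "lvm": self.lvm})
        df["label"] = self.labels if self.labels is not None else ""
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSeries":
        labels = list(df["label"]) if "label" in df and df["label"].astype(bool).all() else None
        return cls(df["minute"].to_numpy(), df["npsd"].to_numpy(),
                   df["lvm"].to_numpy(), labels)


def resample_tachogram(beat_times: np.ndarray, intervals_ms: np.ndarray,
                       fs: float = RESAMPLE_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of the RR tachogram onto a uniform grid.

    The tachogram value at the onset beat of each interval is the
    interval length; a cubic spline through those points is evaluated at
    ``fs`` Hz across the window's span.
    """
    t = np.asarray(beat_times[:-1], dtype=float)
    rr = np.asarray(intervals_ms, dtype=float)
    if len(t) < 4:
        raise InsufficientDataError("need >= 4 intervals to spline the tachogram")
    spline = interpolate.CubicSpline(t, rr)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return grid, spline(grid)


def compute_npsd(rr_window: RRSeries | tuple[np.ndarray, np.ndarray],
                 band_lo: float = BAND_LO, band_hi: float = BAND_HI,
                 total_band: tuple[float, float] = TOTAL_BAND,
                 fs: float = RESAMPLE_HZ) -> float:
    """Fraction of tachogram spectral power in ``[band_lo, band_hi]``.

    The window is spline-resampled to ``fs`` Hz, linearly detrended, and
    a Welch periodogram accumulated; the result is the in-band power
    divided by the power over ``total_band``, a unitless value in [0, 1].
    """
    if band_lo >= band_hi:
        raise OsaprogError("band_lo must be < band_hi")
    beat_times, intervals = _unpack_window(rr_window)
    if len(beat_times) < 10:
        raise InsufficientDataError(f"{len(beat_times)} beats < 10 in NPSD window")
    _, tach = resample_tachogram(beat_times, intervals, fs)
    tach = signal.detrend(tach, type="linear")
    if np.allclose(tach, 0.0, atol=1e-12):
        warnings.warn("constant tachogram window: zero total power, NPSD = 0",
                      stacklevel=2)
        return 0.0
    nperseg = min(len(tach), int(fs * 64))
    freqs, psd = signal.welch(tach, fs=fs, nperseg=nperseg, detrend="constant")
    total = _band_power(freqs, psd, *total_band)
    if total <= 0:
        warnings.warn("zero total power in NPSD window", stacklevel=2)
        return 0.0
    return float(np.clip(_band_power(freqs, psd, band_lo, band_hi) / total, 0.0, 1.0))


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Integrate the PSD over [lo, hi], interpolating at the band edges.

    Restricting the trapezoid to grid points inside the band would
    silently shrink any band whose edges fall between frequency bins.
    """
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def _unpack_window(rr_window) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(rr_window, RRSeries):
        return rr_window.beat_times, rr_window.intervals
    beat_times, intervals = rr_window
    return np.asarray(beat_times, float), np.asarray(intervals, float)


def recurrence_matrix(rr_window, params: RecurrenceParams) -> np.ndarray:
    """Binary recurrence matrix of a window after delay embedding.

    ``R[i, j] = 1`` iff the Euclidean distance between delay vectors i
    and j is ≤ ε.  In rate mode ε is the requested quantile of the
    off-diagonal distances, so the realized off-diagonal recurrence rate
    matches ``epsilon_or_rate``.  ``rr_window`` may be an
    :class:`~osaprog.io_formats.RRSeries` (or ``(beat_times, intervals)``
    pair), in which case the tachogram is resampled first, or a plain
    scalar sample array.
    """
    if isinstance(rr_window, (RRSeries, tuple)):
        beat_times, intervals = _unpack_window(rr_window)
        _, values = resample_tachogram(beat_times, intervals)
    else:
        values = rr_window
    values = np.asarray(values, dtype=float)
    emb = _delay_embed_scalar(values, params.embed_dim, params.delay)
    if len(emb) < 2:
        raise InsufficientDataError("window too short after embedding")
    dists = spatial.distance.squareform(spatial.distance.pdist(emb))
    if params.threshold_mode == "fixed_epsilon":
        eps = params.epsilon_or_rate
    else:
        off = dists[~np.eye(len(dists), dtype=bool)]
        if np.allclose(off, 0.0):
            warnings.warn("degenerate window (all states identical); ε = 0",
                          stacklevel=2)
            eps = 0.0
        else:
            eps = float(np.quantile(off, params.epsilon_or_rate))
    R = (dists <= eps).astype(np.uint8)
    if params.exclude_loi:
        np.fill_diagonal(R, 0)
    return R


def _delay_embed_scalar(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n < 1:
        return np.empty((0, dim))
    return np.column_stack([x[k * delay: k * delay + n] for k in range(dim)])


def longest_vertical_line(R: np.ndarray, min_line: int = 2,
                          exclude_loi: bool = True) -> int:
    """Length of the longest vertical run of 1s in the recurrence plot.

    Runs shorter than ``min_line`` are ignored (reported as 0 when no
    longer run exists); the line of identity is removed first when
    ``exclude_loi``.  Returns 0 for an empty plot.
    """
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise OsaprogError("R must be square")
    work = R.astype(np.int64).copy()
    if exclude_loi:
        np.fill_diagonal(work, 0)
    # vectorized per-column run lengths: pad with zero rows, diff the
    # positions of zeros in each column
    padded = np.zeros((work.shape[0] + 2, work.shape[1]), dtype=np.int64)
    padded[1:-1, :] = work
    best = 0
    for col in range(padded.shape[1]):
        zeros = np.nonzero(padded[:, col] == 0)[0]
        if len(zeros) > 1:
            best = max(best, int(np.max(np.diff(zeros)) - 1))
    return best if best >= min_line else 0


def extract_feature_series(series: RRSeries,
                           params: RecurrenceParams | None = None,
                           band_lo: float = BAND_LO, band_hi: float = BAND_HI,
                           min_beats: int = 10) -> FeatureSeries:
    """Per-minute NPSD and LVM over non-overlapping minute windows.

    Minutes with fewer than ``min_beats`` beats are omitted from the
    output (and logged); labels are copied from the series annotations.
    """
    if series.duration_min < 5:
        raise InsufficientDataError(
            f"{series.duration_min}-minute record too short (need >= 5)")
    params = params or RecurrenceParams()
    minutes, npsds, lvms, labels = [], [], [], []
    for m in range(series.duration_min):
        idx = series.beats_in_minute(m)
        if len(idx) < min_beats or idx[-1] + 1 >= series.n_beats:
            logger.info("minute %d skipped: %d beats", m, len(idx))
            continue
        bt = series.beat_times[np.append(idx, idx[-1] + 1)]
        rr = series.intervals[idx]
        try:
            npsd = compute_npsd((bt, rr), band_lo, band_hi)
            _, tach = resample_tachogram(bt, rr)
            R = recurrence_matrix(tach, params)
            lvm = longest_vertical_line(R, params.min_line, params.exclude_loi)
        except InsufficientDataError:
            logger.info("minute %d skipped: insufficient data for features", m)
            continue
        minutes.append(m)
        npsds.append(npsd)
        lvms.append(lvm)
        if series.annotations is not None:
            labels.append(series.annotations[m])
    return FeatureSeries(np.array(minutes, dtype=int), np.array(npsds),
                         np.array(lvms),
                         labels if series.annotations is not None else None)


def ks_feature_screen(features_by_label: dict[str, tuple[np.ndarray, np.ndarray]],
                      alpha: float = 0.01) -> tuple[list[str], dict[str, dict]]:
    """Two-sample Kolmogorov–Smirnov feature screen.

    Parameters
    ----------
    features_by_label
        Maps feature name → (apneic sample, non-apneic sample).
    alpha
        Selection level; a feature is kept iff its KS p-value < alpha.

    Returns
    -------
    (selected names, per-feature {'statistic', 'pvalue', 'selected'}).
    """
    selected, details = [], {}
    for name, (a, b) in features_by_label.items():
        a, b = np.asarray(a, float), np.asarray(b, float)
        if len(a) == 0 or len(b) == 0:
            raise InsufficientDataError(f"empty class for feature {name!r}")
        res = stats.ks_2samp(a, b, method="auto")
        keep = bool(res.pvalue < alpha)
        details[name] = {"statistic": float(res.statistic),
                         "pvalue": float(res.pvalue), "selected": keep}
        if keep:
            selected.append(name)
    return selected, details


def split_features_by_label(features: FeatureSeries) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Apneic/non-apneic samples per feature, ready for the KS screen."""
    if features.labels is None:
        raise OsaprogError("feature series carries no labels")
    is_ap = np.array([lab == APNEA for lab in features.labels])
    return {"npsd": (features.npsd[is_ap], features.npsd[~is_ap]),
            "lvm": (features.lvm[is_ap], features.lvm[~is_ap])}
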