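"""State-space reconstruction from the minute-wise feature series.

A multivariate delay embedding stacks lagged copies of each HRV feature
into one state vector per minute, x*_t = (NPSD_t, NPSD_{t−δ}, …,
LVM_t, LVM_{t−δ}, …).  The false-nearest-neighbors (FNN) test of
Kennel et al. estimates the smallest total dimension at which apparent
neighbors stop being projection artifacts; for the HRV features this is
around ten, i.e. five lags per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import InsufficientDataError, OsaprogError
from .hrv_features import FeatureSeries

#: default lags per feature: 5 lags × 2 features = 10-dimensional states
DEFAULT_LAGS = 5
DEFAULT_DELAY = 1


@dataclass
class EmbeddedStates:
    """Delay-coordinate state vectors with their minute timestamps."""

    vectors: np.ndarray           # (n, m)
    timestamps: np.ndarray        # minute index of the leading coordinate
    per_feature_lags: list[int]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, float))
        self.timestamps = np.asarray(self.timestamps, int)
        if len(self.vectors) != len(self.timestamps):
            raise OsaprogError("vectors/timestamps length mismatch")
        if np.any(np.diff(self.timestamps) <= 0):
            raise OsaprogError("timestamps must be strictly increasing")
        if self.total_dim != self.vectors.shape[1]:
            raise OsaprogError(
                f"dimension {self.vectors.shape[1]} != sum of lags {self.total_dim}")
        if self.labels is not None and len(self.labels) != len(self.vectors):
            raise OsaprogError("labels length mismatch")

    @property
    def total_dim(self) -> int:
        return int(sum(self.per_feature_lags))

    @property
    def n_states(self) -> int:
        return len(self.vectors)

    def successor_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_t, x_{t+1}) pairs for consecutive minutes only."""
        consec = np.diff(self.timestamps) == 1
        idx = np.nonzero(consec)[0]
        return self.vectors[idx], self.vectors[idx + 1]


def _contiguous_segments(minutes: np.ndarray) -> list[np.ndarray]:
    breaks = np.nonzero(np.diff(minutes) != 1)[0]
    return np.split(np.arange(len(minutes)), breaks + 1)


def delay_embed(features: FeatureSeries, lags_per_feature: int = DEFAULT_LAGS,
                delay: int = DEFAULT_DELAY) -> EmbeddedStates:
    """Multivariate delay embedding of the feature series.

    The vector at minute t stacks, per feature, the values at
    t, t−δ, …, t−(L−1)δ.  Gaps in the minute index split the series into
    segments embedded independently; each state is labeled with the
    annotation of its leading minute t.
    """
    span = (lags_per_feature - 1) * delay
    if len(features.minutes) < span + 1:
        raise InsufficientDataError(
            f"{len(features.minutes)} minutes < {span + 1} needed for embedding")
    F = features.matrix()
    vec_chunks, ts_chunks, lab_chunks = [], [], []
    for seg in _contiguous_segments(features.minutes):
        if len(seg) < span + 1:
            continue
        sub = F[seg]
        n = len(seg) - span
        cols = [sub[span - k * delay: span - k * delay + n, f]
                for f in range(F.shape[1]) for k in range(lags_per_feature)]
        vec_chunks.append(np.column_stack(cols))
        ts_chunks.append(features.minutes[seg][span:])
        if features.labels is not None:
            lab_chunks.extend(features.labels[i] for i in seg[span:])
    if not vec_chunks:
        raise InsufficientDataError("no segment long enough to embed")
    return EmbeddedStates(np.vstack(vec_chunks), np.concatenate(ts_chunks),
                          [lags_per_feature] * F.shape[1],
                          lab_chunks if features.labels is not None else None)


def _fnn_fraction(series: np.ndarray, lags: int, delay: int,
                  rtol: float, atol: float, theiler: int) -> float:
    """Kennel false-neighbor fraction going from ``lags`` to ``lags+1``.

    ``series`` is (n, k); the embedding with L lags per feature has
    dimension L·k.  A neighbor pair is false if the extra coordinates
    revealed at L+1 push it apart by more than ``rtol`` times its
    current distance, or beyond ``atol`` times the series' scale.
    """
    n_obs, k = series.shape
    span = lags * delay  # leading index of the first usable vector at L+1
    n = n_obs - span
    if n < 10:
        raise InsufficientDataError("series too short for FNN at this dimension")
    emb = np.column_stack([series[span - j * delay: span - j * delay + n, f]
                           for f in range(k) for j in range(lags)])
    extra = np.column_stack([series[0: n, f] for f in range(k)])  # lag L coords
    scale = float(np.sqrt(np.mean(np.sum((series - series.mean(0)) ** 2, axis=1))))
    nn = NearestNeighbors(n_neighbors=min(2 * theiler + 2, n)).fit(emb)
    dists, idxs = nn.kneighbors(emb)
    false = 0
    counted = 0
    for i in range(n):
        j = -1
        for cand, d in zip(idxs[i], dists[i]):
            if abs(int(cand) - i) > theiler:
                j, dist_m = int(cand), float(d)
                break
        if j < 0:
            continue
        gap = float(np.linalg.norm(extra[i] - extra[j]))
        counted += 1
        if dist_m <= 1e-12:
            if gap > atol * scale:
                false += 1
            continue
        dist_m1 = np.hypot(dist_m, gap)
        if gap / dist_m > rtol or dist_m1 / scale > atol:
            false += 1
    if counted == 0:
        raise InsufficientDataError("no valid neighbor pairs for FNN")
    return false / counted


def fnn_dimension(features: FeatureSeries | np.ndarray, max_dim: int = 20,
                  rtol: float = 15.0, atol: float = 2.0,
                  fnn_threshold: float = 0.01, delay: int = 1,
                  theiler: int = 1) -> int:
    """Smallest embedding dimension passing the false-nearest-neighbor test.

    Accepts a :class:`~osaprog.hrv_features.FeatureSeries` (dimension
    grows in steps of the feature count) or a univariate/multivariate
    sample array.  Returns the smallest total dimension at which the
    false-neighbor fraction drops below ``fnn_threshold``; if never
    reached, returns ``max_dim`` with a warning (typical for noise).
    """
    if isinstance(features, FeatureSeries):
        series = features.matrix()
    else:
        series = np.asarray(features, float)
        if series.ndim == 1:
            series = series[:, None]
    if len(series) < 50:
        raise InsufficientDataError("need >= 50 points for the FNN test")
    k = series.shape[1]
    lags = 1
    while lags * k <= max_dim:
        frac = _fnn_fraction(series, lags, delay, rtol, atol, theiler)
        if frac < fnn_threshold:
            return lags * k
        lags += 1
    warnings.warn(f"FNN fraction never fell below {fnn_threshold}; "
                  f"returning max_dim={max_dim}", stacklevel=2)
    return max_dim
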