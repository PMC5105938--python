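"""Quantized state-space transition graph.

The embedded HRV states are discretized into a lattice of 20 bins per
dimension; each occupied cell ("block") becomes a node of a directed
graph whose arc weights are one-step transition probabilities.  Blocks
are labeled apneic / non-apneic, yielding the absorbing-set structure
that the time-to-onset computation consumes, and a Laplacian-eigenmap
projection places strongly connected blocks nearby in a low-dimensional
coordinate system (V2, V3, V4).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.sparse import csgraph, csr_matrix

from .errors import ConfigurationError, InsufficientDataError, OsaprogError

APNEIC = "apneic"
NON_APNEIC = "non_apneic"


@dataclass
class BlockQuantizer:
    """Uniform lattice over the embedded state space.

    Each dimension's range [min, max] is split into ``bins_per_dim``
    equal bins, left-closed/right-open, with the last bin right-closed.
    A zero-range dimension collapses to a single bin.
    """

    mins: np.ndarray
    maxs: np.ndarray
    bins_per_dim: int

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, float)
        self.maxs = np.asarray(self.maxs, float)
        if self.bins_per_dim < 1:
            raise ConfigurationError("bins_per_dim must be >= 1")

    @property
    def widths(self) -> np.ndarray:
        span = self.maxs - self.mins
        return np.where(span > 0, span / self.bins_per_dim, 1.0)

    def assign(self, X: np.ndarray) -> np.ndarray:
        """(n, d) points → (n, d) integer lattice cell indices."""
        X = np.atleast_2d(np.asarray(X, float))
        idx = np.floor((X - self.mins) / self.widths).astype(int)
        degenerate = self.maxs - self.mins <= 0
        idx[:, degenerate] = 0
        return np.clip(idx, 0, self.bins_per_dim - 1)

    def cell_bounds(self, cell: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        cell_arr = np.asarray(cell)
        lo = self.mins + cell_arr * self.widths
        return lo, lo + self.widths

    def cell_center(self, cell: tuple[int, ...]) -> np.ndarray:
        lo, hi = self.cell_bounds(cell)
        return (lo + hi) / 2.0


def quantize(states: np.ndarray, bins_per_dim: int = 20
             ) -> tuple[list[tuple[int, ...]], np.ndarray, BlockQuantizer]:
    """Discretize states into occupied lattice cells.

    Returns ``(block_ids, block_of_state, quantizer)`` where
    ``block_ids`` lists the occupied cells in lexicographic order and
    ``block_of_state[t]`` is the row of ``block_ids`` holding state t.
    """
    X = np.atleast_2d(np.asarray(states, float))
    if len(X) < 2:
        raise InsufficientDataError("need >= 2 states to quantize")
    if not np.all(np.isfinite(X)):
        raise OsaprogError("non-finite state coordinates")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    if np.any(maxs - mins <= 0):
        warnings.warn("zero-range dimension collapsed to a single bin", stacklevel=2)
    q = BlockQuantizer(mins, maxs, bins_per_dim)
    cells = q.assign(X)
    block_ids = sorted({tuple(int(v) for v in c) for c in cells})
    index = {b: i for i, b in enumerate(block_ids)}
    block_of_state = np.array([index[tuple(int(v) for v in c)] for c in cells],
                              dtype=int)
    return block_ids, block_of_state, q


@dataclass
class BlockGraph:
    """Labeled block graph with a row-stochastic transition matrix.

    ``Q`` is the restriction of ``P`` to non-apneic rows/columns and
    ``r[j] = 1 − Σ_k Q[j, k]`` the one-step probability of entering the
    apneic set from non-apneic block j — the phase-type parameters of
    the time-to-onset distribution.
    """

    block_ids: list[tuple[int, ...]]
    labels: list[str]
    P: np.ndarray
    block_of_state: np.ndarray | None = None
    centroids: np.ndarray | None = None
    quantizer: BlockQuantizer | None = None
    mode: str = "empirical"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, float)
        n = len(self.block_ids)
        if self.P.shape != (n, n):
            raise OsaprogError(f"P shape {self.P.shape} != ({n}, {n})")
        if np.any(self.P < -1e-12):
            raise OsaprogError("negative transition probability")
        rows = self.P.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise OsaprogError("transition matrix rows must sum to 1")
        bad = set(self.labels) - {APNEIC, NON_APNEIC}
        if bad:
            raise OsaprogError(f"unknown block labels {bad}")

    @property
    def n_blocks(self) -> int:
        return len(self.block_ids)

    @property
    def apneic_mask(self) -> np.ndarray:
        return np.array([lab == APNEIC for lab in self.labels])

    @property
    def transient_indices(self) -> np.ndarray:
        """Indices of non-apneic blocks, in block order."""
        return np.nonzero(~self.apneic_mask)[0]

    @property
    def Q(self) -> np.ndarray:
        t = self.transient_indices
        return self.P[np.ix_(t, t)]

    @property
    def r(self) -> np.ndarray:
        return 1.0 - self.Q.sum(axis=1)

    def transient_position(self, block: int) -> int:
        """Row of ``Q`` corresponding to global block index ``block``."""
        pos = np.searchsorted(self.transient_indices, block)
        if pos >= len(self.transient_indices) or self.transient_indices[pos] != block:
            raise OsaprogError(f"block {block} is not non-apneic")
        return int(pos)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        i, j = np.nonzero(self.P)
        payload = {
            "version": 1,
            "mode": self.mode,
            "block_ids": [[int(v) for v in b] for b in self.block_ids],
            "labels": self.labels,
            "P_triplets": [[int(a), int(b), float(self.P[a, b])] for a, b in zip(i, j)],
            "centroids": None if self.centroids is None else self.centroids.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "BlockGraph":
        d = json.loads(text)
        n = len(d["block_ids"])
        P = np.zeros((n, n))
        for a, b, v in d["P_triplets"]:
            P[a, b] = v
        cents = None if d.get("centroids") is None else np.asarray(d["centroids"])
        return cls([tuple(b) for b in d["block_ids"]], list(d["labels"]), P,
                   centroids=cents, mode=d.get("mode", "empirical"))


def label_blocks(block_ids: list[tuple[int, ...]], block_of_state: np.ndarray,
                 states: np.ndarray, partition=None,
                 state_labels: list[str] | None = None,
                 mode: str = "partition") -> tuple[list[str], np.ndarray]:
    """Label each block apneic / non-apneic.

    ``mode='partition'`` classifies the block's member-state centroid
    with the trained SVM partition; ``mode='majority'`` takes the
    majority of the member states' annotations, ties resolved to
    non-apneic (conservative).  Returns ``(labels, centroids)``.
    """
    states = np.atleast_2d(np.asarray(states, float))
    centroids = np.vstack([states[block_of_state == b].mean(axis=0)
                           for b in range(len(block_ids))])
    if mode == "partition":
        if partition is None:
            raise OsaprogError("partition mode requires a trained partition")
        preds = partition.predict(centroids)
        labels = [APNEIC if p else NON_APNEIC for p in preds]
    elif mode == "majority":
        if state_labels is None:
            raise OsaprogError("majority mode requires per-state labels")
        from .io_formats import APNEA
        labels = []
        for b in range(len(block_ids)):
            members = np.nonzero(block_of_state == b)[0]
            n_ap = sum(state_labels[m] == APNEA for m in members)
            if 2 * n_ap == len(members):
                warnings.warn(f"annotation tie in block {b}: labeled non-apneic",
                              stacklevel=2)
            labels.append(APNEIC if 2 * n_ap > len(members) else NON_APNEIC)
    else:
        raise ConfigurationError(f"unknown labeling mode {mode!r}")
    return labels, centroids


def estimate_transitions(n_blocks: int, block_sequence: np.ndarray,
                         timestamps: np.ndarray | None = None,
                         dpmg=None, centroids: np.ndarray | None = None,
                         quantizer: BlockQuantizer | None = None,
                         block_ids: list[tuple[int, ...]] | None = None,
                         smoothing: float = 0.5,
                         mode: str = "empirical",
                         blend_weight: float = 1.0) -> np.ndarray:
    """Row-stochastic one-step transition matrix over blocks.

    ``mode='empirical'`` counts first-order transitions between
    consecutively visited blocks, adds ``smoothing`` pseudo-counts to
    each *observed* successor cell only (probability never leaks into
    unvisited space), and normalizes rows.  ``mode='dpmg'`` makes row i
    the DPMG one-step predictive Gaussian from block i's centroid
    integrated over each occupied cell (diagonal-covariance
    approximation), renormalized.  ``mode='blend'`` adds the DPMG row,
    scaled to ``blend_weight`` pseudo-observations, to the empirical
    counts — the observed successors anchor the jumps the data actually
    made while the DPMG predictive supplies dispersion where a single
    visit would otherwise make the chain deterministic.  Rows with no
    information become self-loops with a warning.
    """
    seq = np.asarray(block_sequence, int)
    if len(seq) < 2:
        raise InsufficientDataError("need >= 2 consecutive block visits")
    if mode not in ("empirical", "dpmg", "blend"):
        raise ConfigurationError(f"unknown transition mode {mode!r}")
    if mode in ("dpmg", "blend"):
        if dpmg is None or centroids is None or quantizer is None or block_ids is None:
            raise OsaprogError(f"{mode} mode needs dpmg, centroids, quantizer "
                               "and block_ids")
        P_pred = _dpmg_transitions(n_blocks, centroids, quantizer, block_ids, dpmg)
        if mode == "dpmg":
            return P_pred
    counts = np.zeros((n_blocks, n_blocks))
    if timestamps is None:
        timestamps = np.arange(len(seq))
    consecutive = np.diff(np.asarray(timestamps)) == 1
    for t in np.nonzero(consecutive)[0]:
        counts[seq[t], seq[t + 1]] += 1
    P = np.zeros_like(counts)
    for i in range(n_blocks):
        observed = counts[i] > 0
        row = counts[i].astype(float)
        if mode == "blend":
            row = row + blend_weight * P_pred[i]
        elif observed.any():
            row = row + smoothing * observed
        if row.sum() <= 0:
            warnings.warn(f"block {i} has no observed successor: self-loop",
                          stacklevel=2)
            P[i, i] = 1.0
            continue
        P[i] = row / row.sum()
    return P


def _dpmg_transitions(n_blocks, centroids, quantizer, block_ids, dpmg,
                      n_samples: int = 400) -> np.ndarray:
    """Propagate the DPMG predictive through the quantizer by sampling.

    For each block, samples from the full-covariance Gaussian predictive
    at the block centroid are quantized to their lattice cell; samples
    landing in unvisited cells are assigned to the nearest occupied
    block by centroid distance (exactly how a live query would be
    handled).  Row i is the resulting sample frequency over blocks.
    Sampling respects the predictive's cross-dimension correlations,
    which box-wise marginal integration would destroy.
    """
    cell_index = {tuple(int(v) for v in c): j for j, c in enumerate(block_ids)}
    P = np.zeros((n_blocks, n_blocks))
    rng = np.random.default_rng(getattr(dpmg, "seed", 0) + 12345)
    for i in range(n_blocks):
        mean, cov = dpmg.predict(centroids[i])
        cov = np.atleast_2d(cov)
        cov = (cov + cov.T) / 2.0 + 1e-12 * np.eye(len(mean))
        draws = rng.multivariate_normal(mean, cov, size=n_samples,
                                        method="cholesky")
        cells = quantizer.assign(draws)
        targets = np.empty(n_samples, dtype=int)
        miss = []
        for s_idx in range(n_samples):
            key = tuple(int(v) for v in cells[s_idx])
            j = cell_index.get(key, -1)
            targets[s_idx] = j
            if j < 0:
                miss.append(s_idx)
        if miss:
            d = np.linalg.norm(draws[miss][:, None, :] - centroids[None, :, :],
                               axis=2)
            targets[miss] = np.argmin(d, axis=1)
        np.add.at(P[i], targets, 1.0)
        P[i] /= n_samples
    return P


def build_block_graph(states: np.ndarray, timestamps: np.ndarray,
                      partition=None, state_labels: list[str] | None = None,
                      bins_per_dim: int = 20, dpmg=None,
                      smoothing: float = 0.5, mode: str | None = None,
                      blend_weight: float = 1.0,
                      label_mode: str = "partition") -> BlockGraph:
    """Quantize → label → estimate transitions, returning the full graph."""
    if mode is None:
        mode = "blend" if dpmg is not None else "empirical"
    block_ids, block_of_state, q = quantize(states, bins_per_dim)
    labels, centroids = label_blocks(block_ids, block_of_state, states,
                                     partition=partition,
                                     state_labels=state_labels, mode=label_mode)
    P = estimate_transitions(len(block_ids), block_of_state,
                             timestamps=timestamps, dpmg=dpmg,
                             centroids=centroids, quantizer=q,
                             block_ids=block_ids, smoothing=smoothing,
                             mode=mode, blend_weight=blend_weight)
    return BlockGraph(block_ids, labels, P, block_of_state=block_of_state,
                      centroids=centroids, quantizer=q, mode=mode)


@dataclass
class LaplacianProjection:
    """Low-dimensional block coordinates from the graph Laplacian."""

    coordinates: np.ndarray      # (n_blocks, n_coords), columns V2, V3, ...
    eigenvalues: np.ndarray      # ascending, including the leading zero(s)
    weights: np.ndarray          # symmetrized weight matrix used

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) < -1e-9):
            raise OsaprogError("eigenvalues must be non-decreasing")


def laplacian_project(graph: BlockGraph, n_coords: int = 3) -> LaplacianProjection:
    """Spectral embedding of the blocks via the normalized Laplacian.

    The directed transition matrix is symmetrized, W = (P + Pᵀ)/2, the
    symmetric normalized Laplacian formed, and eigenvectors 2..n_coords+1
    (ascending eigenvalues) returned as coordinates.  Signs are fixed by
    making each eigenvector's largest-magnitude entry positive.  On a
    disconnected graph the degenerate zero eigenspace is replaced by the
    canonical piecewise-constant basis, so every component receives
    constant, distinct coordinates; a warning is issued.
    """
    n = graph.n_blocks
    if n < n_coords + 1:
        warnings.warn(f"only {n} blocks: reducing n_coords to {n - 1}", stacklevel=2)
        n_coords = max(n - 1, 0)
    W = (graph.P + graph.P.T) / 2.0
    deg = W.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)
    d_isqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - (d_isqrt[:, None] * W) * d_isqrt[None, :]
    L = (L + L.T) / 2.0
    vals, vecs = sla.eigh(L)

    n_comp, comp = csgraph.connected_components(csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        warnings.warn(f"block graph has {n_comp} components; zero eigenspace "
                      "replaced by per-component indicators", stacklevel=2)
        basis = np.zeros((n, n_comp))
        for c in range(n_comp):
            mask = comp == c
            v = np.where(mask, np.sqrt(deg), 0.0)
            basis[:, c] = v / np.linalg.norm(v)
        # orthonormal basis whose first vector is the global D^{1/2}·1
        first = np.sqrt(deg) / np.linalg.norm(np.sqrt(deg))
        stacked = np.column_stack([first, basis])
        qmat, _ = np.linalg.qr(stacked)
        vecs[:, :n_comp] = qmat[:, :n_comp]
        vals[:n_comp] = 0.0

    coords = vecs[:, 1:1 + n_coords].copy()
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] *= -1
    return LaplacianProjection(coords, vals, W)
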