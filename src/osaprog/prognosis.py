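"""Distribution of time until the next apnea onset.

From the quantized block chain, the time T until first entry into the
apneic block set from a non-apneic start block is a discrete
phase-type (first-passage) random variable:

    Pr[T = t | start k] = e_kᵀ Q^{t−1} r ,   t = 1, 2, …

where Q is the transition matrix restricted to non-apneic blocks and
r_j = 1 − Σ_l Q[j, l] the one-step apneic-entry probability from block
j.  This closed form equals the concatenation of all transient paths of
length t−1 ending in an apneic entry, each weighted by the product of
its transition probabilities.  The risk indicator at t minutes is the
cumulative probability Pr[T ≤ t].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, OsaprogError
from .state_graph import APNEIC, BlockGraph

DEFAULT_HORIZON = 120


@dataclass
class OnsetDistribution:
    """Probability mass over minutes-to-onset from one start block.

    ``pmf[i]`` is Pr[T = i+1]; mass not absorbed within the horizon is
    reported separately.  Expectation and the discrete 95% CI are
    computed on the within-horizon mass renormalized to 1 (flagged when
    more than 5% of mass lies beyond the horizon); ``risk(t)`` is the
    raw (unrenormalized) cumulative probability Pr[T ≤ t].
    """

    pmf: np.ndarray
    start_block: int
    horizon: int
    onset_now: bool = False

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, float)
        if np.any(self.pmf < -1e-12):
            raise OsaprogError("negative probability mass")
        if self.pmf.sum() > 1 + 1e-9:
            raise OsaprogError("pmf mass exceeds 1")

    @property
    def mass_beyond_horizon(self) -> float:
        return float(max(0.0, 1.0 - self.pmf.sum())) if not self.onset_now else 0.0

    @property
    def truncation_flagged(self) -> bool:
        return self.mass_beyond_horizon > 0.05

    @property
    def expectation(self) -> float:
        """Expected minutes to onset (renormalized within horizon).

        ``inf`` when the apneic set is effectively unreachable
        (reported to users as "horizon+").
        """
        if self.onset_now:
            return 0.0
        total = self.pmf.sum()
        if total <= 1e-12:
            return float("inf")
        t = np.arange(1, len(self.pmf) + 1)
        return float((t * self.pmf).sum() / total)

    def _renorm_cdf(self) -> np.ndarray:
        total = self.pmf.sum()
        if total <= 1e-12:
            return np.zeros_like(self.pmf)
        return np.cumsum(self.pmf) / total

    @property
    def ci_low(self) -> int:
        return self._quantile(0.025)

    @property
    def ci_high(self) -> int:
        return self._quantile(0.975)

    def _quantile(self, q: float) -> int:
        if self.onset_now:
            return 0
        cdf = self._renorm_cdf()
        idx = np.searchsorted(cdf, q - 1e-12)
        return int(min(idx, len(cdf) - 1) + 1)

    def risk(self, t: int) -> float:
        """Pr[T ≤ t]: the likelihood of onset within ``t`` minutes."""
        if not (1 <= t <= self.horizon):
            raise OsaprogError(f"t={t} outside [1, horizon={self.horizon}]")
        if self.onset_now:
            return 1.0
        return float(self.pmf[:t].sum())


def time_to_onset_distribution(graph: BlockGraph, start_block: int,
                               horizon: int = DEFAULT_HORIZON) -> OnsetDistribution:
    """Phase-type first-passage distribution from ``start_block``.

    Computed iteratively as pmf(t) = vᵀ r with v ← vᵀQ, starting from
    the start block's indicator over non-apneic blocks.  An apneic start
    returns the degenerate "onset now" distribution; an unreachable
    apneic set returns (with a warning) a distribution whose mass lies
    entirely beyond the horizon.
    """
    if horizon < 1:
        raise OsaprogError("horizon must be >= 1")
    if graph.labels[start_block] == APNEIC:
        return OnsetDistribution(np.zeros(horizon), start_block, horizon,
                                 onset_now=True)
    Q, r = graph.Q, graph.r
    pos = graph.transient_position(start_block)
    v = np.zeros(len(r))
    v[pos] = 1.0
    pmf = np.empty(horizon)
    for t in range(horizon):
        pmf[t] = v @ r
        v = v @ Q
    dist = OnsetDistribution(pmf, start_block, horizon)
    if dist.mass_beyond_horizon > 0.999:
        warnings.warn(f"apneic set unreachable from block {start_block} "
                      "within the horizon", stacklevel=2)
    return dist


def risk_indicator(dist: OnsetDistribution, t: int) -> float:
    """Cumulative onset probability within ``t`` minutes (Pr[T ≤ t])."""
    return dist.risk(t)


def path_enumeration_pmf(graph: BlockGraph, start_block: int,
                         max_t: int) -> np.ndarray:
    """Time-to-onset pmf by explicit path concatenation (test oracle).

    Enumerates every sequence of non-apneic blocks k → l₁ → … → l_{t−1}
    and weights it by the product of its transient transition terms
    times the terminal apneic-entry probability — the nested-sum form of
    the first-passage law.  Exponential in ``max_t``; small fixtures only.
    """
    Q, r = graph.Q, graph.r
    n = len(r)
    pos = graph.transient_position(start_block)
    pmf = np.zeros(max_t)
    # paths of length t: t-1 transient hops then an apneic entry
    frontier = {(pos,): 1.0}
    for t in range(1, max_t + 1):
        pmf[t - 1] = sum(w * r[path[-1]] for path, w in frontier.items())
        new_frontier = {}
        for path, w in frontier.items():
            for nxt in range(n):
                if Q[path[-1], nxt] > 0:
                    new_frontier[path + (nxt,)] = w * Q[path[-1], nxt]
        frontier = new_frontier
    return pmf


def predict_from_state(x: np.ndarray, graph: BlockGraph,
                       horizon: int = DEFAULT_HORIZON) -> OnsetDistribution:
    """Time-to-onset distribution for a raw embedded state vector.

    The state is quantized into its lattice cell; if that cell was never
    visited during training, the nearest occupied block by centroid
    distance is used (ties broken toward the lexicographically smaller
    block index).  An apneic current block yields the degenerate
    "onset now" distribution.
    """
    x = np.asarray(x, float).ravel()
    if not np.all(np.isfinite(x)):
        raise OsaprogError("non-finite state vector")
    if graph.quantizer is None or graph.centroids is None:
        raise OsaprogError("graph lacks quantizer/centroids for state lookup")
    cell = tuple(graph.quantizer.assign(x[None, :])[0])
    try:
        block = graph.block_ids.index(cell)
    except ValueError:
        d = np.linalg.norm(graph.centroids - x, axis=1)
        best = np.min(d)
        candidates = np.nonzero(np.abs(d - best) <= 1e-12)[0]
        # candidates come in block_ids order, which is lexicographic
        block = int(candidates[0])
    return time_to_onset_distribution(graph, block, horizon)


@dataclass
class EvaluationReport:
    """Accuracy/calibration summary of a batch of onset predictions."""

    r2: float
    coverage: float
    n: int
    residuals_by_bin: dict[str, float]
    mean_risk_by_true_t: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"r2": self.r2, "coverage": self.coverage, "n": self.n,
                "residuals_by_bin": self.residuals_by_bin,
                "mean_risk_by_true_t": {str(k): v for k, v
                                        in self.mean_risk_by_true_t.items()}}


def evaluate_predictions(predicted: list[OnsetDistribution],
                         observed: np.ndarray) -> EvaluationReport:
    """R², CI coverage and binned residuals of onset predictions.

    ``observed`` holds the true minutes-to-onset per prediction.  R² is
    the coefficient of determination between predicted expectations and
    observations; coverage the fraction of observations inside the
    discrete 95% CI.  Residuals are binned by true horizon at 1–5 min
    and 5-minute increments to 40 min.
    """
    observed = np.asarray(observed, float)
    finite = np.isfinite(observed)
    if finite.sum() < 10:
        raise InsufficientDataError("need >= 10 finite evaluation points")
    preds = [p for p, ok in zip(predicted, finite) if ok]
    obs = observed[finite]
    exp = np.array([p.expectation for p in preds])
    usable = np.isfinite(exp)
    exp, obs = exp[usable], obs[usable]
    preds = [p for p, ok in zip(preds, usable) if ok]

    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        r2 = float("nan")
        warnings.warn("degenerate observed variance: R² undefined", stacklevel=2)
    else:
        r2 = 1.0 - float(np.sum((obs - exp) ** 2)) / ss_tot
    covered = np.array([p.ci_low <= o <= p.ci_high for p, o in zip(preds, obs)])
    coverage = float(covered.mean())

    bins = [(t, t) for t in range(1, 6)] + [(lo, lo + 4) for lo in range(5, 40, 5)]
    residuals = {}
    for lo, hi in bins:
        mask = (obs >= lo) & (obs <= hi)
        if mask.any():
            residuals[f"{lo}-{hi}"] = float(np.mean(np.abs(exp[mask] - obs[mask])))
    mean_risk = {}
    for t in range(1, 6):
        mask = obs == t
        if mask.any():
            mean_risk[t] = float(np.mean([p.risk(t) for p, ok
                                          in zip(preds, mask) if ok]))
    return EvaluationReport(r2, coverage, int(len(obs)), residuals, mean_risk)
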