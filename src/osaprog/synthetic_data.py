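"""Synthetic RR series and Markov fixtures with known ground truth.

The RR generator emulates the HRV signature of obstructive apnea that
the prognosis method relies on: during apneic minutes the heart rate
carries a cyclic variation inside the sympathetic low-frequency band
(0.04–0.12 Hz), which elevates the in-band spectral fraction (NPSD) and
reorganizes the recurrence structure of the minute, shifting the
longest-vertical-line (LVM) distribution away from that of non-apneic
minutes.  Non-apneic minutes carry only jitter plus weak broadband
modulation.
Minute-wise apnea labels follow a two-state Markov chain switching at
minute boundaries, so the ground-truth time to the next onset is known
exactly.

Markov block-graph fixtures with designated apneic (absorbing-set)
blocks provide analytically tractable first-passage distributions for
testing the time-to-onset computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .errors import ConfigurationError
from .io_formats import APNEA, NON_APNEA, RRSeries
from .state_graph import APNEIC, NON_APNEIC, BlockGraph


@dataclass
class SimulationConfig:
    """Conditions of the synthetic study.

    Defaults: a 400-minute night at mean RR 1000 ms; apneic minutes are
    modulated at 0.08 Hz with 60 ms depth over 5 ms of beat-to-beat
    jitter; the label chain enters apnea with probability 0.15 and exits
    with 0.30 per minute (stationary apnea fraction 1/3, mean bout
    ≈ 3.3 min — between the clinical databases' severities).
    """

    duration_min: int = 400
    mean_rr_ms: float = 1000.0
    apnea_modulation_freq_hz: float = 0.08
    apnea_modulation_depth_ms: float = 60.0
    background_noise_ms: float = 5.0
    p_enter: float = 0.15
    p_exit: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min < 5:
            raise ConfigurationError("duration_min must be >= 5 (too short to embed)")
        if not (0 < self.p_enter < 1 and 0 < self.p_exit < 1):
            raise ConfigurationError("p_enter and p_exit must lie in (0, 1)")
        if self.apnea_modulation_depth_ms < 0:
            raise ConfigurationError("modulation depth must be >= 0")

    @property
    def stationary_apnea_fraction(self) -> float:
        return self.p_enter / (self.p_enter + self.p_exit)


def generate_labels(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Minute labels from the 2-state chain, started at its stationary law."""
    labels = []
    state = APNEA if rng.random() < cfg.stationary_apnea_fraction else NON_APNEA
    for _ in range(cfg.duration_min):
        labels.append(state)
        if state == NON_APNEA:
            state = APNEA if rng.random() < cfg.p_enter else NON_APNEA
        else:
            state = NON_APNEA if rng.random() < cfg.p_exit else APNEA
    return labels


def generate_rr_series(cfg: SimulationConfig) -> RRSeries:
    """Seeded RR series with planted apneic spectral/laminar structure.

    Beat times accumulate interval by interval; each interval is the
    baseline plus, on apneic minutes, a sinusoid at the apneic
    modulation frequency, or, on non-apneic minutes, a weak smoothed
    broadband wander; white jitter is added throughout.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = generate_labels(cfg, rng)

    total_s = cfg.duration_min * 60.0
    # broadband wander for non-apneic minutes: smoothed white noise,
    # amplitude well below the apneic modulation depth
    n_grid = int(total_s) + 2
    wander = rng.normal(0.0, 1.0, n_grid)
    kernel = np.ones(3) / 3.0  # ~3 s smoothing: broadband relative to the LF band
    wander = np.convolve(wander, kernel, mode="same")
    wander *= (cfg.apnea_modulation_depth_ms / 8.0) / max(wander.std(), 1e-12)

    phase = rng.uniform(0, 2 * np.pi)
    beat_times = [0.0]
    t = 0.0
    while t < total_s:
        minute = min(int(t // 60.0), cfg.duration_min - 1)
        if labels[minute] == APNEA:
            mod = cfg.apnea_modulation_depth_ms * np.sin(
                2 * np.pi * cfg.apnea_modulation_freq_hz * t + phase)
        else:
            mod = wander[int(t)]
        rr_ms = cfg.mean_rr_ms + mod + rng.normal(0.0, cfg.background_noise_ms)
        rr_ms = max(rr_ms, 300.0)
        t += rr_ms / 1000.0
        beat_times.append(t)
    beat_arr = np.asarray(beat_times)
    return RRSeries(beat_arr, np.diff(beat_arr) * 1000.0,
                    record_id=f"synthetic-seed{cfg.seed}",
                    annotations=labels, duration_min=cfg.duration_min)


def minutes_to_onset(labels: list[str]) -> np.ndarray:
    """True minutes until the next apneic minute, per minute.

    Apneic minutes get 0; minutes with no later onset get -1.
    """
    n = len(labels)
    out = np.full(n, -1, dtype=int)
    next_onset = -1
    for m in range(n - 1, -1, -1):
        if labels[m] == APNEA:
            next_onset = m
            out[m] = 0
        elif next_onset >= 0:
            out[m] = next_onset - m
    return out


def generate_markov_fixture(n_blocks: int, n_apneic: int, seed: int = 0,
                            self_loop: float | None = None) -> BlockGraph:
    """Random block graph with known first-passage structure.

    Rows of the transition matrix are Dirichlet(1) draws; the last
    ``n_apneic`` blocks are apneic and absorbing (self-loop 1).
    Resampled until every non-apneic block can reach the apneic set.
    ``self_loop``, if given, forces a two-block geometric fixture: one
    transient block with the stated self-loop probability, the rest of
    its mass entering the apneic set (requires n_blocks=2, n_apneic=1).
    """
    if not (1 <= n_apneic < n_blocks):
        raise ConfigurationError(f"need 1 <= n_apneic < n_blocks, got "
                                 f"{n_apneic}, {n_blocks}")
    rng = np.random.default_rng(seed)
    if self_loop is not None:
        if (n_blocks, n_apneic) != (2, 1):
            raise ConfigurationError("self_loop fixture requires n_blocks=2, n_apneic=1")
        P = np.array([[self_loop, 1.0 - self_loop], [0.0, 1.0]])
        return BlockGraph([(0,), (1,)], [NON_APNEIC, APNEIC], P)
    apneic = set(range(n_blocks - n_apneic, n_blocks))
    for _ in range(1000):
        P = rng.dirichlet(np.ones(n_blocks), size=n_blocks)
        for a in apneic:
            P[a] = 0.0
            P[a, a] = 1.0
        if _apneic_set_reachable(P, apneic):
            labels = [APNEIC if i in apneic else NON_APNEIC for i in range(n_blocks)]
            return BlockGraph([(i,) for i in range(n_blocks)], labels, P)
    raise ConfigurationError("could not generate a fixture with reachable apneic set")


def _apneic_set_reachable(P: np.ndarray, apneic: set[int]) -> bool:
    """True iff every transient block has a directed path into the apneic set."""
    n = len(P)
    dist = csgraph.shortest_path(csr_matrix((P > 0).astype(float)),
                                 method="D", unweighted=True)
    for i in range(n):
        if i in apneic:
            continue
        if not any(np.isfinite(dist[i, a]) for a in apneic):
            return False
    return True


def simulate_chain(graph: BlockGraph, start: int, n_steps: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample a block trajectory of ``n_steps`` transitions from ``start``."""
    path = np.empty(n_steps + 1, dtype=int)
    path[0] = start
    for t in range(n_steps):
        path[t + 1] = rng.choice(graph.n_blocks, p=graph.P[path[t]])
    return path


def first_passage_samples(graph: BlockGraph, start: int, n_traj: int,
                          seed: int = 0, max_steps: int = 10_000) -> np.ndarray:
    """Monte-Carlo first-passage times into the apneic set (vectorized).

    Returns, per trajectory, the number of steps until first entry into
    an apneic block (``max_steps`` if never absorbed).
    """
    rng = np.random.default_rng(seed)
    apneic = graph.apneic_mask
    cum = np.cumsum(graph.P, axis=1)
    state = np.full(n_traj, start, dtype=int)
    hit = np.full(n_traj, max_steps, dtype=int)
    alive = np.ones(n_traj, dtype=bool)
    for step in range(1, max_steps + 1):
        if not alive.any():
            break
        alive_idx = np.nonzero(alive)[0]
        cur = state[alive_idx]
        nxt = np.empty(len(cur), dtype=int)
        for s in np.unique(cur):
            mask = cur == s
            draws = np.searchsorted(cum[s], rng.random(mask.sum()), side="right")
            nxt[mask] = np.minimum(draws, graph.n_blocks - 1)
        state[alive_idx] = nxt
        entered = apneic[nxt]
        hit[alive_idx[entered]] = step
        alive[alive_idx[entered]] = False
    return hit
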