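"""Synchronous cellular-automaton dynamics of excitation on a substrate.

State convention
----------------
Each cell carries an integer counter in [0, tau+1]:

* ``counter == tau + 1`` -- excited (depolarising, lasts exactly one step);
* ``counter in [1, tau]`` -- refractory;
* ``counter == 0``       -- resting (excitable).

An excitation therefore makes a cell unexcitable for tau + 1 consecutive
steps: the excited step itself followed by a refractory period of exactly
tau steps.  This convention makes the two-cable reentry motif sustain a
circuit precisely when the gap length satisfies ell >= tau/2, the same
cutoff the closed-form risk is built on (see docs/methods.md).

Update rule (fully synchronous; every neighbour read refers to the
pre-update state):

1. every cell with counter >= 1 decrements it by one;
2. every resting, non-ablated cell with at least one coupled excited
   neighbour becomes excited (counter <- tau+1); dysfunctional cells
   instead become excited with probability 1 - epsilon, one independent
   trial per cell per step regardless of how many neighbours are excited;
3. if t = 0 (mod T), every resting non-ablated pacemaker cell (column
   x = 0) becomes excited deterministically, bypassing epsilon.

Random draws are consumed in a fixed documented order: one uniform per
stimulated dysfunctional resting cell, row-major, per step.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .substrate import ModelConfig, Substrate

__all__ = [
    "TissueState",
    "EpisodeTrace",
    "ReentryTracker",
    "excited_value",
    "initialize_state",
    "step",
    "run",
    "apply_lesion",
]

#: spawn key of the dynamics random stream relative to the substrate seed
DYNAMICS_STREAM = 1


def excited_value(tau: int) -> int:
    """Counter value of an excited cell (tau refractory steps follow)."""
    return tau + 1


@dataclass
class TissueState:
    """Mutable per-cell excitation counters plus the simulation clock."""

    counters: np.ndarray
    t: int
    rng: np.random.Generator

    @property
    def shape(self) -> tuple[int, int]:
        return self.counters.shape

    def copy(self) -> "TissueState":
        return TissueState(self.counters.copy(), self.t, copy.deepcopy(self.rng))


@dataclass
class EpisodeTrace:
    """Record of one simulation episode.

    ``n_excited[i]`` is the number of excited cells after step i+1 of the
    episode (length equals the number of steps run).  ``events`` is a list
    of ``(t, kind, payload)`` tuples for pacing firings and reentry
    detections.  ``snapshots`` maps selected times t to dense counter
    grids.  ``final_state`` allows a run to be continued.
    """

    n_excited: np.ndarray
    events: list
    snapshots: dict
    config: ModelConfig
    final_state: Optional[TissueState] = None


def initialize_state(substrate: Substrate) -> TissueState:
    """All-resting state at t = 0 with a reproducible random stream.

    The stream is derived from the substrate seed on a separate spawn key,
    so it never collides with the substrate-generation stream nor with the
    streams of neighbouring realisation seeds.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=substrate.seed, spawn_key=(DYNAMICS_STREAM,))
    )
    counters = np.zeros(substrate.shape, dtype=np.int16)
    return TissueState(counters=counters, t=0, rng=rng)


class ReentryTracker:
    """Label-propagation detector of reentrant activation.

    Every excitation wave carries the label of the pacemaker beat that
    started it (labels >= 1; waves of unknown origin, e.g. from a prepared
    initial state, carry label 0).  Labels propagate with the excitation.
    A reentry is flagged when a cell is re-excited by a wave carrying the
    same label as the cell's own previous excitation within one pacing
    interval: no pacemaker firing can have reached the cell in between, so
    the excitation must have travelled a closed path back to it.
    """

    UNKNOWN = 0

    def __init__(self, shape: tuple[int, int], T: int):
        self.T = int(T)
        self.labels = np.full(shape, -1, dtype=np.int64)
        self.last_t = np.full(shape, np.iinfo(np.int64).min // 2, dtype=np.int64)
        self.beat = 0
        self.first_detection: Optional[tuple[int, tuple[int, int]]] = None
        self.detections: list[tuple[int, tuple[int, int]]] = []

    def observe(
        self,
        excited_prev: np.ndarray,
        fire: np.ndarray,
        paced: np.ndarray,
        pacing_step: bool,
        edges: np.ndarray,
        edges_up: np.ndarray,
        t_new: int,
    ) -> int:
        """Ingest one synchronous update; returns #reentrant excitations."""
        lab = np.where(excited_prev, self.labels, -1)
        cand = np.full(lab.shape, -1, dtype=np.int64)
        np.maximum(cand[:, 1:], lab[:, :-1], out=cand[:, 1:])
        np.maximum(cand[:, :-1], lab[:, 1:], out=cand[:, :-1])
        np.maximum(cand, np.where(edges, np.roll(lab, -1, axis=0), -1), out=cand)
        np.maximum(cand, np.where(edges_up, np.roll(lab, 1, axis=0), -1), out=cand)
        if pacing_step:
            self.beat += 1
        reent = fire & ~paced & (cand >= 0) & (cand == self.labels)
        reent &= (t_new - self.last_t) <= self.T
        n = int(reent.sum())
        if n:
            ys, xs = np.nonzero(reent)
            cell = (int(ys[0]), int(xs[0]))
            if self.first_detection is None:
                self.first_detection = (t_new, cell)
            self.detections.append((t_new, cell))
        src = np.where(cand >= 0, cand, self.UNKNOWN)
        src = np.where(paced, self.beat, src)
        self.labels[fire] = src[fire]
        self.last_t[fire] = t_new
        return n


def _advance(
    counters: np.ndarray,
    t: int,
    rng: np.random.Generator,
    substrate: Substrate,
    pace: bool,
    tracker: Optional[ReentryTracker],
    edges_up: np.ndarray,
) -> int:
    """One in-place synchronous update; returns the new time t+1."""
    cfg = substrate.config
    exc = cfg.tau + 1
    edges = substrate.vertical_edges
    excited = counters == exc
    resting = counters == 0

    stim = np.zeros(counters.shape, dtype=bool)
    stim[:, 1:] |= excited[:, :-1]
    stim[:, :-1] |= excited[:, 1:]
    stim |= np.roll(excited, -1, axis=0) & edges
    stim |= np.roll(excited, 1, axis=0) & edges_up

    fire = stim & resting & ~substrate.ablated
    trials = fire & substrate.dysfunctional
    k = int(trials.sum())
    if k and cfg.epsilon > 0.0:
        failed = rng.random(k) < cfg.epsilon
        if failed.any():
            idx = np.flatnonzero(trials.ravel())
            fire.ravel()[idx[failed]] = False
    elif k:
        rng.random(k)  # keep the draw schedule independent of epsilon

    np.subtract(counters, 1, out=counters, where=counters > 0)
    counters[fire] = exc

    pacing_step = pace and (t % cfg.T == 0)
    paced = np.zeros(counters.shape, dtype=bool)
    if pacing_step:
        paced[:, 0] = resting[:, 0] & ~substrate.ablated[:, 0]
        counters[paced] = exc
        fire = fire | paced

    if tracker is not None:
        tracker.observe(excited, fire, paced, pacing_step, edges, edges_up, t + 1)
    return t + 1


def step(state: TissueState, substrate: Substrate, pace: bool = True) -> TissueState:
    """Apply one synchronous update, returning a new state."""
    if state.shape != substrate.shape:
        raise ValueError(
            f"state shape {state.shape} does not match substrate shape {substrate.shape}"
        )
    new = state.copy()
    edges_up = np.roll(substrate.vertical_edges, 1, axis=0)
    new.t = _advance(new.counters, new.t, new.rng, substrate, pace, None, edges_up)
    return new


def run(
    substrate: Substrate,
    n_steps: int,
    record_snapshots: Optional[Iterable[int] | str] = None,
    *,
    pace: bool = True,
    detect_reentry: bool = False,
    stop_on_reentry: bool = False,
    initial_state: Optional[TissueState] = None,
    tracker: Optional[ReentryTracker] = None,
) -> EpisodeTrace:
    """Run the automaton for ``n_steps`` from a fresh (or given) state.

    Parameters
    ----------
    record_snapshots
        ``None``, the string ``"all"``, or an iterable of times t at which
        to store dense counter grids.
    detect_reentry
        Attach a :class:`ReentryTracker`; detections appear as events
        ``(t, "reentry", (n_cells, (y, x)))``.
    stop_on_reentry
        Stop the episode at the step of the first reentry detection (the
        trace then holds exactly the steps run).
    initial_state
        Continue from a copy of this state instead of all-resting; the
        caller's state is not mutated.

    With a fixed seed the trace is bit-identical across runs.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    state = initial_state.copy() if initial_state is not None else initialize_state(substrate)
    if state.shape != substrate.shape:
        raise ValueError(
            f"state shape {state.shape} does not match substrate shape {substrate.shape}"
        )
    snap_all = record_snapshots == "all"
    snap_at = set() if (record_snapshots is None or snap_all) else set(record_snapshots)
    if detect_reentry and tracker is None:
        tracker = ReentryTracker(substrate.shape, substrate.config.T)

    exc = substrate.config.tau + 1
    edges_up = np.roll(substrate.vertical_edges, 1, axis=0)
    counters, rng = state.counters, state.rng
    n_excited = np.zeros(n_steps, dtype=np.int64)
    events: list = []
    snapshots: dict = {}
    if snap_all:
        snapshots[state.t] = counters.copy()

    steps_done = 0
    for i in range(n_steps):
        pacing_step = pace and (state.t % substrate.config.T == 0)
        n_det_before = len(tracker.detections) if tracker is not None else 0
        state.t = _advance(counters, state.t, rng, substrate, pace, tracker, edges_up)
        n_excited[i] = int((counters == exc).sum())
        steps_done = i + 1
        if pacing_step:
            events.append((state.t, "pacing", None))
        if tracker is not None and len(tracker.detections) > n_det_before:
            new_dets = tracker.detections[n_det_before:]
            events.append((state.t, "reentry", (len(new_dets), new_dets[0][1])))
        if snap_all or state.t in snap_at:
            snapshots[state.t] = counters.copy()
        if stop_on_reentry and tracker is not None and tracker.first_detection is not None:
            break

    trace = EpisodeTrace(
        n_excited=n_excited[:steps_done],
        events=events,
        snapshots=snapshots,
        config=substrate.config,
        final_state=state,
    )
    return trace


def apply_lesion(
    substrate: Substrate, x0: int, y0: int, width: int, height: int
) -> Substrate:
    """Render a rectangle of tissue permanently unexcitable.

    The rectangle spans ``width`` columns from x0 (must fit within the
    open horizontal boundaries) and ``height`` rows from y0, wrapping
    periodically in y.  Returns a modified copy; the input substrate is
    unchanged.
    """
    if width < 1 or height < 1:
        raise ValueError(f"lesion width and height must be >= 1, got {width}x{height}")
    R, C = substrate.shape
    if not (0 <= x0 and x0 + width <= C):
        raise ValueError(
            f"lesion columns [{x0}, {x0 + width}) out of bounds for {C} columns"
        )
    if height > R:
        raise ValueError(f"lesion height {height} exceeds {R} rows")
    rows = (y0 + np.arange(height)) % R
    ablated = substrate.ablated.copy()
    ablated[np.ix_(rows, np.arange(x0, x0 + width))] = True
    return substrate.with_ablated(ablated)
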