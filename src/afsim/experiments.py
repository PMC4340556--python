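"""Computational experiments: AF classification, phase diagram, ablation.

The fraction of time a system spends displaying nonplanar (fibrillatory)
activity is measured from the excited-cell count: a single planar front
excites at most one cell per row per step, so sustained counts above the
row count indicate multiple simultaneous wavefronts.  Dysfunctional-cell
conduction lags can transiently push the count a few cells above the row
count even during planar rhythm, so the experiments classify a step as
fibrillatory when n_excited exceeds 1.1x the row count by default (the
factor is configurable; :func:`af_activity` itself defaults to the strict
factor 1.0).  A label-propagation reentry detector provides a second,
threshold-free criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    EpisodeTrace,
    ReentryTracker,
    apply_lesion,
    initialize_state,
    run,
)
from .scan import CriticalRegion, find_critical_regions
from .substrate import ModelConfig, Substrate, generate_substrate

__all__ = [
    "SweepResult",
    "AblationReport",
    "af_activity",
    "time_in_af",
    "reentry_detector",
    "phase_sweep",
    "ablation_experiment",
    "DEFAULT_AF_FACTOR",
]

#: threshold factor used by the experiments (tolerates conduction-lag blips)
DEFAULT_AF_FACTOR = 1.1


def af_activity(
    trace: EpisodeTrace, L: int, threshold_factor: float = 1.0
) -> np.ndarray:
    """Boolean series: step t is fibrillatory iff n_excited[t] > factor*L."""
    if len(trace.n_excited) == 0:
        raise ValueError("trace is empty")
    return trace.n_excited > threshold_factor * L


def time_in_af(
    trace: EpisodeTrace, L: int, threshold_factor: float = DEFAULT_AF_FACTOR
) -> float:
    """Fraction of the episode spent in fibrillatory activity."""
    return float(af_activity(trace, L, threshold_factor).mean())


def reentry_detector(
    trace: EpisodeTrace, substrate: Substrate, T: Optional[int] = None
) -> Optional[int]:
    """First time at which some cell is re-excited within one pacing
    interval without an intervening pacemaker firing reaching it.

    Requires dense snapshots over consecutive steps (``record_snapshots=
    "all"``); returns ``None`` when no reentry occurs in the inspected
    window.
    """
    if T is None:
        T = trace.config.T
    times = sorted(trace.snapshots)
    if len(times) < 2:
        raise ValueError("reentry detection requires >= 2 consecutive snapshots")
    if any(b - a != 1 for a, b in zip(times, times[1:])):
        raise ValueError("snapshots must cover consecutive steps")
    exc = trace.config.tau + 1
    edges = substrate.vertical_edges
    edges_up = np.roll(edges, 1, axis=0)
    tracker = ReentryTracker(substrate.shape, T)
    for t_prev, t in zip(times, times[1:]):
        prev = trace.snapshots[t_prev]
        cur = trace.snapshots[t]
        excited_prev = prev == exc
        fire = cur == exc
        pacing_step = (t_prev % T) == 0
        paced = np.zeros(substrate.shape, dtype=bool)
        if pacing_step:
            paced[:, 0] = fire[:, 0] & (prev[:, 0] == 0)
        tracker.observe(excited_prev, fire, paced, pacing_step, edges, edges_up, t)
        if tracker.first_detection is not None:
            return tracker.first_detection[0]
    return None


@dataclass
class SweepResult:
    """Phase-diagram sweep: one row per (nu, realization)."""

    data: pd.DataFrame
    meta: dict


def phase_sweep(
    nu_grid: Sequence[float],
    n_realizations: int,
    n_steps: int,
    base_config: ModelConfig,
    *,
    threshold_factor: float = DEFAULT_AF_FACTOR,
    detect_reentry: bool = False,
    progress: bool = False,
) -> SweepResult:
    """Measure time-in-AF and critical-region counts across a nu grid.

    Realization r of every nu uses seed ``base_config.seed + r`` (fresh
    substrate and dynamics stream), so rows are deterministic given the
    base seed and independent across realizations.  ``reentry_detected``
    is filled only when ``detect_reentry`` is set (pd.NA otherwise).
    """
    if len(nu_grid) == 0 or n_realizations < 1:
        raise ValueError("nu_grid and n_realizations must be nonempty/positive")
    rows = []
    for nu in nu_grid:
        for r in range(n_realizations):
            seed = base_config.seed + r
            cfg = replace(base_config, nu=float(nu), seed=seed)
            sub = generate_substrate(cfg)
            trace = run(sub, n_steps, detect_reentry=detect_reentry)
            rows.append(
                {
                    "nu": float(nu),
                    "realization": r,
                    "seed": seed,
                    "time_in_af": time_in_af(trace, sub.n_rows, threshold_factor),
                    "n_critical": len(find_critical_regions(sub, cfg.tau)),
                    "reentry_detected": (
                        any(kind == "reentry" for _, kind, _ in trace.events)
                        if detect_reentry
                        else pd.NA
                    ),
                }
            )
            if progress:
                print(f"nu={nu:.3f} r={r}: time_in_af={rows[-1]['time_in_af']:.3f}")
    meta = {
        "L": base_config.L,
        "tau": base_config.tau,
        "delta": base_config.delta,
        "epsilon": base_config.epsilon,
        "T": base_config.T,
        "n_steps": n_steps,
        "n_realizations": n_realizations,
        "base_seed": base_config.seed,
        "seed_schedule": "base_seed + realization_index",
        "threshold_factor": threshold_factor,
    }
    return SweepResult(data=pd.DataFrame(rows), meta=meta)


@dataclass
class AblationReport:
    """Outcome of a targeted-ablation experiment."""

    outcome: str  # "terminated" | "persisted" | "inconclusive"
    onset_t: Optional[int]
    lesion_t: Optional[int]
    lesion_bbox: Optional[tuple[int, int, int, int]]
    target: Optional[CriticalRegion]
    time_to_termination: Optional[int]
    pre_trace: EpisodeTrace
    post_trace: Optional[EpisodeTrace]


def _wrapped_dist(a: tuple[int, int], b: tuple[int, int], n_rows: int) -> float:
    dy = abs(a[0] - b[0])
    dy = min(dy, n_rows - dy)
    return float(dy + abs(a[1] - b[1]))


def ablation_experiment(
    config: ModelConfig,
    max_wait: int,
    *,
    substrate: Optional[Substrate] = None,
    lesion_size: int = 20,
    lesion_center: Optional[tuple[int, int]] = None,
    post_steps: Optional[int] = None,
    threshold_factor: float = DEFAULT_AF_FACTOR,
) -> AblationReport:
    """Wait for reentry, ablate the critical structure, report the outcome.

    Runs until the label tracker detects reentry (or ``max_wait`` steps,
    giving outcome ``"inconclusive"``), scans the substrate for critical
    regions and places a ``lesion_size`` x ``lesion_size`` unexcitable
    square centred on the critical cell nearest the detected reentry core
    (``lesion_center=(x, y)`` overrides the placement, e.g. for off-target
    controls).  The run then continues for ``post_steps`` (default 6T).

    Outcome ``"terminated"``: no post-lesion reentry detection and no
    fibrillatory activity over the final two pacing cycles; otherwise
    ``"persisted"``.
    """
    sub = substrate if substrate is not None else generate_substrate(config)
    if sub.config is not config:
        config = sub.config
    T = config.T
    pre = run(sub, max_wait, detect_reentry=True, stop_on_reentry=True)
    detections = [e for e in pre.events if e[1] == "reentry"]
    if not detections:
        return AblationReport(
            outcome="inconclusive",
            onset_t=None,
            lesion_t=None,
            lesion_bbox=None,
            target=None,
            time_to_termination=None,
            pre_trace=pre,
            post_trace=None,
        )
    onset_t = detections[0][0]
    core_yx = detections[0][2][1]  # (y, x) of the first reentrant cell

    regions = find_critical_regions(sub, config.tau)
    target = None
    if regions:
        target = min(
            regions, key=lambda r: _wrapped_dist((r.y, r.x), core_yx, sub.n_rows)
        )
    if lesion_center is not None:
        cx, cy = lesion_center
    elif target is not None:
        cx, cy = target.x, target.y
    else:
        cy, cx = core_yx
    R, C = sub.shape
    size = min(lesion_size, C)
    x0 = int(np.clip(cx - size // 2, 0, C - size))
    y0 = (cy - lesion_size // 2) % R
    height = min(lesion_size, R)
    sub_lesioned = apply_lesion(sub, x0, y0, size, height)

    state = pre.final_state.copy()
    rows = (y0 + np.arange(height)) % R
    state.counters[np.ix_(rows, np.arange(x0, x0 + size))] = 0  # lesioned tissue is inert
    lesion_t = state.t

    if post_steps is None:
        post_steps = 6 * T
    post = run(sub_lesioned, post_steps, detect_reentry=True, initial_state=state)
    post_reentry = [e for e in post.events if e[1] == "reentry"]
    af = af_activity(post, sub.n_rows, threshold_factor)
    quiet_tail = not af[-2 * T :].any() if len(af) >= 2 * T else not af.any()
    terminated = (not post_reentry) and quiet_tail

    time_to_termination: Optional[int] = None
    if terminated:
        active = np.flatnonzero(af)
        time_to_termination = int(active[-1]) + 1 if active.size else 0
    return AblationReport(
        outcome="terminated" if terminated else "persisted",
        onset_t=onset_t,
        lesion_t=lesion_t,
        lesion_bbox=(x0, y0, size, height),
        target=target,
        time_to_termination=time_to_termination,
        pre_trace=pre,
        post_trace=post,
    )
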