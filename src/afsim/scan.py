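"""Locate fibrillation-inducing critical regions in a substrate.

The simplest reentry-capable structure is a dysfunctional cell whose
stretch of transversely uncoupled cells to the right is long enough that
a wave entering the lower cable through the first transverse coupling and
propagating retrogradely finds recovered tissue: distance ell >= tau/2.
The scanner finds exactly those cells, and a Monte Carlo over substrate
realisations turns the count into a simulation-side estimate of the
analytic risk P_risk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .substrate import ModelConfig, Substrate, generate_substrate

__all__ = [
    "CriticalRegion",
    "ell_distance",
    "ell_map",
    "find_critical_regions",
    "mc_risk_estimate",
]


@dataclass(frozen=True)
class CriticalRegion:
    """A dysfunctional cell capable of anchoring a microreentry circuit.

    ``ell`` is the distance (in cells) to the first transversely coupled
    cell at or to the right of (x, y); ``bbox = (x0, y0, width, height)``
    is a suggested lesion rectangle covering both cables of the circuit,
    anchored at (x-1, y-1), spanning ell+2 columns and 3 rows, clipped at
    the open horizontal boundaries and wrapped vertically.
    """

    x: int
    y: int
    ell: int
    bbox: tuple[int, int, int, int]


def _incident_edges(substrate: Substrate) -> np.ndarray:
    """Cells with >= 1 incident vertical edge (to row y+1 or row y-1)."""
    ve = substrate.vertical_edges
    return ve | np.roll(ve, 1, axis=0)


def ell_map(substrate: Substrate) -> np.ndarray:
    """Distance from every cell to the first transversely coupled cell at
    or to its right, -1 where no such cell exists before the boundary."""
    R, C = substrate.shape
    incident = _incident_edges(substrate)
    cols = np.arange(C)
    idx = np.where(incident, cols, C)
    nxt = np.minimum.accumulate(idx[:, ::-1], axis=1)[:, ::-1]
    ell = nxt - cols
    ell[nxt == C] = -1
    return ell


def ell_distance(substrate: Substrate, x: int, y: int) -> Optional[int]:
    """ell for a single cell; ``None`` when no coupled cell lies to the right.

    The cell itself counts as offset 0: the geometric support of ell
    starts at 0, which is what makes the closed form 1 - (1-nu)^tau exact.
    """
    R, C = substrate.shape
    if not (0 <= x < C and 0 <= y < R):
        raise ValueError(f"cell ({x}, {y}) out of bounds for shape {(R, C)}")
    incident = _incident_edges(substrate)[y, x:]
    hits = np.flatnonzero(incident)
    return int(hits[0]) if hits.size else None


def _critical_mask(substrate: Substrate, tau: int) -> tuple[np.ndarray, np.ndarray]:
    ell = ell_map(substrate)
    crit = (
        substrate.dysfunctional
        & ~substrate.ablated
        & (ell >= 0)
        & (ell >= tau / 2)  # real-valued cutoff; ties at tau/2 are critical
    )
    return crit, ell


def find_critical_regions(substrate: Substrate, tau: int) -> list[CriticalRegion]:
    """All dysfunctional, non-ablated cells with defined ell >= tau/2.

    Deterministic given the substrate; regions are returned in row-major
    order of (y, x).
    """
    if int(tau) != tau or tau < 1:
        raise ValueError(f"tau must be an integer >= 1, got {tau!r}")
    crit, ell = _critical_mask(substrate, tau)
    R, C = substrate.shape
    regions = []
    for y, x in np.argwhere(crit):
        y, x = int(y), int(x)
        e = int(ell[y, x])
        x0 = max(x - 1, 0)
        width = min(e + 2, C - x0)
        regions.append(
            CriticalRegion(x=x, y=y, ell=e, bbox=(x0, (y - 1) % R, width, 3))
        )
    return regions


def mc_risk_estimate(
    config: ModelConfig, n_substrates: int
) -> tuple[float, float]:
    """Fraction of substrate realisations containing >= 1 critical region.

    Generates ``n_substrates`` independent substrates (seeds config.seed,
    config.seed+1, ...) and returns ``(fraction, binomial standard
    error)``.  Consistent with the closed-form P_risk as n grows, up to
    the small deficit from open-boundary truncation of ell.  At nu = 0 no
    cell has a transverse coupling, no circuit can close, and the
    estimate is 0 -- outside the validity of the closed form, which gives 1.
    """
    if n_substrates < 1:
        raise ValueError(f"n_substrates must be >= 1, got {n_substrates}")
    hits = 0
    for i in range(n_substrates):
        sub = generate_substrate(replace(config, seed=config.seed + i))
        crit, _ = _critical_mask(sub, config.tau)
        hits += bool(crit.any())
    frac = hits / n_substrates
    se = float(np.sqrt(frac * (1.0 - frac) / n_substrates))
    return frac, se
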