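"""Event-probability curves, percolation thresholds and degradation phases.

The degradation of a random (percolation-map) landscape from pristine
(q = 0) to fully destroyed (q = 1) passes through four structural
transitions that delimit five phases:

1. the probability of patch shrinkage falls below 99% (isolated patches
   appear and splitting becomes noticeable),
2. the percolation threshold q_c (the landscape fragments),
3. the patch-splitting probability peaks,
4. patch loss overtakes both shrinkage and splitting.

This module builds the per-q event-probability curves from swap-dynamics
runs, estimates q_c from torus wrapping probabilities and locates the
transitions on a curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effective_loss as efl
from .events import DEFAULT_SIZE_CAP, EventType, run_events
from .landscape import random_landscape, wrapping_cluster_exists
from .lattice import HEX6, SQUARE4, Lattice, REFERENCE_PC

log = logging.getLogger(__name__)

#: Number of elementary events per q used in the original full-scale study.
PAPER_N_EVENTS = 6_000_000
#: Desk-scale default.
DEFAULT_N_EVENTS = 100_000


class TransitionError(RuntimeError):
    """A transition cannot be located on the supplied curve."""


class ThresholdBracketError(RuntimeError):
    """The wrapping-probability scan does not bracket the 0.5 crossing."""


# ---------------------------------------------------------------------
# Analytic baseline and default grids
# ---------------------------------------------------------------------

def analytic_loss_probability(p: float, kind: str, conditioned: bool = False) -> float:
    """Probability of a patch-loss configuration on an infinite lattice.

    A removal is a patch loss iff the removed site is isolated: a random
    *site* is an isolated habitat site with probability p(1−p)^z.
    Conditioning on removal events (the site is known to be habitat)
    divides by p, giving (1−p)^z — the form comparable with the
    per-removal event probabilities of :func:`build_curve`.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    z = Lattice(kind, 3).coordination
    raw = p * (1.0 - p) ** z
    return (1.0 - p) ** z if conditioned else raw


def default_p_grid(kind: str) -> np.ndarray:
    """Habitat-fraction grids of the original study, per geometry."""
    coarse = np.round(np.arange(0.05, 0.951, 0.05), 2)
    if kind == HEX6:
        dense = np.round(np.arange(0.45, 0.551, 0.01), 2)
        extra = np.array([0.57, 0.63, 0.67])
    elif kind == SQUARE4:
        dense = np.round(np.arange(0.45, 0.801, 0.01), 2)
        extra = np.array([])
    else:
        raise ValueError(f"unknown lattice kind {kind!r}")
    return np.unique(np.round(np.concatenate([coarse, dense, extra]), 2))


def default_q_grid(kind: str) -> np.ndarray:
    """Default habitat-loss grid (q = 1 − p), ascending."""
    return np.unique(np.round(1.0 - default_p_grid(kind), 2))


# ---------------------------------------------------------------------
# Event-probability curves
# ---------------------------------------------------------------------

@dataclass
class EventCurve:
    """Per-q probabilities of the three removal-side events.

    ``table`` columns: q, n_events, n_removals, counts of all six event
    types, per-removal probabilities p_loss / p_shrink / p_split (they
    sum to 1 by construction) and their binomial standard errors.
    ``amplification`` (optional) holds A(q, m) rows from the same runs.
    """

    kind: str
    table: pd.DataFrame
    n_events_per_point: int
    seed: int | None = None
    size_cap: int | None = DEFAULT_SIZE_CAP
    amplification: pd.DataFrame | None = None

    @property
    def q(self) -> np.ndarray:
        return self.table["q"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


def build_curve(
    kind: str,
    q_grid=None,
    n_events: int = DEFAULT_N_EVENTS,
    side: int = 100,
    seed=None,
    m_values=None,
    size_cap: int | None = DEFAULT_SIZE_CAP,
    engine: str = "auto",
) -> EventCurve:
    """Run swap dynamics over a q grid and collect event probabilities.

    One :func:`~patchdyn.events.run_events` call per grid point, each
    with a seed derived from ``seed``.  ``q_grid=None`` uses the default
    (full-scale study) grid for the geometry.  If ``m_values`` is given,
    the amplification factors A(q, m) are accumulated from the same
    event streams in the same pass.
    """
    lattice = Lattice(kind, side)
    if q_grid is None:
        q_grid = default_q_grid(kind)
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.ndim != 1 or len(q_grid) == 0:
        raise ValueError("q_grid must be a non-empty 1-D sequence")
    if not (np.all(np.diff(q_grid) > 0)):
        raise ValueError("q_grid values must be strictly increasing")
    if q_grid[0] <= 0.0 or q_grid[-1] >= 1.0:
        raise ValueError("q_grid values must lie strictly inside (0, 1)")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(q_grid))

    rows = []
    amp_rows = []
    for q, child in zip(q_grid, children):
        observers = []
        acc = None
        if m_values:
            acc = efl.AmplificationAccumulator(m_values)
            observers.append(acc)
        tally = run_events(lattice, float(q), n_events, seed=child,
                           observers=observers, size_cap=size_cap, engine=engine)
        probs = tally.removal_probabilities()
        row = {"q": float(q), "n_events": n_events, "n_removals": tally.n_removals}
        for t in EventType:
            row[f"n_{t.value}"] = tally.counts.get(t, 0)
        for t, short in ((EventType.LOSS, "loss"), (EventType.SHRINKAGE, "shrink"),
                         (EventType.SPLITTING, "split")):
            row[f"p_{short}"], row[f"se_{short}"] = probs[t]
        rows.append(row)
        if acc is not None:
            res = acc.results()
            res.insert(0, "q", float(q))
            amp_rows.append(res)
        log.info("%s q=%.3f: %s", kind, q,
                 {t.value: tally.counts.get(t, 0) for t in EventType})

    table = pd.DataFrame(rows)
    amp = pd.concat(amp_rows, ignore_index=True) if amp_rows else None
    if amp is not None:
        amp.insert(0, "geometry", kind)
    seed_repr = seed if isinstance(seed, (int, type(None))) else None
    return EventCurve(kind, table, n_events, seed_repr, size_cap, amp)


# ---------------------------------------------------------------------
# Percolation-threshold estimation from torus wrapping
# ---------------------------------------------------------------------

@dataclass
class ThresholdEstimate:
    kind: str
    p_c: float
    se: float
    scan: pd.DataFrame = field(repr=False)

    @property
    def q_c(self) -> float:
        return 1.0 - self.p_c


def default_threshold_scan(kind: str) -> np.ndarray:
    if kind == HEX6:
        return np.round(np.arange(0.40, 0.601, 0.01), 2)
    if kind == SQUARE4:
        return np.round(np.arange(0.50, 0.701, 0.01), 2)
    raise ValueError(f"unknown lattice kind {kind!r}")


def estimate_percolation_threshold(
    kind: str,
    side: int = 100,
    p_scan=None,
    replicates: int = 200,
    seed=None,
) -> ThresholdEstimate:
    """Estimate p_c as the 0.5 crossing of the torus wrapping probability.

    For each scan value of p, ``replicates`` random landscapes are drawn
    and tested for a cluster winding around each torus axis.  The
    wrapping probability used for the crossing is the per-axis mean
    (P(wrap axis 0) + P(wrap axis 1)) / 2: its value at criticality is
    close to 1/2 (≈ 0.521 in the infinite-size limit), so the 0.5
    crossing is a nearly unbiased threshold estimator, unlike the
    either-axis union whose critical value is ≈ 0.69.  The either-axis
    probability is reported in the scan table as well.

    Raises :class:`ThresholdBracketError` if the scan does not cross 0.5.
    """
    lattice = Lattice(kind, side)
    if p_scan is None:
        p_scan = default_threshold_scan(kind)
    p_scan = np.asarray(p_scan, dtype=float)
    if not np.all(np.diff(p_scan) > 0):
        raise ValueError("p_scan must be strictly increasing")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(p_scan))

    rows = []
    for p, child in zip(p_scan, children):
        rng = np.random.default_rng(child)
        axis_hits = 0  # counts each wrapped axis as one half-replicate
        either = 0
        for _ in range(replicates):
            ls = random_landscape(lattice, float(p), rng)
            w0, w1 = wrapping_cluster_exists(ls)
            axis_hits += int(w0) + int(w1)
            either += int(w0 or w1)
        w = axis_hits / (2 * replicates)
        rows.append({
            "p": float(p),
            "wrap_prob": w,
            "se": float(np.sqrt(max(w * (1 - w), 1e-12) / replicates)),
            "wrap_either": either / replicates,
            "replicates": replicates,
        })
        log.info("%s threshold scan p=%.3f wrap=%.3f", kind, p, w)
    scan = pd.DataFrame(rows)

    w = scan["wrap_prob"].to_numpy()
    p = scan["p"].to_numpy()
    if w[0] >= 0.5:
        raise ThresholdBracketError(
            f"scan starts at wrapping probability {w[0]:.3f} >= 0.5; "
            "extend the scan to smaller p"
        )
    idx = np.flatnonzero((w[:-1] < 0.5) & (w[1:] >= 0.5))
    if len(idx) == 0:
        raise ThresholdBracketError(
            "wrapping probability never crosses 0.5 inside the scan; "
            "extend the scan to larger p"
        )
    if len(idx) > 1:
        log.warning("multiple 0.5 crossings in threshold scan; using the first")
    i = int(idx[0])
    slope = (w[i + 1] - w[i]) / (p[i + 1] - p[i])
    p_c = p[i] + (0.5 - w[i]) / slope
    se = float(max(scan["se"][i], scan["se"][i + 1]) / abs(slope))
    return ThresholdEstimate(kind, float(p_c), se, scan)


# ---------------------------------------------------------------------
# Transition detection
# ---------------------------------------------------------------------

@dataclass
class TransitionSet:
    """The four transition points and the five phases they delimit."""

    kind: str
    q1: float  # P(shrinkage) falls below 0.99
    q2: float  # percolation threshold q_c
    q3: float  # P(splitting) peaks
    q4: float  # P(loss) overtakes shrinkage and splitting
    threshold_method: str = "reference"

    @property
    def phases(self) -> list[tuple[float, float]]:
        return [(0.0, self.q1), (self.q1, self.q2), (self.q2, self.q3),
                (self.q3, self.q4), (self.q4, 1.0)]

    def as_dict(self) -> dict:
        return {
            "geometry": self.kind,
            "q1": self.q1, "q2": self.q2, "q3": self.q3, "q4": self.q4,
            "phase_intervals": self.phases,
            "threshold_method": self.threshold_method,
        }


def _first_crossing(x: np.ndarray, y: np.ndarray, level: float,
                    direction: str) -> float:
    """Linearly interpolated first crossing of ``level`` along x ascending."""
    d = y - level
    if direction == "down":
        hits = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0))
    else:
        hits = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
    if len(hits) == 0:
        raise TransitionError(
            f"no {direction}ward crossing of {level} found on the curve"
        )
    if len(hits) > 1:
        log.warning("multiple %sward crossings of %s; using the first in "
                    "increasing q", direction, level)
    i = int(hits[0])
    t = d[i] / (d[i] - d[i + 1])
    return float(x[i] + t * (x[i + 1] - x[i]))


def quadratic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Peak location from a parabola through the maximal point and its
    two grid neighbours; exact for 3 points, handles non-uniform grids."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise TransitionError(
            "splitting probability peaks at the edge of the grid; extend the grid"
        )
    a, b, _c = np.polyfit(x[i - 1:i + 2], y[i - 1:i + 2], 2)
    if a >= 0:
        return float(x[i])
    vertex = -b / (2 * a)
    return float(np.clip(vertex, x[i - 1], x[i + 1]))


def detect_transitions(curve: EventCurve, threshold_estimate: float | None = None,
                       use_reference: bool = False) -> TransitionSet:
    """Locate the four degradation transitions on an event curve.

    ``q2`` is ``threshold_estimate`` (a q value, e.g. from
    :func:`estimate_percolation_threshold`) unless ``use_reference`` is
    set, in which case the geometry's reference q_c is used; with
    neither given, the reference is used.
    """
    df = curve.table.sort_values("q")
    q = df["q"].to_numpy()
    if q[0] > 0.05 + 1e-9 or q[-1] < 0.95 - 1e-9:
        raise TransitionError(
            f"curve covers q in [{q[0]}, {q[-1]}]; transition detection "
            "needs coverage from <= 0.05 to >= 0.95"
        )
    p_shrink = df["p_shrink"].to_numpy()
    p_split = df["p_split"].to_numpy()
    p_loss = df["p_loss"].to_numpy()

    q1 = _first_crossing(q, p_shrink, 0.99, "down")
    if use_reference or threshold_estimate is None:
        q2 = 1.0 - REFERENCE_PC[curve.kind]
        method = "reference"
    else:
        q2 = float(threshold_estimate)
        method = "wrapping-estimate"
    q3 = quadratic_peak(q, p_split)
    q4 = _first_crossing(q, p_loss - np.maximum(p_shrink, p_split), 0.0, "up")
    return TransitionSet(curve.kind, q1, q2, q3, q4, method)
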