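"""Classification of elementary patch events and swap dynamics.

Removing a single habitat site necessarily causes exactly one of three
elementary events in the affected patch: **loss** (the patch consisted
of that one site), **shrinkage** (the remaining sites stay connected)
or **splitting** (the patch falls apart into two or more fragments).
Adding a habitat site causes the mirror events: **formation**,
**enlargement** or **coalescence**.

The steady-state process is swap dynamics at constant habitat density:
one uniformly chosen habitat site turns non-habitat while one uniformly
chosen non-habitat site (of the pre-swap state) turns habitat.

Classification is local and avoids global relabelling.  The habitat
neighbours of the focal site are first grouped by the ring-occupancy
lookup tables (two neighbours connected around the focal site are
provably in one fragment); only if several groups remain is a bounded
multi-source breadth-first search run, with searches merging on contact
and terminating as soon as at most one unexhausted search remains.
Exhausted searches delimit fragments and size them exactly.

Patch sizes can be reported *saturated*: with ``size_cap = c`` any size
larger than ``c`` is recorded as ``c + 1``.  Sizes at most ``c`` are
always exact, which is all the effective-habitat-loss computation needs
(see :mod:`patchdyn.effective_loss`).  ``size_cap=None`` sizes
everything exactly.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._rng import SplitMix64, derive_state
from .landscape import Landscape, label_patches, random_landscape
from .lattice import Lattice

#: Default saturation cap for sizes recorded during long simulations.
#: Any minimum-viable-patch size m <= DEFAULT_SIZE_CAP is evaluated
#: exactly under this cap.
DEFAULT_SIZE_CAP = 16


class EventType(enum.Enum):
    FORMATION = "formation"
    LOSS = "loss"
    ENLARGEMENT = "enlargement"
    SHRINKAGE = "shrinkage"
    COALESCENCE = "coalescence"
    SPLITTING = "splitting"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


REMOVAL_TYPES = (EventType.LOSS, EventType.SHRINKAGE, EventType.SPLITTING)
ADDITION_TYPES = (EventType.FORMATION, EventType.ENLARGEMENT, EventType.COALESCENCE)

# Integer codes shared with the numba kernel.
_REM_CODE = {EventType.LOSS: 0, EventType.SHRINKAGE: 1, EventType.SPLITTING: 2}
_ADD_CODE = {EventType.FORMATION: 0, EventType.ENLARGEMENT: 1, EventType.COALESCENCE: 2}
REM_TYPES_BY_CODE = (EventType.LOSS, EventType.SHRINKAGE, EventType.SPLITTING)
ADD_TYPES_BY_CODE = (EventType.FORMATION, EventType.ENLARGEMENT, EventType.COALESCENCE)


class SiteStateError(ValueError):
    """The focal site is not in the state the operation requires."""


class SimulationStateError(RuntimeError):
    """The landscape cannot support a swap (empty or full lattice)."""


@dataclass(frozen=True)
class EventRecord:
    """One elementary event: type plus before/after patch sizes.

    ``sizes_before`` and ``sizes_after`` list the sizes of the patches
    involved (descending).  If ``size_cap`` is an integer c, sizes are
    saturated: a recorded value of c + 1 stands for "larger than c".
    """

    event_type: EventType
    site: int
    sizes_before: tuple[int, ...]
    sizes_after: tuple[int, ...]
    size_cap: int | None = None

    @property
    def is_removal(self) -> bool:
        return self.event_type in REMOVAL_TYPES

    @property
    def is_addition(self) -> bool:
        return self.event_type in ADDITION_TYPES


def _rep(value: int, truncated: bool, cap: int | None) -> int:
    if cap is None:
        return int(value)
    return cap + 1 if (truncated or value > cap) else int(value)


# ---------------------------------------------------------------------
# Local connectivity resolution (python reference implementation; the
# numba kernel in _kernels.py mirrors this logic exactly)
# ---------------------------------------------------------------------

def _habitat_neighbor_groups(landscape: Landscape, site: int) -> list[list[int]]:
    """Habitat neighbours of ``site`` grouped by ring connectivity."""
    lat = landscape.lattice
    ring = lat.ring_array[site]
    occ = landscape.occ
    mask = 0
    for r, s2 in enumerate(ring):
        if occ[s2]:
            mask |= 1 << r
    n_groups_tbl, group_of_tbl = lat.ring_tables
    ng = int(n_groups_tbl[mask])
    groups: list[list[int]] = [[] for _ in range(ng)]
    cross = lat.cross_positions
    for d in range(lat.coordination):
        g = int(group_of_tbl[mask, d])
        if g >= 0:
            groups[g].append(int(ring[cross[d]]))
    return groups


def _resolve_components(
    landscape: Landscape,
    groups: Sequence[Sequence[int]],
    exclude: int = -1,
    size_cap: int | None = None,
) -> list[tuple[int, bool]]:
    """Connected components reachable from each seed group.

    Runs one search per group; searches merge when they touch and finish
    when at most one unexhausted search remains.  Exhausted searches are
    fragments with exact sizes; the surviving search (the rest of the
    patch) is completed only up to ``size_cap`` sites.

    Returns ``[(size, truncated), ...]``, one entry per distinct
    component; ``truncated`` marks a size that is only a lower bound.
    """
    occ = landscape.occ
    nbr = landscape.lattice.neighbor_array
    k = len(groups)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[int, int] = {}
    queues = [deque(g) for g in groups]
    sizes = [len(g) for g in groups]
    final = [False] * k
    for gi, g in enumerate(groups):
        for s in g:
            owner[s] = gi
    active = k
    while active > 1:
        for g in range(k):
            if final[g] or parent[g] != g:
                continue
            site = None
            for h in range(k):
                if find(h) == g and queues[h]:
                    site = queues[h].popleft()
                    break
            if site is None:
                final[g] = True
                active -= 1
                continue
            for nb in nbr[site]:
                nb = int(nb)
                if nb == exclude or not occ[nb]:
                    continue
                if nb in owner:
                    r2 = find(owner[nb])
                    if r2 != g:
                        parent[r2] = g
                        sizes[g] += sizes[r2]
                        active -= 1
                else:
                    owner[nb] = g
                    queues[g].append(nb)
                    sizes[g] += 1

    survivor = next((g for g in range(k) if parent[g] == g and not final[g]), None)
    truncated = False
    if survivor is not None:
        cap = float("inf") if size_cap is None else size_cap
        while sizes[survivor] <= cap:
            site = None
            for h in range(k):
                if find(h) == survivor and queues[h]:
                    site = queues[h].popleft()
                    break
            if site is None:
                break
            for nb in nbr[site]:
                nb = int(nb)
                if nb == exclude or not occ[nb]:
                    continue
                if nb not in owner:
                    owner[nb] = survivor
                    queues[survivor].append(nb)
                    sizes[survivor] += 1
        truncated = any(queues[h] for h in range(k) if find(h) == survivor)
    return [
        (sizes[g], truncated and g == survivor)
        for g in range(k)
        if parent[g] == g
    ]


# ---------------------------------------------------------------------
# One-off classification
# ---------------------------------------------------------------------

def classify_removal(landscape: Landscape, site: int,
                     size_cap: int | None = None) -> EventRecord:
    """Classify the removal of habitat ``site`` without mutating anything.

    Loss if the site has no habitat neighbours; shrinkage if its habitat
    neighbours remain mutually connected after the removal; splitting
    otherwise, with every fragment sized.
    """
    landscape.lattice._check_site(site)
    site = int(site)
    if not landscape.occ[site]:
        raise SiteStateError(f"site {site} is non-habitat; cannot classify a removal")
    groups = _habitat_neighbor_groups(landscape, site)
    if not groups:
        return EventRecord(EventType.LOSS, site, (1,), (), size_cap)
    comps = _resolve_components(landscape, groups, exclude=site, size_cap=size_cap)
    if len(comps) == 1:
        t, tr = comps[0]
        return EventRecord(
            EventType.SHRINKAGE, site,
            (_rep(t + 1, tr, size_cap),), (_rep(t, tr, size_cap),), size_cap,
        )
    frags = tuple(sorted((_rep(t, tr, size_cap) for t, tr in comps), reverse=True))
    total = sum(t for t, _ in comps) + 1
    any_tr = any(tr for _, tr in comps)
    return EventRecord(
        EventType.SPLITTING, site, (_rep(total, any_tr, size_cap),), frags, size_cap
    )


def classify_addition(landscape: Landscape, site: int,
                      size_cap: int | None = None) -> EventRecord:
    """Classify the addition of a habitat site at non-habitat ``site``.

    Formation if no patch is adjacent, enlargement if exactly one
    distinct patch is adjacent, coalescence if two or more distinct
    patches are adjacent.
    """
    landscape.lattice._check_site(site)
    site = int(site)
    if landscape.occ[site]:
        raise SiteStateError(f"site {site} is habitat; cannot classify an addition")
    groups = _habitat_neighbor_groups(landscape, site)
    if not groups:
        return EventRecord(EventType.FORMATION, site, (), (1,), size_cap)
    comps = _resolve_components(landscape, groups, exclude=-1, size_cap=size_cap)
    if len(comps) == 1:
        t, tr = comps[0]
        return EventRecord(
            EventType.ENLARGEMENT, site,
            (_rep(t, tr, size_cap),), (_rep(t + 1, tr, size_cap),), size_cap,
        )
    parts = tuple(sorted((_rep(t, tr, size_cap) for t, tr in comps), reverse=True))
    total = sum(t for t, _ in comps) + 1
    any_tr = any(tr for _, tr in comps)
    return EventRecord(
        EventType.COALESCENCE, site, parts, (_rep(total, any_tr, size_cap),), size_cap
    )


# ---------------------------------------------------------------------
# Brute-force oracle: full relabelling before and after a trial change
# ---------------------------------------------------------------------

def classify_removal_by_relabel(landscape: Landscape, site: int) -> EventRecord:
    """Oracle classification via global patch relabelling (exact, O(N))."""
    site = int(site)
    if not landscape.occ[site]:
        raise SiteStateError(f"site {site} is non-habitat")
    labels, sizes = label_patches(landscape)
    pid = int(labels[site])
    s = sizes[pid]
    if s == 1:
        return EventRecord(EventType.LOSS, site, (1,), ())
    members = np.flatnonzero(labels == pid)
    landscape.set_site(site, 0)
    try:
        labels2, sizes2 = label_patches(landscape)
        frag_ids = {int(labels2[m]) for m in members if m != site}
        frags = tuple(sorted((sizes2[i] for i in frag_ids), reverse=True))
    finally:
        landscape.set_site(site, 1)
    if len(frags) == 1:
        return EventRecord(EventType.SHRINKAGE, site, (s,), frags)
    return EventRecord(EventType.SPLITTING, site, (s,), frags)


def classify_addition_by_relabel(landscape: Landscape, site: int) -> EventRecord:
    """Oracle classification of an addition via global relabelling."""
    site = int(site)
    if landscape.occ[site]:
        raise SiteStateError(f"site {site} is habitat")
    labels, sizes = label_patches(landscape)
    pids = {int(labels[nb]) for nb in landscape.lattice.neighbors(site) if labels[nb] > 0}
    if not pids:
        return EventRecord(EventType.FORMATION, site, (), (1,))
    parts = tuple(sorted((sizes[i] for i in pids), reverse=True))
    total = sum(parts) + 1
    if len(parts) == 1:
        return EventRecord(EventType.ENLARGEMENT, site, parts, (total,))
    return EventRecord(EventType.COALESCENCE, site, parts, (total,))


# ---------------------------------------------------------------------
# Swap dynamics
# ---------------------------------------------------------------------

def apply_swap(landscape: Landscape, rng,
               size_cap: int | None = None) -> tuple[EventRecord, EventRecord]:
    """One constant-density swap: remove and add one site, classifying both.

    The removal target is uniform over habitat sites and the addition
    target uniform over the *pre-swap* non-habitat sites (so the two
    draws are independent and the just-removed site is never re-added
    within the same swap).  The removal is classified against the
    pre-swap state, applied, and the addition is then classified against
    the intermediate state and applied; the habitat count is unchanged.
    """
    n = landscape.lattice.n_sites
    if not 0 < landscape.n_habitat < n:
        raise SimulationStateError(
            f"cannot swap with n_habitat={landscape.n_habitat} of {n} sites"
        )
    habitat = landscape.habitat_sites()
    empty = np.flatnonzero(landscape.occ == 0)
    if isinstance(rng, SplitMix64):
        rem = int(habitat[rng.randbelow(len(habitat))])
        add = int(empty[rng.randbelow(len(empty))])
    else:
        rem = int(habitat[rng.integers(len(habitat))])
        add = int(empty[rng.integers(len(empty))])
    removal = classify_removal(landscape, rem, size_cap)
    landscape.set_site(rem, 0)
    addition = classify_addition(landscape, add, size_cap)
    landscape.set_site(add, 1)
    return removal, addition


@dataclass
class EventTally:
    """Counts of the six elementary events for one run at fixed q."""

    q: float
    n_events: int
    counts: dict[EventType, int] = field(default_factory=dict)

    @property
    def n_removals(self) -> int:
        return sum(self.counts.get(t, 0) for t in REMOVAL_TYPES)

    @property
    def n_additions(self) -> int:
        return sum(self.counts.get(t, 0) for t in ADDITION_TYPES)

    def removal_probabilities(self) -> dict[EventType, tuple[float, float]]:
        """Per-removal-event probabilities with binomial standard errors.

        Conditioned on removals: loss + shrinkage + splitting sum to 1.
        """
        n = self.n_removals
        out = {}
        for t in REMOVAL_TYPES:
            c = self.counts.get(t, 0)
            p = c / n
            out[t] = (p, float(np.sqrt(p * (1.0 - p) / n)))
        return out


@dataclass
class EventBatch:
    """Array-of-records form of one run's event stream.

    Sizes are saturated at ``size_cap`` (see module docstring); the
    fragment / merged-part columns are zero-padded (at most 4 fragments
    on square4, 3 on hex6).
    """

    lattice: Lattice
    q: float
    size_cap: int | None
    rem_site: np.ndarray
    rem_type: np.ndarray      # codes 0 loss / 1 shrinkage / 2 splitting
    rem_s: np.ndarray         # pre-event patch size (saturated)
    rem_after: np.ndarray     # (n, 4) post-event sizes, zero-padded
    add_site: np.ndarray
    add_type: np.ndarray      # codes 0 formation / 1 enlargement / 2 coalescence
    add_after: np.ndarray     # merged patch size after the addition
    add_parts: np.ndarray     # (n, 4) pre-event patch sizes, zero-padded

    @property
    def n_swaps(self) -> int:
        return len(self.rem_type)

    def to_tally(self) -> EventTally:
        counts = {}
        rc = np.bincount(self.rem_type, minlength=3)
        ac = np.bincount(self.add_type, minlength=3)
        for code, t in enumerate(REM_TYPES_BY_CODE):
            counts[t] = int(rc[code])
        for code, t in enumerate(ADD_TYPES_BY_CODE):
            counts[t] = int(ac[code])
        return EventTally(q=self.q, n_events=2 * self.n_swaps, counts=counts)

    def iter_records(self) -> Iterator[EventRecord]:
        """Yield EventRecords in simulation order (removal, addition, ...)."""
        for i in range(self.n_swaps):
            rt = REM_TYPES_BY_CODE[self.rem_type[i]]
            s = int(self.rem_s[i])
            after = tuple(int(x) for x in self.rem_after[i] if x > 0)
            if rt is EventType.LOSS:
                yield EventRecord(rt, int(self.rem_site[i]), (1,), (), self.size_cap)
            else:
                yield EventRecord(rt, int(self.rem_site[i]), (s,), after, self.size_cap)
            at = ADD_TYPES_BY_CODE[self.add_type[i]]
            parts = tuple(int(x) for x in self.add_parts[i] if x > 0)
            aft = (int(self.add_after[i]),)
            if at is EventType.FORMATION:
                yield EventRecord(at, int(self.add_site[i]), (), (1,), self.size_cap)
            else:
                yield EventRecord(at, int(self.add_site[i]), parts, aft, self.size_cap)


def _python_engine(landscape: Landscape, n_swaps: int, state: int,
                   size_cap: int | None) -> EventBatch:
    """Reference engine; draws the same SplitMix64 stream as the kernel."""
    rng = SplitMix64(state)
    ls = landscape
    n = ls.lattice.n_sites
    perm = list(np.flatnonzero(ls.occ)) + list(np.flatnonzero(ls.occ == 0))
    perm = [int(x) for x in perm]
    pos = [0] * n
    for idx, s in enumerate(perm):
        pos[s] = idx
    n_h = ls.n_habitat

    rem_site = np.empty(n_swaps, np.int32)
    rem_type = np.empty(n_swaps, np.uint8)
    rem_s = np.empty(n_swaps, np.int64)
    rem_after = np.zeros((n_swaps, 4), np.int64)
    add_site = np.empty(n_swaps, np.int32)
    add_type = np.empty(n_swaps, np.uint8)
    add_after = np.empty(n_swaps, np.int64)
    add_parts = np.zeros((n_swaps, 4), np.int64)

    for i in range(n_swaps):
        ri = rng.randbelow(n_h)
        ai = rng.randbelow(n - n_h)
        rem = perm[ri]
        add = perm[n_h + ai]

        rec = classify_removal(ls, rem, size_cap)
        rem_site[i] = rem
        rem_type[i] = _REM_CODE[rec.event_type]
        rem_s[i] = rec.sizes_before[0]
        for k, v in enumerate(rec.sizes_after):
            rem_after[i, k] = v
        ls.set_site(rem, 0)
        j, last = pos[rem], n_h - 1
        other = perm[last]
        perm[j], perm[last] = other, rem
        pos[other], pos[rem] = j, last
        n_h = last

        rec = classify_addition(ls, add, size_cap)
        add_site[i] = add
        add_type[i] = _ADD_CODE[rec.event_type]
        add_after[i] = rec.sizes_after[0]
        for k, v in enumerate(rec.sizes_before):
            add_parts[i, k] = v
        ls.set_site(add, 1)
        j = pos[add]
        other = perm[n_h]
        perm[j], perm[n_h] = other, add
        pos[other], pos[add] = j, n_h
        n_h += 1

    return EventBatch(ls.lattice, ls.q, size_cap, rem_site, rem_type, rem_s,
                      rem_after, add_site, add_type, add_after, add_parts)


def run_events(
    lattice: Lattice,
    q: float,
    n_events: int,
    seed=None,
    observers: Iterable = (),
    size_cap: int | None = DEFAULT_SIZE_CAP,
    engine: str = "auto",
    return_batch: bool = False,
):
    """Run swap dynamics at habitat loss ``q`` and tally all events.

    ``n_events`` counts removals and additions (one swap = 2 events) and
    must be even.  The run is deterministic given ``seed``.  Observers
    receive the event stream: objects exposing ``observe_batch(batch)``
    get the whole :class:`EventBatch`; objects exposing ``observe(rec)``
    get individual :class:`EventRecord` instances.

    Returns the :class:`EventTally` (and the batch when
    ``return_batch=True``).
    """
    if not isinstance(n_events, (int, np.integer)) or n_events <= 0:
        raise ValueError("n_events must be a positive integer")
    if n_events % 2:
        raise ValueError("n_events must be even (removal/addition pairs)")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"habitat loss q={q} outside [0, 1]")
    p = 1.0 - q
    n_habitat = int(round(p * lattice.n_sites))
    if not 0 < n_habitat < lattice.n_sites:
        raise SimulationStateError(
            f"q={q} leaves n_habitat={n_habitat}; swap dynamics needs both "
            "habitat and non-habitat sites"
        )

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, stream_ss = ss.spawn(2)
    landscape = random_landscape(lattice, p, init_ss)
    state = derive_state(stream_ss)
    n_swaps = n_events // 2

    if engine == "auto":
        from . import _kernels
        engine = "numba" if (_kernels.HAVE_NUMBA and size_cap is not None) else "python"
    if engine == "numba":
        from . import _kernels
        if size_cap is None:
            raise ValueError("the numba engine requires an integer size_cap")
        batch = _kernels.simulate(landscape, n_swaps, state, size_cap)
    elif engine == "python":
        batch = _python_engine(landscape, n_swaps, state, size_cap)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    tally = batch.to_tally()
    for obs in observers:
        if hasattr(obs, "observe_batch"):
            obs.observe_batch(batch)
        else:
            for rec in batch.iter_records():
                obs.observe(rec)
    if return_batch:
        return tally, batch
    return tally
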