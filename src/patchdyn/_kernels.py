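"""Numba-accelerated swap-dynamics engine.

This mirrors the pure-python reference in :mod:`patchdyn.events`
operation for operation — same SplitMix64 draws, same seed-group
tables, same bounded multi-source search with the same saturation
semantics — so that both engines produce identical event streams for a
given seed (asserted by the test suite).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if len(args) == 1 and callable(args[0]):
            return args[0]
        return wrap

from .events import EventBatch

_U = np.uint64


@njit(cache=True)
def _next(state):
    state = state + _U(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    z = z ^ (z >> _U(31))
    return state, z


@njit(cache=True)
def _find(parent, g):
    while parent[g] != g:
        g = parent[g]
    return g


@njit(cache=True)
def _resolve(occ, nbr, exclude, seed_sites, seed_gids, n_seeds, ngroups, cap,
             stamp, owner, epoch, queues, qhead, qtail, parent, csize, final,
             comp_sizes, comp_trunc):
    z = nbr.shape[1]
    for g in range(ngroups):
        parent[g] = g
        csize[g] = 0
        final[g] = 0
        qhead[g] = 0
        qtail[g] = 0
    for k in range(n_seeds):
        s = seed_sites[k]
        g = seed_gids[k]
        stamp[s] = epoch
        owner[s] = g
        queues[g, qtail[g]] = s
        qtail[g] += 1
        csize[g] += 1
    active = ngroups
    while active > 1:
        for g in range(ngroups):
            if final[g] == 1 or parent[g] != g:
                continue
            site = -1
            for h in range(ngroups):
                if _find(parent, h) == g and qhead[h] < qtail[h]:
                    site = queues[h, qhead[h]]
                    qhead[h] += 1
                    break
            if site == -1:
                final[g] = 1
                active -= 1
                continue
            for d in range(z):
                nb = nbr[site, d]
                if nb == exclude or occ[nb] == 0:
                    continue
                if stamp[nb] == epoch:
                    r2 = _find(parent, np.int64(owner[nb]))
                    if r2 != g:
                        parent[r2] = g
                        csize[g] += csize[r2]
                        active -= 1
                else:
                    stamp[nb] = epoch
                    owner[nb] = g
                    queues[g, qtail[g]] = nb
                    qtail[g] += 1
                    csize[g] += 1
    survivor = -1
    for g in range(ngroups):
        if parent[g] == g and final[g] == 0:
            survivor = g
    trunc = False
    if survivor >= 0:
        while csize[survivor] <= cap:
            site = -1
            for h in range(ngroups):
                if _find(parent, h) == survivor and qhead[h] < qtail[h]:
                    site = queues[h, qhead[h]]
                    qhead[h] += 1
                    break
            if site == -1:
                break
            for d in range(z):
                nb = nbr[site, d]
                if nb == exclude or occ[nb] == 0:
                    continue
                if stamp[nb] != epoch:
                    stamp[nb] = epoch
                    owner[nb] = survivor
                    queues[survivor, qtail[survivor]] = nb
                    qtail[survivor] += 1
                    csize[survivor] += 1
        for h in range(ngroups):
            if _find(parent, h) == survivor and qhead[h] < qtail[h]:
                trunc = True
                break
    n_comps = 0
    for g in range(ngroups):
        if parent[g] == g:
            comp_sizes[n_comps] = csize[g]
            comp_trunc[n_comps] = 1 if (g == survivor and trunc) else 0
            n_comps += 1
    return n_comps


@njit(cache=True)
def _classify(site, removal, occ, nbr, ring, cross, tbl_ng, tbl_gof, cap,
              stamp, owner, epoch, queues, qhead, qtail, parent, csize, final,
              comp_sizes, comp_trunc, seed_sites, seed_gids, out_sizes):
    # Returns (type_code, s): s is the pre-event patch size for removals
    # and the post-event merged size for additions, saturated at cap + 1.
    n_ring = ring.shape[1]
    z = nbr.shape[1]
    mask = 0
    for r in range(n_ring):
        if occ[ring[site, r]] == 1:
            mask |= 1 << r
    for i in range(4):
        out_sizes[i] = 0
    ng = np.int64(tbl_ng[mask])
    if ng == 0:
        return 0, 1  # loss / formation; singleton patch
    n_seeds = 0
    for d in range(z):
        g = np.int64(tbl_gof[mask, d])
        if g >= 0:
            seed_sites[n_seeds] = ring[site, cross[d]]
            seed_gids[n_seeds] = g
            n_seeds += 1
    exclude = site if removal else -1
    nc = _resolve(occ, nbr, exclude, seed_sites, seed_gids, n_seeds, ng, cap,
                  stamp, owner, epoch, queues, qhead, qtail, parent, csize,
                  final, comp_sizes, comp_trunc)
    capp = cap + 1
    if nc == 1:
        t = comp_sizes[0]
        tr = comp_trunc[0] == 1
        if removal:
            s = capp if (tr or t + 1 > cap) else t + 1
            out_sizes[0] = capp if (tr or t > cap) else t
            return 1, s  # shrinkage
        out_sizes[0] = capp if (tr or t > cap) else t
        s = capp if (tr or t + 1 > cap) else t + 1
        return 1, s  # enlargement
    total = 0
    any_tr = False
    for i in range(nc):
        t = comp_sizes[i]
        tr = comp_trunc[i] == 1
        out_sizes[i] = capp if (tr or t > cap) else t
        total += t
        any_tr = any_tr or tr
    # descending insertion sort of the (at most 4) component sizes
    for i in range(1, nc):
        v = out_sizes[i]
        j = i - 1
        while j >= 0 and out_sizes[j] < v:
            out_sizes[j + 1] = out_sizes[j]
            j -= 1
        out_sizes[j + 1] = v
    s = capp if (any_tr or total + 1 > cap) else total + 1
    return 2, s  # splitting / coalescence


@njit(cache=True)
def _sim(occ, perm, pos, n_h0, nbr, ring, cross, tbl_ng, tbl_gof, cap,
         n_swaps, state,
         rem_site, rem_type, rem_s, rem_after,
         add_site, add_type, add_after, add_parts,
         stamp, owner, queues, qhead, qtail, parent, csize, final,
         comp_sizes, comp_trunc, seed_sites, seed_gids, out_sizes):
    n = occ.shape[0]
    n_h = n_h0
    epoch = np.int64(0)
    for i in range(n_swaps):
        state, z1 = _next(state)
        ri = int(z1 % _U(n_h))
        state, z2 = _next(state)
        ai = int(z2 % _U(n - n_h))
        rs = perm[ri]
        ad = perm[n_h + ai]

        epoch += 1
        code, s = _classify(rs, True, occ, nbr, ring, cross, tbl_ng, tbl_gof,
                            cap, stamp, owner, epoch, queues, qhead, qtail,
                            parent, csize, final, comp_sizes, comp_trunc,
                            seed_sites, seed_gids, out_sizes)
        rem_site[i] = rs
        rem_type[i] = code
        rem_s[i] = s
        for k in range(4):
            rem_after[i, k] = out_sizes[k]
        occ[rs] = 0
        last = n_h - 1
        j = pos[rs]
        other = perm[last]
        perm[j] = other
        pos[other] = j
        perm[last] = rs
        pos[rs] = last
        n_h = last

        epoch += 1
        code, s = _classify(ad, False, occ, nbr, ring, cross, tbl_ng, tbl_gof,
                            cap, stamp, owner, epoch, queues, qhead, qtail,
                            parent, csize, final, comp_sizes, comp_trunc,
                            seed_sites, seed_gids, out_sizes)
        add_site[i] = ad
        add_type[i] = code
        add_after[i] = s
        for k in range(4):
            add_parts[i, k] = out_sizes[k]
        occ[ad] = 1
        j = pos[ad]
        other = perm[n_h]
        perm[j] = other
        pos[other] = j
        perm[n_h] = ad
        pos[ad] = n_h
        n_h += 1
    return state


def simulate(landscape, n_swaps: int, state: int, size_cap: int) -> EventBatch:
    """Run ``n_swaps`` swaps on ``landscape`` (mutated in place)."""
    if not HAVE_NUMBA:  # pragma: no cover
        raise RuntimeError("numba is not available; use the python engine")
    lat = landscape.lattice
    n = lat.n_sites
    occ = landscape.occ
    perm = np.concatenate(
        [np.flatnonzero(occ), np.flatnonzero(occ == 0)]
    ).astype(np.int64)
    pos = np.empty(n, np.int64)
    pos[perm] = np.arange(n, dtype=np.int64)

    rem_site = np.empty(n_swaps, np.int32)
    rem_type = np.empty(n_swaps, np.uint8)
    rem_s = np.empty(n_swaps, np.int64)
    rem_after = np.zeros((n_swaps, 4), np.int64)
    add_site = np.empty(n_swaps, np.int32)
    add_type = np.empty(n_swaps, np.uint8)
    add_after = np.empty(n_swaps, np.int64)
    add_parts = np.zeros((n_swaps, 4), np.int64)

    stamp = np.zeros(n, np.int64)
    owner = np.zeros(n, np.int32)
    queues = np.empty((4, n), np.int32)
    qhead = np.zeros(4, np.int64)
    qtail = np.zeros(4, np.int64)
    parent = np.zeros(4, np.int64)
    csize = np.zeros(4, np.int64)
    final = np.zeros(4, np.uint8)
    comp_sizes = np.zeros(4, np.int64)
    comp_trunc = np.zeros(4, np.uint8)
    seed_sites = np.zeros(8, np.int64)
    seed_gids = np.zeros(8, np.int64)
    out_sizes = np.zeros(4, np.int64)

    tbl_ng, tbl_gof = lat.ring_tables
    _sim(occ, perm, pos, landscape.n_habitat,
         lat.neighbor_array, lat.ring_array, lat.cross_positions,
         tbl_ng, tbl_gof, size_cap, n_swaps, _U(state),
         rem_site, rem_type, rem_s, rem_after,
         add_site, add_type, add_after, add_parts,
         stamp, owner, queues, qhead, qtail, parent, csize, final,
         comp_sizes, comp_trunc, seed_sites, seed_gids, out_sizes)

    return EventBatch(lat, landscape.q, size_cap, rem_site, rem_type, rem_s,
                      rem_after, add_site, add_type, add_after, add_parts)
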