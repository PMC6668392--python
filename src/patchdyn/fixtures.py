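"""Worked example grids and phase-illustration snapshots.

The three event fixtures per geometry are minimal configurations in
which removing the focal site produces each of the three removal-side
events (and, read in the opposite direction, adding it produces the
mirror event):

* ``isolated``  — the focal site is a single-site patch: removal = loss,
  addition = formation;
* ``perimeter`` — the focal site sits on the edge of a patch: removal =
  shrinkage, addition = enlargement;
* ``bottleneck`` — the focal site is the only connection between two
  lobes of a patch: removal = splitting (two fragments), addition =
  coalescence.

The snapshot fixtures are 20 x 20 random landscapes at the habitat-loss
levels 10%, 32.5%, 50%, 70% and 92.5% — mid-interval values
characteristic of the five degradation phases, used purely for
illustration.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .events import EventType
from .landscape import Landscape, random_landscape
from .lattice import HEX6, KINDS, SQUARE4, Lattice
from .raster import write_raster

#: Mid-interval habitat-loss levels of the five approximate phases.
PHASE_SNAPSHOT_Q = (0.10, 0.325, 0.50, 0.70, 0.925)
_SNAPSHOT_SIDE = 20
_SNAPSHOT_SEED = 771  # fixed so the shipped illustrations are reproducible

_FIXTURE_SIDE = 7
_FOCAL = (3, 3)


def _grid(sites: list[tuple[int, int]]) -> np.ndarray:
    g = np.zeros((_FIXTURE_SIDE, _FIXTURE_SIDE), dtype=np.uint8)
    for i, j in sites:
        g[i, j] = 1
    return g


def isolated_site_fixture(kind: str = HEX6) -> tuple[Landscape, int]:
    """Single-site patch; removing the focal site is a patch loss."""
    ls = Landscape.from_grid(kind, _grid([_FOCAL]))
    return ls, ls.lattice.site_index(*_FOCAL)


def perimeter_site_fixture(kind: str = HEX6) -> tuple[Landscape, int]:
    """Focal site on a patch perimeter; removal shrinks the patch 4 -> 3."""
    ls = Landscape.from_grid(kind, _grid([(2, 2), (3, 1), (3, 2), _FOCAL]))
    return ls, ls.lattice.site_index(*_FOCAL)


def bottleneck_site_fixture(kind: str = HEX6) -> tuple[Landscape, int]:
    """Focal site bridges two lobes; removal splits the patch 5 -> {2, 2}."""
    ls = Landscape.from_grid(
        kind, _grid([(3, 1), (3, 2), _FOCAL, (3, 4), (3, 5)])
    )
    return ls, ls.lattice.site_index(*_FOCAL)


EVENT_FIXTURES = {
    "isolated": (isolated_site_fixture, EventType.LOSS, EventType.FORMATION),
    "perimeter": (perimeter_site_fixture, EventType.SHRINKAGE, EventType.ENLARGEMENT),
    "bottleneck": (bottleneck_site_fixture, EventType.SPLITTING, EventType.COALESCENCE),
}


def phase_snapshot(q: float, side: int = _SNAPSHOT_SIDE, kind: str = HEX6,
                   seed: int = _SNAPSHOT_SEED) -> Landscape:
    """Random landscape at habitat loss q, for illustration."""
    derived = np.random.SeedSequence([seed, int(round(q * 1000))])
    return random_landscape(Lattice(kind, side), 1.0 - q, derived)


def make_fixtures(outdir: os.PathLike | str) -> list[Path]:
    """Write all fixture rasters plus a manifest; returns the raster paths.

    3 hex + 3 square event fixtures and 5 phase snapshots (11 rasters).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = []
    for kind in KINDS:
        for name, (builder, rem_ev, add_ev) in EVENT_FIXTURES.items():
            ls, focal = builder(kind)
            path = outdir / f"{kind}_{name}.txt"
            write_raster(ls, path)
            written.append(path)
            manifest.append({
                "file": path.name,
                "kind": kind,
                "focal": list(ls.lattice.coords(focal)),
                "removal_event": rem_ev.value,
                "addition_event": add_ev.value,
            })
    for q in PHASE_SNAPSHOT_Q:
        ls = phase_snapshot(q)
        path = outdir / f"snapshot_hex6_q{q:g}.txt"
        write_raster(ls, path)
        written.append(path)
        manifest.append({"file": path.name, "kind": HEX6, "q": q,
                         "side": _SNAPSHOT_SIDE})
    with open(outdir / "manifest.json", "w", encoding="ascii") as fh:
        json.dump(manifest, fh, indent=2)
    return written
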