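"""Event classification, swap dynamics and engine consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import patchdyn as pdn
from patchdyn import fixtures as fx
from patchdyn._rng import SplitMix64
from patchdyn.events import (
    DEFAULT_SIZE_CAP,
    EventType,
    SimulationStateError,
    SiteStateError,
    _python_engine,
)

from conftest import BOTH_KINDS, random_ls


class TestWorkedConfigurations:
    """The three removal events and their addition-side mirrors on the
    minimal worked grids, for both geometries."""

    @pytest.mark.parametrize("name", list(fx.EVENT_FIXTURES))
    def test_removal_and_mirror_addition(self, kind, name):
        builder, rem_ev, add_ev = fx.EVENT_FIXTURES[name]
        ls, focal = builder(kind)
        rec = pdn.classify_removal(ls, focal)
        assert rec.event_type is rem_ev
        # reading the same configuration in the opposite direction
        bare = ls.copy()
        bare.set_site(focal, 0)
        mirror = pdn.classify_addition(bare, focal)
        assert mirror.event_type is add_ev
        # the mirror case has the sizes reversed
        assert mirror.sizes_before == rec.sizes_after
        assert mirror.sizes_after == rec.sizes_before

    def test_bottleneck_sizes(self, kind):
        ls, focal = fx.bottleneck_site_fixture(kind)
        rec = pdn.classify_removal(ls, focal)
        assert rec.sizes_before == (5,)
        assert rec.sizes_after == (2, 2)

    def test_three_way_split_is_representable(self):
        """A T-shaped patch on square4 splits into three fragments."""
        g = np.zeros((7, 7), np.uint8)
        for ij in [(3, 3), (2, 3), (1, 3), (4, 3), (3, 4), (3, 5)]:
            g[ij] = 1
        ls = pdn.Landscape.from_grid(pdn.SQUARE4, g)
        rec = pdn.classify_removal(ls, ls.lattice.site_index(3, 3))
        assert rec.event_type is EventType.SPLITTING
        assert rec.sizes_before == (6,)
        assert sorted(rec.sizes_after) == [1, 2, 2]

    def test_enlargement_all_neighbors_one_patch(self):
        g = np.zeros((5, 5), np.uint8)
        for ij in [(1, 2), (3, 2), (2, 1), (2, 3), (1, 1), (1, 3), (3, 1), (3, 3)]:
            g[ij] = 1
        ls = pdn.Landscape.from_grid(pdn.SQUARE4, g)
        rec = pdn.classify_addition(ls, ls.lattice.site_index(2, 2))
        assert rec.event_type is EventType.ENLARGEMENT
        assert rec.sizes_before == (8,)
        assert rec.sizes_after == (9,)

    def test_preconditions(self):
        ls, focal = fx.isolated_site_fixture()
        with pytest.raises(SiteStateError):
            pdn.classify_addition(ls, focal)  # focal is habitat
        with pytest.raises(SiteStateError):
            pdn.classify_removal(ls, focal + 1)  # a non-habitat site

    def test_classification_does_not_mutate(self, kind):
        ls, focal = fx.bottleneck_site_fixture(kind)
        before = ls.occ.copy()
        pdn.classify_removal(ls, focal)
        assert np.array_equal(ls.occ, before)


class TestOracleAgreement:
    def test_random_trials_match_relabel_oracle(self, kind):
        """Fast local classifier vs full-relabel oracle: exact agreement
        of event type and all patch sizes on random landscapes."""
        rng = np.random.default_rng(101)
        trials = 0
        while trials < 600:
            ls = random_ls(kind, 12, rng.uniform(0.15, 0.85), rng)
            for site in rng.integers(0, ls.lattice.n_sites, 20):
                site = int(site)
                if ls.occ[site]:
                    fast = pdn.classify_removal(ls, site)
                    oracle = pdn.classify_removal_by_relabel(ls, site)
                else:
                    fast = pdn.classify_addition(ls, site)
                    oracle = pdn.classify_addition_by_relabel(ls, site)
                assert fast.event_type == oracle.event_type
                assert fast.sizes_before == oracle.sizes_before
                assert fast.sizes_after == oracle.sizes_after
                trials += 1

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           kind=st.sampled_from(BOTH_KINDS),
           p=st.floats(0.1, 0.9))
    def test_classifier_matches_oracle_property(self, seed, kind, p):
        rng = np.random.default_rng(seed)
        ls = random_ls(kind, 8, p, rng)
        site = int(rng.integers(ls.lattice.n_sites))
        if ls.occ[site]:
            fast = pdn.classify_removal(ls, site)
            oracle = pdn.classify_removal_by_relabel(ls, site)
        else:
            fast = pdn.classify_addition(ls, site)
            oracle = pdn.classify_addition_by_relabel(ls, site)
        assert (fast.event_type, fast.sizes_before, fast.sizes_after) == \
            (oracle.event_type, oracle.sizes_before, oracle.sizes_after)


class TestSizeInvariants:
    def test_fragments_sum_and_mirror_identities(self, kind):
        """Splitting fragments sum to s − 1; coalescence merges to the
        sum of the parts plus one (random exact-mode trials)."""
        rng = np.random.default_rng(55)
        seen_split = seen_coal = 0
        for _ in range(300):
            ls = random_ls(kind, 10, rng.uniform(0.3, 0.7), rng)
            site = int(rng.integers(ls.lattice.n_sites))
            if ls.occ[site]:
                rec = pdn.classify_removal(ls, site)
                assert sum(rec.sizes_after) == rec.sizes_before[0] - 1
                seen_split += rec.event_type is EventType.SPLITTING
            else:
                rec = pdn.classify_addition(ls, site)
                assert rec.sizes_after[0] == sum(rec.sizes_before) + 1
                seen_coal += rec.event_type is EventType.COALESCENCE
        assert seen_split > 0 and seen_coal > 0

    def test_saturation_semantics(self):
        """With a size cap c, sizes <= c are exact and larger sizes are
        reported as c + 1."""
        ls = pdn.random_landscape(pdn.Lattice(pdn.HEX6, 20), 0.9, seed=4)
        site = int(ls.habitat_sites()[10])
        exact = pdn.classify_removal(ls, site)
        capped = pdn.classify_removal(ls, site, size_cap=5)
        assert capped.event_type is exact.event_type
        for got, true in zip(capped.sizes_before, exact.sizes_before):
            assert got == (6 if true > 5 else true)
        for got, true in zip(capped.sizes_after, exact.sizes_after):
            assert got == (6 if true > 5 else true)


class TestSwapDynamics:
    def test_swap_conserves_density_and_avoids_readding(self, kind):
        rng = np.random.default_rng(8)
        ls = random_ls(kind, 12, 0.5, rng)
        n0 = ls.n_habitat
        for _ in range(60):
            rem, add = pdn.apply_swap(ls, rng)
            assert ls.n_habitat == n0
            assert rem.is_removal and add.is_addition
            assert rem.site != add.site  # addition drawn from pre-swap empties

    def test_swap_requires_mixed_state(self):
        lat = pdn.Lattice(pdn.HEX6, 5)
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationStateError):
            pdn.apply_swap(pdn.random_landscape(lat, 1.0, seed=0), rng)
        with pytest.raises(SimulationStateError):
            pdn.apply_swap(pdn.random_landscape(lat, 0.0, seed=0), rng)

    def test_run_events_validation(self):
        lat = pdn.Lattice(pdn.HEX6, 10)
        with pytest.raises(ValueError):
            pdn.run_events(lat, 0.5, 101, seed=0)  # odd
        with pytest.raises(ValueError):
            pdn.run_events(lat, 0.5, 0, seed=0)
        with pytest.raises(SimulationStateError):
            pdn.run_events(lat, 0.0, 100, seed=0)  # full lattice
        with pytest.raises(SimulationStateError):
            pdn.run_events(lat, 1.0, 100, seed=0)  # empty lattice

    def test_tally_partition(self, kind):
        tally = pdn.run_events(pdn.Lattice(kind, 30), 0.5, 5000, seed=3)
        assert tally.n_removals == tally.n_additions == 2500
        probs = tally.removal_probabilities()
        assert sum(p for p, _ in probs.values()) == pytest.approx(1.0)

    def test_determinism(self, kind):
        a = pdn.run_events(pdn.Lattice(kind, 20), 0.4, 4000, seed=5)
        b = pdn.run_events(pdn.Lattice(kind, 20), 0.4, 4000, seed=5)
        assert a.counts == b.counts

    def test_extreme_q_regimes(self):
        """Near-total loss is dominated by patch loss; near-pristine
        landscapes shrink almost exclusively."""
        lat = pdn.Lattice(pdn.HEX6, 100)
        high = pdn.run_events(lat, 0.95, 10_000, seed=2)
        c = high.counts
        assert c[EventType.LOSS] > c[EventType.SHRINKAGE]
        assert c[EventType.LOSS] > c[EventType.SPLITTING]
        low = pdn.run_events(lat, 0.10, 10_000, seed=2)
        assert low.counts[EventType.SHRINKAGE] / low.n_removals > 0.99

    def test_observer_receives_all_records(self):
        class Collect:
            def __init__(self):
                self.records = []

            def observe(self, rec):
                self.records.append(rec)

        obs = Collect()
        tally = pdn.run_events(pdn.Lattice(pdn.HEX6, 15), 0.5, 400, seed=1,
                               observers=[obs])
        assert len(obs.records) == 400
        assert sum(r.is_removal for r in obs.records) == tally.n_removals


class TestEngineEquivalence:
    @pytest.mark.parametrize("q", [0.3, 0.6])
    def test_numba_and_python_engines_identical(self, kind, q):
        """Both engines draw the same stream and must produce identical
        event sequences, sizes included."""
        from patchdyn import _kernels

        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba not available")
        lat = pdn.Lattice(kind, 15)
        _, b1 = pdn.run_events(lat, q, 3000, seed=21, engine="numba",
                               return_batch=True)
        _, b2 = pdn.run_events(lat, q, 3000, seed=21, engine="python",
                               return_batch=True)
        for f in ("rem_site", "rem_type", "rem_s", "rem_after",
                  "add_site", "add_type", "add_after", "add_parts"):
            assert np.array_equal(getattr(b1, f), getattr(b2, f)), f

    def test_splitmix_reference_values_stable(self):
        rng = SplitMix64(12345)
        first = [rng.next_u64() for _ in range(3)]
        rng2 = SplitMix64(12345)
        assert first == [rng2.next_u64() for _ in range(3)]


class TestStationarity:
    def test_patch_count_stable_over_time(self):
        """The uniform random start is already stationary under swap
        dynamics: patch-count statistics do not drift between early and
        late sweeps (replicate-averaged)."""
        from patchdyn import _kernels
        from patchdyn.landscape import label_patches

        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba not available")
        lat = pdn.Lattice(pdn.HEX6, 30)
        early, late = [], []
        for rep in range(4):
            ls = pdn.random_landscape(lat, 0.5, seed=300 + rep)
            counts = []
            for chunk in range(30):
                _kernels.simulate(ls, 900, state=rep * 1000 + chunk, size_cap=8)
                counts.append(len(label_patches(ls)[1]))
            early.append(np.mean(counts[:10]))
            late.append(np.mean(counts[-10:]))
        diff = np.mean(late) - np.mean(early)
        se = np.sqrt(np.var(early, ddof=1) / 4 + np.var(late, ddof=1) / 4)
        assert abs(diff) < 4 * se + 0.02 * np.mean(early)
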