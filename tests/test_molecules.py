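"""Molecular rule set: state machines and stochastic interaction rules."""

import numpy as np
import pytest

import endosim as es
from endosim import molecules as mol


def _binding_fixture(seed=1, sens=5):
    """One macrophage, one open TLR4 at the given sensitivity, one free LPS
    parked in contact with it."""
    w = es.build_fixture("one_receptor_one_lps", seed=seed)
    w.macrophages[0].tlr4_sens[0] = sens
    return w


def _reset_binding(w):
    mac = w.macrophages[0]
    w.lps["bound"][0] = 0
    w.lps["decay_at"][0] = -1
    mac.tlr4_occupied_until[0] = 0
    mac.tlr4_sens[0] = 5
    if w.tnf.n:
        w.tnf.remove(np.ones(w.tnf.n, dtype=bool))


class TestLpsBinding:
    def test_sensitivity_one_never_binds(self):
        # no integer in 1..5 is < 1, so P(bind | s=1) = 0 and the
        # sensitivity counter can never fall below 1 through binding
        w = _binding_fixture(sens=1)
        for _ in range(300):
            assert not mol.attempt_lps_binding(w, 0, 0, 0)
        assert w.macrophages[0].tlr4_sens[0] == 1

    @pytest.mark.parametrize("sens,expected", [(5, 0.8), (3, 0.4), (2, 0.2)])
    def test_binding_probability_matches_enumeration(self, sens, expected):
        # P(bind | s) = (s-1)/5: the integers 1..s-1 out of 1..5 succeed
        w = _binding_fixture(seed=2)
        n, hits = 10_000, 0
        for _ in range(n):
            w.macrophages[0].tlr4_sens[0] = sens
            hits += mol.attempt_lps_binding(w, 0, 0, 0)
            _reset_binding(w)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se + 1e-12

    def test_successful_binding_side_effects(self):
        w = _binding_fixture(seed=3)
        mac = w.macrophages[0]
        while not mol.attempt_lps_binding(w, 0, 0, 0):
            _reset_binding(w)
        assert w.lps["bound"][0] == 1
        assert 1 <= w.lps["decay_at"][0] - w.tick <= 2
        assert mac.tlr4_sens[0] == 4              # decremented
        assert mac.tlr4_occupied_until[0] > w.tick
        assert w.tnf.n == 1                       # 1 TNF-a spawned

    def test_occupied_receptor_is_noop(self):
        w = _binding_fixture(seed=4)
        w.macrophages[0].tlr4_occupied_until[0] = 10**9
        assert not mol.attempt_lps_binding(w, 0, 0, 0)

    def test_bound_lps_removed_within_two_ticks(self):
        w = _binding_fixture(seed=5)
        for _ in range(600):
            w.step()
            if w.lps.n and w.lps["bound"].max() == 1:
                break
        assert w.lps.n == 1 and w.lps["bound"][0] == 1
        bound_tick = w.tick
        while w.lps.n:
            w.step()
        assert w.tick - bound_tick <= 2

    def test_repeat_binding_drives_sensitivity_to_floor(self):
        # successive bindings desensitise the receptor down to s=1, where
        # the binding probability reaches zero (the paper's saturation)
        w = _binding_fixture(seed=6)
        mac = w.macrophages[0]
        for _ in range(2000):
            if mol.attempt_lps_binding(w, 0, 0, 0):
                w.lps["bound"][0] = 0
                mac.tlr4_occupied_until[0] = 0
            if mac.tlr4_sens[0] == 1:
                break
        assert mac.tlr4_sens[0] == 1


class TestTlr4Production:
    def test_one_tnf_per_hundred_ticks_of_activation(self, cell_world):
        w = cell_world
        mac = w.macrophages[0]
        mac.tlr4_act_start[0] = w.tick
        mac.tlr4_act_until[0] = w.tick + 100
        produced = []
        for _ in range(120):
            before = w.tnf.n
            w.tick += 1
            mol.tlr4_phase(w)
            if w.tnf.n > before:
                produced.append(w.tick - mac.tlr4_act_start[0])
        assert produced == [100]

    def test_no_production_at_99_ticks(self, cell_world):
        w = cell_world
        mac = w.macrophages[0]
        mac.tlr4_act_start[0] = w.tick
        mac.tlr4_act_until[0] = w.tick + 99
        for _ in range(99):
            w.tick += 1
            mol.tlr4_phase(w)
        assert w.tnf.n == 0

    def test_inactive_receptor_produces_nothing(self, cell_world):
        w = cell_world
        for _ in range(300):
            w.tick += 1
            mol.tlr4_phase(w)
        assert w.tnf.n == 0


class TestTnfLifecycle:
    def test_free_tnf_lives_exactly_600_ticks(self, empty_world):
        w = empty_world
        w.spawn_tnf(np.array([[30.0, 30.0]]))
        for _ in range(599):
            w.step()
        assert w.tnf.n == 1
        w.step()
        assert w.tnf.n == 0

    def _bind_tnf(self, w):
        w.spawn_tnf(w.random_perimeter_xy(0, 30))
        while w.tnf.n and not w.tnf["bound"].max():
            w.step()
        assert w.tnf.n, "no TNF bound before the cohort expired"
        return w.tick

    def test_bound_decay_50_without_il4(self, small_params):
        w = es.World(small_params, seed=21)
        t0 = self._bind_tnf(w)
        j = int(np.argmax(w.tnf["bound"]))
        assert w.tnf["remove_at"][j] - t0 == 50

    def test_bound_decay_200_with_nearby_bound_il4(self, small_params):
        w = es.World(small_params, seed=22)
        w.macrophages[0].il4r_occupied_until[:] = 10**9  # bound IL-4 present
        t0 = self._bind_tnf(w)
        j = int(np.argmax(w.tnf["bound"]))
        assert w.tnf["remove_at"][j] - t0 == 200

    def test_alternative_reading_swaps_constants(self, small_params):
        small_params.molecules.il4_extends_tnf = False
        w = es.World(small_params, seed=23)
        w.macrophages[0].il4r_occupied_until[:] = 10**9
        t0 = self._bind_tnf(w)
        j = int(np.argmax(w.tnf["bound"]))
        assert w.tnf["remove_at"][j] - t0 == 50


class TestIkk:
    def _pair_world(self, seed=1):
        w = es.build_fixture("single_macrophage", seed=seed)
        mac = w.macrophages[0]
        w.nfkb.remove(np.ones(w.nfkb.n, dtype=bool))
        spot = mac.center + np.array([mac.nucleus_radius + 2.0, 0.0])
        w.nfkb.add(x=spot[0], y=spot[1], cell=0, state=mol.NFKB_COMPLEXED,
                   release_at=-1, next_tx=-1)
        w.ikk.add(x=spot[0], y=spot[1], cell=0, state=mol.IKK_ACTIVE,
                  expire_at=10**9, release_at=-1)
        return w

    def test_binding_probability_70_percent(self):
        w = self._pair_world(seed=31)
        n, hits = 10_000, 0
        for _ in range(n):
            if mol.ikk_bind_nfkb(w, 0, 0):
                hits += 1
                w.ikk["state"][0] = mol.IKK_ACTIVE
                w.nfkb["state"][0] = mol.NFKB_COMPLEXED
        p = w.params.molecules.p_bind_ikk
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_binding_requires_inactive_complex(self):
        w = self._pair_world(seed=32)
        w.nfkb["state"][0] = mol.NFKB_ACTIVE_CYT
        assert not any(mol.ikk_bind_nfkb(w, 0, 0) for _ in range(100))

    def test_dissociation_after_10_ticks_frees_active_nfkb(self):
        # bind at T; at T+10 IKK dissociates (spent) and NF-kB activates,
        # its IkBa partner having been ubiquitinated
        w = self._pair_world(seed=33)
        while not mol.ikk_bind_nfkb(w, 0, 0):
            pass
        t_bind = w.tick
        ubiq0 = w.counters["ikba_ubiquitinated"]
        for _ in range(10):
            w.step()
        assert w.tick == t_bind + 10
        assert w.nfkb["state"][0] in (mol.NFKB_ACTIVE_CYT, mol.NFKB_NUCLEAR)
        assert w.counters["ikba_ubiquitinated"] == ubiq0 + 1
        # single catalytic act: the bound kinase itself is spent (only
        # freshly produced inactive IKK may remain)
        assert not np.any(w.ikk["expire_at"] == 10**9) if w.ikk.n else True

    def test_lifetime_draws_uniform_1_to_799(self, cell_world):
        w = cell_world
        from endosim import cells
        draws = []
        while len(draws) < 10_000:
            w.tick += w.params.molecules.ikk_prod_interval
            before = w.ikk.n
            cells.macrophage_phase(w)
            for i in range(before, w.ikk.n):
                draws.append(int(w.ikk["expire_at"][i] - w.tick))
            if w.ikk.n > 5000:
                w.ikk.remove(np.ones(w.ikk.n, dtype=bool))
        draws = np.asarray(draws[:10_000])
        assert draws.min() >= 1 and draws.max() <= 799
        assert abs(draws.mean() - 400) < 7

    def test_activation_by_tnf_complex(self, small_params):
        w = es.World(small_params, seed=35)
        mac = w.macrophages[0]
        for _ in range(3):
            xy = w.random_cytosol_xy(0, 1)
            w.ikk.add(x=xy[0, 0], y=xy[0, 1], cell=0, state=mol.IKK_INACTIVE,
                      expire_at=10**9, release_at=-1)
        w.tick += 1
        mol.ikk_phase(w)
        assert np.count_nonzero(w.ikk["state"] == mol.IKK_ACTIVE) == 0
        mac.tnfr_occupied_until[0] = w.tick + 50  # a complex now exists
        w.tick += 1
        mol.ikk_phase(w)
        # all three activated (some may already have bound an NF-kB complex
        # in the same phase)
        assert np.count_nonzero(w.ikk["state"] != mol.IKK_INACTIVE) == 3


class TestTranscription:
    def test_products_over_1000_cycles_switch_off(self):
        w = es.build_fixture("nfkb_unit", seed=41)
        w.macrophages[0].energy = 10**9  # hold the switch OFF
        w.macrophages[0].energy_init = 10**9
        il12 = ikba = tnf = 0
        for _ in range(1000):
            out = mol.nfkb_transcribe(w, 0)
            il12 += out["il12"]
            ikba += out["ikba"]
            tnf += out["tnf"]
            for pool in (w.il12, w.tnf, w.ikba):
                if pool.n > 500:
                    pool.remove(np.ones(pool.n, dtype=bool))
        assert ikba == 1000
        assert tnf == 1000
        se = np.sqrt(0.8 * 0.2 / 1000)
        assert abs(il12 / 1000 - 0.8) < 3 * se

    def test_amplified_tnf_when_switch_on(self):
        w = es.build_fixture("nfkb_unit", seed=42)
        mac = w.macrophages[0]
        mac.energy = 0.0
        mac.switch_on = True
        total = sum(mol.nfkb_transcribe(w, 0)["tnf"] for _ in range(10))
        assert total == 20  # default amplification factor 2

    def test_bound_il4_attenuates_tnf_on_healthy_cell(self):
        w = es.build_fixture("nfkb_unit", seed=43)
        mac = w.macrophages[0]
        mac.energy = 10**9
        mac.il4r_occupied_until[:] = 10**9
        total = sum(mol.nfkb_transcribe(w, 0)["tnf"] for _ in range(10))
        assert total == 0

    def test_transcription_costs_energy(self):
        w = es.build_fixture("nfkb_unit", seed=44)
        mac = w.macrophages[0]
        e0 = mac.energy
        mol.nfkb_transcribe(w, 0)
        assert mac.energy == e0 - 1


class TestIkba:
    def test_inhibit_within_radius_forms_inactive_complex(self):
        w = es.build_fixture("nfkb_unit", seed=51)
        mac = w.macrophages[0]
        w.ikba.add(x=w.nfkb["x"][0] + 0.5, y=w.nfkb["y"][0], cell=0)
        target = mol.ikba_inhibit(w, 0)
        assert target == 0
        assert w.nfkb["state"][0] == mol.NFKB_COMPLEXED

    def test_no_binding_beyond_radius(self):
        w = es.build_fixture("nfkb_unit", seed=52)
        w.ikba.add(x=w.nfkb["x"][0] + 1.5, y=w.nfkb["y"][0], cell=0)
        assert mol.ikba_inhibit(w, 0) is None
        assert w.nfkb["state"][0] == mol.NFKB_NUCLEAR

    def test_one_partner_each(self):
        # two activated IkBa, one activated NF-kB: exactly one binds
        w = es.build_fixture("nfkb_unit", seed=53)
        for dx in (0.4, 0.6):
            w.ikba.add(x=w.nfkb["x"][0] + dx, y=w.nfkb["y"][0], cell=0)
        mol.ikba_phase(w)
        assert w.nfkb["state"][0] == mol.NFKB_COMPLEXED
        assert w.ikba.n == 1  # the second remains activated


class TestIl4Production:
    def test_no_free_il12_means_no_il4(self, empty_world):
        assert mol.il4_production_cycle(empty_world) == 0

    def test_yield_statistics(self, empty_world):
        w = empty_world
        w.il12.add(x=50.0, y=50.0, expire_at=10**18)
        n = 10_000
        spawned = []
        for _ in range(n):
            spawned.append(mol.il4_production_cycle(w))
            if w.il4.n > 5000:
                w.il4.remove(np.ones(w.il4.n, dtype=bool))
        spawned = np.asarray(spawned)
        frac3 = np.mean(spawned == 3)
        se = np.sqrt(0.86 * 0.14 / n)
        assert abs(frac3 - 0.86) < 3 * se
        assert abs(spawned.mean() - 3 * 0.86) < 0.05

    def test_cycle_interval_uniform_1_to_5(self, empty_world):
        w = empty_world
        w.il12.add(x=50.0, y=50.0, expire_at=10**18)
        intervals = []
        for _ in range(10_000):
            w.tick = w.next_il4_cycle
            before = w.next_il4_cycle
            mol.cytokine_phase(w)
            intervals.append(w.next_il4_cycle - before)
            if w.il4.n > 5000:
                w.il4.remove(np.ones(w.il4.n, dtype=bool))
        intervals = np.asarray(intervals)
        assert intervals.min() >= 1 and intervals.max() <= 5
        assert abs(intervals.mean() - 3.0) < 0.1


class TestInhibitor:
    def test_contact_neutralises_ikk_one_to_one(self, cell_world):
        w = cell_world
        xy = w.random_cytosol_xy(0, 1)
        w.ikk.add(x=xy[0, 0], y=xy[0, 1], cell=0, state=mol.IKK_ACTIVE,
                  expire_at=10**9, release_at=-1)
        w.inh.add(x=xy[0, 0], y=xy[0, 1])
        for _ in range(5):   # the inhibitor roams; contact within a few ticks
            mol.inhibitor_update(w)
            if w.ikk.n == 0:
                break
        assert w.ikk.n == 0
        assert w.inh.n == 0
        assert w.counters["ikk_inhibited"] == 1

    def test_persists_with_no_ikk(self, empty_world):
        w = empty_world
        w.inh.add(x=10.0, y=10.0)
        for _ in range(50):
            w.step()
        assert w.inh.n == 1

    def test_stoichiometric_bound(self, small_params):
        # more inhibitor than kinase ever produced: consumption events are
        # capped by the number of IKK agents
        small_params.molecules.ikk_lifetime_min = 799
        w = es.World(small_params, seed=61)
        w.spawn_inhibitor(w.random_nucleus_free_xy(200))
        mac = w.macrophages[0]
        mac.tnfr_occupied_until[0] = 10**9  # keep IKK activated
        w.run(250)  # 50 IKK produced at 1 per 5 ticks
        produced = 250 // w.params.molecules.ikk_prod_interval
        # every kinase is accounted for: neutralised by inhibitor, spent
        # catalytically, or still alive -- and consumption events can never
        # exceed the number of kinase agents that ever existed
        accounted = (w.counters["ikk_inhibited"] + w.counters["ikk_spent"]
                     + w.counters["ikk_deactivated_by_ikba"] + w.ikk.n)
        assert accounted == produced
        assert w.counters["ikk_inhibited"] <= produced
        assert w.inh.n == 200 - w.counters["ikk_inhibited"]
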