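"""Torus world, discrete-tick scheduler and movement/containment rules.

One call to :meth:`World.step` advances the simulation by exactly one tick,
executing the phases in a fixed order:

1. apply due dose events;
2. LPS movement and receptor binding;
3. TLR4 TNF-α production;
4. TNF-α movement, TNFR binding and decay;
5. macrophage IKK production and (when due) chemotactic movement;
6. IKK-inhibitor competition, IKK activation/binding/lifetime;
7. NF-κB translocation and transcription;
8. IκBα inhibition;
9. cytokine (IL-12/IL-4) movement, binding and production;
10. Th recruitment, differentiation and secretion;
11. energy/switch update;
12. observables recording.

Within a phase, agents are processed in creation order with draws taken from
the world's single seeded random stream, so an identical (config, seed) pair
reproduces a bit-identical trajectory.

Movement cadence encodes the published 800:1 frequency ratio between
molecular and cellular agents: molecules move every tick, cells once per
``cell_move_interval`` ticks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import cells as _cells
from . import molecules as _mol
from . import observables as _obs
from ._pool import Pool
from .geometry import heading_to_unit, torus_dist, wrap as _wrap
from .params import Params

#: containment classes understood by the movement helpers
CONTAINMENT_KINDS = ("membrane_blocked", "nucleus_blocked", "cytosol",
                     "cell_interior", "nucleus_interior")


def wrap(pos: np.ndarray, world: "World") -> np.ndarray:
    """Map a position onto the world torus."""
    return _wrap(np.asarray(pos, dtype=float), world.width, world.height)


def movement_due(agent_class: str, tick: int, params: Params) -> bool:
    """Whether agents of a mobility class move on this tick.

    ``molecular`` agents (LPS, cytokines, intracellular molecules) move every
    tick; ``cellular`` agents (macrophages, Th cells) once per
    ``cell_move_interval`` ticks, which realises the 800x molecular:cellular
    movement-frequency ratio.
    """
    if agent_class == "molecular":
        return True
    if agent_class == "cellular":
        return tick > 0 and tick % params.engine.cell_move_interval == 0
    raise ValueError(f"unknown agent class: {agent_class!r}")


def random_walk(pos: np.ndarray, step_len: float,
                rng: np.random.Generator) -> np.ndarray:
    """Propose one unbiased random-walk move: a fresh uniform heading and
    ``step_len`` forward.  Containment is the caller's concern."""
    heading = rng.uniform(0.0, 360.0)
    return np.asarray(pos, dtype=float) + step_len * heading_to_unit(heading)


class World:
    """The full simulation state (agents, clock, RNG, parameters)."""

    def __init__(self, params: Params, seed: int,
                 doses: Sequence[tuple[int, str, int]] = (),
                 n_macrophages: int | None = None):
        params.validate()
        self.params = params
        self.width = float(params.engine.width)
        self.height = float(params.engine.height)
        self.rng = np.random.default_rng(seed)
        self.seed = int(seed)
        self.tick = 0
        #: pending (tick, species, amount), sorted by tick
        self.dose_queue: list[tuple[int, str, int]] = sorted(
            (int(t), s, int(a)) for t, s, a in doses)
        self.counters = {
            "ikba_transcribed": 0,
            "ikba_ubiquitinated": 0,
            "ikk_deactivated_by_ikba": 0,
            "ikk_inhibited": 0,
            "ikk_spent": 0,
        }

        f8, i8, i32, i64 = np.float64, np.int8, np.int32, np.int64
        self.lps = Pool({"x": f8, "y": f8, "bound": i8, "decay_at": i64})
        self.tnf = Pool({"x": f8, "y": f8, "bound": i8, "remove_at": i64})
        self.il12 = Pool({"x": f8, "y": f8, "expire_at": i64})
        self.il4 = Pool({"x": f8, "y": f8, "expire_at": i64})
        self.inh = Pool({"x": f8, "y": f8})
        self.ikk = Pool({"x": f8, "y": f8, "cell": i32, "state": i8,
                         "expire_at": i64, "release_at": i64})
        self.nfkb = Pool({"x": f8, "y": f8, "cell": i32, "state": i8,
                          "release_at": i64, "next_tx": i64})
        self.ikba = Pool({"x": f8, "y": f8, "cell": i32})
        self.th = Pool({"x": f8, "y": f8, "kind": i8, "il12": i64,
                        "il4": i64, "next_secrete": i64})

        n_cells = (params.engine.n_macrophages if n_macrophages is None
                   else n_macrophages)
        self.macrophages: list[_cells.Macrophage] = []
        self._place_macrophages(n_cells)
        for ci in range(len(self.macrophages)):
            xy = self.random_cytosol_xy(ci, params.cells.n_nfkb)
            self.nfkb.add(x=xy[:, 0], y=xy[:, 1], cell=ci,
                          state=_mol.NFKB_COMPLEXED, release_at=-1, next_tx=-1)

        self.next_il4_cycle = int(self.rng.integers(
            params.molecules.il4_interval_min,
            params.molecules.il4_interval_max + 1))
        self.reset_nfkb_baseline()
        self.history: list[tuple] = [_obs.record(self)]

    def reset_nfkb_baseline(self) -> None:
        """Record the per-cell NF-κB census the conservation audit holds
        the simulation to (call after hand-editing pools in fixtures)."""
        self._nfkb_baseline = [
            int(np.count_nonzero(self.nfkb["cell"] == ci))
            for ci in range(len(self.macrophages))]

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def _place_macrophages(self, n: int) -> None:
        """Random non-overlapping placement (rejection sampling)."""
        c = self.params.cells
        min_sep = 2.0 * (c.cell_radius + 1.0)
        centers: list[np.ndarray] = []
        for _ in range(n):
            for _attempt in range(10_000):
                xy = np.array([self.rng.uniform(0.0, self.width),
                               self.rng.uniform(0.0, self.height)])
                if all(torus_dist(xy, c0, self.width, self.height) >= min_sep
                       for c0 in centers):
                    centers.append(xy)
                    break
            else:
                raise RuntimeError(
                    "could not place macrophages without overlap; "
                    "world too small for the requested count/radius")
        for xy in centers:
            self.macrophages.append(_cells.build_macrophage(xy, self.params))

    # ------------------------------------------------------------------
    # spatial helpers
    # ------------------------------------------------------------------
    @property
    def cell_centers(self) -> np.ndarray:
        if not self.macrophages:
            return np.empty((0, 2))
        return np.stack([m.center for m in self.macrophages])

    def random_extracellular_xy(self, n: int) -> np.ndarray:
        """Uniform positions outside every macrophage membrane."""
        out = np.empty((n, 2))
        filled = 0
        radius = self.params.cells.cell_radius + 0.5
        centers = self.cell_centers
        for _ in range(1000):
            if filled >= n:
                break
            cand = self.rng.uniform([0, 0], [self.width, self.height],
                                    size=(n - filled, 2))
            if centers.shape[0]:
                d = torus_dist(cand[:, None, :], centers[None, :, :],
                               self.width, self.height)
                cand = cand[(d >= radius).all(axis=1)]
            out[filled:filled + cand.shape[0]] = cand
            filled += cand.shape[0]
        if filled < n:
            raise RuntimeError("no extracellular space to place agents")
        return out

    def random_cytosol_xy(self, cell: int, n: int) -> np.ndarray:
        """Positions in the cytosolic annulus of one macrophage."""
        mac = self.macrophages[cell]
        r = self.rng.uniform(mac.nucleus_radius + 0.5, mac.cell_radius - 0.5, n)
        ang = self.rng.uniform(0.0, 360.0, n)
        return _wrap(mac.center + r[:, None] * heading_to_unit(ang),
                     self.width, self.height)

    def random_nucleus_xy(self, cell: int, n: int) -> np.ndarray:
        """Positions inside one macrophage's nuclear region."""
        mac = self.macrophages[cell]
        r = mac.nucleus_radius * np.sqrt(self.rng.uniform(0.0, 1.0, n))
        ang = self.rng.uniform(0.0, 360.0, n)
        return _wrap(mac.center + r[:, None] * heading_to_unit(ang),
                     self.width, self.height)

    def random_perimeter_xy(self, cell: int, n: int) -> np.ndarray:
        """Positions just outside one macrophage's membrane ring."""
        mac = self.macrophages[cell]
        ang = self.rng.uniform(0.0, 360.0, n)
        return _wrap(mac.center + (mac.cell_radius + 1.5)
                     * heading_to_unit(ang), self.width, self.height)

    def random_nucleus_free_xy(self, n: int) -> np.ndarray:
        """Uniform positions excluded only from nuclei (TNF-a, inhibitor)."""
        out = np.empty((n, 2))
        filled = 0
        nr = self.params.cells.nucleus_radius
        centers = self.cell_centers
        for _ in range(1000):
            if filled >= n:
                break
            cand = self.rng.uniform([0, 0], [self.width, self.height],
                                    size=(n - filled, 2))
            if centers.shape[0]:
                d = torus_dist(cand[:, None, :], centers[None, :, :],
                               self.width, self.height)
                cand = cand[(d >= nr).all(axis=1)]
            out[filled:filled + cand.shape[0]] = cand
            filled += cand.shape[0]
        return out

    # ------------------------------------------------------------------
    # containment
    # ------------------------------------------------------------------
    def containment_accept(self, kind: str, proposal: np.ndarray,
                           cell_ids: np.ndarray | None = None) -> np.ndarray:
        """Boolean mask of proposals that violate no containment rule.

        ``membrane_blocked``: excluded from every cell interior (LPS,
        cytokines, Th cells).  ``nucleus_blocked``: excluded from nuclei
        only (TNF-α and the IKK inhibitor diffuse through membranes).
        ``cytosol``: confined to the annulus of the agent's own cell.
        ``cell_interior``: confined to the own cell, nucleus permitted
        (activated NF-κB / IκBα).  ``nucleus_interior``: confined to the
        own nucleus.
        """
        proposal = np.asarray(proposal, dtype=float)
        n = proposal.shape[0]
        centers = self.cell_centers
        if centers.shape[0] == 0:
            return np.ones(n, dtype=bool)
        cr = self.params.cells.cell_radius
        nr = self.params.cells.nucleus_radius
        if kind == "membrane_blocked":
            d = torus_dist(proposal[:, None, :], centers[None, :, :],
                           self.width, self.height)
            return (d >= cr).all(axis=1)
        if kind == "nucleus_blocked":
            d = torus_dist(proposal[:, None, :], centers[None, :, :],
                           self.width, self.height)
            return (d >= nr).all(axis=1)
        if cell_ids is None:
            raise ValueError(f"containment kind {kind!r} needs cell_ids")
        own = centers[np.asarray(cell_ids, dtype=int)]
        d = torus_dist(proposal, own, self.width, self.height)
        if kind == "cytosol":
            return (d >= nr) & (d < cr - 0.2)
        if kind == "cell_interior":
            return d < cr - 0.2
        if kind == "nucleus_interior":
            return d < nr - 0.1
        raise ValueError(f"unknown containment kind: {kind!r}")

    def random_walk_pool(self, pool: Pool, step_len: float, containment: str,
                         rows: np.ndarray | None = None) -> None:
        """Vectorised random walk for (a subset of) one pool, with rejected
        moves leaving the agent in place (it 'faces another direction until
        the next move')."""
        if pool.n == 0 or step_len == 0:
            return
        rows = np.arange(pool.n) if rows is None else np.asarray(rows)
        if rows.size == 0:
            return
        start = pool.positions()[rows]
        headings = self.rng.uniform(0.0, 360.0, rows.size)
        proposal = _wrap(start + step_len * heading_to_unit(headings),
                         self.width, self.height)
        cell_ids = pool["cell"][rows] if "cell" in pool.columns else None
        ok = self.containment_accept(containment, proposal, cell_ids)
        xy = pool.positions()
        xy[rows[ok]] = proposal[ok]
        pool.set_positions(xy)

    def translate_cell(self, cell: int, delta: np.ndarray) -> None:
        """Rigidly translate a macrophage's intracellular agents with it."""
        for pool in (self.ikk, self.nfkb, self.ikba):
            if pool.n == 0:
                continue
            sel = pool["cell"] == cell
            if not np.any(sel):
                continue
            xy = pool.positions()
            xy[sel] = _wrap(xy[sel] + np.asarray(delta, dtype=float),
                            self.width, self.height)
            pool.set_positions(xy)

    # ------------------------------------------------------------------
    # spawning
    # ------------------------------------------------------------------
    def spawn_lps(self, xy: np.ndarray) -> None:
        self.lps.add(x=xy[:, 0], y=xy[:, 1], bound=0, decay_at=-1)

    def spawn_tnf(self, xy: np.ndarray) -> None:
        self.tnf.add(x=xy[:, 0], y=xy[:, 1], bound=0,
                     remove_at=self.tick + self.params.molecules.tnf_free_lifetime)

    def spawn_il12(self, xy: np.ndarray) -> None:
        self.il12.add(x=xy[:, 0], y=xy[:, 1],
                      expire_at=self.tick + self.params.molecules.il12_lifetime)

    def spawn_il4(self, xy: np.ndarray) -> None:
        self.il4.add(x=xy[:, 0], y=xy[:, 1],
                     expire_at=self.tick + self.params.molecules.il4_lifetime)

    def spawn_inhibitor(self, xy: np.ndarray) -> None:
        self.inh.add(x=xy[:, 0], y=xy[:, 1])

    def inject(self, species: str, amount: int) -> None:
        """Spawn a dose of ``amount`` agents at random legal positions."""
        if amount <= 0:
            return
        if species == "LPS":
            self.spawn_lps(self.random_extracellular_xy(amount))
        elif species == "TNF":
            self.spawn_tnf(self.random_nucleus_free_xy(amount))
        elif species == "IKK_INHIBITOR":
            self.spawn_inhibitor(self.random_nucleus_free_xy(amount))
        else:
            raise ValueError(f"species {species!r} is not injectable")

    # ------------------------------------------------------------------
    # the tick
    # ------------------------------------------------------------------
    def _apply_doses(self) -> None:
        while self.dose_queue and self.dose_queue[0][0] <= self.tick:
            _, species, amount = self.dose_queue.pop(0)
            self.inject(species, amount)

    def step(self) -> "World":
        """Advance exactly one tick through the fixed phase order."""
        self.tick += 1
        self._apply_doses()
        _mol.lps_phase(self)
        _mol.tlr4_phase(self)
        _mol.tnf_phase(self)
        _cells.macrophage_phase(self)
        _mol.ikk_phase(self)
        _mol.nfkb_phase(self)
        _mol.ikba_phase(self)
        _mol.cytokine_phase(self)
        _cells.th_phase(self)
        _cells.energy_phase(self)
        self.history.append(_obs.record(self))
        return self

    def run(self, ticks: int) -> "World":
        for _ in range(ticks):
            self.step()
        return self

    # ------------------------------------------------------------------
    # invariants (used by the test suite; cheap enough to call freely)
    # ------------------------------------------------------------------
    def audit(self) -> None:
        """Raise AssertionError on any broken structural invariant."""
        for pool in (self.lps, self.tnf, self.il12, self.il4, self.inh,
                     self.ikk, self.nfkb, self.ikba, self.th):
            if pool.n == 0:
                continue
            xy = pool.positions()
            assert np.all((xy[:, 0] >= 0) & (xy[:, 0] < self.width)), \
                "x out of bounds"
            assert np.all((xy[:, 1] >= 0) & (xy[:, 1] < self.height)), \
                "y out of bounds"
        cr = self.params.cells.cell_radius
        centers = self.cell_centers
        for pool in (self.ikk, self.nfkb, self.ikba):
            if pool.n == 0 or centers.shape[0] == 0:
                continue
            d = torus_dist(pool.positions(),
                           centers[pool["cell"].astype(int)],
                           self.width, self.height)
            assert np.all(d <= cr + 1e-9), "intracellular agent escaped"
        # NF-kB conservation per cell (vs the recorded baseline census)
        for ci, expected in enumerate(self._nfkb_baseline):
            count = int(np.count_nonzero(self.nfkb["cell"] == ci))
            assert count == expected, \
                f"NF-kB not conserved in cell {ci}: {count} != {expected}"
        # no TNF-a survives past its budget
        if self.tnf.n:
            assert np.all(self.tnf["remove_at"] > self.tick - 1), \
                "overdue TNF-a alive"

    # ------------------------------------------------------------------
    # snapshots
    # ------------------------------------------------------------------
    _POOLS = ("lps", "tnf", "il12", "il4", "inh", "ikk", "nfkb", "ikba", "th")
    _MAC_ARRAYS = ("tlr4_angles", "tnfr_angles", "il4r_angles", "tlr4_sens",
                   "tlr4_occupied_until", "tlr4_act_start", "tlr4_act_until",
                   "tnfr_occupied_until", "il4r_occupied_until")

    def to_snapshot(self) -> dict:
        """A self-describing, JSON-serialisable dump of the full state."""
        macs = []
        for m in self.macrophages:
            entry = {
                "center": m.center.tolist(), "heading": m.heading,
                "cell_radius": m.cell_radius,
                "nucleus_radius": m.nucleus_radius,
                "membrane_count": m.membrane_count,
                "energy": m.energy, "energy_init": m.energy_init,
                "switch_on": m.switch_on,
                "last_complex_tick": m.last_complex_tick,
                "n_intracellular_init": m.n_intracellular_init,
            }
            for name in self._MAC_ARRAYS:
                entry[name] = getattr(m, name).tolist()
            macs.append(entry)
        return {
            "format": "endosim-snapshot-1",
            "tick": self.tick,
            "seed": self.seed,
            "params": self.params.to_dict(),
            "rng_state": self.rng.bit_generator.state,
            "dose_queue": [list(d) for d in self.dose_queue],
            "counters": dict(self.counters),
            "next_il4_cycle": self.next_il4_cycle,
            "macrophages": macs,
            "pools": {name: list(getattr(self, name).to_records())
                      for name in self._POOLS},
        }

    @classmethod
    def from_snapshot(cls, snap: dict) -> "World":
        if snap.get("format") != "endosim-snapshot-1":
            raise ValueError("not an endosim snapshot")
        params = Params.from_dict(snap["params"])
        world = cls(params, seed=snap["seed"], n_macrophages=0)
        world.tick = int(snap["tick"])
        world.dose_queue = [tuple(d) for d in snap["dose_queue"]]
        world.counters = dict(snap["counters"])
        world.next_il4_cycle = int(snap["next_il4_cycle"])
        world.rng.bit_generator.state = snap["rng_state"]
        world.macrophages = []
        for entry in snap["macrophages"]:
            arrays = {name: np.asarray(entry[name]) for name in cls._MAC_ARRAYS}
            arrays["tlr4_sens"] = arrays["tlr4_sens"].astype(np.int64)
            for name in cls._MAC_ARRAYS[4:]:
                arrays[name] = arrays[name].astype(np.int64)
            world.macrophages.append(_cells.Macrophage(
                center=np.asarray(entry["center"], dtype=float),
                heading=float(entry["heading"]),
                cell_radius=float(entry["cell_radius"]),
                nucleus_radius=float(entry["nucleus_radius"]),
                membrane_count=int(entry["membrane_count"]),
                energy=float(entry["energy"]),
                energy_init=float(entry["energy_init"]),
                switch_on=bool(entry["switch_on"]),
                last_complex_tick=int(entry["last_complex_tick"]),
                n_intracellular_init=int(entry["n_intracellular_init"]),
                **arrays))
        for name in cls._POOLS:
            getattr(world, name).load_records(snap["pools"][name])
        world.reset_nfkb_baseline()
        world.history = [_obs.record(world)]
        return world
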