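"""Cellular agents: macrophage composition and T-helper dynamics.

A macrophage is a composite agent: a ring of plasma-membrane agents around a
central nucleus, with LPS (TLR4), TNF-α and IL-4 receptors embedded at fixed
angular positions on the ring and the NF-κB signalling triad living in the
cytosol between nucleus and membrane.  Its scalar state is the energetic
level E with a bistability switch: while E drops strictly below a fraction
(default 25 %) of its initial value the cell amplifies TNF-α transcription
and the world boosts anti-inflammatory production.

T-helper cells are point agents recruited while circulating pro-inflammatory
mediator (free IL-12) is elevated.  A Th0 counts the interleukin units bound
to its surface receptors and differentiates exactly once when the total
reaches a threshold (default 25): majority IL-12 gives Th1 (which secretes
IL-12), otherwise Th2 (which secretes IL-4/A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import angle_to_sector, heading_to_unit, torus_delta, torus_dist, wrap
from .params import Params

TH0, TH1, TH2 = 0, 1, 2


@dataclass
class Macrophage:
    """One macrophage: geometry, receptor state, energy."""

    center: np.ndarray            # (2,) continuous position
    heading: float                # compass degrees
    cell_radius: float
    nucleus_radius: float
    membrane_count: int
    energy: float
    energy_init: float
    switch_on: bool
    # receptor angular layouts (compass degrees, fixed at build time)
    tlr4_angles: np.ndarray
    tnfr_angles: np.ndarray
    il4r_angles: np.ndarray
    # receptor state
    tlr4_sens: np.ndarray         # int, 0..sensitivity_max
    tlr4_occupied_until: np.ndarray
    tlr4_act_start: np.ndarray    # tick activation window began, -1 if never
    tlr4_act_until: np.ndarray    # activated while tick < act_until
    tnfr_occupied_until: np.ndarray
    il4r_occupied_until: np.ndarray
    #: tick at which a TNF-a:TNFR complex last formed (activation events)
    last_complex_tick: int = -1
    n_intracellular_init: int = 0
    constituent_count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.constituent_count = (
            self.membrane_count + len(self.tlr4_angles) + len(self.tnfr_angles)
            + len(self.il4r_angles) + self.n_intracellular_init)

    # -- geometry ----------------------------------------------------------
    def receptor_xy(self, kind: str, width: float, height: float) -> np.ndarray:
        """Absolute positions of receptors of ``kind`` on the membrane ring."""
        angles = getattr(self, f"{kind}_angles")
        return wrap(self.center + self.cell_radius * heading_to_unit(angles),
                    width, height)

    def membrane_xy(self, width: float, height: float) -> np.ndarray:
        angles = np.linspace(0.0, 360.0, self.membrane_count, endpoint=False)
        return wrap(self.center + self.cell_radius * heading_to_unit(angles),
                    width, height)

    # -- receptor predicates (tick-based; no cross-pool references) --------
    def has_tnf_complex(self, tick: int) -> bool:
        """True while >= 1 TNF-a:TNFR complex exists on this cell."""
        return bool(np.any(self.tnfr_occupied_until > tick))

    def has_bound_il4(self, tick: int) -> bool:
        return bool(np.any(self.il4r_occupied_until > tick))


def build_macrophage(center: np.ndarray, params: Params) -> Macrophage:
    """Construct a macrophage with the default composition.

    Receptors are embedded at evenly spaced (interleaved) angles on the
    membrane ring; all TLR4 sensitivities start at the maximum.  Raises
    ``ValueError`` if the requested composition does not exceed the minimum
    constituent-agent count.
    """
    c = params.cells
    total = (c.membrane_count + c.n_tlr4 + c.n_tnfr + c.n_il4r + c.n_nfkb)
    if total <= c.min_constituents:
        raise ValueError(
            f"macrophage would have {total} constituent agents; "
            f"more than {c.min_constituents} are required")

    def ring(n: int, offset: float) -> np.ndarray:
        return (np.linspace(0.0, 360.0, n, endpoint=False) + offset) % 360.0

    zeros = lambda n: np.zeros(n, dtype=np.int64)
    return Macrophage(
        center=np.asarray(center, dtype=float),
        heading=0.0,
        cell_radius=c.cell_radius,
        nucleus_radius=c.nucleus_radius,
        membrane_count=c.membrane_count,
        energy=float(c.energy_init),
        energy_init=float(c.energy_init),
        switch_on=False,
        tlr4_angles=ring(c.n_tlr4, 0.0),
        tnfr_angles=ring(c.n_tnfr, 360.0 / (2 * c.n_tnfr)),
        il4r_angles=ring(c.n_il4r, 360.0 / (4 * c.n_il4r)),
        tlr4_sens=np.full(c.n_tlr4, params.molecules.sensitivity_max,
                          dtype=np.int64),
        tlr4_occupied_until=zeros(c.n_tlr4),
        tlr4_act_start=np.full(c.n_tlr4, -1, dtype=np.int64),
        tlr4_act_until=zeros(c.n_tlr4),
        tnfr_occupied_until=zeros(c.n_tnfr),
        il4r_occupied_until=zeros(c.n_il4r),
        n_intracellular_init=c.n_nfkb,
    )


def energy_update(mac: Macrophage, event: str, params: Params
                  ) -> tuple[float, bool]:
    """Apply an energy event and refresh the switch state.

    ``transcription_cycle`` costs one unit (clamped at zero); ``il4_binding``
    restores one unit.  The switch is ON strictly below the threshold
    fraction of the initial energy.
    """
    if event == "transcription_cycle":
        # amplified transcription (switch ON) consumes energy in proportion
        # to its doubled output, deepening the dysregulated state
        cost = float(params.molecules.tnf_amplified) if mac.switch_on else 1.0
        mac.energy = max(0.0, mac.energy - cost)
    elif event == "il4_binding":
        mac.energy += 1.0
    else:
        raise ValueError(f"unknown energy event: {event!r}")
    mac.switch_on = mac.energy < params.cells.energy_switch_frac * mac.energy_init
    return mac.energy, mac.switch_on


def macrophage_chemotaxis(mac: Macrophage, world) -> float:
    """Heading towards the 8-sector direction with the most free LPS.

    Counts free LPS within radius ``5 + cell_radius`` of the cell centre in
    eight compass sectors; ties break to the lowest sector index.  With no
    LPS in range the heading is left unchanged (the cell still steps).
    """
    e = world.params.engine
    lps = world.lps
    if lps.n:
        free = lps["bound"] == 0
        xy = lps.positions()[free]
    else:
        xy = np.empty((0, 2))
    if xy.shape[0]:
        d = torus_delta(mac.center, xy, e.width, e.height)
        within = np.hypot(d[:, 0], d[:, 1]) <= 5.0 + mac.cell_radius
        d = d[within]
        if d.shape[0]:
            sectors = angle_to_sector(d[:, 0], d[:, 1])
            counts = np.bincount(sectors, minlength=8)
            return float(np.argmax(counts) * 45.0)
    return mac.heading


def th0_differentiate(il12: int, il4: int, threshold: int = 25) -> int:
    """Differentiation fate of a Th0 with the given bound surface counts.

    Returns TH0 (unchanged) below the threshold total; at or above it, TH1
    when strictly more IL-12 than IL-4 is bound, else TH2 (ties included,
    per the 'otherwise' reading of the rule).
    """
    if il12 + il4 < threshold:
        return TH0
    return TH1 if il12 > il4 else TH2


# ---------------------------------------------------------------------------
# scheduler phases
# ---------------------------------------------------------------------------

def macrophage_phase(world) -> None:
    """IKK production every ``ikk_prod_interval`` ticks plus (when due)
    chemotactic movement with rigid translation of all constituents."""
    p = world.params
    tick = world.tick
    if tick > 0 and tick % p.molecules.ikk_prod_interval == 0:
        for ci, mac in enumerate(world.macrophages):
            xy = world.random_cytosol_xy(ci, 1)
            lifetime = world.rng.integers(p.molecules.ikk_lifetime_min,
                                          p.molecules.ikk_lifetime_max + 1)
            world.ikk.add(x=xy[0, 0], y=xy[0, 1], cell=ci, state=0,
                          expire_at=tick + int(lifetime), release_at=-1)

    if tick > 0 and tick % p.engine.cell_move_interval == 0:
        e = p.engine
        min_sep = 2.0 * (p.cells.cell_radius + 1.0)
        for ci, mac in enumerate(world.macrophages):
            mac.heading = macrophage_chemotaxis(mac, world)
            delta = e.cell_step_len * heading_to_unit(mac.heading)
            proposed = wrap(mac.center + delta, e.width, e.height)
            others = [m.center for j, m in enumerate(world.macrophages)
                      if j != ci]
            if others and np.any(
                    torus_dist(proposed, np.stack(others), e.width, e.height)
                    < min_sep):
                continue  # overlap forbidden; skip this move
            mac.center = proposed
            world.translate_cell(ci, delta)


def th_phase(world) -> None:
    """Th0 recruitment, differentiation, Th1/Th2 secretion and movement."""
    p = world.params
    c = p.cells
    tick = world.tick
    th = world.th

    # recruitment: circulating P above threshold pulls Th0 into the world
    circulating_p = world.il12.n
    if (circulating_p > c.th0_entry_threshold
            and tick > 0 and tick % c.th0_entry_interval == 0
            and th.n < c.th0_cap):
        xy = world.random_extracellular_xy(1)
        th.add(x=xy[0, 0], y=xy[0, 1], kind=TH0, il12=0, il4=0,
               next_secrete=-1)

    if th.n:
        # differentiation: exactly once, at the interleukin threshold
        total = th["il12"] + th["il4"]
        ready = (th["kind"] == TH0) & (total >= c.th_diff_threshold)
        if np.any(ready):
            becomes_th1 = ready & (th["il12"] > th["il4"])
            becomes_th2 = ready & ~becomes_th1
            kind = th["kind"].copy()
            nxt = th["next_secrete"].copy()
            kind[becomes_th1] = TH1
            kind[becomes_th2] = TH2
            nxt[becomes_th1] = tick + c.th1_secretion_interval
            nxt[becomes_th2] = tick + c.th2_secretion_interval
            th["kind"] = kind
            th["next_secrete"] = nxt

        # secretion
        any_switch = any(m.switch_on for m in world.macrophages)
        due = (th["next_secrete"] >= 0) & (tick >= th["next_secrete"])
        if np.any(due):
            nxt = th["next_secrete"].copy()
            for i in np.flatnonzero(due):
                if th["kind"][i] == TH1:
                    world.spawn_il12(th.positions()[i:i + 1])
                    nxt[i] = tick + c.th1_secretion_interval
                else:
                    world.spawn_il4(th.positions()[i:i + 1])
                    interval = c.th2_secretion_interval
                    if any_switch:  # anti-inflammatory output doubles
                        interval = max(1, interval // 2)
                    nxt[i] = tick + interval
            th["next_secrete"] = nxt

        # cellular movement cadence
        if tick > 0 and tick % p.engine.cell_move_interval == 0:
            world.random_walk_pool(th, p.engine.cell_step_len,
                                   containment="membrane_blocked")


def energy_phase(world) -> None:
    """Refresh every macrophage's bistability switch from its energy."""
    frac = world.params.cells.energy_switch_frac
    for mac in world.macrophages:
        mac.switch_on = mac.energy < frac * mac.energy_init
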