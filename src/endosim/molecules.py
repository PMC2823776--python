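"""State machines and stochastic interaction rules for the molecular agents.

Species covered: LPS (the endotoxin stimulus), TNF-α (early pro-inflammatory
cytokine), IL-12 (the circulating pro-inflammatory mediator P), IL-4 (the
anti-inflammatory mediator A), the NF-κB signalling triad (IKK kinase, NF-κB
transcription factor, IκBα inhibitor) and a therapeutic IKK inhibitor.

Each rule exists once: the per-agent operation (``attempt_lps_binding``,
``ikk_bind_nfkb``, ``nfkb_transcribe``, ...) both defines the contract used
by unit tests and is what the scheduler phases below invoke, looping over
the (small) sets of agents that are actually in contact on a given tick.
Bulk movement is vectorised over each species pool.

Cross-agent relationships are expressed entirely through tick arithmetic:
when an LPS binds a receptor, both sides record matching expiry ticks, so no
agent ever holds a reference into another pool.  A TNF-α:TNFR complex
"exists" on a macrophage exactly while some TNFR's ``occupied_until``
exceeds the clock, which is the condition that keeps that cell's inactive
IKK pool activated.
"""

from __future__ import annotations

import numpy as np

from . import cells as _cells
from .geometry import heading_to_unit, torus_delta, torus_dist, wrap

# ikk.state codes
IKK_INACTIVE, IKK_ACTIVE, IKK_BOUND = 0, 1, 2
# nfkb.state codes
NFKB_COMPLEXED, NFKB_IKK_BOUND, NFKB_ACTIVE_CYT, NFKB_NUCLEAR = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# per-agent operations
# ---------------------------------------------------------------------------

def attempt_lps_binding(world, lps_idx: int, cell: int, ridx: int) -> bool:
    """One LPS/TLR4 collision: the sensitivity-gated binding rule.

    Binding succeeds when an integer drawn uniformly from
    ``1..sensitivity_max`` compares below the receptor's current sensitivity
    (strict ``<`` by default), so P(bind | s) = (s-1)/sensitivity_max.  On
    success the LPS snaps onto the receptor with a 1-2 tick degradation
    budget, the receptor activates (renewing a production window), its
    sensitivity drops by one (floor 0), and one TNF-α unit is emitted just
    outside the membrane.
    """
    m = world.params.molecules
    mac = world.macrophages[cell]
    tick = world.tick
    if world.lps["bound"][lps_idx] != 0:
        return False
    if mac.tlr4_occupied_until[ridx] > tick:
        return False  # occupied receptors cannot receive another LPS
    s = int(mac.tlr4_sens[ridx])
    draw = int(world.rng.integers(1, m.sensitivity_max + 1))
    success = (draw <= s) if m.sensitivity_inclusive else (draw < s)
    if not success:
        return False

    decay = int(world.rng.integers(m.lps_bound_decay_min,
                                   m.lps_bound_decay_max + 1))
    rxy = mac.receptor_xy("tlr4", world.width, world.height)[ridx]
    world.lps["bound"][lps_idx] = 1
    world.lps["decay_at"][lps_idx] = tick + decay
    world.lps["x"][lps_idx] = rxy[0]
    world.lps["y"][lps_idx] = rxy[1]
    mac.tlr4_occupied_until[ridx] = tick + decay
    mac.tlr4_sens[ridx] = max(0, s - 1)
    if tick > mac.tlr4_act_until[ridx] or mac.tlr4_act_start[ridx] < 0:
        mac.tlr4_act_start[ridx] = tick
    mac.tlr4_act_until[ridx] = tick + m.tlr4_activation_window
    out = wrap(mac.center + (mac.cell_radius + 1.5)
               * heading_to_unit(mac.tlr4_angles[ridx]),
               world.width, world.height)
    world.spawn_tnf(out[None, :])
    return True


def ikk_bind_nfkb(world, ikk_idx: int, nfkb_idx: int) -> bool:
    """Contact between an active IKK and an inactive NF-κB:IκBα complex.

    With probability ``p_bind_ikk`` (default 0.70) the kinase binds the
    complex; the pair then stays bound for ``ikk_complex_ticks`` (default
    10), after which IKK dissociates, the IκBα partner is ubiquitinated and
    the freed NF-κB becomes active (handled by the release logic in the
    scheduler phases via the matching ``release_at`` ticks).
    """
    m = world.params.molecules
    if world.ikk["state"][ikk_idx] != IKK_ACTIVE:
        return False
    if world.nfkb["state"][nfkb_idx] != NFKB_COMPLEXED:
        return False
    if world.rng.random() >= m.p_bind_ikk:
        return False
    until = world.tick + m.ikk_complex_ticks
    world.ikk["state"][ikk_idx] = IKK_BOUND
    world.ikk["release_at"][ikk_idx] = until
    world.nfkb["state"][nfkb_idx] = NFKB_IKK_BOUND
    world.nfkb["release_at"][nfkb_idx] = until
    world.nfkb["x"][nfkb_idx] = world.ikk["x"][ikk_idx]
    world.nfkb["y"][nfkb_idx] = world.ikk["y"][ikk_idx]
    return True


def nfkb_transcribe(world, nfkb_idx: int) -> dict:
    """One transcription cycle of a nuclear NF-κB.

    Emits 1 activated IκBα into the cytosol, 1 IL-12 unit with probability
    ``p_il12`` (default 0.80) outside the membrane, and ``tnf_per_cycle``
    TNF-α units (``tnf_amplified`` while the cell's energy switch is ON),
    and costs the macrophage one energy unit.
    """
    m = world.params.molecules
    cell = int(world.nfkb["cell"][nfkb_idx])
    mac = world.macrophages[cell]
    products = {"ikba": 1, "il12": 0, "tnf": 0}

    # the fresh inhibitor appears in the nuclear region, close to the
    # transcriptional machinery that produced it
    xy = world.random_nucleus_xy(cell, 1)
    world.ikba.add(x=xy[0, 0], y=xy[0, 1], cell=cell)
    world.counters["ikba_transcribed"] += 1

    if world.rng.random() < m.p_il12:
        world.spawn_il12(world.random_perimeter_xy(cell, 1))
        products["il12"] = 1

    if mac.switch_on:
        # bistability: low energy amplifies TNF-a output unconditionally
        n_tnf = m.tnf_amplified
    elif m.il4_attenuates_tnf and mac.has_bound_il4(world.tick):
        # the anti-inflammatory arm: bound IL-4 on a healthy cell
        # suppresses its TNF-a transcription
        n_tnf = 0
    else:
        n_tnf = m.tnf_per_cycle
    if n_tnf:
        world.spawn_tnf(world.random_perimeter_xy(cell, n_tnf))
    products["tnf"] = n_tnf

    _cells.energy_update(mac, "transcription_cycle", world.params)
    world.nfkb["next_tx"][nfkb_idx] = world.tick + m.nfkb_transcribe_interval
    return products


def ikba_inhibit(world, ikba_idx: int) -> int | None:
    """Attempt re-inhibition: bind an activated NF-κB within radius 1.

    Returns the nfkb row index on success (the pair forms an inactive
    complex relocated to the cytosol and the free IκBα agent is consumed by
    the caller), or None when no activated NF-κB lies within the contact
    radius this tick.
    """
    e = world.params.engine
    cell = int(world.ikba["cell"][ikba_idx])
    active = np.flatnonzero(
        ((world.nfkb["state"] == NFKB_ACTIVE_CYT)
         | (world.nfkb["state"] == NFKB_NUCLEAR))
        & (world.nfkb["cell"] == cell))
    if active.size == 0:
        return None
    pos = np.array([world.ikba["x"][ikba_idx], world.ikba["y"][ikba_idx]])
    d = torus_dist(pos, world.nfkb.positions()[active], world.width,
                   world.height)
    j = int(active[np.argmin(d)])
    if d.min() > e.contact_radius:
        return None
    cyt = world.random_cytosol_xy(cell, 1)
    world.nfkb["state"][j] = NFKB_COMPLEXED
    world.nfkb["release_at"][j] = -1
    world.nfkb["next_tx"][j] = -1
    world.nfkb["x"][j] = cyt[0, 0]
    world.nfkb["y"][j] = cyt[0, 1]
    return j


def il4_production_cycle(world) -> int:
    """One world-level IL-4 production cycle.

    In the presence of at least one free IL-12, with probability ``p_il4``
    (default 0.86) spawn ``il4_units`` (default 3) IL-4 agents at random
    extracellular positions; the batch is multiplied by ``a_boost`` while
    any macrophage's energy switch is ON.  Returns the number spawned.
    """
    m = world.params.molecules
    if world.il12.n == 0:
        return 0
    if world.rng.random() >= m.p_il4:
        return 0
    units = m.il4_units
    if any(mac.switch_on for mac in world.macrophages):
        units *= world.params.cells.a_boost
    world.spawn_il4(world.random_extracellular_xy(units))
    return units


# ---------------------------------------------------------------------------
# scheduler phases
# ---------------------------------------------------------------------------

def _paths_near_cells(world, start, delta, n_sub):
    """Substep positions along each agent's move, for contact detection."""
    return [wrap(start + delta * (k / n_sub), world.width, world.height)
            for k in range(1, n_sub + 1)]


def lps_phase(world) -> None:
    """Receptor sensitivity recovery, bound-LPS degradation, and the random
    walk of free LPS with path-sampled receptor collisions."""
    p = world.params
    e = p.engine
    tick = world.tick
    lps = world.lps

    # desensitised receptors regain one sensitivity unit per recovery
    # period, staggered across the receptor population so recovery is a
    # steady trickle rather than a synchronised wave
    if tick > 0:
        period = p.sensitivity_recovery_ticks
        cap = p.molecules.sensitivity_max
        for mac in world.macrophages:
            n = len(mac.tlr4_sens)
            offsets = (np.arange(n) * period) // max(n, 1)
            due = (tick + offsets) % period == 0
            if np.any(due):
                mac.tlr4_sens[due] = np.minimum(mac.tlr4_sens[due] + 1, cap)

    if lps.n:
        lps.remove((lps["bound"] == 1) & (lps["decay_at"] <= tick))
    if lps.n == 0:
        return

    free = np.flatnonzero(lps["bound"] == 0)
    if free.size == 0:
        return
    start = lps.positions()[free]
    headings = world.rng.uniform(0.0, 360.0, free.size)
    delta = e.lps_step_len * heading_to_unit(headings)

    centers = world.cell_centers
    if centers.shape[0] == 0:
        lps_xy = lps.positions()
        lps_xy[free] = wrap(start + delta, world.width, world.height)
        lps.set_positions(lps_xy)
        return

    radius = p.cells.cell_radius
    n_sub = max(1, int(np.ceil(e.lps_step_len / (2.0 * e.contact_radius))))
    substeps = _paths_near_cells(world, start, delta, n_sub)

    moving = np.ones(free.size, dtype=bool)
    final = wrap(start + delta, world.width, world.height)
    last_ok = start.copy()
    rxy_cache = [mac.receptor_xy("tlr4", world.width, world.height)
                 for mac in world.macrophages]
    for pos_k in substeps:
        if not moving.any():
            break
        act = np.flatnonzero(moving)
        d_cent = torus_dist(pos_k[act, None, :], centers[None, :, :],
                            world.width, world.height)
        # stop agents whose path would enter a cell interior
        inside = (d_cent < radius - e.contact_radius).any(axis=1)
        for ai in act[inside]:
            final[ai] = last_ok[ai]
            moving[ai] = False
        # collision checks for agents within reach of a membrane ring
        for ci, mac in enumerate(world.macrophages):
            band = np.flatnonzero(
                moving[act]
                & (np.abs(d_cent[:, ci] - radius) <= e.contact_radius + 1.0))
            if band.size == 0:
                continue
            rd = torus_dist(pos_k[act[band]][:, None, :],
                            rxy_cache[ci][None, :, :],
                            world.width, world.height)
            open_r = mac.tlr4_occupied_until <= tick
            for row in np.flatnonzero(((rd <= e.contact_radius)
                                       & open_r[None, :]).any(axis=1)):
                ai = int(act[band[row]])
                if not moving[ai]:
                    continue
                cand = np.flatnonzero((rd[row] <= e.contact_radius) & open_r)
                if cand.size == 0:
                    continue
                ridx = int(cand[np.argmin(rd[row][cand])])
                if attempt_lps_binding(world, int(free[ai]), ci, ridx):
                    moving[ai] = False
                    open_r[ridx] = False
        survivors = act[moving[act]]
        last_ok[survivors] = pos_k[survivors]
    # bound agents were repositioned onto their receptor; everything else
    # lands at `final` (the full move, or the last in-bounds substep)
    lps_xy = lps.positions()
    still_free = lps["bound"][free] == 0
    lps_xy[free[still_free]] = final[still_free]
    lps.set_positions(lps_xy)


def tlr4_phase(world) -> None:
    """Activated TLR4 receptors produce 1 TNF-α per production interval of
    continuous activation."""
    m = world.params.molecules
    tick = world.tick
    for mac in world.macrophages:
        dur = tick - mac.tlr4_act_start
        due = ((mac.tlr4_act_start >= 0) & (tick <= mac.tlr4_act_until)
               & (dur > 0) & (dur % m.tlr4_prod_interval == 0))
        if np.any(due):
            out = wrap(mac.center + (mac.cell_radius + 1.5)
                       * heading_to_unit(mac.tlr4_angles[due]),
                       world.width, world.height)
            world.spawn_tnf(out)


def bound_tnf_decay_ticks(world, mac) -> int:
    """Bound-TNF removal delay, fixed at binding time.

    The literal rule lengthens the complex lifetime to 200 ticks when the
    same macrophage carries a bound IL-4 (``il4_extends_tnf=True``); the
    alternative narrative reading swaps the two constants so IL-4
    accelerates TNF-α removal.
    """
    m = world.params.molecules
    if m.il4_extends_tnf:
        return (m.tnf_bound_decay_il4 if mac.has_bound_il4(world.tick)
                else m.tnf_bound_decay)
    return (m.tnf_bound_decay if mac.has_bound_il4(world.tick)
            else m.tnf_bound_decay_il4)


def tnf_phase(world) -> None:
    """TNF-α expiry, free movement (membrane-permeable), and TNFR binding."""
    p = world.params
    e = p.engine
    tick = world.tick
    tnf = world.tnf
    if tnf.n:
        tnf.remove(tnf["remove_at"] <= tick)
    if tnf.n == 0:
        return
    free = np.flatnonzero(tnf["bound"] == 0)
    if free.size == 0:
        return

    start = tnf.positions()[free]
    headings = world.rng.uniform(0.0, 360.0, free.size)
    delta = e.tnf_step_len * heading_to_unit(headings)
    proposal = wrap(start + delta, world.width, world.height)
    ok = world.containment_accept("nucleus_blocked", proposal)
    final = np.where(ok[:, None], proposal, start)

    centers = world.cell_centers
    if centers.shape[0]:
        radius = p.cells.cell_radius
        d_cent = torus_dist(final[:, None, :], centers[None, :, :],
                            world.width, world.height)
        # receptors sit on the membrane ring: only agents landing within
        # contact range of a ring can bind
        for ci, mac in enumerate(world.macrophages):
            band = np.flatnonzero(
                np.abs(d_cent[:, ci] - radius) <= e.contact_radius + 0.5)
            if band.size == 0:
                continue
            rxy = mac.receptor_xy("tnfr", world.width, world.height)
            rd = torus_dist(final[band][:, None, :], rxy[None, :, :],
                            world.width, world.height)
            open_r = mac.tnfr_occupied_until <= tick
            hit_rows = np.flatnonzero(((rd <= e.contact_radius)
                                       & open_r[None, :]).any(axis=1))
            for row in hit_rows:
                k = int(band[row])
                gi = int(free[k])
                if tnf["bound"][gi]:
                    continue
                cand = np.flatnonzero((rd[row] <= e.contact_radius) & open_r)
                if cand.size == 0:
                    continue
                ridx = int(cand[np.argmin(rd[row][cand])])
                decay = bound_tnf_decay_ticks(world, mac)
                tnf["bound"][gi] = 1
                tnf["remove_at"][gi] = tick + decay
                mac.tnfr_occupied_until[ridx] = tick + decay
                mac.last_complex_tick = tick
                open_r[ridx] = False
                final[k] = rxy[ridx]
    tnf_xy = tnf.positions()
    tnf_xy[free] = final
    tnf.set_positions(tnf_xy)


def inhibitor_update(world) -> None:
    """IKK-inhibitor movement and 1:1 neutralisation of IKK on contact.

    The inhibitor diffuses quickly through the extracellular space but,
    having crossed a membrane, roams the cytosol at molecular pace — so a
    dose is spent hunting kinase where it lives rather than drifting by.
    """
    e = world.params.engine
    inh = world.inh
    if inh.n == 0:
        return
    centers = world.cell_centers
    if centers.shape[0]:
        d = torus_dist(inh.positions()[:, None, :], centers[None, :, :],
                       world.width, world.height)
        inside = (d < world.params.cells.cell_radius).any(axis=1)
        world.random_walk_pool(inh, e.intra_step_len, "nucleus_blocked",
                               rows=np.flatnonzero(inside))
        world.random_walk_pool(inh, e.inhibitor_step_len, "nucleus_blocked",
                               rows=np.flatnonzero(~inside))
    else:
        world.random_walk_pool(inh, e.inhibitor_step_len, "nucleus_blocked")
    if world.ikk.n == 0:
        return
    targets = np.flatnonzero(world.ikk["state"] != IKK_BOUND)
    if targets.size == 0:
        return
    txy = world.ikk.positions()[targets]
    d = torus_dist(inh.positions()[:, None, :], txy[None, :, :],
                   world.width, world.height)
    ikk_dead = np.zeros(world.ikk.n, dtype=bool)
    inh_dead = np.zeros(inh.n, dtype=bool)
    taken = np.zeros(targets.size, dtype=bool)
    for i in range(inh.n):
        cand = np.flatnonzero((d[i] <= e.contact_radius) & ~taken)
        if cand.size == 0:
            continue
        j = int(cand[np.argmin(d[i][cand])])
        taken[j] = True
        ikk_dead[targets[j]] = True
        inh_dead[i] = True
        world.counters["ikk_inhibited"] += 1
    world.ikk.remove(ikk_dead)
    inh.remove(inh_dead)


def ikk_phase(world) -> None:
    """Inhibitor competition, IKK release/lifetime/activation, cytosolic
    movement, and the 70 % binding rule against inactive NF-κB complexes."""
    p = world.params
    e = p.engine
    tick = world.tick
    inhibitor_update(world)
    ikk = world.ikk
    if ikk.n == 0:
        return

    # dissociation ends the kinase's single catalytic act: the spent IKK
    # is cleared (each IKK molecule stimulates at most one NF-kB complex)
    bound = ikk["state"] == IKK_BOUND
    release = bound & (ikk["release_at"] <= tick)
    if np.any(release):
        world.counters["ikk_spent"] += int(np.count_nonzero(release))
        ikk.remove(release)
    if ikk.n == 0:
        return
    ikk.remove((ikk["state"] != IKK_BOUND) & (ikk["expire_at"] <= tick))
    if ikk.n == 0:
        return

    # while >= 1 TNF-a:TNFR complex exists on the cell, every inactive IKK
    # there becomes active (TNF-a binding amplifies the kinase activity)
    for ci, mac in enumerate(world.macrophages):
        if mac.has_tnf_complex(tick):
            sel = (ikk["cell"] == ci) & (ikk["state"] == IKK_INACTIVE)
            ikk["state"][np.flatnonzero(sel)] = IKK_ACTIVE

    mobile = ikk["state"] != IKK_BOUND
    world.random_walk_pool(ikk, e.intra_step_len, "cytosol",
                           rows=np.flatnonzero(mobile))

    # binding attempts: one per active IKK per tick, nearest open complex
    nfkb = world.nfkb
    for ci in range(len(world.macrophages)):
        act = np.flatnonzero((ikk["cell"] == ci) & (ikk["state"] == IKK_ACTIVE))
        cplx = np.flatnonzero((nfkb["cell"] == ci)
                              & (nfkb["state"] == NFKB_COMPLEXED))
        if act.size == 0 or cplx.size == 0:
            continue
        d = torus_dist(ikk.positions()[act][:, None, :],
                       nfkb.positions()[cplx][None, :, :],
                       world.width, world.height)
        open_c = np.ones(cplx.size, dtype=bool)
        for a_local, ai in enumerate(act):
            cand = np.flatnonzero((d[a_local] <= e.contact_radius) & open_c)
            if cand.size == 0:
                continue
            j = int(cand[np.argmin(d[a_local][cand])])
            if ikk_bind_nfkb(world, int(ai), int(cplx[j])):
                open_c[j] = False


def nfkb_phase(world) -> None:
    """NF-κB release from IKK, nuclear translocation, transcription, and
    cytosolic movement of the inactive complexes."""
    p = world.params
    e = p.engine
    tick = world.tick
    nfkb = world.nfkb
    if nfkb.n == 0:
        return

    release = (nfkb["state"] == NFKB_IKK_BOUND) & (nfkb["release_at"] <= tick)
    if np.any(release):
        nfkb["state"][release] = NFKB_ACTIVE_CYT
        world.counters["ikba_ubiquitinated"] += int(np.count_nonzero(release))

    centers = world.cell_centers
    nr = p.cells.nucleus_radius

    # active cytosolic NF-kB translocates towards the nucleus
    act = np.flatnonzero(nfkb["state"] == NFKB_ACTIVE_CYT)
    if act.size:
        pos = nfkb.positions()[act]
        own = centers[nfkb["cell"][act]]
        d = torus_delta(pos, own, world.width, world.height)
        dist = np.hypot(d[:, 0], d[:, 1])
        step = np.minimum(e.intra_step_len, dist)[:, None]
        unit = np.where(dist[:, None] > 0, d / np.maximum(dist, 1e-12)[:, None], 0.0)
        newpos = wrap(pos + step * unit, world.width, world.height)
        newdist = torus_dist(newpos, own, world.width, world.height)
        entered = newdist < nr - 0.3
        xy = nfkb.positions()
        xy[act] = newpos
        nfkb.set_positions(xy)
        if np.any(entered):
            rows = act[entered]
            nfkb["state"][rows] = NFKB_NUCLEAR
            nfkb["next_tx"][rows] = tick + p.molecules.nfkb_transcribe_interval

    # nuclear NF-kB wanders inside the nucleus and transcribes when due
    nuc = np.flatnonzero(nfkb["state"] == NFKB_NUCLEAR)
    if nuc.size:
        world.random_walk_pool(nfkb, e.intra_step_len, "nucleus_interior",
                               rows=nuc)
        due = nuc[(nfkb["next_tx"][nuc] >= 0)
                  & (nfkb["next_tx"][nuc] <= tick)]
        for row in due:
            nfkb_transcribe(world, int(row))

    # inactive complexes random-walk in the cytosol
    cplx = np.flatnonzero(nfkb["state"] == NFKB_COMPLEXED)
    if cplx.size:
        world.random_walk_pool(nfkb, e.intra_step_len, "cytosol", rows=cplx)


def ikba_phase(world) -> None:
    """Activated IκBα: deactivate IKK it runs into, otherwise seek out and
    re-inhibit activated NF-κB within the contact radius.

    Deactivation applies to free active IKK and to IKK currently holding an
    NF-κB:IκBα complex — disbanding the pair returns the untouched complex
    to the inactive cytosolic pool.  Either way the IκBα agent is consumed
    (1:1 stoichiometry), which is what lets a strong transcriptional wave
    extinguish the kinase activity that created it.
    """
    e = world.params.engine
    ikba = world.ikba
    if ikba.n == 0:
        return
    ikk = world.ikk
    nfkb = world.nfkb
    ikba_dead = np.zeros(ikba.n, dtype=bool)
    ikk_dead = np.zeros(ikk.n, dtype=bool) if ikk.n else np.empty(0, bool)

    # per-cell caches for this tick
    n_cells = len(world.macrophages)
    ikk_rows = [np.flatnonzero((ikk["cell"] == c)
                               & (ikk["state"] != IKK_INACTIVE))
                for c in range(n_cells)] if ikk.n else [np.empty(0, int)] * n_cells
    nfkb_by_cell = [np.flatnonzero(((nfkb["state"] == NFKB_ACTIVE_CYT)
                                    | (nfkb["state"] == NFKB_NUCLEAR))
                                   & (nfkb["cell"] == c))
                    for c in range(n_cells)]
    nfkb_taken = np.zeros(nfkb.n, dtype=bool)

    for i in range(ikba.n):
        cell = int(ikba["cell"][i])
        pos = np.array([ikba["x"][i], ikba["y"][i]])
        # interception: any non-degraded IKK within contact is deactivated
        rows = ikk_rows[cell]
        if rows.size:
            rows = rows[~ikk_dead[rows]]
        if rows.size:
            d = torus_dist(pos, ikk.positions()[rows], world.width,
                           world.height)
            jmin = int(np.argmin(d))
            if d[jmin] <= e.contact_radius:
                target = int(rows[jmin])
                if ikk["state"][target] == IKK_BOUND:
                    # disband: the partner complex returns to the inactive
                    # pool (it is co-located with the bound IKK)
                    partners = np.flatnonzero(
                        (nfkb["state"] == NFKB_IKK_BOUND)
                        & (nfkb["cell"] == cell) & ~nfkb_taken)
                    if partners.size:
                        pd = torus_dist(ikk.positions()[target],
                                        nfkb.positions()[partners],
                                        world.width, world.height)
                        pj = int(partners[np.argmin(pd)])
                        nfkb["state"][pj] = NFKB_COMPLEXED
                        nfkb["release_at"][pj] = -1
                        nfkb_taken[pj] = True
                ikk_dead[target] = True
                ikba_dead[i] = True
                world.counters["ikk_deactivated_by_ikba"] += 1
                continue
        # re-inhibition: bind an activated NF-kB within the contact radius
        cand = nfkb_by_cell[cell]
        cand = cand[~nfkb_taken[cand]] if cand.size else cand
        if cand.size:
            tpos = nfkb.positions()[cand]
            d = torus_dist(pos, tpos, world.width, world.height)
            j = int(np.argmin(d))
            if d[j] <= e.contact_radius:
                row = int(cand[j])
                cyt = world.random_cytosol_xy(cell, 1)
                nfkb["state"][row] = NFKB_COMPLEXED
                nfkb["release_at"][row] = -1
                nfkb["next_tx"][row] = -1
                nfkb["x"][row] = cyt[0, 0]
                nfkb["y"][row] = cyt[0, 1]
                nfkb_taken[row] = True
                ikba_dead[i] = True
                continue
            # seek: move towards the nearest activated NF-kB
            vec = torus_delta(pos, tpos[j], world.width, world.height)
            norm = max(float(np.hypot(*vec)), 1e-12)
            step = min(e.intra_step_len, norm)
            new = wrap(pos + step * vec / norm, world.width, world.height)
        else:
            heading = world.rng.uniform(0.0, 360.0)
            new = wrap(pos + e.intra_step_len * heading_to_unit(heading),
                       world.width, world.height)
        if world.containment_accept("cell_interior", new[None, :],
                                    cell_ids=np.array([cell]))[0]:
            ikba["x"][i] = new[0]
            ikba["y"][i] = new[1]
    if ikk.n:
        ikk.remove(ikk_dead)
    ikba.remove(ikba_dead)


def cytokine_phase(world) -> None:
    """IL-12 and IL-4 movement, expiry, receptor binding and production."""
    p = world.params
    e = p.engine
    tick = world.tick
    il12, il4, th = world.il12, world.il4, world.th

    # --- IL-12 (pro-inflammatory mediator P) ---
    if il12.n:
        il12.remove(il12["expire_at"] <= tick)
    if il12.n:
        world.random_walk_pool(il12, e.cytokine_step_len, "membrane_blocked")
        _bind_to_th0(world, il12, "il12")

    # --- IL-4 production cycle ---
    if tick >= world.next_il4_cycle:
        il4_production_cycle(world)
        world.next_il4_cycle = tick + int(world.rng.integers(
            p.molecules.il4_interval_min, p.molecules.il4_interval_max + 1))

    # --- IL-4 (anti-inflammatory mediator A) ---
    if il4.n:
        il4.remove(il4["expire_at"] <= tick)
    if il4.n:
        world.random_walk_pool(il4, e.cytokine_step_len, "membrane_blocked")
        _bind_il4_to_macrophages(world)
    if il4.n:
        _bind_to_th0(world, il4, "il4")


def _bind_to_th0(world, pool, counter: str) -> None:
    """Cytokines within contact of an undifferentiated Th0 bind its surface
    receptors: the agent is consumed and the surface count increments."""
    th = world.th
    if th.n == 0 or pool.n == 0:
        return
    e = world.params.engine
    th0 = np.flatnonzero(th["kind"] == _cells.TH0)
    if th0.size == 0:
        return
    d = torus_dist(pool.positions()[:, None, :],
                   th.positions()[th0][None, :, :],
                   world.width, world.height)
    dead = np.zeros(pool.n, dtype=bool)
    counts = th[counter].copy()
    for i in np.flatnonzero((d <= e.contact_radius).any(axis=1)):
        cand = np.flatnonzero(d[i] <= e.contact_radius)
        j = int(th0[cand[np.argmin(d[i][cand])]])
        counts[j] += 1
        dead[i] = True
    th[counter] = counts
    pool.remove(dead)


def _bind_il4_to_macrophages(world) -> None:
    """IL-4 binding an unoccupied macrophage IL-4R raises that cell's energy
    by one and parks residence on the receptor for ``il4_bound_ticks``."""
    e = world.params.engine
    m = world.params.molecules
    tick = world.tick
    il4 = world.il4
    dead = np.zeros(il4.n, dtype=bool)
    pos = il4.positions()
    radius = world.params.cells.cell_radius
    for ci, mac in enumerate(world.macrophages):
        d_cent = torus_dist(pos, mac.center, world.width, world.height)
        band = np.flatnonzero(np.abs(d_cent - radius)
                              <= e.contact_radius + 0.5)
        if band.size == 0:
            continue
        rxy = mac.receptor_xy("il4r", world.width, world.height)
        d = torus_dist(pos[band][:, None, :], rxy[None, :, :],
                       world.width, world.height)
        open_r = mac.il4r_occupied_until <= tick
        for row in np.flatnonzero(((d <= e.contact_radius)
                                   & open_r[None, :]).any(axis=1)):
            i = int(band[row])
            if dead[i]:
                continue
            cand = np.flatnonzero((d[row] <= e.contact_radius) & open_r)
            if cand.size == 0:
                continue
            ridx = int(cand[np.argmin(d[row][cand])])
            mac.il4r_occupied_until[ridx] = tick + m.il4_bound_ticks
            open_r[ridx] = False
            _cells.energy_update(mac, "il4_binding", world.params)
            dead[i] = True
    il4.remove(dead)
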