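# Methods

`endosim` is a spatially explicit, discrete-tick, stochastic rule-based
(agent-based) model of the acute inflammatory response of blood leukocytes
to bacterial endotoxin (LPS).  This note records the model, its
assumptions, the parameters that matter, the numerical choices, and what
the simulations do and do not demonstrate.

## The model

**World.** A `width x height` (default 161 x 161) continuous-coordinate
torus holding `n_macrophages` (default 4) composite macrophage agents and
free point agents for every molecular species.  Time advances in discrete
ticks; `ticks_per_hour` (default 400) anchors the unitless model clock to
hours for dosing and classification.  Every tick executes a fixed phase
order (doses → LPS → TLR4 production → TNF-α → macrophage
production/movement → inhibitor+IKK → NF-κB → IκBα → cytokines → T-helper
cells → energy switch → recording); within a phase, agents are processed in
creation order against a single seeded RNG stream, so a (config, seed) pair
reproduces a bit-identical trajectory.

**Macrophages.** Each cell is a ring of 240 membrane agents of radius 8
patches around a nucleus of radius 3, with 46 TLR4, 20 TNFR and 20 IL-4
receptors embedded at fixed angles (446 constituent agents including the
120 intracellular NF-κB:IκBα complexes — more than the 400 the architecture
requires).  Cells move once per `cell_move_interval` (800) ticks — the
published 800:1 molecular:cellular movement-frequency ratio — towards the
45°-sector with the most free LPS within radius 5 + cell radius (ties to
the lowest compass sector; no LPS in range leaves the heading unchanged),
rigidly translating membrane, receptors and intracellular agents, and never
overlapping another cell.

**Signalling rules** (constants printed in the source model are marked •):

- LPS walks with a fresh uniform heading each tick, `lps_step_len` (20)
  patches forward, sampled every 2 patches for membrane collisions.  A
  collision with an unoccupied TLR4 binds with probability (s−1)/5 where s
  is the receptor's sensitivity counter (strict `<` against a uniform draw
  from 1..5 •); binding spawns 1 TNF-α •, decrements s (to a floor where
  binding probability is zero — receptor saturation), occupies the receptor
  for the bound LPS's 1–2 tick • degradation, and opens a renewable 100-tick
  activation window during which the receptor emits 1 TNF-α per 100 ticks •.
  Free LPS never decays •.  Desensitised receptors recover one sensitivity
  unit per `sensitivity_recovery_hours` (24 h), staggered across the
  receptor population so recovery is a steady trickle, not a synchronised
  wave.
- TNF-α starts with a 600-tick budget •, diffuses through membranes (not
  nuclei), and binds unoccupied TNFR on contact; the complex is removed 50
  ticks after binding, or 200 • if the macrophage carries a bound IL-4 at
  binding time (the literal published rule; the flag `il4_extends_tnf=False`
  selects the alternative "IL-4 accelerates TNF removal" reading).
- While ≥1 TNF-α:TNFR complex exists on a cell, every inactive IKK there
  becomes active.  Macrophages produce 1 IKK per 5 ticks •, each with a
  uniform 1–799-tick • lifetime.  An active IKK in contact (radius 1) with
  an inactive NF-κB:IκBα complex binds it with probability 0.70 •, holds it
  for 10 ticks •, then dissociates: the IκBα partner is ubiquitinated, the
  freed NF-κB is active, and the kinase is **spent** (removed) — one
  catalytic act per IKK molecule (see *Design choices*).
- Active NF-κB translocates to the nucleus and transcribes every 10 ticks •:
  1 activated IκBα, 1 IL-12 with probability 0.80 •, and TNF-α — 1 unit
  normally, `tnf_amplified` (2) while the cell's energy switch is ON, and 0
  on a healthy (switch-OFF) cell currently carrying bound IL-4 (the
  anti-inflammatory attenuation; see *Design choices*).  Each cycle costs
  the cell 1 energy unit (2 while amplified).
- Activated IκBα appears in the nuclear region near its producer, seeks the
  nearest activated NF-κB, and within radius 1 • re-forms an inactive
  complex relocated to the cytosol.  On the way it deactivates any IKK it
  contacts — free-active or complex-bound (disbanding the intermediate) —
  and is consumed 1:1.
- IL-4 production: whenever ≥1 free IL-12 exists, every 1–5 ticks • (uniform
  redraw) a 3-unit • IL-4 batch spawns with probability 0.86 • at random
  extracellular positions, multiplied by `a_boost` (2) while any switch is
  ON.  IL-4 binding a macrophage IL-4R raises that cell's energy by 1 • and
  occupies the receptor for `il4_bound_ticks` (100).  IL-12 and IL-4 carry
  600-tick lifetimes (the generic degradation-counter property; the model
  description prints no number — chosen to mirror the TNF-α budget).
- Th0 cells enter the world while circulating P (free IL-12) exceeds 10,
  one per 200 ticks up to 50 live cells; they accumulate IL-12/IL-4 units
  on surface receptors and differentiate exactly once when the total
  reaches 25 • — Th1 on a strict IL-12 majority, otherwise Th2 • (ties
  included).  Th1 secretes 1 IL-12 per 300 ticks; Th2 secretes 1 IL-4 per
  50 ticks, twice as fast while a switch is ON.
- The IKK inhibitor diffuses fast extracellularly (step 8), drops to
  molecular pace inside cells, and neutralises IKK 1:1 on contact.

**Bistability.** The energy reserve `energy_init` (234) per cell is drained by transcription and restored by IL-4 binding
(bounded by initial value + total bindings; no upper clamp, so a quiet,
IL-4-rich interlude *pre-charges* the reserve — the acquired protective
state behind endotoxin tolerance).  Strictly below 25 % of the initial
value the switch turns ON: TNF-α transcription amplifies (overriding the
IL-4 attenuation) and anti-inflammatory production boosts.  Because the
amplified state's drain (2/cycle) exceeds the receptor-limited IL-4 income,
the ON state is self-sustaining: the model has two attractors — a resolved
baseline and a sustained-elevated inflammatory state — and the dose decides
which one a trajectory reaches.

## Outcome classification

Per tick the recorder censuses: total LPS (bound + free), free TNF-α,
P (circulating IL-12), A (IL-4 agents), E (summed macrophage energy), and
activated NF-κB/IKK/IκBα summed over cells, plus Th0/Th1/Th2 counts.
*Clearance time* is the first time total LPS reaches zero and stays zero.
A run is *resolved* when P, free TNF-α and activated NF-κB each return to
within 5 % of their run peak around the pre-dose (t = 0) baseline and hold
it for ≥1 h through the horizon; the resolution time is when the last
channel enters the band for good.  Both the tolerance and the hold window
are exposed settings (`observables.resolve_tol`, `observables.hold_hours`);
the source model states no numeric criterion, so these are artifact
definitions.

## Design choices where the description was open

- **Single-turnover IKK.**  The published rule list gives the kinase a
  1–799-tick lifetime, a 70 % binding rule and a 10-tick dissociation, but
  not what happens after dissociation.  A persistent multi-turnover kinase
  (~36 activations per molecule at the printed production rate) makes the
  TNF→IKK→NF-κB loop supercritical at *any* dose — measured during
  calibration as a sustained, dose-independent fixed point — so no
  self-limited response exists.  With one catalytic act per molecule, total
  signalling is proportional to the stimulus and the printed self-limited
  behaviour emerges.
- **Nuclear IκBα spawn.**  Transcribed IκBα appears in the nuclear region
  near the transcribing NF-κB.  Spawned in the outer cytosol instead, each
  NF-κB activation yields ≥2 extra cycles before re-inhibition and the
  negative feedback cannot terminate a burst.
- **IL-4 attenuation of TNF-α transcription.**  The narrative of the source
  model is explicit that the anti-inflammatory population suffices "to
  attenuate TNF-α production in macrophages"; without some A→TNF coupling
  the model has no absorbing resolved state (any TNF remnant re-ignites
  kinase activity indefinitely).  Implemented as: a healthy cell carrying
  bound IL-4 emits no TNF-α that cycle (`il4_attenuates_tnf`).
- **Amplified cycles cost amplified energy.** Keeps the latched state
  stable against the boosted anti-inflammatory income; the energy ledger of
  the amplified state is unstated in the source description.
- **Staggered slow receptor recovery (24 h).**  Synchronised fast recovery
  converts the persistent-infection scenario into discrete benign waves and
  erases tolerance memory; a staggered 24 h trickle keeps an overwhelming
  dose's excess LPS in the system with continuous low-grade stimulation.
- **Chemotaxis sectors, tie-breaks, placement separation, contact radius
  1**: as documented in the API; the description gives only the sensing
  radius and "no overlapping".

## Calibration

Free parameters (receptor counts, step lengths, `energy_init`,
`ticks_per_hour`, cytokine lifetimes) were calibrated pattern-oriented
against the published qualitative regimes, primarily the self-limited
pattern (stimulus eliminated within ~1 h, transcriptional resolution within
24 h) — the procedure the `calibrate()` harness automates with its
clearance ≤ 2 h / resolution ≤ 24 h predicate.  The decisive quantity is
the *hottest-cell energy drop* of an episode: with TLR4 binding capacity
4·Σsensitivity = 736, the measured drops separate cleanly into a
resolved-side band (self-limited ≈115–140; tolerance ≈110–120, protected by
its pre-charged reserve and Th2-era income; inhibitor-treated high dose
≈120–160) and a latched-side band (high dose ≈220–275, potentiation
≈190–210), and `energy_init = 234` places the switch threshold (25 %,
i.e. a 175.5-unit drop) between the bands.  These values are the shipped
defaults; every one is sweepable through the config.

## Problem sizes in the shipped suites

The test suite runs the headline self-limited experiment at the published
full size (161×161, 4 macrophages, 20 seeded replicates, 24 h) and the
scenario-ordering properties at 4–5 replicates with 12 h horizons (16 h for
tolerance, whose resolution lands near 13 h) — the attractor class of a
trajectory is settled well before 12 h, so longer horizons only re-confirm
the verdict.  Stochastic rule frequencies use 10⁴ seeded trials (assertions
at 3 binomial standard errors).  The acceptance script
(`scripts/acceptance.py`) re-runs the 20×24 h experiment and the 10⁴-trial
rule measurements from scratch.

## What the synthetic scenarios do and do not show

All inputs are synthetic: dosing schedules printed in the source
description, applied to a calibrated artificial world.  Passing scenarios
demonstrate that the *rule set reproduces the published qualitative
regimes* — self-limited resolution, clearance failure at saturating dose,
an unconstrained response at high dose even after clearance, tolerance
attenuation, potentiation by closely spaced doses, and rescue by kinase
inhibition.  They do not validate the model against clinical outcomes,
transcriptomic data, or quantitative cytokine kinetics; the published
figures are single qualitative trajectories, and no curve fitting to them
is attempted or claimed.

## Known limitations

- Resolved/unresolved fractions at replicate level are definitions of this
  artifact (the source reports single illustrative runs).
- The tick↔hour mapping is a calibration artifact; rule constants are per
  tick, so changing `ticks_per_hour` rescales kinetics in wall-clock hours.
- Cytokine lifetimes for IL-12/IL-4 are assumed, not printed.
- The margin between the tolerance and potentiation regimes is a
  calibrated property of the shipped defaults; distant parameter sets need
  re-calibration (`endosim calibrate`).
- A single spatial compartment: macrophage and T-helper populations share
  one world, with cytokine diffusion standing in for inter-tissue
  transport.
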