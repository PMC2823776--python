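"""Rule constants and world-level parameters.

Every numeric constant that appears in an agent rule lives here, grouped the
way the model is organised: the discrete-tick world (:class:`EngineParams`),
the molecular state machines (:class:`MoleculeParams`), the cellular agents
(:class:`CellParams`) and the outcome classifier (:class:`ObservableParams`).

Defaults fall into two classes.  Constants printed in the source model
description (binding probabilities 70 % / 80 % / 86 %, the 1–799 tick IKK
lifetime, the 600-tick TNF-α budget, the 25-interleukin differentiation
threshold, ...) are fixed at those values.  Constants the model description
leaves open (copy numbers, step lengths, the tick↔hour mapping, the energy
reservoir) carry calibrated defaults chosen so that the self-limited
response clears its stimulus within one simulated hour and resolves within
24 h; see ``docs/methods.md`` for the provenance of each choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class EngineParams:
    """World geometry, tick scheduling and movement."""

    width: int = 161
    height: int = 161
    n_macrophages: int = 4
    #: ticks per simulated hour; the model clock is unitless, this constant
    #: anchors dose times and the classifier to hours.
    ticks_per_hour: int = 400
    #: cellular agents (macrophages, Th cells) move once per this many ticks;
    #: molecular agents move every tick, giving the 800:1 frequency ratio.
    cell_move_interval: int = 800
    #: two agents are "in contact" at toroidal distance <= this (patches).
    contact_radius: float = 1.0
    lps_step_len: float = 20.0
    tnf_step_len: float = 4.0
    cytokine_step_len: float = 4.0
    inhibitor_step_len: float = 8.0
    intra_step_len: float = 1.0
    cell_step_len: float = 1.0

    def validate(self) -> None:
        _check(self.width >= 1 and self.height >= 1, "world size must be >= 1")
        _check(self.n_macrophages >= 0, "n_macrophages must be >= 0")
        _check(self.ticks_per_hour >= 1, "ticks_per_hour must be >= 1")
        _check(self.cell_move_interval >= 1, "cell_move_interval must be >= 1")
        _check(self.contact_radius > 0, "contact_radius must be > 0")
        for name in ("lps_step_len", "tnf_step_len", "cytokine_step_len",
                     "inhibitor_step_len", "intra_step_len", "cell_step_len"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass
class MoleculeParams:
    """Constants of the molecular rule set (stimulus, cytokines, NF-kB triad)."""

    # --- LPS / TLR4 ---
    #: maximum receptor sensitivity; binding succeeds when an integer drawn
    #: uniformly from 1..sensitivity_max compares below the current sensitivity.
    sensitivity_max: int = 5
    #: strict '<' comparison as printed; True switches to '<=' for sweeps.
    sensitivity_inclusive: bool = False
    #: hours for a desensitised receptor to regain one sensitivity unit.
    sensitivity_recovery_hours: float = 24.0
    lps_bound_decay_min: int = 1
    lps_bound_decay_max: int = 2
    #: an activated TLR4 produces 1 TNF-a every this many ticks.
    tlr4_prod_interval: int = 100
    #: a successful binding keeps the receptor activated this many ticks.
    tlr4_activation_window: int = 100
    # --- TNF-a ---
    tnf_free_lifetime: int = 600
    tnf_bound_decay: int = 50
    tnf_bound_decay_il4: int = 200
    #: literal rule: nearby bound IL-4 lengthens bound-TNF decay to 200 ticks.
    #: False selects the alternative narrative reading (IL-4 shortens it,
    #: swapping the two constants).
    il4_extends_tnf: bool = True
    # --- IKK ---
    ikk_prod_interval: int = 5
    ikk_lifetime_min: int = 1
    ikk_lifetime_max: int = 799
    p_bind_ikk: float = 0.70
    ikk_complex_ticks: int = 10
    # --- NF-kB transcription ---
    nfkb_transcribe_interval: int = 10
    p_il12: float = 0.80
    tnf_per_cycle: int = 1
    #: TNF units per transcription cycle while the energy switch is ON.
    tnf_amplified: int = 2
    #: anti-inflammatory counter-regulation: a cell with bound IL-4 (and a
    #: healthy energy switch) emits no TNF-a during transcription.
    il4_attenuates_tnf: bool = True
    # --- IL-4 production ---
    p_il4: float = 0.86
    il4_units: int = 3
    il4_interval_min: int = 1
    il4_interval_max: int = 5
    #: ticks an IL-4 molecule occupies an IL-4 receptor after binding.
    il4_bound_ticks: int = 100
    # --- cytokine lifetimes (not printed in the rule table; see methods) ---
    il12_lifetime: int = 600
    il4_lifetime: int = 600

    def validate(self) -> None:
        for name in ("p_bind_ikk", "p_il12", "p_il4"):
            p = getattr(self, name)
            _check(0.0 <= p <= 1.0, f"{name} must lie in [0, 1], got {p}")
        for name in ("sensitivity_max", "lps_bound_decay_min",
                     "lps_bound_decay_max", "tlr4_prod_interval",
                     "tlr4_activation_window", "tnf_free_lifetime",
                     "tnf_bound_decay", "tnf_bound_decay_il4",
                     "ikk_prod_interval", "ikk_lifetime_min",
                     "ikk_lifetime_max", "ikk_complex_ticks",
                     "nfkb_transcribe_interval", "tnf_per_cycle",
                     "tnf_amplified", "il4_units", "il4_interval_min",
                     "il4_interval_max", "il4_bound_ticks", "il12_lifetime",
                     "il4_lifetime"):
            _check(getattr(self, name) >= 1, f"{name} must be >= 1")
        _check(self.lps_bound_decay_min <= self.lps_bound_decay_max,
               "lps bound-decay range inverted")
        _check(self.ikk_lifetime_min <= self.ikk_lifetime_max,
               "ikk lifetime range inverted")
        _check(self.il4_interval_min <= self.il4_interval_max,
               "il4 interval range inverted")
        _check(self.sensitivity_recovery_hours > 0,
               "sensitivity_recovery_hours must be > 0")


@dataclass
class CellParams:
    """Macrophage composition, the energy switch, and T-helper dynamics."""

    cell_radius: float = 8.0
    nucleus_radius: float = 3.0
    membrane_count: int = 240
    n_tlr4: int = 46
    n_tnfr: int = 20
    n_il4r: int = 20
    #: inactive NF-kB:IkBa complexes per macrophage at start.
    n_nfkb: int = 120
    #: each macrophage must be composed of more than this many agents.
    min_constituents: int = 400
    energy_init: float = 234.0
    #: switch turns ON while energy < energy_switch_frac * energy_init.
    energy_switch_frac: float = 0.25
    #: multiplier on world IL-4/A production while any switch is ON.
    a_boost: int = 2
    th0_entry_threshold: int = 10
    th0_entry_interval: int = 200
    th0_cap: int = 50
    th_diff_threshold: int = 25
    th1_secretion_interval: int = 300
    th2_secretion_interval: int = 50

    def validate(self) -> None:
        _check(self.cell_radius > self.nucleus_radius > 0,
               "need cell_radius > nucleus_radius > 0")
        for name in ("membrane_count", "n_tlr4", "n_tnfr", "n_il4r", "n_nfkb",
                     "a_boost", "th0_entry_interval", "th0_cap",
                     "th_diff_threshold", "th1_secretion_interval",
                     "th2_secretion_interval"):
            _check(getattr(self, name) >= 1, f"{name} must be >= 1")
        _check(self.th0_entry_threshold >= 0, "th0_entry_threshold must be >= 0")
        _check(self.energy_init > 0, "energy_init must be > 0")
        _check(0.0 < self.energy_switch_frac < 1.0,
               "energy_switch_frac must lie in (0, 1)")


@dataclass
class ObservableParams:
    """Resolution classifier settings (artifact definitions, exposed)."""

    #: a channel counts as "at baseline" when within resolve_tol * run peak
    #: of its t=0 value.
    resolve_tol: float = 0.05
    #: hours the three resolution channels must hold baseline through horizon.
    hold_hours: float = 1.0

    def validate(self) -> None:
        _check(0.0 < self.resolve_tol < 1.0, "resolve_tol must lie in (0, 1)")
        _check(self.hold_hours > 0, "hold_hours must be > 0")


@dataclass
class Params:
    """The full parameter set; every rule constant with its default."""

    engine: EngineParams = field(default_factory=EngineParams)
    molecules: MoleculeParams = field(default_factory=MoleculeParams)
    cells: CellParams = field(default_factory=CellParams)
    observables: ObservableParams = field(default_factory=ObservableParams)

    def validate(self) -> "Params":
        self.engine.validate()
        self.molecules.validate()
        self.cells.validate()
        self.observables.validate()
        return self

    # -- derived quantities ------------------------------------------------
    @property
    def sensitivity_recovery_ticks(self) -> int:
        return max(1, round(self.molecules.sensitivity_recovery_hours
                            * self.engine.ticks_per_hour))

    def hours_to_ticks(self, hours: float) -> int:
        return int(hours * self.engine.ticks_per_hour)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, dict[str, Any]]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Params":
        """Build from a nested mapping, rejecting unknown keys by name."""
        params = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, values in data.items():
            if section not in sections:
                raise KeyError(f"unknown parameter section: {section!r}")
            target = getattr(params, section)
            known = {f.name: f.type for f in dataclasses.fields(target)}
            if not isinstance(values, Mapping):
                raise TypeError(f"section {section!r} must be a mapping")
            for key, value in values.items():
                if key not in known:
                    raise KeyError(f"unknown parameter: {section}.{key}")
                if not isinstance(value, (int, float, bool)):
                    raise TypeError(
                        f"parameter {section}.{key} must be numeric or bool")
                setattr(target, key, value)
        return params.validate()

    def override(self, dotted: Mapping[str, Any]) -> "Params":
        """Return a copy with ``section.name -> value`` overrides applied."""
        new = Params.from_dict(self.to_dict())
        for path, value in dotted.items():
            section, _, key = path.partition(".")
            if not key:
                raise KeyError(f"override {path!r} must be 'section.key'")
            target = getattr(new, section, None)
            if target is None or not hasattr(target, key):
                raise KeyError(f"unknown parameter: {path}")
            setattr(target, key, value)
        return new.validate()
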