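"""Dose-dependent fate: self-limited vs unconstrained vs persistent.

The same world responds qualitatively differently to 350, 750 and 1000
units of endotoxin: the low dose resolves; the high dose is cleared but the
energy switch latches the cells into amplified TNF-α production (an
unconstrained response); the overwhelming dose saturates the receptors so
LPS is never eliminated at all.
"""

import endosim as es

params = es.Params()
for name in ("self_limited", "high_dose", "persistent_infectious"):
    spec = es.builtin_scenario(name, run_hours=12.0)
    series = es.run_scenario(spec, params, seed=1)
    report = es.classify(series, tol=0.05, hold_hours=1.0)
    dose = ", ".join(f"{d.species} {d.amount}@{d.time_hours:g}h"
                     for d in spec.doses)
    clear = (f"{report.clearance_time_hours:.2f} h"
             if report.clearance_time_hours is not None
             else "never (LPS remains)")
    print(f"{name:22s} [{dose}]")
    print(f"    clearance: {clear:24s} resolved by 12 h: {report.resolved}")
    print(f"    peak TNF-a: {report.peaks['tnf_free']:.0f}   "
          f"peak P: {report.peaks['P']:.0f}   "
          f"final E: {series.E.iloc[-1]:.0f}")
# Expected pattern: only the 350-unit run resolves; the 750-unit run ends
# with E driven to zero and TNF-a sustained (bistable latched state); the
# 1000-unit run still has LPS in circulation at the horizon.
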