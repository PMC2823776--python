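"""Therapeutic intervention: IKK inhibition rescues a high endotoxin dose.

400 units of an IKK inhibitor injected together with 750 units of LPS
diffuse into the cytosol and neutralise kinase one-for-one during the acute
wave, keeping the transcriptional burden below the energy-switch threshold
that would otherwise latch the unconstrained response.
"""

import endosim as es

params = es.Params()
for name in ("high_dose", "ikk_inhibitor"):
    spec = es.builtin_scenario(name, run_hours=12.0)
    series = es.run_scenario(spec, params, seed=1)
    report = es.classify(series, tol=0.05, hold_hours=1.0)
    doses = " + ".join(f"{d.species} {d.amount}" for d in spec.doses)
    print(f"{name:14s} [{doses}]")
    print(f"    resolved by 12 h: {report.resolved}   "
          f"peak TNF-a: {report.peaks['tnf_free']:.0f}   "
          f"min E: {series.E.min():.0f}")
# The inhibited run keeps its energy reserve and resolves within hours;
# the uninhibited 750-unit run drains to E = 0 and stays inflamed.
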