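"""The stochastic micro-rules, measured one at a time.

Each printed frequency should sit within sampling error of its rule
constant: receptor binding at (sensitivity-1)/5, IKK -> NF-kB binding at
70 %, IL-12 emission at 80 % per transcription cycle, and the 3-unit IL-4
burst at 86 % per production cycle.
"""

import numpy as np

import endosim as es
from endosim import molecules as mol

N = 5000

# --- LPS/TLR4 sensitivity rule ------------------------------------------
w = es.build_fixture("one_receptor_one_lps", seed=1)
mac = w.macrophages[0]
for sens in (5, 3, 1):
    hits = 0
    for _ in range(N):
        mac.tlr4_sens[0] = sens
        hits += mol.attempt_lps_binding(w, 0, 0, 0)
        w.lps["bound"][0] = 0
        mac.tlr4_occupied_until[0] = 0
        if w.tnf.n > 1000:
            w.tnf.remove(np.ones(w.tnf.n, dtype=bool))
    print(f"TLR4 binding at sensitivity {sens}: {hits / N:.3f} "
          f"(rule: {(sens - 1) / 5:.1f})")

# --- IKK -> NF-kB 70% rule ----------------------------------------------
w = es.build_fixture("single_macrophage", seed=1)
mac = w.macrophages[0]
w.nfkb.remove(np.ones(w.nfkb.n, dtype=bool))
spot = mac.center + np.array([mac.nucleus_radius + 2.0, 0.0])
w.nfkb.add(x=spot[0], y=spot[1], cell=0, state=mol.NFKB_COMPLEXED,
           release_at=-1, next_tx=-1)
w.ikk.add(x=spot[0], y=spot[1], cell=0, state=mol.IKK_ACTIVE,
          expire_at=10**9, release_at=-1)
hits = 0
for _ in range(N):
    if mol.ikk_bind_nfkb(w, 0, 0):
        hits += 1
        w.ikk["state"][0] = mol.IKK_ACTIVE
        w.nfkb["state"][0] = mol.NFKB_COMPLEXED
print(f"IKK binds inactive NF-kB complex:  {hits / N:.3f} (rule: 0.70)")

# --- transcription: IL-12 at 80% per cycle ------------------------------
w = es.build_fixture("nfkb_unit", seed=1)
w.macrophages[0].energy = 10**9
w.macrophages[0].energy_init = 10**9
il12 = sum(mol.nfkb_transcribe(w, 0)["il12"] for _ in range(N))
print(f"IL-12 emissions per cycle:         {il12 / N:.3f} (rule: 0.80)")

# --- IL-4 production at 86% per cycle -----------------------------------
w = es.build_fixture("empty", seed=1)
w.il12.add(x=50.0, y=50.0, expire_at=10**18)
bursts = 0
for _ in range(N):
    bursts += mol.il4_production_cycle(w) == 3
    if w.il4.n > 2000:
        w.il4.remove(np.ones(w.il4.n, dtype=bool))
print(f"3-unit IL-4 bursts per cycle:      {bursts / N:.3f} (rule: 0.86)")
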