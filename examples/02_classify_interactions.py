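"""Classify pairwise coculture outcomes from biofilm yields.

Three hand-made assays show the three regimes: a coculture out-producing the
best monoculture (positive), one falling below the monoculture average
(negative), and one inside the buffer (unresolved).
"""

import trophnet as tn

mono_a = [0.40, 0.42, 0.38]   # replicate A590 biofilm yields, strain A alone
mono_b = [0.30, 0.31, 0.29]   # strain B alone

for co, label in [([0.55, 0.57, 0.53], "synergy"),
                  ([0.20, 0.21, 0.19], "antagonism"),
                  ([0.37, 0.38, 0.36], "ambiguous")]:
    res = tn.classify_pair(mono_a, mono_b, co)
    print(f"{label}: coculture mean {res.co_mean:.2f} vs best mono "
          f"{res.best_mono_mean:.2f} / avg mono {res.avg_mono_mean:.2f} "
          f"-> {res.regime} (p+={res.p_positive:.3g}, p-={res.p_negative:.3g})")

print("\nintensity (the coculture mean itself) becomes the network edge weight.")
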