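"""Score a drug combination with the fractional-product null.

Uses effect triples like those reported in dose-finding experiments: the
cytostatic alone, the modulator alone, and the combination, all on the TGI
scale.
"""

import precombi as pc

cases = [
    ("low-dose cytostatic + modulator", 48, 6, 70),
    ("within band but below cytostatic", 38, 1, 36),
    ("tolerance-band case", 38, 1, 40),
    ("modulator worse than control", 38, -35, 36),
    ("high doses", 87, 25, 96),
]

for label, e_cyt, e_mod, e_obs in cases:
    v = pc.score_combination("TGI", e_cyt, e_mod, e_obs)
    print(
        f"{label:35s} E1={e_cyt:>3} E2={e_mod:>4} observed={e_obs:>3} "
        f"%H={v.h_expected:6.2f} -> {v.verdict.value}"
    )

print()
print("%H is the expected combined effect if the agents act independently;")
print("observed above it = synergism, within ±3 points = additive, below it")
print("= subadditive, and below the cytostatic alone = antagonism.")
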