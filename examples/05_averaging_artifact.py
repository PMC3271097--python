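"""Why averaging across start positions hides the start-position effect.

Generates data in which fixations 2+ shift toward the side of the face
opposite the start position. Averaged across the four peripheral start
positions those opposite shifts cancel, so the pooled mean fixation
location regresses to the face center even though every individual
condition is strongly displaced.
"""

from fixmap import GeneratorConfig, averaging_demo

cfg = GeneratorConfig(n_participants=8, n_faces=8, trials_per_cell_study=10,
                      trials_per_cell_test=1, delta=1.5, kappa=0.3, seed=5)
table = averaging_demo(cfg)

for ordinal in (1, 2):
    sub = table[table["ordinal"] == ordinal]
    print(f"\nordinal fixation {ordinal} - mean offset from face center "
          "(deg; +x right, +y down):")
    print(sub[["start_position", "dx", "dy"]].round(2).to_string(index=False))

print(
    "\nPer-start means for fixation 2 are displaced toward the opposite "
    "side (left start -> +x, upper start -> +y ...), while the "
    "start-averaged row sits near zero: pooling start positions averages "
    "away the very effect that structures the data."
)
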