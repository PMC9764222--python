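"""Build the oddball design: pairings, hazard probabilities, amplitude models.

Each trial presents eight sounds; the deviant occupies position 4, 5, or
6 with equal probability, so its conditional probability (hazard) rises
1/3 -> 1/2 -> 1 across the allowed positions.
"""

import numpy as np

from oddball_fmri import design

pairings = design.build_stimulus_pairings(design.default_pure_tones())
print("Six standard/deviant pairings (Δ = absolute frequency difference):")
for p in pairings:
    print(f"  {p.name:16s} Δ = {p.delta:5.0f} Hz")

print("\nDeviant hazard: P(deviant at d | no deviant yet)")
for d in (4, 5, 6):
    print(f"  position {d}: {design.predictability(d, d, exact=True)}")

print("\nAmplitude models (deviant at position 5):")
print("  h1 (habituation)     :", np.round(design.h1_amplitudes(5), 3))
print("  h2 (prediction error):", np.round(design.h2_amplitudes(5), 3))
print("Under h1 responses decay with repetition; under h2 each sound's")
print("amplitude equals the probability of hearing it at that position.")

run = design.build_run(seed=0)
events = design.event_table(run)
print(f"\nOne run: {len(run.trials)} trials, {len(events)} sounds, "
      f"duration {run.duration:.0f} s,")
print(f"ITIs in [{run.itis.min():.2f}, {run.itis.max():.2f}] s, "
      f"deviant-position counts "
      f"{np.bincount(run.deviant_positions())[4:].tolist()} (always 20 each).")
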