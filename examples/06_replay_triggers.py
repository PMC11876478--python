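"""Real-time emulation: stream the test minute and fire phase triggers.

The trained network is driven sample by sample over the replayed stream;
whenever its predicted phase enters a 5-degree window around a target
(rising edge 0, peak 90, falling edge 180, trough 270 - protocol
convention) and the refractory period has elapsed, a trigger is emitted.
Each trigger is then scored against the true phase at that instant, which
is what a phase-locked stimulation session would have hit.
"""

import time
import warnings

from eegphase import pipeline, simulate

print("generating one subject and training the network ...")
sub = simulate.synthetic_subject(seed=4, target_snr=2.5)
cfg = pipeline.RunConfig(models=("epn",), replications=25,
                         refractory_s=0.5, epochs=300, seed=4)
t0 = time.time()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    rep = pipeline.run_benchmark([sub], cfg, evaluation="triggers")
print(f"replay done in {time.time() - t0:.0f} s\n")

print("target  |   n  |  ACC (%) | MACE (rad) | circ. mean (deg)")
import numpy as np
for row in rep["summaries"]:
    tag = row["phase"] if row["phase"] == "all" else f"{row['phase']:.0f} deg"
    print(f"{tag:>7} | {row['n']:4d} | {100*row['acc']:8.2f} | "
          f"{row['mace']:10.3f} | {np.degrees(row['mean']):+8.2f}")
# ACC counts how close triggered instants landed to the requested phase of
# the true rhythm; the circular mean near zero shows the triggers are
# unbiased rather than systematically early or late.
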