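"""Offline benchmark: all four models on a small synthetic cohort.

Each subject's 4-min training range trains the learned models (EPN, MLOF)
and calibrates ETP; the held-out final minute is epoch-scored against the
noise-free rhythm phase.  The report carries per-subject circular error
summaries, pairwise Wilcoxon comparisons of accuracy, and (with >= 3
subjects) the accuracy ~ SNR regression.
"""

import time
import warnings

import numpy as np

from eegphase import pipeline, simulate

n_subjects = 3
print(f"generating {n_subjects} subjects at target SNR 2 ...")
subs = [simulate.synthetic_subject(seed=10 + i, target_snr=2.0)
        for i in range(n_subjects)]

cfg = pipeline.RunConfig(seed=0, epochs=300)
t0 = time.time()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    rep = pipeline.run_benchmark(subs, cfg, evaluation="windows")
print(f"benchmark done in {time.time() - t0:.0f} s\n")

print(pipeline.report_to_rows(rep))
for kind, accs in rep["acc"].items():
    print(f"{kind:5s} mean ACC {100 * np.mean(accs):5.2f} %")
print("\npairwise Wilcoxon (Bonferroni-adjusted p):")
for pair, p in rep["comparisons"].items():
    print(f"  {pair}: p = {p:.3f}")
# The expected picture mirrors the method's motivation: the trained network
# leads, peak interpolation (ETP) follows, and the untrained AR chain
# suffers most from the background noise.
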