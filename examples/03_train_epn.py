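"""Train the phase prediction network on one synthetic subject.

The network maps the 250 first-order differences of the causal half second
before "time 0" to a 2-vector whose angle is the predicted phase.  Training
regresses that vector onto (cos theta, sin theta) of the true phase.  Here
a desk-scale schedule (300 epochs, Adam 1e-3) is used; predictions on the
held-out final minute are scored against the noise-free rhythm phase.
"""

import time

from eegphase import epn, metrics, simulate, windowing

print("generating a 5-min subject at SNR 3 ...")
rec = simulate.synthetic_subject(seed=7, duration_s=300.0, rate=1000.0,
                                 target_snr=3.0)
r5 = rec.resample_to(500.0)

ds = windowing.build_dataset(r5.signal, 500.0, kind="epn",
                             true_phase=r5.true_phase)
print(f"windows: {len(ds['train'][1])} train, {len(ds['val'][1])} val, "
      f"{len(ds['test'][1])} test")

cfg = epn.EPNConfig.desk_scale(seed=0, epochs=300)
t0 = time.time()
weights, trace = epn.train(ds["train"][:2], ds["val"][:2], cfg)
print(f"trained in {time.time() - t0:.1f} s; "
      f"loss {trace['train'][0]:.3f} -> {trace['train'][-1]:.3f}")

pred = epn.predict_phase(ds["test"][0], weights, cfg)
print("held-out vs true rhythm phase:", metrics.summarize_errors(pred, ds["test"][1]))
# ACC near 1 and MACE near 0 mean the causal network recovers the phase the
# non-causal chain can only compute after the fact.
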