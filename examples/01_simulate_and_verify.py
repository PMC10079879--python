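"""Generate a synthetic 40-class SSVEP recording set and verify that the
class signal is recoverable by classical matched-frequency spectral
analysis (no learning involved).

The generated data mimics a cued-flicker experiment: each trial's class is
a stimulus frequency between 8.0 and 15.8 Hz (0.2 Hz steps); the response
appears as a harmonic stack over posterior channels on top of pink + white
noise, with per-subject amplitude/phase offsets.
"""

import numpy as np

from eegformer import (DEFAULT_STIMULUS_FREQS, DatasetSpec, SimulationConfig,
                       generate_ssvep_set, spectral_match_classify)

spec = DatasetSpec(n_subjects=10, epp=1, tpe=40, chn=9, sr=250.0, tlpt=2.0)
cfg = SimulationConfig(spec=spec, seed=3)
recs = generate_ssvep_set(cfg)
print(f"generated {len(recs)} trials, {recs.n_channels} channels "
      f"({', '.join(recs.montage[:4])}, ...) at {recs.sr:.0f} Hz")

pred = spectral_match_classify(recs, DEFAULT_STIMULUS_FREQS)
acc = (pred == recs.labels).mean()
print(f"matched-frequency spectral classification: {100 * acc:.1f}% correct")
print("-> the generator carries class-discriminative frequency content; "
      "anything a trained network achieves can be compared against this "
      "closed-form baseline.")

errors = np.flatnonzero(pred != recs.labels)
if errors.size:
    i = errors[0]
    print(f"   (e.g. trial {i}: true {DEFAULT_STIMULUS_FREQS[recs.labels[i]]}"
          f" Hz, predicted {DEFAULT_STIMULUS_FREQS[pred[i]]} Hz)")
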