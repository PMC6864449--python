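"""Turn one recording into the fixed-length feature vector, step by step.

Shows the intermediate sizes: band-pass filtering preserves length,
framing fixes it to 50,000 samples (12.5 s at 4 kHz), and two-stage
8 x 8 decimation reduces it to 782 features with max |value| = 1.
"""

import numpy as np

from pcglearn import (
    ClassLabel,
    DecimationConfig,
    FramingConfig,
    SynthConfig,
    bandpass_zero_phase,
    decimate_signal,
    featurize,
    frame_fixed,
    generate_recording,
)

rec = generate_recording(SynthConfig(), ClassLabel.MURMUR, 7, duration_s=6.0)
print(f"raw recording:   {len(rec):6d} samples at {rec.rate} Hz "
      f"({len(rec)/rec.rate:.1f} s)")

filtered = bandpass_zero_phase(rec)
print(f"band-passed:     {len(filtered):6d} samples (50-800 Hz, zero phase)")

framed = frame_fixed(filtered, FramingConfig())
print(f"framed:          {len(framed):6d} samples (6-s file tiled to 12.5 s)")

features = decimate_signal(framed, DecimationConfig(factor=8, stages=2))
print(f"decimated:       {len(features):6d} features (50,000 / 8 / 8, "
      "ceil per stage)")

fv = featurize(rec)  # the one-call equivalent (plus final normalisation)
print(f"featurize():     {len(fv):6d} features, "
      f"max |value| = {np.max(np.abs(fv.values)):.3f}")
# 782 features per recording is the fixed classifier input size; murmur
# recordings keep visibly more inter-beat energy in this vector than
# normal ones (median |value| here ~0.05 vs ~0.01 for a normal sibling).
print(f"median |value| = {np.median(np.abs(fv.values)):.4f}")
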