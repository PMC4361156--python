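"""Reduce one swallow to its nine per-channel features.

Per channel: skewness and (non-excess) kurtosis; the entropy-rate regularity
index (1 = perfectly regular, ~0 = random) from a 10-level quantisation; the
normalised Lempel-Ziv complexity from a 100-level quantisation; peak
frequency, magnitude-weighted spectral centroid and bandwidth; and the
Shannon entropy of the wavelet level-energy distribution.  The duration is
shared across channels since all transducers see the same segmentation.
"""

import swallowkit as sk

spec = sk.CohortSpec(n_subjects=1, fs=4000.0, seed=42)
subject = sk.SubjectMeta(subject_id="S000", sex="male", age=51.0)
rec, truth = sk.gen_recording(spec, subject, seed=3)

models = sk.baseline_ar_models(spec)
clean = sk.preprocess_recording(rec, models)
segments = sk.segment_recording(clean)
table = sk.extract_features(clean, segments[:1])

wide = table.pivot_table(index="feature", columns="channel", values="value")
print(wide.round(3).to_string())
print()
print("The SOUND channel sits higher in centre frequency and bandwidth than")
print("either accelerometer axis, as swallowing sounds do; noise-carrier")
print("bursts are less regular than real swallows, so the entropy-rate index")
print("lands below the ~0.98 typical of human recordings.")
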