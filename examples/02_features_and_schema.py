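"""Extract the texture/shape feature vector of segmented regions.

Shows the 23-feature schema (9 texture + 14 shape statistics) computed for
each candidate region; these vectors are the only input the classifier
sees.
"""

from fincount import FEATURE_NAMES, SceneConfig, extract_features, generate_sequence, segment_frame

cfg = SceneConfig(n_frames=10, rng_seed=8)
seq, _, truth = generate_sequence(cfg)
rois = next(r for r in (segment_frame(seq, i) for i in range(1, 10)) if r)

vec = extract_features(rois[0])
print(f"schema: {len(FEATURE_NAMES)} features")
for name, value in zip(FEATURE_NAMES, vec):
    print(f"  {name:22s} {value:10.4f}")
# intensity_* and glcm_* describe the patch texture; hull/solidity/Hu
# describe the region geometry. All are finite by contract.
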