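"""Generate a short synthetic camera sequence and segment one frame.

Prints the number of candidate regions found by consecutive-frame
differencing on a frame with a known number of fish; regions in excess of
the true count are motion "ghosts" (the fish's previous position) that the
classifier stage later rejects.
"""

from fincount import SceneConfig, generate_sequence, segment_frame

cfg = SceneConfig(n_frames=20, day_fish_mean=3.0, rng_seed=8)
seq, annotations, truth = generate_sequence(cfg)

index = next(i for i in range(1, 20) if truth.counts[i] >= 2)
rois = segment_frame(seq, index)
print(f"frame {index}: true fish count = {truth.counts[index]}")
print(f"candidate regions (fish + motion ghosts) = {len(rois)}")
for roi in rois:
    print(f"  bbox={roi.bbox} area={roi.area_px}px hull_vertices={len(roi.hull)}")
# Expect roughly 2x the true count: each moving fish leaves one region at
# its new position and one ghost at its old position.
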