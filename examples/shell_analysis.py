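"""Location-resolved motion statistics in equal-area nuclear shells.

Segments a rendered nucleus, splits it into 7 nested shells of equal area
(convex hull scaled by sqrt(i/7) about its centroid), assigns each
trajectory to the shell holding most of its points, and compares the outer
shell against the interior with rank-sum tests. Here tracks near the
nuclear border are simulated slower, mimicking peripheral chromatin.
"""

import numpy as np

from chromomotion import (
    MotionSpec,
    SceneConfig,
    assign_tracks,
    make_shells,
    motion_properties_table,
    per_shell_stats,
    render_timelapse,
    segment_nucleus,
    simulate_tracks,
)

cfg = SceneConfig(seed=21)
cx, cy, cz = cfg.nucleus_center_um
ax, ay, _ = cfg.nucleus_semiaxes_um

rng = np.random.default_rng(21)
tracks = []
tid = 0
for n, rfrac, D in ((120, (0.88, 1.0), 4e-5), (120, (0.0, 0.88), 8.32e-5)):
    # peripheral tracks (outer radii) at half the mobility of interior ones
    for _ in range(n):
        while True:
            u = rng.uniform(-1, 1, 2)
            r = np.hypot(*u)
            if rfrac[0] <= r <= rfrac[1]:
                break
        start = np.array([cx + u[0] * ax, cy + u[1] * ay, cz])
        tr = simulate_tracks(MotionSpec(model="brownian", D=D), 1, rng=rng)[0]
        tr.positions_um = tr.positions_um + start
        tr.track_id = tid
        tracks.append(tr)
        tid += 1

stack, _ = render_timelapse([], cfg)  # nucleus channel only is needed
mask = segment_nucleus(stack.frame(0, 0).max(axis=0))
part = make_shells(mask, 7, voxel_size_yx_um=cfg.voxel_size_um[1:])
shell_of = assign_tracks(tracks, part)

props = motion_properties_table(tracks)
summary, pvals = per_shell_stats(props, shell_of, ["mean_velocity_um_s"])
print("tracks per shell:", dict(summary[("mean_velocity_um_s", "count")]))
print("\nmean velocity (um/s) per shell:")
print(summary[("mean_velocity_um_s", "mean")].round(5).to_string())
print("\nrank-sum p-values, shell 1 (outer, slowed) vs. shells 2..7:")
print(pvals["mean_velocity_um_s"].map("{:.2e}".format).to_string())
print("\nsmall p-values in the interior comparisons reflect the constructed border effect.")
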