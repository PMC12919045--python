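"""Generate a synthetic movie and turn it into a membrane kymograph.

A deforming, drifting cell carries a traveling intensity wave on its
membrane. The pipeline extracts and aligns the boundary, samples the
membrane, and builds the kymograph; we then compare against the
generator's known ground truth.
"""

import tempfile
from pathlib import Path

import numpy as np

import memkymo as mk

out = Path(tempfile.mkdtemp(prefix="memkymo_example_"))
spec = mk.SynthSpec(
    n_frames=24, height=256, width=256, base_radius=60.0,
    pattern="traveling_wave", drift=0.5, noise_sigma=2.0, seed=1,
)
truth = mk.write_movie(spec, out / "movie.tif", out / "mask.tif")

cfg = mk.RunConfig(
    image_path=str(out / "movie.tif"), mask_path=str(out / "mask.tif"),
    out_root=str(out), rng_seed=1,
)
result = mk.run_pipeline(cfg)
k = result.kymographs[0]

ideal = truth.ideal_kymograph(k.n_rows, k.n_frames)
r = np.corrcoef(k.normalized.ravel(), ideal.ravel())[0, 1]

print(f"kymograph shape (rows x frames): {k.raw.shape}")
print(f"per-frame circular shifts: {result.series.shifts[:6]} ...")
print(f"normalization anchors (2nd/98th pct): {k.norm_lo:.2f} / {k.norm_hi:.2f}")
print(f"correlation with generator ground truth: r = {r:.3f}")
print(f"outputs written under: {out}")
# r close to 1 means the pipeline's aligned, normalized kymograph
# reproduces the known membrane pattern; the shifts show how each frame's
# outline was re-indexed to keep membrane positions consistent over time.
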