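"""Regenerate the bundled precomputed segmentation matrices.

Builds a fixed-seed synthetic calibration set of 25 ROIs spanning a wide
range of Ki67 indices, pools their pixels, clusters them into the
background / hematoxylin / DAB centroids, derives the chroma projection,
and commits the result as a JSON fixture used by the presence check.

Run from the repository root:

    python scripts/make_precomputed.py
"""

from pathlib import Path

import numpy as np

from ki67area.segmentation import PrecomputedModel, cluster_pixel_array
from ki67area.synth import ROISpec, generate_dataset

CALIBRATION_SEED = 20180903
N_CALIBRATION_ROIS = 25
OUT = Path(__file__).resolve().parents[1] / "src" / "ki67area" / "data" / "precomputed_hdab.json"


def main() -> None:
    template = ROISpec(n_positive=30, n_negative=30, width=400, height=240)
    rois, _ = generate_dataset(
        n_rois=N_CALIBRATION_ROIS,
        index_range=(10.0, 70.0),  # every calibration ROI carries both stains
        template=template,
        seed=CALIBRATION_SEED,
    )
    pixels = np.concatenate([roi.image.reshape(-1, 3)[::7] for roi in rois])
    model = cluster_pixel_array(pixels, k=3, seed=0)
    pre = PrecomputedModel.from_cluster_model(model)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    pre.to_json(OUT)
    print(f"wrote {OUT}")
    print("centroids (RGB):")
    for role, c in zip(model.roles, model.centroids):
        print(f"  {role:12s} {np.round(c, 1)}")
    print(f"presence threshold: {pre.presence_threshold:.3f}")


if __name__ == "__main__":
    main()
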