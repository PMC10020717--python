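"""Train the shape autoencoder on pooled cross-section rasters.

Compresses 68x68 binary lumen images to a 4-dimensional code and checks the
round-trip reconstruction quality by pixel-count IoU.
"""

import numpy as np

from hemoline import (
    GeometryParams,
    build_case,
    rasterize_section,
    reconstruction_iou,
    sample_geometry_params,
    train_autoencoder,
)

images = []
for k in range(6):
    case = build_case(sample_geometry_params(seed=40 + k))
    images += [rasterize_section(s) for s in case.sections]
print(f"corpus: {len(images)} cross-section rasters from 6 geometries")

held = images[-120:]
model = train_autoencoder(images[:-120], m=4, seed=0, epochs=80)
print(f"trained m=4 autoencoder, final MSE {model.final_loss:.5f}")
print(f"held-out reconstruction IoU: {reconstruction_iou(model, held):.3f}")

valve_img = images[15]   # a valve-region orifice raster
vessel_img = images[60]  # a regular vessel section
print("valve section code: ", np.round(model.encode(valve_img), 3))
print("vessel section code:", np.round(model.encode(vessel_img), 3))
# Distinct shape families land in distinct corners of the 4-D code space;
# these codes are the per-point shape feature the LSTM consumes.
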