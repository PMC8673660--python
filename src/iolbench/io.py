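"""Raster and metadata export: float TIFF for fields/PSFs, PNG for images,
plain-text key:value sidecars for physical metadata."""

from __future__ import annotations

import numpy as np
import tifffile
from PIL import Image

__all__ = ["save_intensity_tiff", "save_complex_tiff", "save_png",
           "write_sidecar"]


def write_sidecar(path, **meta):
    with open(str(path) + ".meta.txt", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}: {v}\n")


def save_intensity_tiff(path, raster, pitch_mm, **meta):
    tifffile.imwrite(path, np.asarray(raster, dtype=np.float32))
    write_sidecar(path, pitch_mm=pitch_mm, **meta)


def save_complex_tiff(path, field, **meta):
    """Field snapshot: paired real/imaginary float TIFF pages + sidecar."""
    amp = field.amplitude
    tifffile.imwrite(path, np.stack([amp.real, amp.imag]).astype(np.float32))
    write_sidecar(path, pitch_x_mm=field.pitch_x, pitch_y_mm=field.pitch_y,
                  wavelength_nm=field.wavelength,
                  medium_index=field.medium_index, z_mm=field.z,
                  carrier_curvature_per_mm=field.carrier_curvature, **meta)


def save_png(path, raster, gamma=0.5):
    """8-bit PNG of an intensity raster (gamma-compressed for display)."""
    r = np.asarray(raster, dtype=float)
    r = r / r.max() if r.max() > 0 else r
    img = (255 * np.clip(r, 0, 1) ** gamma).astype(np.uint8)
    Image.fromarray(img).save(path)
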