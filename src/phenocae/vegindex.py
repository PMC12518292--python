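"""Vegetation indices as per-plot baseline features.

Thirteen standard indices are computed per pixel from the 6-band
reflectance and then averaged over the plot's pixels. Indices are
evaluated on outlier-clipped but *not* min-max-normalized reflectance:
min-max scaling is an affine per-channel map and would distort ratio
indices. All denominators are guarded by eps = 1e-12.

Coefficient conventions (recorded here once): EVI uses the standard
MODIS constants G=2.5, C1=6, C2=7.5, L=1; SAVI uses L=0.5 in its
1.5*(N-R)/(N+R+0.5) form; VEG uses a=0.667; ExG/ExR operate on the
chromatic coordinates r=R/(R+G+B), g=G/(R+G+B), b=B/(R+G+B).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import BAND_NAMES, PlotImage

EPS = 1e-12

#: Fixed output order of the feature table.
INDEX_NAMES: tuple[str, ...] = (
    "GLI", "NGRDI", "VARI", "VEG", "RGBVI", "ExG", "ExR",
    "NDVI", "GNDVI", "EVI", "SAVI", "NDRE", "RDVI",
)

#: Bands each index needs (subset of Red, Green, Blue, NIR, RedEdge).
REQUIRED_BANDS: dict[str, tuple[str, ...]] = {
    "GLI": ("Red", "Green", "Blue"),
    "NGRDI": ("Red", "Green"),
    "VARI": ("Red", "Green", "Blue"),
    "VEG": ("Red", "Green", "Blue"),
    "RGBVI": ("Red", "Green", "Blue"),
    "ExG": ("Red", "Green", "Blue"),
    "ExR": ("Red", "Green", "Blue"),
    "NDVI": ("Red", "NIR"),
    "GNDVI": ("Green", "NIR"),
    "EVI": ("Red", "Blue", "NIR"),
    "SAVI": ("Red", "NIR"),
    "NDRE": ("NIR", "RedEdge"),
    "RDVI": ("Red", "NIR"),
}


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.where(np.abs(den) < EPS, np.where(den < 0, -EPS, EPS), den)
    return num / den


def _pixel_index(name: str, bands: dict[str, np.ndarray]) -> np.ndarray:
    r = bands.get("Red")
    g = bands.get("Green")
    b = bands.get("Blue")
    n = bands.get("NIR")
    re = bands.get("RedEdge")
    if name == "NDVI":
        return _safe_div(n - r, n + r)
    if name == "GNDVI":
        return _safe_div(n - g, n + g)
    if name == "NDRE":
        return _safe_div(n - re, n + re)
    if name == "RDVI":
        return _safe_div(n - r, np.sqrt(np.maximum(n + r, EPS)))
    if name == "EVI":
        return _safe_div(2.5 * (n - r), n + 6.0 * r - 7.5 * b + 1.0)
    if name == "SAVI":
        return _safe_div(1.5 * (n - r), n + r + 0.5)
    if name == "NGRDI":
        return _safe_div(g - r, g + r)
    if name == "GLI":
        return _safe_div(2.0 * g - r - b, 2.0 * g + r + b)
    if name == "VARI":
        return _safe_div(g - r, g + r - b)
    if name == "RGBVI":
        return _safe_div(g * g - r * b, g * g + r * b)
    if name == "VEG":
        a = 0.667
        return _safe_div(g, np.maximum(r, EPS) ** a * np.maximum(b, EPS) ** (1.0 - a))
    if name in ("ExG", "ExR"):
        tot = np.maximum(r + g + b, EPS)
        rc, gc, bc = r / tot, g / tot, b / tot
        return 2.0 * gc - rc - bc if name == "ExG" else 1.4 * rc - gc
    raise ValueError(f"unknown vegetation index {name!r}")


def _band_arrays(image: PlotImage) -> dict[str, np.ndarray]:
    if image.n_channels > len(BAND_NAMES):
        raise ValueError(f"image has {image.n_channels} channels; band order unknown")
    return {BAND_NAMES[c]: image.pixels[:, :, c].astype(float)
            for c in range(image.n_channels)}


def compute_vi(image: PlotImage, name: str) -> float:
    """One index for one plot: per-pixel evaluation, then the plot mean."""
    if name not in REQUIRED_BANDS:
        raise ValueError(f"unknown vegetation index {name!r}; known: {INDEX_NAMES}")
    bands = _band_arrays(image)
    missing = [b for b in REQUIRED_BANDS[name] if b not in bands]
    if missing:
        raise ValueError(f"{name} requires missing band(s) {missing}")
    return float(np.mean(_pixel_index(name, bands)))


def vi_feature_table(images) -> pd.DataFrame:
    """All 13 indices for every plot, columns in the fixed order."""
    rows = []
    for im in images:
        row = {"plot_id": im.plot_id}
        row.update({name: compute_vi(im, name) for name in INDEX_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["plot_id", *INDEX_NAMES])
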