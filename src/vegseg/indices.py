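"""Vegetation spectral indices and the 10-channel feature stack.

Six per-pixel band-ratio transforms are derived from the four native
channels and stacked with them, giving the 10-channel feature cube the
segmentation engines cluster:

====== ==============================================================
NDVI   (NIR - Red) / (NIR + Red) -- vegetation signal
EVI    2.5 (NIR - Red) / (NIR + 6 Red + 7.5 Blue + 1) -- vegetation signal
SAVI   (NIR - Red)(1 + L) / (NIR + Red + L) -- suppresses soil background
CI     1 - (Red - Blue) / (Red + Blue) -- crust/soil index
ARVI   (NIR - 2 Red + Blue) / (NIR + 2 Red + Blue) -- atmosphere-resistant
VARI   (Green - Red) / (Green + Red + Blue) -- atmosphere-resistant, visible
====== ==============================================================

Two formula dialects are supported. ``as_printed`` (the default) uses the
denominators exactly as tabulated in the source material this pipeline
follows, in which EVI, ARVI and VARI carry a ``+`` where the classical
formulations have a ``-`` (ARVI: NIR + 2 Red + Blue; VARI:
Green + Red + Blue; EVI: +7.5 Blue). ``canonical`` restores the classical
signs. The dialect in force is stamped into every stack.

All indices are computed on [0, 1]-scaled reflectance-like values, not raw
digital numbers. NDVI, CI and VARI-like ratios are invariant to that
choice; EVI and SAVI are not, so fixing it matters.

Division guards: an additive epsilon keeps every denominator nonzero;
pixels whose unguarded denominator would vanish are tallied per index in
``ChannelStack.degenerate_counts`` instead of becoming NaN, so downstream
clustering needs no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_core import Raster

__all__ = [
    "IndexParams",
    "ChannelStack",
    "ndvi",
    "evi",
    "savi",
    "ci",
    "arvi",
    "vari",
    "build_stack",
    "STACK_CHANNELS",
]

#: Fixed channel order of the feature stack.
STACK_CHANNELS = ("blue", "green", "red", "nir",
                  "ndvi", "evi", "savi", "ci", "arvi", "vari")


@dataclass(frozen=True)
class IndexParams:
    """Parameters governing index computation.

    savi_L : soil-adjustment constant, dimensionless; 0.5 is the canonical
        intermediate-vegetation value.
    epsilon : additive denominator guard.
    formula_dialect : ``as_printed`` or ``canonical`` (see module docstring).
    """

    savi_L: float = 0.5
    epsilon: float = 1e-9
    formula_dialect: str = "as_printed"

    def __post_init__(self) -> None:
        if self.savi_L < 0:
            raise ValueError("savi_L must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.formula_dialect not in ("as_printed", "canonical"):
            raise ValueError(f"unknown dialect {self.formula_dialect!r}")


@dataclass
class ChannelStack:
    """10-channel feature cube: 4 native bands + 6 derived indices."""

    raster: Raster
    index_params: IndexParams
    degenerate_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.raster.n_channels != len(STACK_CHANNELS):
            raise ValueError(
                f"stack must have {len(STACK_CHANNELS)} channels, "
                f"got {self.raster.n_channels}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.raster.values

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.raster.nodata_mask

    def channel(self, name: str) -> np.ndarray:
        return self.raster.channel(name)

    def pervious_matrix(self, keep: np.ndarray) -> np.ndarray:
        """Flatten kept pixels to an (n, 10) feature matrix."""
        return self.values[keep & ~self.nodata_mask]


def _guarded_ratio(num, den, eps):
    """num/(den + eps·sign-preserving guard); returns (ratio, n_degenerate)."""
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    degenerate = np.abs(den) <= eps
    out = num / (den + eps)
    return out, int(np.count_nonzero(degenerate))


def ndvi(nir, red, params: IndexParams = IndexParams()):
    """Normalized Difference Vegetation Index, in [-1, 1]."""
    out, _ = _guarded_ratio(np.asarray(nir, float) - red,
                            np.asarray(nir, float) + red, params.epsilon)
    return out


def evi(nir, red, blue, params: IndexParams = IndexParams()):
    """Enhanced Vegetation Index."""
    nir = np.asarray(nir, dtype=np.float64)
    blue_sign = 7.5 if params.formula_dialect == "as_printed" else -7.5
    den = nir + 6.0 * np.asarray(red, float) + blue_sign * np.asarray(blue, float) + 1.0
    out, _ = _guarded_ratio(2.5 * (nir - red), den, params.epsilon)
    return out


def savi(nir, red, L: float | None = None, params: IndexParams = IndexParams()):
    """Soil Adjusted Vegetation Index; reduces to NDVI as L -> 0."""
    if L is None:
        L = params.savi_L
    if L < 0:
        raise ValueError("L must be >= 0")
    nir = np.asarray(nir, dtype=np.float64)
    out, _ = _guarded_ratio((nir - red) * (1.0 + L), nir + red + L, params.epsilon)
    return out


def ci(red, blue, params: IndexParams = IndexParams()):
    """Crust Index, 1 - (Red - Blue)/(Red + Blue), in [0, 2]."""
    ratio, _ = _guarded_ratio(np.asarray(red, float) - blue,
                              np.asarray(red, float) + blue, params.epsilon)
    return 1.0 - ratio


def arvi(nir, red, blue, params: IndexParams = IndexParams()):
    """Atmospherically Resistant Vegetation Index."""
    nir = np.asarray(nir, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    blue = np.asarray(blue, dtype=np.float64)
    num = nir - (2.0 * red - blue)
    if params.formula_dialect == "as_printed":
        den = nir + (2.0 * red + blue)
    else:
        den = nir + 2.0 * red - blue
    out, _ = _guarded_ratio(num, den, params.epsilon)
    return out


def vari(green, red, blue, params: IndexParams = IndexParams()):
    """Visual Atmospheric Resistance Index."""
    green = np.asarray(green, dtype=np.float64)
    num = green - red
    if params.formula_dialect == "as_printed":
        den = green + np.asarray(red, float) + blue
    else:
        den = green + np.asarray(red, float) - blue
    out, _ = _guarded_ratio(num, den, params.epsilon)
    return out


def build_stack(raster: Raster, params: IndexParams = IndexParams()) -> ChannelStack:
    """Assemble the 10-channel stack from a scaled 4-band raster.

    The input must carry bands named blue, green, red and nir (any case,
    any order). The nodata mask propagates to all derived channels, and
    per-index degenerate-pixel counts are recorded on the stack.
    """
    names = {c.lower() for c in raster.channel_names}
    missing = {"blue", "green", "red", "nir"} - names
    if missing:
        raise ValueError(f"raster is missing bands: {sorted(missing)}")

    b = np.asarray(raster.channel("blue"), dtype=np.float64)
    g = np.asarray(raster.channel("green"), dtype=np.float64)
    r = np.asarray(raster.channel("red"), dtype=np.float64)
    n = np.asarray(raster.channel("nir"), dtype=np.float64)
    eps = params.epsilon

    counts: dict[str, int] = {}
    ndvi_v, counts["ndvi"] = _guarded_ratio(n - r, n + r, eps)
    blue_sign = 7.5 if params.formula_dialect == "as_printed" else -7.5
    evi_v, counts["evi"] = _guarded_ratio(2.5 * (n - r), n + 6 * r + blue_sign * b + 1.0, eps)
    L = params.savi_L
    savi_v, counts["savi"] = _guarded_ratio((n - r) * (1 + L), n + r + L, eps)
    ci_ratio, counts["ci"] = _guarded_ratio(r - b, r + b, eps)
    ci_v = 1.0 - ci_ratio
    if params.formula_dialect == "as_printed":
        arvi_v, counts["arvi"] = _guarded_ratio(n - 2 * r + b, n + 2 * r + b, eps)
        vari_v, counts["vari"] = _guarded_ratio(g - r, g + r + b, eps)
    else:
        arvi_v, counts["arvi"] = _guarded_ratio(n - 2 * r + b, n + 2 * r - b, eps)
        vari_v, counts["vari"] = _guarded_ratio(g - r, g + r - b, eps)

    values = np.stack([b, g, r, n, ndvi_v, evi_v, savi_v, ci_v, arvi_v, vari_v], axis=-1)
    out = Raster(values=values, channel_names=STACK_CHANNELS,
                 nodata_mask=raster.nodata_mask.copy(),
                 bit_depth=raster.bit_depth, geo=raster.geo)
    return ChannelStack(raster=out, index_params=params, degenerate_counts=counts)
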