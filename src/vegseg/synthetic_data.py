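"""Synthetic NAIP-like labeled scenes for exercising every pipeline stage.

Real 4-band aerial tiles come with no usable ground truth at this scale,
so the generator plants it: scenes are painted from geometric primitives
(rectangles, ellipses, blobs, a meandering river strip), each carrying a
land-cover material with a 4-band spectral signature (mean + covariance).
The generator then emulates the features of real very high-resolution
imagery that the segmentation methods contend with:

* **Shadow** is modeled multiplicatively -- a shadowed pixel is its
  underlying cover darkened by a factor in (0, 1), preserving the
  substrate's band ratios. This is what lets a soft-clustering engine
  recover the cover beneath shadow from secondary class membership.
* **Mixed boundary pixels**: within a configurable width of a class
  border, pixel spectra are convex combinations of the adjacent class
  means (linear spectral mixing).
* **Sensor noise**: per-class Gaussian scatter plus additive band noise.
* **8-bit quantization** (on by default) to NAIP's radiometric depth.

Truth rasters carry the 5-class land-cover label (water/shadow,
ground/soil, grass, trees/shrubs, other), a pervious flag (False for
impervious surfaces and pure open water, the covers the masking stage
must drop), a shadow flag, and the substrate class beneath shadow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_core import CLASS_NAMES, Raster

__all__ = [
    "SignatureTable",
    "Primitive",
    "SceneSpec",
    "LabeledScene",
    "default_signatures",
    "generate_scene",
    "benchmark_scene",
]

#: material -> (5-class label, pervious). Impervious surfaces carry -1:
#: they are outside the land-cover legend and excluded from evaluation.
MATERIALS = {
    "water": (0, False),       # highly reflective pure water: dropped by masking
    "river": (0, True),        # sediment-mixed river water: survives masking
    "impervious": (-1, False),
    "soil": (1, True),
    "grass": (2, True),
    "tree": (3, True),
    "other": (4, True),
}

BAND_NAMES = ("blue", "green", "red", "nir")


@dataclass
class SignatureTable:
    """Per-material 4-band spectral signatures: mean vector and covariance."""

    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, m in self.means.items():
            m = np.asarray(m, dtype=np.float64)
            if m.shape != (4,) or (m < 0).any() or (m > 1).any():
                raise ValueError(f"signature mean for {name!r} must be 4 values in [0,1]")
            self.means[name] = m
            c = np.asarray(self.covs[name], dtype=np.float64)
            if c.shape != (4, 4):
                raise ValueError(f"covariance for {name!r} must be 4x4")
            eig = np.linalg.eigvalsh((c + c.T) / 2)
            if eig.min() < -1e-12:
                raise ValueError(f"covariance for {name!r} is not PSD")
            self.covs[name] = c


#: Default within-class brightness heterogeneity (relative illumination
#: scatter); canopy self-shading makes trees the most heterogeneous cover.
DEFAULT_HETEROGENEITY = {
    "water": 0.01, "impervious": 0.04, "soil": 0.04, "grass": 0.06,
    "tree": 0.10, "other": 0.04, "river": 0.04,
}


def default_signatures(heterogeneity: dict[str, float] | None = None) -> SignatureTable:
    """The documented default signature table.

    Band order blue, green, red, nir; values are reflectance-like in
    [0, 1]. The table satisfies NIR(tree) > NIR(grass) > NIR(soil) >
    NIR(water) and the NDVI ordering tree ~ grass > soil > impervious >
    water that the land-cover classes rely on. The river material is the
    linear mix of soil and water that emulates sediment-laden urban
    river water.

    Each covariance is an isotropic sensor-noise term (sd 0.012, about 3
    digital numbers at 8 bits) plus a rank-one multiplicative-illumination
    term ``(beta * mean)(beta * mean)^T`` modeling within-class brightness
    variation (sun angle, canopy self-shading). Brightness variation
    scales all bands together, so it spreads a class along its own
    brightness axis while leaving ratio indices such as NDVI untouched.
    ``heterogeneity`` overrides the per-material beta values.
    """
    means = {
        "water": np.array([0.08, 0.10, 0.09, 0.03]),
        "impervious": np.array([0.32, 0.33, 0.33, 0.35]),
        "soil": np.array([0.13, 0.23, 0.17, 0.44]),
        "grass": np.array([0.12, 0.36, 0.16, 0.48]),
        "tree": np.array([0.05, 0.20, 0.09, 0.52]),
        "other": np.array([0.24, 0.32, 0.20, 0.50]),
    }
    means["river"] = 0.7 * means["soil"] + 0.3 * means["water"]
    betas = dict(DEFAULT_HETEROGENEITY)
    if heterogeneity:
        betas.update(heterogeneity)
    sd = 0.012
    covs = {}
    for name, mu in means.items():
        b = betas[name] * mu
        covs[name] = (sd ** 2) * np.eye(4) + np.outer(b, b)
    return SignatureTable(means=means, covs=covs)


@dataclass(frozen=True)
class Primitive:
    """One painted region: shape name, material, and geometry parameters.

    Shapes (all coordinates fractional in [0, 1] of scene height/width):

    - ``rectangle``: r0, c0, r1, c1
    - ``ellipse``: cy, cx, ry, rx
    - ``blob``: cy, cx, r (an ellipse perturbed by seeded lobes)
    - ``river_strip``: c (center column), width, amplitude (sinusoidal meander)
    """

    shape: str
    material: str
    params: tuple

    def __post_init__(self) -> None:
        if self.material not in MATERIALS and self.material != "shadow":
            raise ValueError(f"unknown material {self.material!r}")
        if self.shape not in ("rectangle", "ellipse", "blob", "river_strip"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(p < 0 or p > 1.5 for p in self.params):
            raise ValueError("primitive parameters must be fractional coordinates")


@dataclass
class SceneSpec:
    """Complete recipe for a synthetic scene; regeneration is bit-identical."""

    height: int
    width: int
    background: str = "grass"
    primitives: list[Primitive] = field(default_factory=list)
    shadow_regions: list[Primitive] = field(default_factory=list)
    shadow_factor: float = 0.55
    boundary_mix_width: int = 1
    noise_sd: float = 0.01
    quantize_8bit: bool = True
    seed: int = 0
    signatures: SignatureTable | None = None

    def __post_init__(self) -> None:
        if not (0 < self.shadow_factor < 1):
            raise ValueError("shadow_factor must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.boundary_mix_width < 0:
            raise ValueError("boundary_mix_width must be >= 0")


@dataclass
class LabeledScene:
    """A synthetic 4-band raster with aligned ground truth."""

    raster: Raster
    truth_class: np.ndarray      # 5-class label, -1 for impervious
    pervious: np.ndarray         # bool: True = should survive masking
    shadow: np.ndarray           # bool: shadowed pixel
    substrate: np.ndarray        # class beneath shadow, -1 elsewhere
    spec: SceneSpec


def _paint(prim: Primitive, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    if prim.shape == "rectangle":
        r0, c0, r1, c1 = prim.params
        return ((rr >= r0 * h) & (rr < r1 * h) & (cc >= c0 * w) & (cc < c1 * w))
    if prim.shape == "ellipse":
        cy, cx, ry, rx = prim.params
        return (((rr - cy * h) / (ry * h)) ** 2 + ((cc - cx * w) / (rx * w)) ** 2) <= 1.0
    if prim.shape == "blob":
        cy, cx, r = prim.params
        ang = np.arctan2(rr - cy * h, cc - cx * w)
        lobes = rng.uniform(0.7, 1.3, size=8)
        radius = r * h * np.interp((ang + np.pi) / (2 * np.pi) * 8,
                                   np.arange(9), np.r_[lobes, lobes[0]])
        return np.hypot(rr - cy * h, cc - cx * w) <= radius
    if prim.shape == "river_strip":
        c, width, amplitude = prim.params
        center = c * w + amplitude * w * np.sin(2 * np.pi * rr[:, 0] / h)
        return np.abs(cc - center[:, None]) <= (width * w) / 2
    raise AssertionError(prim.shape)


def generate_scene(spec: SceneSpec) -> LabeledScene:
    """Render a SceneSpec into a labeled 4-band scene.

    Primitives are painted in order (later occludes earlier) over the
    background material; shadow regions darken the underlying cover
    multiplicatively; boundary pixels mix adjacent class means linearly;
    Gaussian noise is added; values are clipped to [0, 1] and optionally
    quantized to 8-bit digital numbers.
    """
    sig = spec.signatures or default_signatures()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    material_names = list(sig.means)
    mat_index = {m: i for i, m in enumerate(material_names)}
    mat = np.full((h, w), mat_index[spec.background], dtype=np.int64)
    for prim in spec.primitives:
        mat[_paint(prim, h, w, rng)] = mat_index[prim.material]

    present = set(np.unique(mat).tolist())
    for prim in spec.primitives:
        if mat_index[prim.material] not in present:
            import warnings
            warnings.warn(f"primitive material {prim.material!r} fully occluded")

    # linear spectral mixing near class borders
    onehot = np.stack([(mat == i).astype(np.float64) for i in range(len(material_names))],
                      axis=-1)
    if spec.boundary_mix_width > 0:
        size = 2 * spec.boundary_mix_width + 1
        onehot = np.stack(
            [ndimage.uniform_filter(onehot[..., i], size=size, mode="nearest")
             for i in range(onehot.shape[-1])], axis=-1)
        onehot /= onehot.sum(axis=-1, keepdims=True)
    mean_table = np.stack([sig.means[m] for m in material_names])
    image = onehot @ mean_table  # (h, w, 4)

    # shadow: multiplicative darkening of the substrate
    shadow = np.zeros((h, w), dtype=bool)
    for prim in spec.shadow_regions:
        shadow |= _paint(prim, h, w, rng)
    image[shadow] *= spec.shadow_factor

    # per-class covariance scatter + additive band noise
    if any(np.any(sig.covs[m]) for m in material_names):
        noise = np.zeros_like(image)
        for m in material_names:
            sel = mat == mat_index[m]
            n = int(sel.sum())
            if n:
                L = np.linalg.cholesky(sig.covs[m] + 1e-15 * np.eye(4))
                noise[sel] = rng.standard_normal((n, 4)) @ L.T
        image += noise
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    if spec.quantize_8bit:
        values = np.round(image * 255.0).astype(np.uint8)
    else:
        values = image

    class_of = np.array([MATERIALS[m][0] for m in material_names])
    pervious_of = np.array([MATERIALS[m][1] for m in material_names])
    truth = class_of[mat]
    pervious = pervious_of[mat]
    substrate = np.full((h, w), -1, dtype=np.int64)
    substrate[shadow] = truth[shadow]
    truth = truth.copy()
    truth[shadow & pervious] = 0  # shadowed cover is labeled water/shadow

    raster = Raster(values=values, channel_names=BAND_NAMES, bit_depth=8)
    return LabeledScene(raster=raster, truth_class=truth, pervious=pervious,
                        shadow=shadow, substrate=substrate, spec=spec)


def benchmark_scene(kind: str, size: int = 256, seed: int = 0) -> LabeledScene:
    """Canned scene parameterizations used by the acceptance tests.

    - ``five_class_easy``: all five pervious land-cover classes present
      (each >= 2% of pixels) plus an impervious road strip; strong class
      separation (>= 4x the noise scale in at least one band).
    - ``shadow_river``: tree stands casting shadow (darkened tree
      substrate), a sediment-mixed meandering river strip that survives
      masking, a pure-water pond and road that do not.
    - ``mixed_boundary``: a grass/soil split with a 3-pixel linear
      mixing zone.
    """
    if size < 64:
        raise ValueError("benchmark scenes require size >= 64")
    if kind == "five_class_easy":
        spec = SceneSpec(
            height=size, width=size, background="grass", seed=seed,
            primitives=[
                Primitive("rectangle", "soil", (0.05, 0.55, 0.45, 0.95)),
                Primitive("rectangle", "other", (0.60, 0.60, 0.95, 0.95)),
                Primitive("ellipse", "tree", (0.30, 0.25, 0.22, 0.18)),
                Primitive("ellipse", "tree", (0.72, 0.30, 0.15, 0.14)),
                Primitive("rectangle", "impervious", (0.0, 0.0, 1.0, 0.08)),
            ],
            shadow_regions=[Primitive("rectangle", "shadow", (0.15, 0.18, 0.38, 0.34))],
        )
    elif kind == "shadow_river":
        # mature riparian canopy: strong self-shading heterogeneity
        spec = SceneSpec(
            height=size, width=size, background="grass", seed=seed,
            primitives=[
                Primitive("rectangle", "soil", (0.05, 0.05, 0.35, 0.30)),
                Primitive("ellipse", "tree", (0.50, 0.32, 0.28, 0.24)),
                Primitive("river_strip", "river", (0.80, 0.03, 0.03)),
                Primitive("ellipse", "water", (0.12, 0.55, 0.08, 0.08)),
                Primitive("rectangle", "impervious", (0.90, 0.0, 1.0, 1.0)),
            ],
            shadow_regions=[Primitive("rectangle", "shadow", (0.34, 0.16, 0.64, 0.48))],
            signatures=default_signatures(heterogeneity={"tree": 0.22}),
        )
    elif kind == "mixed_boundary":
        # pure mixing-model diagnostic: no class scatter, no band noise
        base = default_signatures()
        noiseless = SignatureTable(means=dict(base.means),
                                   covs={m: np.zeros((4, 4)) for m in base.means})
        spec = SceneSpec(
            height=size, width=size, background="grass", seed=seed,
            primitives=[Primitive("rectangle", "soil", (0.0, 0.5, 1.0, 1.0))],
            boundary_mix_width=3,
            noise_sd=0.0,
            signatures=noiseless,
        )
    else:
        raise ValueError(f"unknown benchmark scene kind {kind!r}")
    return generate_scene(spec)
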