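"""Synthetic hyperspectral scenes of dried chrysanthemum flowers.

Emulates the statistical structure the downstream analysis relies on,
so the whole pipeline is testable without the original instrument data:

* three flower size classes (small / medium / big) whose polysaccharide
  content increases, and flavonoid content decreases, with size;
* per-class content distributions whose pooled SDs match the reference
  chemistry summary (polysaccharides ~0.28 % w/w, flavonoids ~0.86 %);
* smooth NIR reflectance signatures with peaks near 1119 / 1311 nm and
  content-proportional absorption troughs near 1210 nm (polysaccharides)
  and 1487 nm (flavonoids), on a class-dependent baseline;
* raw / dark / white frames consistent with the reflectance calibration
  equation R = (raw - dark)/(white - dark), with i.i.d. Gaussian pixel
  noise injected in raw-count space.

One *sample* is a handful of ``n_flowers_per_sample`` flowers of one
size class imaged together in one scene and sharing one assayed
chemistry value; individual flowers scatter around that value with a
small relative jitter that stands in for flower-to-flower heterogeneity
plus reference-assay error.

Randomness: a single integer seed spawns independent child streams in a
fixed, documented order — stream 0 draws the chemistry table, stream
1+i renders scene i — so any scene can be regenerated on demand without
materialising the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hypercube import (
    DEFAULT_BAND_COUNT,
    DEFAULT_WAVELENGTH_MAX_NM,
    DEFAULT_WAVELENGTH_MIN_NM,
    Hypercube,
    WavelengthAxis,
)

__all__ = [
    "FlowerClassSpec",
    "SceneConfig",
    "Scene",
    "GroundTruth",
    "PlacementError",
    "default_classes",
    "signature_spectrum",
    "render_scene",
    "simulate_dataset",
    "SimulatedDataset",
]

# Fixed spectral features: (center nm, amplitude, Gaussian sigma nm).
REFLECTANCE_PEAKS = ((1119.0, 0.060, 28.0), (1311.0, 0.045, 32.0))
# Content-proportional absorption troughs: center, sigma, reflectance
# depth per % w/w of the owning constituent.
POLY_TROUGH_NM, POLY_TROUGH_SIGMA_NM, POLY_TROUGH_COEF = 1210.0, 30.0, 0.08
FLAV_TROUGH_NM, FLAV_TROUGH_SIGMA_NM, FLAV_TROUGH_COEF = 1487.0, 40.0, 0.03

#: Class content distributions are truncated at this many SDs.
CONTENT_CLIP_SD = 2.5


class PlacementError(RuntimeError):
    """Requested flowers cannot be placed without overlap."""


@dataclass(frozen=True)
class FlowerClassSpec:
    """One flower size class and its content distribution.

    Polysaccharide content must increase, and flavonoid content
    decrease, from small to big flowers; flower radius and baseline
    reflectance increase with size.
    """

    name: str
    radius_px: int
    baseline_reflectance: float
    poly_mean: float  # % w/w
    poly_sd: float
    flav_mean: float
    flav_sd: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if not 0.0 < self.baseline_reflectance < 1.0:
            raise ValueError("baseline_reflectance must lie in (0, 1)")
        for v in (self.poly_sd, self.flav_sd):
            if v < 0:
                raise ValueError("content SDs must be nonnegative")

    def content_range(self, analyte: str) -> tuple[float, float]:
        mean, sd = {
            "polysaccharides": (self.poly_mean, self.poly_sd),
            "flavonoids": (self.flav_mean, self.flav_sd),
        }[analyte]
        return mean - CONTENT_CLIP_SD * sd, mean + CONTENT_CLIP_SD * sd


def default_classes() -> tuple[FlowerClassSpec, FlowerClassSpec, FlowerClassSpec]:
    """Small / medium / big flower classes.

    Class means are centered on the reference-chemistry summary (grand
    means 3.76 % polysaccharides, 9.11 % flavonoids) and ordered with
    flower size; the within-class SDs are chosen so the pooled SDs come
    out at ~0.28 and ~0.86 % w/w.  Baseline reflectance rises gently
    with flower size — kept small enough that the content troughs, not
    the size baseline, dominate cross-sample reflectance variation.
    """
    return (
        FlowerClassSpec("small", 8, 0.40, 3.50, 0.167, 10.00, 0.447),
        FlowerClassSpec("medium", 14, 0.41, 3.76, 0.167, 9.11, 0.447),
        FlowerClassSpec("big", 20, 0.42, 4.05, 0.167, 8.20, 0.447),
    )


def _validate_class_ordering(classes) -> None:
    for a, b in zip(classes, classes[1:]):
        if not (a.poly_mean < b.poly_mean and a.flav_mean > b.flav_mean
                and a.radius_px < b.radius_px
                and a.baseline_reflectance < b.baseline_reflectance):
            raise ValueError(
                "classes must be ordered small->big with increasing "
                "polysaccharides/radius/baseline and decreasing flavonoids"
            )


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, sampling plan and noise level of the simulation."""

    image_width_px: int = 160
    image_length_px: int = 160
    n_flowers_per_sample: int = 5
    n_samples_per_class: int = 93
    noise_sd: float = 0.005  # reflectance units; applied in count space
    seed: int = 0
    band_count: int = DEFAULT_BAND_COUNT
    wavelength_min_nm: float = DEFAULT_WAVELENGTH_MIN_NM
    wavelength_max_nm: float = DEFAULT_WAVELENGTH_MAX_NM
    background_reflectance: float = 0.05
    flower_jitter_rel_sd: float = 0.03
    min_separation_px: int = 3
    dark_level: float = 100.0
    white_level: float = 4000.0

    def __post_init__(self) -> None:
        for name in ("image_width_px", "image_length_px",
                     "n_flowers_per_sample", "n_samples_per_class",
                     "band_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.wavelength_min_nm < self.wavelength_max_nm:
            raise ValueError("wavelength_min_nm must be < wavelength_max_nm")
        if not 0 < self.background_reflectance < 1:
            raise ValueError("background_reflectance must lie in (0, 1)")

    def axis(self) -> WavelengthAxis:
        return WavelengthAxis.linear(
            self.band_count, self.wavelength_min_nm, self.wavelength_max_nm
        )


def _gauss(w: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / sigma) ** 2)


def signature_spectrum(
    poly_pct: float,
    flav_pct: float,
    class_spec: FlowerClassSpec,
    axis: WavelengthAxis,
) -> np.ndarray:
    """Noise-free reflectance signature of one flower.

    Class baseline plus fixed Gaussian peaks at 1119 and 1311 nm, minus
    content-proportional Gaussian troughs at 1210 nm (polysaccharides)
    and 1487 nm (flavonoids).  Strictly monotone decreasing in each
    content at its own trough center.  Raises ``ValueError`` if the
    contents drive reflectance outside (0, 1).
    """
    if poly_pct < 0 or flav_pct < 0:
        raise ValueError("contents must be nonnegative")
    w = axis.wavelengths_nm
    r = np.full_like(w, class_spec.baseline_reflectance)
    for center, amp, sigma in REFLECTANCE_PEAKS:
        r = r + amp * _gauss(w, center, sigma)
    r = r - POLY_TROUGH_COEF * poly_pct * _gauss(w, POLY_TROUGH_NM, POLY_TROUGH_SIGMA_NM)
    r = r - FLAV_TROUGH_COEF * flav_pct * _gauss(w, FLAV_TROUGH_NM, FLAV_TROUGH_SIGMA_NM)
    if r.min() <= 0.0 or r.max() >= 1.0:
        raise ValueError(
            f"contents poly={poly_pct}, flav={flav_pct} drive reflectance "
            f"outside (0, 1) for class '{class_spec.name}'"
        )
    return r


@dataclass
class GroundTruth:
    """True chemistry and geometry behind a simulated dataset.

    ``samples``: one row per imaged sample (sample_id, class_name,
    poly_pct, flav_pct).  ``flowers``: one row per flower (sample_id,
    flower_id, per-flower contents, center, radius).  Per-scene pixel
    masks live on the :class:`Scene` objects.
    """

    samples: pd.DataFrame
    flowers: pd.DataFrame


@dataclass
class Scene:
    """One rendered sample: raw cube, reference frames, truth mask."""

    sample_id: int
    raw: np.ndarray          # (lines, samples, bands) counts
    dark: np.ndarray         # (1, samples, bands) single-line reference
    white: np.ndarray        # (1, samples, bands)
    axis: WavelengthAxis
    label_mask: np.ndarray   # int labels, 0 = background, 1..F flowers
    flowers: pd.DataFrame    # rows of GroundTruth.flowers for this scene

    @property
    def raw_cube(self) -> Hypercube:
        return Hypercube(self.raw, self.axis, kind="raw")


def _reference_frames(config: SceneConfig, axis: WavelengthAxis):
    """Deterministic dark/white single-line reference frames.

    The dark frame is a flat dark-current floor; the white frame has a
    broad band-dependent illumination profile peaking mid-range, so the
    calibration denominator varies across bands as on a real instrument.
    """
    w = axis.wavelengths_nm
    dark = config.dark_level * (1.0 + 0.02 * _gauss(w, 1600.0, 400.0))
    illum = 0.75 + 0.25 * _gauss(w, 1300.0, 350.0)
    white = config.white_level * illum
    shape = (1, config.image_width_px, len(axis))
    return (np.broadcast_to(dark, shape).copy(),
            np.broadcast_to(white, shape).copy())


def _place_flowers(config: SceneConfig, radius: int,
                   rng: np.random.Generator, max_tries: int = 2000):
    """Random non-overlapping disk centers via rejection sampling."""
    h, wd = config.image_length_px, config.image_width_px
    margin = radius + 2
    if h - 2 * margin <= 0 or wd - 2 * margin <= 0:
        raise PlacementError(
            f"image {wd}x{h} too small for flowers of radius {radius}"
        )
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < config.n_flowers_per_sample:
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, wd - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2
               >= (2 * radius + config.min_separation_px) ** 2
               for y, x in centers):
            centers.append((cy, cx))
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {config.n_flowers_per_sample} flowers of "
                f"radius {radius} in a {wd}x{h} image after {max_tries} tries"
            )
    return centers


def render_scene(
    config: SceneConfig,
    class_spec: FlowerClassSpec,
    flower_contents: pd.DataFrame,
    rng: np.random.Generator,
    sample_id: int = 0,
) -> Scene:
    """Render one sample's scene from its per-flower contents.

    ``flower_contents`` needs columns ``poly_pct`` and ``flav_pct`` (one
    row per flower).  Raw counts follow the inverse of the calibration
    equation: ``raw = dark + R*(white - dark) + noise`` with noise sd
    ``noise_sd * (white - dark)`` in count units.
    """
    axis = config.axis()
    h, wd = config.image_length_px, config.image_width_px
    n_flowers = len(flower_contents)
    if n_flowers != config.n_flowers_per_sample:
        config = replace(config, n_flowers_per_sample=n_flowers)
    centers = _place_flowers(config, class_spec.radius_px, rng)

    refl = np.full((h, wd, len(axis)), config.background_reflectance)
    label_mask = np.zeros((h, wd), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:wd]
    rows = []
    for i, ((cy, cx), (_, fl)) in enumerate(
            zip(centers, flower_contents.iterrows()), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= class_spec.radius_px ** 2
        spec = signature_spectrum(
            float(fl["poly_pct"]), float(fl["flav_pct"]), class_spec, axis)
        refl[disk] = spec
        label_mask[disk] = i
        rows.append({
            "sample_id": sample_id, "flower_id": i,
            "class_name": class_spec.name,
            "poly_pct": float(fl["poly_pct"]),
            "flav_pct": float(fl["flav_pct"]),
            "center_y": cy, "center_x": cx,
            "radius_px": class_spec.radius_px,
            "area_px": int(disk.sum()),
        })

    dark, white = _reference_frames(config, axis)
    span = white - dark  # broadcasts (1, wd, bands)
    raw = dark + refl * span
    if config.noise_sd > 0:
        raw = raw + rng.standard_normal(raw.shape) * (config.noise_sd * span)
    return Scene(sample_id, raw, dark, white, axis, label_mask,
                 pd.DataFrame(rows))


def _draw_chemistry(config: SceneConfig, classes,
                    rng: np.random.Generator) -> GroundTruth:
    sample_rows, flower_rows = [], []
    sid = 0
    for cls in classes:
        for _ in range(config.n_samples_per_class):
            poly = float(np.clip(rng.normal(cls.poly_mean, cls.poly_sd),
                                 *cls.content_range("polysaccharides")))
            flav = float(np.clip(rng.normal(cls.flav_mean, cls.flav_sd),
                                 *cls.content_range("flavonoids")))
            sample_rows.append({"sample_id": sid, "class_name": cls.name,
                                "poly_pct": poly, "flav_pct": flav})
            jit = config.flower_jitter_rel_sd
            for fid in range(1, config.n_flowers_per_sample + 1):
                fp = max(poly * (1.0 + jit * rng.standard_normal()), 0.0)
                ff = max(flav * (1.0 + jit * rng.standard_normal()), 0.0)
                flower_rows.append({"sample_id": sid, "flower_id": fid,
                                    "class_name": cls.name,
                                    "poly_pct": fp, "flav_pct": ff})
            sid += 1
    return GroundTruth(pd.DataFrame(sample_rows), pd.DataFrame(flower_rows))


@dataclass
class SimulatedDataset:
    """Lazy handle on a full simulated study.

    Holds the chemistry ground truth; scenes are (re)rendered on demand
    from per-sample seed streams, so two calls to :meth:`scene` with the
    same sample id are bit-identical and the whole dataset never has to
    fit in memory.
    """

    config: SceneConfig
    classes: tuple
    ground_truth: GroundTruth
    _scene_seeds: list = field(repr=False, default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.ground_truth.samples)

    def class_of(self, sample_id: int) -> FlowerClassSpec:
        name = self.ground_truth.samples.loc[
            self.ground_truth.samples.sample_id == sample_id, "class_name"
        ].iloc[0]
        return next(c for c in self.classes if c.name == name)

    def scene(self, sample_id: int) -> Scene:
        rng = np.random.default_rng(self._scene_seeds[sample_id])
        contents = self.ground_truth.flowers[
            self.ground_truth.flowers.sample_id == sample_id
        ]
        return render_scene(self.config, self.class_of(sample_id),
                            contents, rng, sample_id=sample_id)

    def iter_scenes(self):
        for sid in self.ground_truth.samples.sample_id:
            yield self.scene(int(sid))


def simulate_dataset(config: SceneConfig | None = None,
                     classes=None) -> SimulatedDataset:
    """Draw the chemistry table and set up deterministic scene streams.

    Stream order from the single seed: child 0 draws the chemistry
    (class by class, sample by sample, polysaccharide then flavonoid,
    then the per-flower jitters); children 1..n_samples each own one
    scene's placement and pixel noise.
    """
    if config is None:
        config = SceneConfig()
    if classes is None:
        classes = default_classes()
    _validate_class_ordering(classes)
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_samples_per_class * len(classes)
    children = ss.spawn(n_total + 1)
    truth = _draw_chemistry(config, classes, np.random.default_rng(children[0]))
    return SimulatedDataset(config, tuple(classes), truth,
                            _scene_seeds=children[1:])
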