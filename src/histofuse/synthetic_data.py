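"""Seeded generator of H&E-like prostate tissue images.

Real prostate fields of view are private clinical data, so the whole pipeline is
exercised on synthetic images that embody the qualitative structures a
pathologist reads: benign tissue shows a few *large* gland cavities (lumens)
whose boundaries fold inward with papillary protrusions and which are rimmed by
a bilayer of epithelial nuclei; malignant tissue shows *many small*
smooth-boundary cavities, enlarged pleomorphic nuclei (high size variance) with
frequent prominent nucleoli, and a more disordered stromal texture.  Stain
appearance follows H&E: nuclei blue-purple (hematoxylin), stroma pink (eosin),
lumens near-white, with per-image multiplicative channel jitter emulating
staining variation.

Every image is a pure function of ``(label, params, seed)`` and ships with a
:class:`~histofuse.datatypes.GroundTruth` listing each placed nucleus and lumen,
which downstream segmentation tests use as their oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .datatypes import BENIGN, CLASS_LABELS, MALIGNANT, DatasetManifest, GroundTruth, LabeledImage

# H&E-ish palette (RGB, 0-255)
STROMA_RGB = np.array([236.0, 172.0, 205.0])
LUMEN_RGB = np.array([248.0, 246.0, 245.0])
NUCLEUS_RGB = np.array([95.0, 70.0, 150.0])
NUCLEOLUS_RGB = np.array([45.0, 30.0, 80.0])

_REFERENCE_SIDE = 512  # lumen geometry defaults are expressed at this side length


@dataclass
class GenParams:
    """Tunable knobs of the tissue generator.

    Pixel quantities refer to the configured ``image_size``; use
    :meth:`for_size` to rescale the lumen geometry from the 512-px reference.
    """

    image_size: tuple = (512, 512)
    # lumens
    n_lumens_benign: tuple = (2, 4)
    n_lumens_malignant: tuple = (12, 22)
    lumen_radius_benign: tuple = (45.0, 85.0)
    lumen_radius_malignant: tuple = (10.0, 20.0)
    papillary_amplitude_benign: float = 0.18  # fraction of radius; plum-like folds
    papillary_amplitude_malignant: float = 0.0  # malignant boundaries are smooth
    # nuclei
    nucleus_radius_mean_benign: float = 4.0
    nucleus_radius_mean_malignant: float = 5.5
    nucleus_radius_cv_benign: float = 0.12
    nucleus_radius_cv_malignant: float = 0.35
    n_stromal_nuclei_benign: tuple = (60, 90)
    n_stromal_nuclei_malignant: tuple = (110, 160)
    bilayer_rim: bool = True  # benign only: inner+outer epithelial ring
    nucleolus_probability_benign: float = 0.05
    nucleolus_probability_malignant: float = 0.7
    # appearance
    texture_amplitude_benign: float = 5.0  # stromal mottling, gray levels
    texture_amplitude_malignant: float = 12.0  # "disordered" malignant texture
    stain_jitter: tuple = (0.9, 1.1)  # per-channel multiplicative range
    noise_sd: float = 4.0  # additive Gaussian, gray levels

    def __post_init__(self) -> None:
        h, w = self.image_size
        if min(h, w) < 224:
            raise ValueError("image sides must be >= 224")
        for name in ("n_lumens_benign", "n_lumens_malignant",
                     "n_stromal_nuclei_benign", "n_stromal_nuclei_malignant"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nonnegative (lo, hi) range")
        if not (self.nucleus_radius_cv_malignant > self.nucleus_radius_cv_benign):
            raise ValueError("malignant nucleus-size CV must exceed benign CV")
        if self.papillary_amplitude_benign <= 0 or self.papillary_amplitude_malignant != 0:
            raise ValueError("benign papillary amplitude must be > 0, malignant must be 0")

    @classmethod
    def for_size(cls, side: int, **overrides) -> "GenParams":
        """Scale lumen geometry linearly from the 512-px reference defaults."""
        s = side / _REFERENCE_SIDE
        scale = lambda rng: (max(8.0, rng[0] * s), max(9.0, rng[1] * s))
        kwargs = dict(
            image_size=(side, side),
            lumen_radius_benign=scale(cls.lumen_radius_benign),
            lumen_radius_malignant=scale(cls.lumen_radius_malignant),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def per_class(self, label: str) -> dict:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        suffix = "benign" if label == BENIGN else "malignant"
        d = asdict(self)
        out = {}
        for k, v in d.items():
            if k.endswith(("_benign", "_malignant")):
                if k.endswith("_" + suffix):
                    out[k[: -len(suffix) - 1]] = v
            else:
                out[k] = v
        return out


def _lumen_boundary(r0: float, amplitude: float, k_lobes: int, phase: float,
                    aspect: float, theta: np.ndarray) -> np.ndarray:
    """Radial boundary of a (possibly papillary) elliptical lumen at angles theta."""
    r = r0 * (1.0 + amplitude * np.sin(k_lobes * theta + phase))
    # elliptical squeeze along one axis
    ell = np.sqrt((np.cos(theta)) ** 2 + (np.sin(theta) / aspect) ** 2)
    return r / ell


def _rasterize_lumen(shape, center, r0, amplitude, k_lobes, phase, aspect) -> np.ndarray:
    h, w = shape
    cy, cx = center
    rmax = int(np.ceil(r0 * (1 + abs(amplitude)) + 2))
    y0, y1 = max(0, int(cy) - rmax), min(h, int(cy) + rmax + 1)
    x0, x1 = max(0, int(cx) - rmax), min(w, int(cx) + rmax + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    inside = rho <= _lumen_boundary(r0, amplitude, k_lobes, phase, aspect, theta)
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def _smooth_noise_field(shape, rng, amplitude: float, coarseness: int = 24) -> np.ndarray:
    """Low-frequency mottling used for stromal texture."""
    h, w = shape
    coarse = rng.normal(0.0, 1.0, (h // coarseness + 2, w // coarseness + 2))
    fy, fx = h / coarse.shape[0], w / coarse.shape[1]
    smooth = ndi.zoom(coarse, (fy, fx), order=3)[:h, :w]
    std = smooth.std()
    return amplitude * smooth / (std if std > 0 else 1.0)


def _paint_disk(img: np.ndarray, center, radius: float, color: np.ndarray) -> None:
    h, w = img.shape[:2]
    cy, cx = center
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img[y0:y1, x0:x1][inside] = color


def render_tissue(image_size, nuclei, lumen_specs=(), *, texture_amplitude=5.0,
                  stain_factors=(1.0, 1.0, 1.0), noise_sd=0.0, nucleoli=(),
                  seed=0) -> np.ndarray:
    """Render stroma + lumens + nuclei into an (H, W, 3) uint8 array.

    ``nuclei`` is a sequence of (center_rc, radius); ``lumen_specs`` of
    (center_rc, r0, amplitude, k_lobes, phase, aspect).  Exposed separately from
    :func:`generate_image` so tests can compose controlled scenes (e.g. two
    touching nuclei) and still go through the exact drawing code.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    img = np.ones((h, w, 3), dtype=float) * STROMA_RGB
    img += _smooth_noise_field((h, w), rng, texture_amplitude)[..., None]
    for spec in lumen_specs:
        mask = _rasterize_lumen((h, w), *spec)
        img[mask] = LUMEN_RGB + rng.normal(0, 1.5, 3)
    for (center, radius) in nuclei:
        jitter = rng.normal(0.0, 8.0, 3)
        _paint_disk(img, center, radius, NUCLEUS_RGB + jitter)
    for (center, radius) in nucleoli:
        _paint_disk(img, center, radius, NUCLEOLUS_RGB)
    img *= np.asarray(stain_factors)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _place_lumens(rng, shape, n_range, r_range, amplitude):
    h, w = shape
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    specs = []
    for _ in range(n):
        for _attempt in range(200):
            r0 = rng.uniform(*r_range)
            reach = r0 * (1 + abs(amplitude)) + 3
            if 2 * reach >= min(h, w):
                continue
            cy = rng.uniform(reach, h - reach)
            cx = rng.uniform(reach, w - reach)
            ok = True
            for (c2, r2, a2, *_rest) in specs:
                min_d = reach + r2 * (1 + abs(a2)) + 6
                if np.hypot(cy - c2[0], cx - c2[1]) < min_d:
                    ok = False
                    break
            if ok:
                k_lobes = int(rng.integers(4, 8))
                phase = rng.uniform(0, 2 * np.pi)
                aspect = rng.uniform(0.75, 1.0)
                specs.append(((cy, cx), r0, amplitude, k_lobes, phase, aspect))
                break
    return specs


def _point_clear_of_lumens(pt, radius, lumen_specs, clearance=2.0) -> bool:
    for (center, r0, amplitude, k_lobes, phase, aspect) in lumen_specs:
        dy, dx = pt[0] - center[0], pt[1] - center[1]
        rho = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        bound = _lumen_boundary(r0, amplitude, k_lobes, phase, aspect, np.array([theta]))[0]
        if rho < bound + radius + clearance:
            return False
    return True


def _sample_radius(rng, mean, cv):
    return max(1.5, rng.normal(mean, cv * mean))


def generate_image(class_label: str, gen_params: GenParams | None = None,
                   seed: int = 0) -> tuple[LabeledImage, GroundTruth]:
    """Generate one labeled image plus its ground truth.

    Deterministic: identical ``(class_label, gen_params, seed)`` reproduce
    bit-identical pixels.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    params = gen_params or GenParams()
    p = params.per_class(class_label)
    h, w = params.image_size
    # independent streams per class so a shared seed still yields distinct scenes
    rng = np.random.default_rng([seed, CLASS_LABELS.index(class_label)])

    lumens = _place_lumens(rng, (h, w), p["n_lumens"], p["lumen_radius"],
                           p["papillary_amplitude"])

    nuclei: list[tuple[tuple[float, float], float]] = []
    nucleoli: list[tuple[tuple[float, float], float]] = []

    def try_add_nucleus(cy, cx, radius) -> bool:
        if not (radius + 1 <= cy <= h - radius - 1 and radius + 1 <= cx <= w - radius - 1):
            return False
        if not _point_clear_of_lumens((cy, cx), radius, lumens):
            return False
        for ((oy, ox), orad) in nuclei:
            if np.hypot(cy - oy, cx - ox) < 0.9 * (radius + orad):
                return False
        nuclei.append(((cy, cx), radius))
        if rng.uniform() < p["nucleolus_probability"]:
            dot_r = rng.uniform(0.8, 1.4)
            nucleoli.append(((cy + rng.uniform(-1, 1), cx + rng.uniform(-1, 1)), dot_r))
        return True

    if class_label == BENIGN and params.bilayer_rim:
        # bilayer epithelial rims hugging each lumen boundary
        for (center, r0, amplitude, k_lobes, phase, aspect) in lumens:
            mean_r = p["nucleus_radius_mean"]
            circumference = 2 * np.pi * r0
            n_ring = max(6, int(circumference / (2.6 * mean_r)))
            for ring in (0, 1):
                offs = rng.uniform(0, 2 * np.pi)
                for j in range(n_ring):
                    theta = offs + 2 * np.pi * j / n_ring + rng.normal(0, 0.04)
                    radius = _sample_radius(rng, mean_r, p["nucleus_radius_cv"])
                    bound = _lumen_boundary(r0, amplitude, k_lobes, phase, aspect,
                                            np.array([theta]))[0]
                    ring_r = bound + radius + 2.0 + ring * (2 * mean_r + 2.0)
                    cy = center[0] + ring_r * np.sin(theta)
                    cx = center[1] + ring_r * np.cos(theta)
                    try_add_nucleus(cy, cx, radius)

    n_stroma = int(rng.integers(p["n_stromal_nuclei"][0], p["n_stromal_nuclei"][1] + 1))
    placed, attempts = 0, 0
    while placed < n_stroma and attempts < 40 * n_stroma:
        attempts += 1
        radius = _sample_radius(rng, p["nucleus_radius_mean"], p["nucleus_radius_cv"])
        cy = rng.uniform(radius + 1, h - radius - 1)
        cx = rng.uniform(radius + 1, w - radius - 1)
        if try_add_nucleus(cy, cx, radius):
            placed += 1

    stain = rng.uniform(params.stain_jitter[0], params.stain_jitter[1], 3)
    pixels = render_tissue(
        (h, w), nuclei, lumens,
        texture_amplitude=p["texture_amplitude"],
        stain_factors=stain, noise_sd=params.noise_sd, nucleoli=nucleoli,
        seed=rng.integers(0, 2**31 - 1),
    )

    lumen_masks = (np.stack([_rasterize_lumen((h, w), *spec) for spec in lumens])
                   if lumens else np.zeros((0, h, w), dtype=bool))
    gt = GroundTruth(
        nucleus_centers=np.array([c for c, _ in nuclei], dtype=float).reshape(-1, 2),
        nucleus_radii=np.array([r for _, r in nuclei], dtype=float),
        lumen_masks=lumen_masks,
        label=class_label,
    )
    image = LabeledImage(pixels=pixels, label=class_label,
                         id=f"{class_label}_{seed}")
    return image, gt


def _lumen_polygon(spec, n_vertices: int = 96) -> np.ndarray:
    (center, r0, amplitude, k_lobes, phase, aspect) = spec
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    rad = _lumen_boundary(r0, amplitude, k_lobes, phase, aspect, theta)
    return np.stack([center[0] + rad * np.sin(theta), center[1] + rad * np.cos(theta)], axis=1)


def _gt_sidecar(gt: GroundTruth, lumen_specs) -> dict:
    return {
        "label": gt.label,
        "nucleus_centers": gt.nucleus_centers.tolist(),
        "nucleus_radii": gt.nucleus_radii.tolist(),
        "lumen_polygons": [_lumen_polygon(s).tolist() for s in lumen_specs],
    }


def load_ground_truth(path, image_size) -> GroundTruth:
    """Rebuild a GroundTruth (rasterizing lumen polygons) from a JSON sidecar."""
    data = json.loads(Path(path).read_text())
    h, w = image_size
    masks = []
    for poly in data["lumen_polygons"]:
        poly = np.asarray(poly)
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        masks.append(m)
    return GroundTruth(
        nucleus_centers=np.asarray(data["nucleus_centers"], dtype=float).reshape(-1, 2),
        nucleus_radii=np.asarray(data["nucleus_radii"], dtype=float),
        lumen_masks=np.stack(masks) if masks else np.zeros((0, h, w), dtype=bool),
        label=data["label"],
    )


def generate_dataset(n_benign: int, n_malignant: int,
                     gen_params: GenParams | None = None, seed: int = 0,
                     out_dir=None) -> DatasetManifest:
    """Generate a labeled dataset; optionally write PNGs + JSON sidecars.

    With ``out_dir=None`` the images stay in memory on the manifest rows
    (``row["image"]``, ``row["ground_truth"]``); otherwise each image is written
    as ``<id>.png`` with a ``<id>.gt.json`` sidecar plus a ``manifest.json``.
    """
    if n_benign + n_malignant < 1:
        raise ValueError("need at least one image")
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("class counts must be nonnegative")
    params = gen_params or GenParams()
    rng = np.random.default_rng(seed)
    total = n_benign + n_malignant
    child_seeds = rng.integers(0, 2**31 - 1, size=total)
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant

    manifest = DatasetManifest()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    counters = {BENIGN: 0, MALIGNANT: 0}
    for label, child_seed in zip(labels, child_seeds):
        image, gt = generate_image(label, params, int(child_seed))
        image_id = f"{label}_{counters[label]:04d}"
        counters[label] += 1
        image.id = image_id
        row = {"id": image_id, "label": label, "seed": int(child_seed), "path": None}
        if out_path is not None:
            png = out_path / f"{image_id}.png"
            iio.imwrite(png, image.pixels)
            # re-derive the lumen specs deterministically for the sidecar
            p = params.per_class(label)
            lrng = np.random.default_rng([int(child_seed), CLASS_LABELS.index(label)])
            specs = _place_lumens(lrng, params.image_size, p["n_lumens"],
                                  p["lumen_radius"], p["papillary_amplitude"])
            (out_path / f"{image_id}.gt.json").write_text(
                json.dumps(_gt_sidecar(gt, specs)))
            row["path"] = str(png)
        else:
            row["image"] = image
            row["ground_truth"] = gt
        manifest.rows.append(row)

    if out_path is not None:
        (out_path / "manifest.json").write_text(json.dumps({
            "seed": seed,
            "rows": [{k: r[k] for k in ("id", "path", "label", "seed")}
                     for r in manifest.rows],
        }, indent=1))
    return manifest


def load_manifest(path) -> DatasetManifest:
    data = json.loads(Path(path).read_text())
    return DatasetManifest(rows=list(data["rows"]))


def load_image(row) -> LabeledImage:
    """Materialize the LabeledImage for a manifest row (disk or in-memory)."""
    if row.get("image") is not None:
        return row["image"]
    pixels = iio.imread(row["path"])
    return LabeledImage(pixels=pixels[..., :3], label=row["label"], id=row["id"])
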