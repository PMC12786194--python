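"""Seeded synthetic grayscale fixtures with known generating structure.

Histopathology-style images are, at the histogram level, multimodal
intensity mixtures: nuclei, cytoplasm and background each contribute a
roughly Gaussian mode.  The generators here emulate exactly that — pixel
intensities drawn from truncated-normal mixtures with known means,
spreads and weights — plus a disks-on-background "nuclei" fixture with an
exact foreground mask, so every optimizer and metric can be validated
against analytically known structure without any external dataset.

Truncation to [0, 255] uses rejection rather than clipping: clipping
would pile probability into spurious spikes at 0 and 255 and corrupt
analytic-density comparisons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .otsu import brute_force_thresholds, compute_histogram

__all__ = [
    "MixtureSpec",
    "make_mixture_image",
    "make_blob_image",
    "fixture_suite",
    "make_fixture_suite",
    "mixture_bin_probabilities",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("bimodal", "trimodal", "fivemode", "blob", "twopoint", "constant")


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian intensity mixture: modes are (mean, sd, weight) triples."""

    modes: tuple[tuple[float, float, float], ...]
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("mixture must have at least one mode")
        means = [m for m, _, _ in self.modes]
        weights = [w for _, _, w in self.modes]
        if any(not 0 <= m <= 255 for m in means):
            raise ValueError("mode means must lie in [0, 255]")
        if any(sd < 0 for _, sd, _ in self.modes):
            raise ValueError("mode standard deviations must be >= 0")
        if any(w <= 0 for w in weights):
            raise ValueError("mode weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1")
        if sorted(means) != means:
            raise ValueError("mode means must be sorted ascending")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw from N(mean, sd) restricted to [0, 255] by rejection."""
    if sd == 0.0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < 0.0) | (out > 255.0)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < 0.0) | (out > 255.0)
    return out


def make_mixture_image(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample an 8-bit mixture image; returns (image, component_labels)."""
    rng = np.random.default_rng(spec.seed)
    n = int(np.prod(spec.image_size))
    weights = np.array([w for _, _, w in spec.modes])
    components = rng.choice(len(spec.modes), size=n, p=weights)
    values = np.empty(n)
    for c, (mean, sd, _) in enumerate(spec.modes):
        idx = np.flatnonzero(components == c)
        values[idx] = _truncated_normal(rng, mean, sd, idx.size)
    image = np.rint(values).astype(np.uint8).reshape(spec.image_size)
    return image, components.reshape(spec.image_size)


def mixture_bin_probabilities(spec: MixtureSpec) -> np.ndarray:
    """Analytic 256-bin pmf of the rounded, truncated mixture."""
    from scipy.stats import norm

    bins = np.arange(256)
    lower = np.maximum(bins - 0.5, 0.0)
    upper = np.minimum(bins + 0.5, 255.0)
    pmf = np.zeros(256)
    for mean, sd, w in spec.modes:
        if sd == 0.0:
            pmf[int(np.rint(mean))] += w
            continue
        z = norm(loc=mean, scale=sd)
        mass = z.cdf(255.0) - z.cdf(0.0)
        pmf += w * (z.cdf(upper) - z.cdf(lower)) / mass
    return pmf


def make_blob_image(
    n_blobs: int = 12,
    blob_intensity: float = 60.0,
    background_intensity: float = 200.0,
    noise_sd: float = 5.0,
    size: tuple[int, int] = (256, 256),
    radius_range: tuple[int, int] = (8, 20),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disks on a uniform background plus Gaussian noise; exact mask returned.

    Emulates dark nuclei on bright tissue.  Blob centers are placed so
    every disk fits inside the frame; disks may overlap.
    """
    if not (0 <= blob_intensity <= 255 and 0 <= background_intensity <= 255):
        raise ValueError("intensities must lie in [0, 255]")
    h, w = size
    if h <= 2 * radius_range[1] or w <= 2 * radius_range[1]:
        raise ValueError("blobs do not fit in the frame")
    rng = np.random.default_rng(seed)
    canvas = np.full(size, float(background_intensity))
    mask = np.zeros(size, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        canvas[disk] = blob_intensity
        mask |= disk
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, size)
    image = np.rint(np.clip(canvas, 0.0, 255.0)).astype(np.uint8)
    return image, mask


def fixture_suite(seed: int = 0, size: tuple[int, int] = (256, 256)) -> dict:
    """Generate the in-memory fixture suite keyed by fixture name.

    Each record has ``image`` (uint8), ``mask`` (bool or None) and
    ``params`` (the generating parameters).  Per-fixture seeds are derived
    deterministically from the base seed.
    """
    suite: dict[str, dict] = {}
    specs = {
        "bimodal": ((60.0, 10.0, 0.5), (180.0, 10.0, 0.5)),
        "trimodal": ((50.0, 12.0, 0.35), (120.0, 15.0, 0.35), (200.0, 10.0, 0.30)),
        "fivemode": (
            (30.0, 8.0, 0.2),
            (80.0, 10.0, 0.2),
            (128.0, 12.0, 0.2),
            (170.0, 10.0, 0.2),
            (220.0, 8.0, 0.2),
        ),
    }
    for i, (name, modes) in enumerate(specs.items()):
        spec = MixtureSpec(modes=modes, image_size=size, seed=seed * 1009 + i)
        image, _ = make_mixture_image(spec)
        suite[name] = {"image": image, "mask": None, "params": {"modes": modes}}

    blob_img, blob_mask = make_blob_image(size=size, seed=seed * 1009 + 10)
    suite["blob"] = {
        "image": blob_img,
        "mask": blob_mask,
        "params": {
            "n_blobs": 12,
            "blob_intensity": 60.0,
            "background_intensity": 200.0,
            "noise_sd": 5.0,
        },
    }

    two = np.full(size, 50, dtype=np.uint8)
    two[:, size[1] // 2 :] = 200
    suite["twopoint"] = {
        "image": two,
        "mask": None,
        "params": {"low": 50, "high": 200, "split": "half"},
    }
    suite["constant"] = {
        "image": np.full(size, 128, dtype=np.uint8),
        "mask": None,
        "params": {"value": 128},
    }
    return suite


def make_fixture_suite(out_dir, seed: int = 0) -> "object":
    """Write the fixture suite as PNGs plus a manifest CSV.

    The manifest records each fixture's generating parameters, a SHA-256
    checksum of the image bytes, and — for k = 1 and 2, where exhaustive
    search is cheap — the brute-force-optimal thresholds and J*.
    Returns the manifest as a DataFrame.
    """
    import pandas as pd
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suite = fixture_suite(seed=seed)
    rows = []
    for name, rec in suite.items():
        img_path = out / f"{name}.png"
        Image.fromarray(rec["image"]).save(img_path)
        mask_path = ""
        if rec["mask"] is not None:
            mask_path = f"{name}_mask.png"
            Image.fromarray(rec["mask"].astype(np.uint8) * 255).save(out / mask_path)
        hist = compute_histogram(rec["image"])
        row = {
            "fixture": name,
            "file": img_path.name,
            "mask_file": mask_path,
            "seed": seed,
            "params": json.dumps(rec["params"], sort_keys=True),
            "sha256": hashlib.sha256(rec["image"].tobytes()).hexdigest(),
        }
        for k in (1, 2):
            ts, j_star = brute_force_thresholds(hist, k)
            row[f"t_star_k{k}"] = json.dumps([int(v) for v in ts.values])
            row[f"J_star_k{k}"] = j_star
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
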