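"""Seeded generator of synthetic angiogram/mask fixtures.

The phantoms emulate the salient properties of clinical X-ray coronary
angiograms: a dark, connected, branching vessel tree covering only a few
percent of the frame, drawn over a brighter background with smooth nonuniform
illumination, low contrast and additive noise.  Every output is fully
determined by its parameters and seed, so fixtures never need to be shipped —
they are regenerated on demand.

These phantoms are deliberately simple: no catheters, ribs, diaphragm
shadows or motion blur, and no physics of contrast-agent propagation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .preprocess import SamplePair, save_image, save_mask

__all__ = [
    "VesselPhantomParams",
    "generate_tree_mask",
    "render_angiogram",
    "generate_pair",
    "generate_dataset",
    "make_fixture",
]


@dataclass(frozen=True)
class VesselPhantomParams:
    """Knobs of the vessel phantom.

    ``target_vessel_fraction`` is enforced by bounded regeneration; widths
    are in pixels at the given image size and taper along each branch.
    """

    image_size: tuple = (96, 96)
    n_branches: int = 4
    width_range: tuple = (1.0, 3.5)
    vessel_contrast: float = 0.35
    illumination_amplitude: float = 0.12
    noise_sd: float = 0.03
    target_vessel_fraction: tuple = (0.03, 0.10)
    max_retries: int = 25

    def __post_init__(self):
        lo, hi = self.target_vessel_fraction
        if not (0.0 < lo < hi < 0.2):
            raise ValueError("vessel fraction interval must satisfy 0 < lo < hi < 0.2")
        if self.width_range[0] < 1.0:
            raise ValueError("minimum vessel width must be >= 1 pixel")


def _draw_branch(canvas: np.ndarray, rng: np.random.Generator,
                 start, direction, length: int, width0: float,
                 width_min: float) -> list:
    """Stamp a random-walk stroke with tapering width; returns visited points."""
    h, w = canvas.shape
    y, x = float(start[0]), float(start[1])
    theta = float(direction)
    pts = []
    for step in range(length):
        width = max(width_min, width0 * (1.0 - 0.6 * step / max(length, 1)))
        r = width / 2.0
        yy, xx = np.ogrid[-int(np.ceil(r)):int(np.ceil(r)) + 1,
                          -int(np.ceil(r)):int(np.ceil(r)) + 1]
        stamp = (yy * yy + xx * xx) <= r * r + 0.25
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < h and 0 <= ix < w):
            break
        y0 = max(0, iy - stamp.shape[0] // 2)
        x0 = max(0, ix - stamp.shape[1] // 2)
        y1 = min(h, y0 + stamp.shape[0])
        x1 = min(w, x0 + stamp.shape[1])
        canvas[y0:y1, x0:x1] |= stamp[:y1 - y0, :x1 - x0]
        pts.append((iy, ix, width))
        theta += float(rng.normal(0.0, 0.12))
        y += np.sin(theta)
        x += np.cos(theta)
    return pts


def _tree_attempt(params: VesselPhantomParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size
    canvas = np.zeros((h, w), dtype=bool)
    scale = min(h, w)
    wmin, wmax = params.width_range
    # main trunk enters from a random border point heading inward
    side = rng.integers(0, 4)
    if side == 0:
        start, theta = (0, rng.integers(w // 4, 3 * w // 4)), np.pi / 2
    elif side == 1:
        start, theta = (h - 1, rng.integers(w // 4, 3 * w // 4)), -np.pi / 2
    elif side == 2:
        start, theta = (rng.integers(h // 4, 3 * h // 4), 0), 0.0
    else:
        start, theta = (rng.integers(h // 4, 3 * h // 4), w - 1), np.pi
    theta += float(rng.normal(0.0, 0.3))
    trunk = _draw_branch(canvas, rng, start, theta,
                         length=int(scale * 0.9), width0=wmax, width_min=wmin)
    parents = [trunk]
    for _ in range(params.n_branches - 1):
        parent = parents[rng.integers(0, len(parents))]
        if len(parent) < 8:
            continue
        idx = int(rng.integers(len(parent) // 4, len(parent)))
        py, px, pw = parent[idx]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        angle = float(rng.uniform(0.4, 1.1)) * sign
        base = np.arctan2(
            parent[min(idx + 1, len(parent) - 1)][0] - parent[idx - 1][0],
            parent[min(idx + 1, len(parent) - 1)][1] - parent[idx - 1][1])
        child = _draw_branch(canvas, rng, (py, px), base + angle,
                             length=int(scale * rng.uniform(0.3, 0.6)),
                             width0=max(wmin, pw * 0.8), width_min=wmin)
        if len(child) > 4:
            parents.append(child)
    return canvas


def generate_tree_mask(params: VesselPhantomParams, seed: int = 0) -> np.ndarray:
    """Binary mask of a connected branching vessel tree.

    Regenerates (bounded by ``max_retries``) until the vessel fraction falls
    inside ``target_vessel_fraction``; raises if the interval is infeasible.
    """
    lo, hi = params.target_vessel_fraction
    for attempt in range(params.max_retries):
        rng = np.random.default_rng((seed, attempt))
        mask = _tree_attempt(params, rng)
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask.astype(np.uint8)
    raise RuntimeError(
        f"could not reach vessel fraction in ({lo}, {hi}) "
        f"after {params.max_retries} attempts (seed {seed})")


def render_angiogram(mask: np.ndarray, params: VesselPhantomParams,
                     seed: int = 0) -> np.ndarray:
    """Render a gray angiogram from a vessel mask.

    Background is mid-gray plus a smooth illumination field (a coarse random
    grid upsampled with a spline) and Gaussian noise; vessel pixels are
    darkened by ``vessel_contrast`` scaled by the distance to the vessel edge
    (dark cores, softer rims), then everything is clipped to [0, 1].
    """
    rng = np.random.default_rng((seed, 977))
    h, w = mask.shape
    background = np.full((h, w), 0.55)
    if params.illumination_amplitude > 0:
        coarse = rng.uniform(-1.0, 1.0, size=(4, 4))
        fine = ndi.zoom(coarse, (h / 4, w / 4), order=3)[:h, :w]
        background += params.illumination_amplitude * fine
    depth = ndi.distance_transform_edt(mask)
    if depth.max() > 0:
        depth = np.minimum(depth / 2.0, 1.0)   # full depth two pixels in
    dip = params.vessel_contrast * (0.4 + 0.6 * depth) * (mask > 0)
    img = background - dip
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(h, w))
    return np.clip(img, 0.0, 1.0)


def generate_pair(params: VesselPhantomParams, seed: int = 0,
                  name: str = "") -> SamplePair:
    mask = generate_tree_mask(params, seed)
    img = render_angiogram(mask, params, seed)
    return SamplePair(img, mask, name=name or f"phantom_{seed:04d}")


def make_fixture(n: int = 4, size: int = 96, seed: int = 0,
                 params: VesselPhantomParams | None = None) -> list:
    """In-memory list of ``n`` seeded sample pairs (the standard fixture)."""
    params = params or VesselPhantomParams(image_size=(size, size))
    return [generate_pair(params, seed=seed * 1000 + i, name=f"phantom_{i:03d}")
            for i in range(n)]


def generate_dataset(n: int, params: VesselPhantomParams, out_dir,
                     seed: int = 0) -> dict:
    """Write ``n`` image/mask PNG pairs plus a JSON manifest; returns it."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out!s}: {exc}") from exc
    entries = []
    for i in range(n):
        s = seed * 1000 + i
        pair = generate_pair(params, seed=s)
        img_name, mask_name = f"image_{i:03d}.png", f"mask_{i:03d}.png"
        save_image(out / img_name, pair.image)
        save_mask(out / mask_name, pair.mask)
        entries.append({
            "image": img_name,
            "mask": mask_name,
            "seed": s,
            "vessel_fraction": float(pair.mask.mean()),
        })
    manifest = {"params": asdict(params), "seed": seed, "pairs": entries}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
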