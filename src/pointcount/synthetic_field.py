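"""Synthetic single-plant scenes with exact seed-centroid ground truth.

Real mature-plant images show beige seeds/pods clustered along dark stems on
soil-coloured ground, with 3-149 seeds per plant and frequent partial
occlusion by pods and stems.  The generator emulates that structure — soil
background with low-frequency mottle and leaf-green blobs, stems as
polylines, seeds as shaded discs clustered along the stems, elliptical
occluders — while keeping the centroid ground truth exact by construction:
a seed contributes a ground-truth point iff its center pixel is not covered
by an occluder (only the visible central region of a seed is annotated).

Determinism: every random choice derives from ``rng_seed`` through named
substreams, and occluder geometry for seed *i* does not depend on
``occluder_fraction``; raising the fraction only adds occluders, so the
visible-center count is nonincreasing in the fraction for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .annotations_io import AnnotationRecord, DatasetManifest, split_dataset, write_annotations, write_manifest
from .point_core import PointSet, density_stratum

CULTIVARS = ("D1", "D2", "D3", "D4", "D5", "D6")

SOIL = np.array([105.0, 82.0, 58.0])
LEAF = np.array([70.0, 110.0, 55.0])
STEM = np.array([84.0, 92.0, 48.0])
SEED = np.array([214.0, 192.0, 128.0])
POD = np.array([150.0, 140.0, 90.0])


@dataclass
class SceneConfig:
    image_size: tuple = (256, 256)
    count_range: tuple = (3, 149)
    seed_radius_range: tuple = (5.0, 8.0)
    cluster_count: int = 5
    cluster_spread: float = 14.0
    occluder_fraction: float = 0.0
    min_separation: float | None = None  # default: ~seed diameter * 0.55
    leaf_blob_count: int = 3
    illumination_gain: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.occluder_fraction <= 1.0):
            raise ValueError("occluder_fraction must be in [0, 1]")
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError("invalid count_range")


def _disc_mask(H, W, cx, cy, r):
    x0, x1 = max(0, int(cx - r - 1)), min(W, int(cx + r + 2))
    y0, y1 = max(0, int(cy - r - 1)), min(H, int(cy + r + 2))
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    return (slice(y0, y1), slice(x0, x1)), d2, r * r


def _paint_disc(img, cx, cy, r, color, shade=0.35):
    m = _disc_mask(img.shape[0], img.shape[1], cx, cy, r)
    if m is None:
        return
    sl, d2, r2 = m
    inside = d2 <= r2
    # radial shading: bright center, darker rim
    factor = 1.0 - shade * (d2 / max(r2, 1e-9))
    patch = img[sl]
    patch[inside] = np.clip(color[None, :] * factor[inside, None], 0, 255)


def _paint_ellipse(img, mask, cx, cy, a, b, ang, color):
    H, W = img.shape[:2]
    rmax = max(a, b)
    x0, x1 = max(0, int(cx - rmax - 1)), min(W, int(cx + rmax + 2))
    y0, y1 = max(0, int(cy - rmax - 1)), min(H, int(cy + rmax + 2))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = color
    if mask is not None:
        mask[y0:y1, x0:x1] |= inside


def _draw_polyline(img, pts, thickness, color):
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.hypot(x1 - x0, y1 - y0) * 2))
        for t in np.linspace(0.0, 1.0, n):
            _paint_disc(img, x0 + t * (x1 - x0), y0 + t * (y1 - y0), thickness, color, shade=0.15)


def generate_scene(config: SceneConfig, count: int | None = None):
    """Render one scene; returns (uint8 RGB image, PointSet of visible centers,
    metadata dict)."""
    H, W = config.image_size
    if H < 32 or W < 32:
        raise ValueError("image size too small to render a plant scene")
    rng = np.random.default_rng([int(config.rng_seed), 101])

    if count is None:
        lo, hi = config.count_range
        count = int(rng.integers(lo, hi + 1))
    else:
        _ = rng.integers(0, 1 << 30)  # keep the layout stream aligned

    # --- background: mottled soil + leaf blobs --------------------------
    coarse = rng.normal(0.0, 1.0, size=(H // 8 + 1, W // 8 + 1))
    mottle = gaussian_filter(np.kron(coarse, np.ones((8, 8)))[:H, :W], 4.0)
    mottle = 1.0 + 0.18 * mottle / max(mottle.std(), 1e-9)
    img = np.clip(SOIL[None, None, :] * mottle[:, :, None], 0, 255)
    img += rng.normal(0.0, 4.0, size=img.shape)
    for _ in range(config.leaf_blob_count):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        _paint_ellipse(img, None, cx, cy, rng.uniform(8, 20), rng.uniform(5, 12),
                       rng.uniform(0, np.pi), LEAF * rng.uniform(0.8, 1.15))

    # --- stems ----------------------------------------------------------
    stems = []
    for _ in range(max(1, config.cluster_count)):
        x = rng.uniform(0.15 * W, 0.85 * W)
        pts = [(x, rng.uniform(0.0, 0.15 * H))]
        y = pts[0][1]
        while y < 0.95 * H:
            y += rng.uniform(0.15 * H, 0.3 * H)
            x = np.clip(x + rng.uniform(-0.12 * W, 0.12 * W), 2, W - 3)
            pts.append((x, min(y, H - 1.0)))
        stems.append(np.asarray(pts))
        _draw_polyline(img, pts, 1.6, STEM)

    # --- seed placement: clustered along stems, minimum separation ------
    rmin, rmax = config.seed_radius_range
    min_sep = config.min_separation
    if min_sep is None:
        min_sep = 0.55 * (rmin + rmax)
    centers, radii = [], []
    margin = rmax + 1
    for _ in range(count):
        placed = False
        for attempt in range(300):
            stem = stems[rng.integers(len(stems))]
            seg = rng.integers(len(stem) - 1)
            t = rng.uniform()
            base = stem[seg] * (1 - t) + stem[seg + 1] * t
            pos = base + rng.normal(0.0, config.cluster_spread, size=2)
            pos = np.clip(pos, margin, [W - 1 - margin, H - 1 - margin])
            if all((pos[0] - c[0]) ** 2 + (pos[1] - c[1]) ** 2 >= min_sep**2 for c in centers):
                placed = True
                break
        if not placed:  # dense scene: accept the last candidate
            pos = np.clip(
                rng.uniform([margin, margin], [W - 1 - margin, H - 1 - margin]),
                margin, max(W, H),
            )
        centers.append(pos)
        radii.append(rng.uniform(rmin, rmax))
    centers = np.asarray(centers).reshape(-1, 2)
    radii = np.asarray(radii)

    # --- pods behind seed clusters (aesthetic context) ------------------
    for i in range(0, len(centers), 4):
        cx, cy = centers[i]
        _paint_ellipse(img, None, cx + rng.uniform(-3, 3), cy + rng.uniform(-3, 3),
                       rng.uniform(1.2, 1.8) * rmax, rng.uniform(0.8, 1.1) * rmax,
                       rng.uniform(0, np.pi), POD * rng.uniform(0.9, 1.05))

    # --- seeds ----------------------------------------------------------
    for (cx, cy), r in zip(centers, radii):
        jitter = rng.uniform(0.92, 1.06)
        _paint_disc(img, cx, cy, r, SEED * jitter)

    # --- occluders (pod/stem fragments drawn over seeds) ----------------
    occ_mask = np.zeros((H, W), dtype=bool)
    n_occ = int(round(config.occluder_fraction * count))
    order = np.random.default_rng([int(config.rng_seed), 777]).permutation(count)
    for i in order[:n_occ]:
        orng = np.random.default_rng([int(config.rng_seed), 888, int(i)])
        cx, cy = centers[i]
        r = radii[i]
        off = orng.uniform(0.2 * r, 1.0 * r)
        ang = orng.uniform(0, 2 * np.pi)
        ocx, ocy = cx + off * np.cos(ang), cy + off * np.sin(ang)
        color = (POD if orng.uniform() < 0.5 else STEM) * orng.uniform(0.85, 1.1)
        _paint_ellipse(img, occ_mask, ocx, ocy, orng.uniform(1.0, 1.6) * r,
                       orng.uniform(0.5, 0.9) * r, orng.uniform(0, np.pi), np.clip(color, 0, 255))

    # --- ground truth: seeds with visible centers ------------------------
    visible = []
    for (cx, cy) in centers:
        ix, iy = int(round(cx)), int(round(cy))
        ix, iy = min(max(ix, 0), W - 1), min(max(iy, 0), H - 1)
        if not occ_mask[iy, ix]:
            visible.append((cx, cy))
    points = PointSet(np.asarray(visible).reshape(-1, 2))

    img = np.clip(img * config.illumination_gain, 0, 255).astype(np.uint8)
    meta = {
        "rendered_count": int(count),
        "occluded": int(n_occ),
        "visible_count": len(points),
        "stratum": density_stratum(len(points)),
    }
    return img, points, meta


def generate_dataset(
    config: SceneConfig,
    n_images: int,
    out_dir,
    strata_targets: tuple | None = None,
    split_fractions=(0.8, 0.1, 0.1),
) -> DatasetManifest:
    """Render ``n_images`` scenes, write PNGs + annotation TXT + manifest.

    ``strata_targets`` = (n_sparse, n_medium, n_dense) pins the number of
    images per density stratum; counts are then sampled inside each
    stratum's bounds intersected with ``count_range``.  With occluders
    disabled the written ground-truth counts land in the requested strata
    exactly.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng([int(config.rng_seed), 4242])
    bounds = {"Sparse": (0, 37), "Medium": (38, 63), "Dense": (64, 10**9)}
    if strata_targets is not None:
        if len(strata_targets) != 3 or sum(strata_targets) != n_images:
            raise ValueError("strata_targets must be 3 counts summing to n_images")
        labels = (["Sparse"] * strata_targets[0] + ["Medium"] * strata_targets[1]
                  + ["Dense"] * strata_targets[2])
        for lab, tgt in zip(("Sparse", "Medium", "Dense"), strata_targets):
            lo = max(bounds[lab][0], config.count_range[0])
            hi = min(bounds[lab][1], config.count_range[1])
            if tgt > 0 and lo > hi:
                raise ValueError(f"stratum {lab} infeasible under count_range {config.count_range}")
    else:
        labels = [None] * n_images

    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    records = []
    for i, lab in enumerate(labels):
        if lab is None:
            count = None
        else:
            lo = max(bounds[lab][0], config.count_range[0])
            hi = min(bounds[lab][1], config.count_range[1])
            count = int(rng.integers(lo, hi + 1))
        scene_cfg = replace(config, rng_seed=int(np.random.default_rng(
            [int(config.rng_seed), 999, i]).integers(2**31)))
        img, pts, _ = generate_scene(scene_cfg, count=count)
        rel = os.path.join("images", f"img_{i:04d}.png")
        Image.fromarray(img).save(os.path.join(out_dir, rel))
        records.append(AnnotationRecord(
            rel, PointSet(pts.points, image_id=rel),
            cultivar=CULTIVARS[i % len(CULTIVARS)],
            salinity="control" if (i // len(CULTIVARS)) % 2 == 0 else "stress",
        ))
    write_annotations(records, os.path.join(out_dir, "annotations.txt"))
    if n_images < 3:
        manifest = DatasetManifest(records, ["train"] * n_images, root=str(out_dir))
    else:
        manifest = split_dataset(records, split_fractions, seed=int(config.rng_seed), root=str(out_dir))
    write_manifest(manifest, os.path.join(out_dir, "manifest.txt"))
    return manifest
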