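"""Point-annotation TXT I/O, dataset splitting and point-aware augmentation.

Annotation dialect (one image per line, tab-separated)::

    relative/image/path<TAB>cultivar<TAB>salinity<TAB>x1,y1;x2,y2;...

The point field may be empty (a plant can carry very few visible seeds).
Lines starting with ``#`` are comments.  All augmentations transform the
image and its centroid annotations with the same map; points whose
transformed center falls outside the output canvas are dropped from the
ground truth (mirroring centroid annotation of the visible region only).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

from .point_core import PointSet, as_points


@dataclass
class AnnotationRecord:
    image_path: str
    points: PointSet
    cultivar: str = ""
    salinity: str = "control"


@dataclass
class DatasetManifest:
    """Records plus a train/val/test assignment (one label per record)."""

    records: list
    split: list  # parallel to records; values in {"train","val","test"}
    root: str = "."

    def subset(self, name: str) -> list:
        return [r for r, s in zip(self.records, self.split) if s == name]


@dataclass
class AugmentationSpec:
    hsv_jitter: tuple = (0.015, 0.7, 0.4)
    hflip_prob: float = 0.5
    mosaic_prob: float = 0.5
    affine_rotation: float = 10.0  # degrees, +/-
    affine_translate: float = 0.10  # fraction of image size, +/-
    affine_scale: tuple = (0.9, 1.1)
    affine_shear: float = 2.0  # degrees, +/-
    affine_prob: float = 0.5
    enabled: bool = True


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TXT dialect
# ---------------------------------------------------------------------------

def _format_points(points: PointSet) -> str:
    # repr gives the shortest digits that round-trip a double exactly
    return ";".join(f"{float(x)!r},{float(y)!r}" for x, y in points.points)


def _parse_points(text: str, lineno: int) -> np.ndarray:
    text = text.strip()
    if not text:
        return np.zeros((0, 2))
    pts = []
    for tok in text.split(";"):
        parts = tok.split(",")
        if len(parts) != 2:
            raise AnnotationError(
                f"line {lineno}: point '{tok}' does not have an even x,y coordinate pair"
            )
        try:
            pts.append((float(parts[0]), float(parts[1])))
        except ValueError as e:
            raise AnnotationError(f"line {lineno}: bad coordinate in '{tok}'") from e
    return np.asarray(pts)


def read_annotations(path) -> list:
    """Parse an annotation TXT file into records; malformed lines raise with
    their line number, duplicate image paths raise."""
    records = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise AnnotationError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            img, cultivar, salinity, pts_text = fields
            if not img:
                raise AnnotationError(f"line {lineno}: empty image path")
            if img in seen:
                raise AnnotationError(f"line {lineno}: duplicate image path '{img}'")
            seen.add(img)
            pts = _parse_points(pts_text, lineno)
            records.append(
                AnnotationRecord(img, PointSet(pts, image_id=img), cultivar, salinity)
            )
    return records


def write_annotations(records, path) -> str:
    """Serialize records in the TXT dialect, one image per line, input order."""
    lines = []
    for r in records:
        for field_val in (r.image_path, r.cultivar, r.salinity):
            if "\t" in field_val or "\n" in field_val:
                raise AnnotationError(f"field {field_val!r} contains a separator")
        lines.append("\t".join((r.image_path, r.cultivar, r.salinity, _format_points(r.points))))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
    return str(path)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def split_dataset(records, fractions=(0.8, 0.1, 0.1), seed: int = 0, root: str = ".") -> DatasetManifest:
    """Shuffle records and assign train/val/test at the given fractions.

    Val/test sizes are floor-allocated; the remainder goes to train, so
    800 records at (0.8, 0.1, 0.1) give 640/80/80.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(records)
    if n < 3:
        raise ValueError("need at least one record per split")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = [""] * n
    for rank, idx in enumerate(order):
        if rank < n_train:
            labels[idx] = "train"
        elif rank < n_train + n_val:
            labels[idx] = "val"
        else:
            labels[idx] = "test"
    return DatasetManifest(list(records), labels, root=root)


def write_manifest(manifest: DatasetManifest, path) -> str:
    """Annotation TXT plus a trailing split column."""
    lines = []
    for r, s in zip(manifest.records, manifest.split):
        lines.append("\t".join((r.image_path, r.cultivar, r.salinity, _format_points(r.points), s)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return str(path)


def read_manifest(path, root: str = ".") -> DatasetManifest:
    records, split = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise AnnotationError(f"line {lineno}: expected 5 fields in manifest")
            img, cultivar, salinity, pts_text, s = fields
            records.append(
                AnnotationRecord(img, PointSet(_parse_points(pts_text, lineno), image_id=img), cultivar, salinity)
            )
            split.append(s)
    return DatasetManifest(records, split, root=root)


# ---------------------------------------------------------------------------
# Augmentations
# ---------------------------------------------------------------------------

def hflip(image: np.ndarray, points) -> tuple:
    """Mirror about the vertical axis; (x, y) -> (W-1-x, y)."""
    pts = as_points(points).copy()
    W = image.shape[1]
    out = image[:, ::-1].copy()
    if len(pts):
        pts[:, 0] = (W - 1) - pts[:, 0]
    return out, pts


def affine(image: np.ndarray, points, matrix: np.ndarray) -> tuple:
    """Apply a 2x3 forward affine map to image and points.

    ``matrix @ [x, y, 1]`` gives the output location of input point (x, y).
    Points mapped outside the canvas are dropped.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (2, 3):
        raise ValueError("affine matrix must be 2x3")
    M = np.vstack([matrix, [0.0, 0.0, 1.0]])
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("singular affine matrix")
    H, W = image.shape[:2]
    tform = sktransform.AffineTransform(matrix=np.linalg.inv(M))
    out = sktransform.warp(image.astype(float), tform, output_shape=(H, W), order=1,
                           mode="constant", cval=0.0, preserve_range=True)
    out = out.astype(image.dtype)
    pts = as_points(points)
    if len(pts):
        ones = np.ones((len(pts), 1))
        moved = (np.hstack([pts, ones]) @ matrix.T)
        keep = (
            (moved[:, 0] >= -0.5) & (moved[:, 0] <= W - 0.5)
            & (moved[:, 1] >= -0.5) & (moved[:, 1] <= H - 0.5)
        )
        pts = moved[keep]
    else:
        pts = pts.copy()
    return out, pts


def random_affine_matrix(spec: AugmentationSpec, size: tuple, rng) -> np.ndarray:
    """Rotation/scale/shear about the image center plus translation, 2x3."""
    H, W = size
    ang = np.deg2rad(rng.uniform(-spec.affine_rotation, spec.affine_rotation))
    shear = np.deg2rad(rng.uniform(-spec.affine_shear, spec.affine_shear))
    s = rng.uniform(*spec.affine_scale)
    tx = rng.uniform(-spec.affine_translate, spec.affine_translate) * W
    ty = rng.uniform(-spec.affine_translate, spec.affine_translate) * H
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    R = np.array([
        [s * np.cos(ang), -s * np.sin(ang + shear)],
        [s * np.sin(ang), s * np.cos(ang + shear)],
    ])
    center = np.array([cx, cy])
    t = center + np.array([tx, ty]) - R @ center
    return np.hstack([R, t[:, None]])


def mosaic(samples, out_size: tuple) -> tuple:
    """2x2 collage of four (image, points) samples with per-quadrant scaling."""
    if len(samples) != 4:
        raise ValueError("mosaic requires exactly 4 samples")
    H, W = out_size
    qh, qw = H // 2, W // 2
    canvas = np.zeros((qh * 2, qw * 2) + samples[0][0].shape[2:], dtype=samples[0][0].dtype)
    all_pts = []
    offsets = [(0, 0), (0, qw), (qh, 0), (qh, qw)]
    for (img, pts), (oy, ox) in zip(samples, offsets):
        h, w = img.shape[:2]
        tile = sktransform.resize(img.astype(float), (qh, qw), order=1,
                                  preserve_range=True, anti_aliasing=False)
        canvas[oy : oy + qh, ox : ox + qw] = tile.astype(img.dtype)
        p = as_points(pts)
        if len(p):
            # pixel-center scaling used by the resampler
            x = (p[:, 0] + 0.5) * qw / w - 0.5 + ox
            y = (p[:, 1] + 0.5) * qh / h - 0.5 + oy
            keep = (x >= -0.5) & (x <= qw * 2 - 0.5) & (y >= -0.5) & (y <= qh * 2 - 0.5)
            all_pts.append(np.stack([x[keep], y[keep]], axis=1))
    pts_out = np.concatenate(all_pts, axis=0) if all_pts else np.zeros((0, 2))
    return canvas, pts_out


def hsv_jitter(image: np.ndarray, amplitudes=(0.015, 0.7, 0.4), seed: int = 0) -> np.ndarray:
    """Random hue shift and saturation/value gain; annotations unaffected."""
    ah, asat, aval = amplitudes
    if ah == 0 and asat == 0 and aval == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    dh = rng.uniform(-ah, ah)
    gs = 1.0 + rng.uniform(-asat, asat)
    gv = 1.0 + rng.uniform(-aval, aval)
    hsv = rgb2hsv(image)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * gs, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * gv, 0.0, 1.0)
    out = hsv2rgb(hsv)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out * 255.0), 0, 255).astype(image.dtype)
    return np.clip(out, 0.0, 1.0).astype(image.dtype)


def augment_sample(image, points, spec: AugmentationSpec, rng, extra_samples=None):
    """Compose the training-time augmentations on one sample.

    ``extra_samples`` supplies the three partner samples for mosaic; when
    absent, mosaic is skipped.  Returns (image, points).
    """
    pts = as_points(points)
    if not spec.enabled:
        return image, pts
    if extra_samples is not None and len(extra_samples) == 3 and rng.random() < spec.mosaic_prob:
        image, pts = mosaic([(image, pts)] + list(extra_samples), image.shape[:2])
    image = hsv_jitter(image, spec.hsv_jitter, seed=int(rng.integers(2**31)))
    if rng.random() < spec.hflip_prob:
        image, pts = hflip(image, pts)
    if rng.random() < spec.affine_prob:
        m = random_affine_matrix(spec, image.shape[:2], rng)
        image, pts = affine(image, pts, m)
    return image, pts
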