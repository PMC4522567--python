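"""IDX image/label files, synthetic multi-class fixtures, and run artifacts.

The IDX format is the simple big-endian binary container used by the
standard handwritten-digit benchmark: a magic number (2051 for uint8 image
tensors, 2049 for label vectors), big-endian int32 dimension sizes, then the
raw uint8 payload.

The synthetic generator draws class-structured intensity images from
stroke-like binary templates (bars, diagonals, a box outline) so that a
competitive network can learn one template per receptive field and the
learned fields are visually checkable.  Templates are guarded to be pairwise
dissimilar (cosine < 0.5), which makes downstream recovery experiments
well-posed.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IdxFormatError",
    "SyntheticSpec",
    "read_idx",
    "write_idx",
    "default_stroke_templates",
    "generate_synthetic",
    "save_weights",
    "load_weights",
]

_IMAGE_MAGIC = 2051
_LABEL_MAGIC = 2049


class IdxFormatError(ValueError):
    """Malformed IDX file (bad magic, truncation, or count mismatch)."""


def _read_header(fh, expected_magic: int, n_dims: int, path) -> tuple[int, ...]:
    head = fh.read(4 * (1 + n_dims))
    if len(head) < 4 * (1 + n_dims):
        raise IdxFormatError(f"{path}: truncated IDX header")
    magic, *dims = struct.unpack(f">{1 + n_dims}i", head)
    if magic != expected_magic:
        raise IdxFormatError(
            f"{path}: bad magic number {magic}, expected {expected_magic}"
        )
    return tuple(dims)


def read_idx(images_path, labels_path, n_classes: int | None = None):
    """Read paired IDX image and label files.

    Returns ``(images, labels)`` with images a uint8 array of shape
    (n, rows, cols) and labels an int array of shape (n,).  Raises
    :class:`IdxFormatError` on bad magic numbers, truncated payloads, or
    image/label count mismatch, and a validation error when ``n_classes``
    is given and a label falls outside ``0..n_classes-1``.
    """
    with open(images_path, "rb") as fh:
        n, rows, cols = _read_header(fh, _IMAGE_MAGIC, 3, images_path)
        payload = fh.read()
    if len(payload) != n * rows * cols:
        raise IdxFormatError(
            f"{images_path}: payload has {len(payload)} bytes, "
            f"expected {n * rows * cols}"
        )
    images = np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols)

    with open(labels_path, "rb") as fh:
        (n_labels,) = _read_header(fh, _LABEL_MAGIC, 1, labels_path)
        label_payload = fh.read()
    if len(label_payload) != n_labels:
        raise IdxFormatError(f"{labels_path}: truncated label payload")
    labels = np.frombuffer(label_payload, dtype=np.uint8).astype(np.int64)

    if n_labels != n:
        raise IdxFormatError(
            f"image count {n} does not match label count {n_labels}"
        )
    if n_classes is not None and labels.size and labels.max(initial=0) >= n_classes:
        raise ValueError(
            f"label {int(labels.max())} outside the {n_classes}-class set"
        )
    return images, labels


def write_idx(images, labels, images_path, labels_path) -> None:
    """Write bit-valid IDX files; inverse of :func:`read_idx`."""
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.ndim != 3:
        raise ValueError("images must have shape (n, rows, cols)")
    if np.any(images < 0) or np.any(images > 255):
        raise ValueError("intensities must lie in 0..255")
    n, rows, cols = images.shape
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per image")
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">4i", _IMAGE_MAGIC, n, rows, cols))
        fh.write(images.astype(np.uint8).tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">2i", _LABEL_MAGIC, n))
        fh.write(labels.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# synthetic fixtures


def default_stroke_templates(n_classes: int = 5, side: int = 28) -> np.ndarray:
    """Procedural binary templates: bars, diagonals, and a filled square.

    Returns a boolean array (n_classes, side, side).  Supports up to 5
    classes; custom template stacks can be passed to :class:`SyntheticSpec`
    directly for other class counts.
    """
    if not 2 <= n_classes <= 5:
        raise ValueError("default templates support 2..5 classes")
    t = np.zeros((5, side, side), dtype=bool)
    lo, hi = side // 7, side - side // 7  # keep strokes away from the frame edge
    mid = side // 2
    # stroke widths chosen so every class has a similar active-pixel mass
    # (roughly equal stimulus energy -> balanced competition for neurons)
    t[0, lo:hi, mid - 2 : mid + 2] = True            # vertical bar
    t[1, mid - 2 : mid + 2, lo:hi] = True            # horizontal bar
    dlo, dhi = max(lo - 2, 1), min(hi + 2, side - 1)
    for k in range(dlo, dhi):                         # main diagonal, width 3
        t[2, k, max(k - 1, 0) : min(k + 2, side)] = True
    for k in range(dlo, dhi):                         # anti-diagonal, width 3
        c = side - 1 - k
        t[3, k, max(c - 1, 0) : min(c + 2, side)] = True
    # pair of short horizontal bars at top and bottom: occupies the pockets
    # the other strokes leave free, grazing only the vertical bar
    c0, c1 = side // 3, side - side // 3 + 1
    t[4, 2:6, c0:c1] = True
    t[4, side - 6 : side - 2, c0:c1] = True
    return t[:n_classes]


def _pairwise_max_cosine(templates: np.ndarray) -> float:
    flat = templates.reshape(templates.shape[0], -1).astype(np.float64)
    norms = np.linalg.norm(flat, axis=1)
    gram = flat @ flat.T / np.outer(norms, norms)
    np.fill_diagonal(gram, 0.0)
    return float(gram.max())


@dataclass
class SyntheticSpec:
    """Recipe for a class-structured synthetic intensity-image dataset."""

    n_classes: int = 5
    image_side: int = 28
    stroke_templates: np.ndarray | None = None  # (n_classes, side, side) bool
    intensity_high: int = 255   # intensity of template (and salt-noise) pixels
    jitter_px: int = 2          # uniform integer translation range, per axis
    noise_flip_prob: float = 0.01  # per-pixel salt-noise probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stroke_templates is None:
            self.stroke_templates = default_stroke_templates(
                self.n_classes, self.image_side
            )
        self.stroke_templates = np.asarray(self.stroke_templates, dtype=bool)
        expect = (self.n_classes, self.image_side, self.image_side)
        if self.stroke_templates.shape != expect:
            raise ValueError(f"templates must have shape {expect}")
        if not 0 <= self.noise_flip_prob <= 1:
            raise ValueError("noise_flip_prob must lie in [0, 1]")
        if not 0 <= self.intensity_high <= 255:
            raise ValueError("intensity_high must lie in 0..255")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")
        worst = _pairwise_max_cosine(self.stroke_templates)
        if worst >= 0.5:
            raise ValueError(
                f"templates too similar (max pairwise cosine {worst:.3f} >= 0.5)"
            )


def _shift(mask: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, bool]:
    """Translate a binary mask with zero fill; report whether pixels clipped."""
    out = np.zeros_like(mask)
    side = mask.shape[0]
    r0, r1 = max(dr, 0), side + min(dr, 0)
    c0, c1 = max(dc, 0), side + min(dc, 0)
    out[r0:r1, c0:c1] = mask[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    clipped = out.sum() < mask.sum()
    return out, clipped


def generate_synthetic(spec: SyntheticSpec, n_per_class: int):
    """Draw a balanced, shuffled synthetic dataset.

    Each image is its class template translated by a uniform integer jitter,
    with template pixels at ``intensity_high`` on a zero background, then
    per-pixel salt noise (pixels set to ``intensity_high`` with probability
    ``noise_flip_prob``).  Reproducible under ``spec.seed``.  Returns
    ``(images uint8 (n, side, side), labels int64 (n,))`` in shuffled order
    so consecutive presentations mix classes.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    n_total = spec.n_classes * n_per_class
    images = np.zeros((n_total, side, side), dtype=np.uint8)
    labels = np.repeat(np.arange(spec.n_classes), n_per_class)
    any_clipped = False
    for i, cls in enumerate(labels):
        dr, dc = rng.integers(-spec.jitter_px, spec.jitter_px + 1, size=2)
        mask, clipped = _shift(spec.stroke_templates[cls], int(dr), int(dc))
        any_clipped = any_clipped or clipped
        img = np.where(mask, spec.intensity_high, 0).astype(np.uint8)
        salt = rng.random((side, side)) < spec.noise_flip_prob
        img[salt] = spec.intensity_high
        images[i] = img
    if any_clipped:
        warnings.warn("jitter pushed template pixels out of frame; clipped",
                      RuntimeWarning, stacklevel=2)
    order = rng.permutation(n_total)
    return images[order], labels[order]


# ---------------------------------------------------------------------------
# run artifacts


def save_weights(path, w, theta, *, rule_id: str, seed: int,
                 n_presentations: int) -> None:
    """Persist the plastic weight matrix and theta vector with run metadata."""
    np.savez(
        path,
        w=np.asarray(w),
        theta=np.asarray(theta),
        rule_id=np.array(rule_id),
        n_exc=np.array(np.asarray(w).shape[1]),
        seed=np.array(seed),
        n_presentations=np.array(n_presentations),
    )


def load_weights(path):
    """Load a persisted weight artifact; returns (w, theta, metadata dict)."""
    with np.load(path, allow_pickle=False) as data:
        meta = {
            "rule_id": str(data["rule_id"]),
            "n_exc": int(data["n_exc"]),
            "seed": int(data["seed"]),
            "n_presentations": int(data["n_presentations"]),
        }
        return data["w"].copy(), data["theta"].copy(), meta
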