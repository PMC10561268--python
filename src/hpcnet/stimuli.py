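"""Synthetic transformation-sequence stimuli.

Generates the inputs the network is trained and probed on: short sequences
of a single object undergoing a continuous transformation (translation,
rotation or scaling), moving bars, optional background noise, and static
occluders that a translating object disappears behind.  Objects are
procedurally drawn "glyphs" — connected stroke figures, one per class —
standing in for handwritten digits or photographed toy objects.

All pixel values live in [0, 1]; everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk
from skimage.transform import AffineTransform, warp

__all__ = [
    "StimulusSequence",
    "Dataset",
    "TRANSFORM_STEPS",
    "make_glyph",
    "make_bar_sequence",
    "make_sequence",
    "make_dataset",
    "make_occlusion_dataset",
    "apply_occluder",
    "shuffle_frame_order",
    "sequence_overlap",
]

#: Per-frame transformation increment at speed 1, per transform kind.
#: Units: pixels (translate), degrees (rotate), scale-factor increment (scale).
TRANSFORM_STEPS = {"translate": 1.0, "rotate": 12.0, "scale": 0.06}

_BACKGROUND_EPS = 0.05  # below this a pixel counts as background for noise


@dataclass
class StimulusSequence:
    """An ordered stack of frames showing one object under one transform."""

    frames: np.ndarray  # (n_frames, H, W), values in [0, 1]
    object_label: int
    transform: str = "none"  # translate | rotate | scale | none
    speed: float = 1.0
    noise: bool = False
    occluder_mask: np.ndarray | None = None  # (n_frames, H, W) bool, True = occluded
    ground_truth: np.ndarray | None = None  # unoccluded frames, same shape

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.occluder_mask is not None:
            self.occluder_mask = np.asarray(self.occluder_mask, dtype=bool)
            if self.occluder_mask.shape != self.frames.shape:
                raise ValueError("occluder_mask shape must match frames")
        if self.ground_truth is not None:
            self.ground_truth = np.asarray(self.ground_truth, dtype=float)
            if self.ground_truth.shape != self.frames.shape:
                raise ValueError("ground_truth shape must match frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def flat(self) -> np.ndarray:
        """Frames flattened to (n_frames, H*W)."""
        return self.frames.reshape(self.n_frames, -1)


@dataclass
class Dataset:
    """A labelled collection of stimulus sequences with a common shape."""

    sequences: list
    n_classes: int
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        for s in self.sequences:
            if s.image_shape != tuple(self.image_shape):
                raise ValueError("all sequences must share the dataset image shape")
            if not (0 <= s.object_label < self.n_classes):
                raise ValueError("object_label outside [0, n_classes)")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def frames_matrix(self) -> np.ndarray:
        """All frames, sequence-major, flattened to (n_seq * n_frames, H*W)."""
        return np.concatenate([s.flat() for s in self.sequences], axis=0)

    def frame_labels(self) -> np.ndarray:
        """Object label of every row of :meth:`frames_matrix`."""
        return np.concatenate(
            [np.full(s.n_frames, s.object_label, dtype=int) for s in self.sequences]
        )


# ---------------------------------------------------------------------------
# object drawing


def make_glyph(
    class_id: int, shape: tuple[int, int] = (28, 28), seed: int = 0
) -> np.ndarray:
    """Draw a connected stroke figure for one object class.

    A chain of straight strokes between random control points, thickened
    and lightly smoothed, then centred on the canvas by centre of mass.
    Deterministic per (class_id, seed) and visually distinct across classes.
    """
    H, W = shape
    if H < 16 or W < 16:
        raise ValueError("canvas must be at least 16x16")
    rng = np.random.default_rng([int(seed), int(class_id)])
    img = np.zeros((H, W))
    # control points inside the central 60% of the canvas
    lo_r, hi_r = int(0.2 * H), int(0.8 * H)
    lo_c, hi_c = int(0.2 * W), int(0.8 * W)
    n_strokes = 3 + int(rng.integers(0, 3))
    pts = np.column_stack(
        [
            rng.integers(lo_r, hi_r, size=n_strokes + 1),
            rng.integers(lo_c, hi_c, size=n_strokes + 1),
        ]
    )
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        img[rr, cc] = 1.0
    img = dilation(img, disk(1))
    img = ndimage.gaussian_filter(img, sigma=0.6)
    img /= img.max()
    # recentre by integer centre-of-mass shift
    com = ndimage.center_of_mass(img)
    shift = (round(H / 2 - 0.5 - com[0]), round(W / 2 - 0.5 - com[1]))
    img = _shift_int(img, int(shift[0]), int(shift[1]))
    return np.clip(img, 0.0, 1.0)


def _shift_int(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Zero-filled integer pixel shift (no interpolation blur)."""
    out = np.zeros_like(img)
    H, W = img.shape
    r_src = slice(max(0, -dr), min(H, H - dr))
    r_dst = slice(max(0, dr), min(H, H + dr))
    c_src = slice(max(0, -dc), min(W, W - dc))
    c_dst = slice(max(0, dc), min(W, W + dc))
    out[r_dst, c_dst] = img[r_src, c_src]
    return out


def _rotate(img: np.ndarray, degrees: float) -> np.ndarray:
    """Counter-clockwise rotation about the canvas centre, bilinear."""
    from skimage.transform import rotate as sk_rotate

    return sk_rotate(img, degrees, order=1, preserve_range=True)


def _scale(img: np.ndarray, factor: float) -> np.ndarray:
    """Scaling about the canvas centre, bilinear, same canvas size."""
    H, W = img.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    inv = AffineTransform(
        matrix=np.array(
            [
                [1 / factor, 0.0, cx * (1 - 1 / factor)],
                [0.0, 1 / factor, cy * (1 - 1 / factor)],
                [0.0, 0.0, 1.0],
            ]
        )
    )
    return warp(img, inv, order=1, preserve_range=True)


# ---------------------------------------------------------------------------
# sequence construction


def make_bar_sequence(
    orientation: str,
    shape: tuple[int, int] = (28, 28),
    n_frames: int = 6,
    step_px: int = 2,
    thickness: int = 3,
) -> StimulusSequence:
    """A full-width bar translating across a zero background.

    A horizontal bar moves downward by ``step_px`` per frame; the vertical
    variant is its exact transpose.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    H, W = shape if orientation == "horizontal" else shape[::-1]
    start = 2
    if start + (n_frames - 1) * step_px + thickness > H:
        raise ValueError("bar leaves the canvas; reduce step_px or n_frames")
    frames = np.zeros((n_frames, H, W))
    for i in range(n_frames):
        r = start + i * step_px
        frames[i, r : r + thickness, :] = 1.0
    if orientation == "vertical":
        frames = frames.transpose(0, 2, 1)
    return StimulusSequence(
        frames=frames,
        object_label=0 if orientation == "horizontal" else 1,
        transform="translate",
        speed=float(step_px),
    )


def make_sequence(
    base: np.ndarray,
    transform: str,
    n_frames: int = 6,
    step: float = 1.0,
    noise: bool = False,
    seed: int = 0,
    label: int = 0,
    speed: float = 1.0,
) -> StimulusSequence:
    """Frame i shows `base` transformed by ``i * step``.

    Translation uses zero-filled integer pixel shifts (rightward); rotation
    and scaling use bilinear interpolation about the canvas centre.  With
    ``noise=True`` a fresh uniform noise pattern of amplitude 0.2 is added
    per frame, only where the frame is background.
    """
    base = np.asarray(base, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    frames = []
    for i in range(n_frames):
        amount = i * step
        if transform == "translate":
            f = _shift_int(base, 0, int(round(amount)))
        elif transform == "rotate":
            f = _rotate(base, amount)
        elif transform == "scale":
            f = _scale(base, 1.0 + amount)
        else:
            raise ValueError(f"unknown transform {transform!r}")
        frames.append(np.clip(f, 0.0, 1.0))
    frames = np.stack(frames)
    if noise:
        rng = np.random.default_rng([int(seed), 77, int(label)])
        for i in range(n_frames):
            bg = frames[i] <= _BACKGROUND_EPS
            pattern = rng.uniform(0.0, 0.2, size=frames[i].shape)
            frames[i] = np.where(bg, pattern, frames[i])
        frames = np.clip(frames, 0.0, 1.0)
    return StimulusSequence(
        frames=frames,
        object_label=label,
        transform=transform,
        speed=speed,
        noise=noise,
    )


def make_dataset(
    n_classes: int,
    transform: str,
    speed: float = 1,
    noise: bool = False,
    shape: tuple[int, int] = (28, 28),
    seed: int = 0,
    n_frames: int = 6,
) -> Dataset:
    """One glyph sequence per class under a common transform.

    ``speed`` multiplies the per-frame step (speed 2 = the "fast" condition
    with smaller overlap between consecutive frames).  Translating glyphs
    are pre-shifted left so that the motion stays centred on the canvas.
    """
    if transform not in TRANSFORM_STEPS:
        raise ValueError(f"unknown transform {transform!r}")
    step = TRANSFORM_STEPS[transform] * speed
    sequences = []
    for class_id in range(n_classes):
        base = make_glyph(class_id, shape=shape, seed=seed)
        if transform == "translate":
            base = _shift_int(base, 0, -int(round((n_frames - 1) * step / 2)))
        seq = make_sequence(
            base,
            transform,
            n_frames=n_frames,
            step=step,
            noise=noise,
            seed=seed,
            label=class_id,
            speed=speed,
        )
        sequences.append(seq)
    return Dataset(sequences=sequences, n_classes=n_classes, image_shape=tuple(shape))


def apply_occluder(
    sequence: StimulusSequence, region: tuple[int, int, int, int]
) -> StimulusSequence:
    """Zero the frames inside a fixed axis-aligned rectangle.

    ``region`` is (row0, col0, row1, col1), half-open.  The returned
    sequence carries the per-frame boolean occluder mask and the original
    frames as ground truth.  An empty region leaves the frames unchanged
    with an all-false mask.
    """
    r0, c0, r1, c1 = region
    H, W = sequence.image_shape
    if not (0 <= r0 <= r1 <= H and 0 <= c0 <= c1 <= W):
        raise ValueError("occluder region must lie inside the canvas")
    mask = np.zeros(sequence.frames.shape, dtype=bool)
    mask[:, r0:r1, c0:c1] = True
    frames = sequence.frames.copy()
    frames[mask] = 0.0
    return replace(
        sequence,
        frames=frames,
        occluder_mask=mask,
        ground_truth=sequence.frames.copy(),
    )


def make_occlusion_dataset(
    n_classes: int = 10,
    shape: tuple[int, int] = (28, 28),
    seed: int = 0,
    n_frames: int = 6,
    step: float = 3.0,
    region: tuple[int, int, int, int] | None = None,
) -> Dataset:
    """Translation sequences in which each glyph slides behind a static occluder.

    The glyph starts just clear of the occluder (only frame 0 is fully
    unoccluded) and translates rightward behind it, so the occluded part of
    the object grows over the sequence.  Default occluder: the right 40% of
    the canvas.
    """
    H, W = shape
    if region is None:
        region = (0, int(0.6 * W), H, W)
    r0, c0, r1, c1 = region
    sequences = []
    for class_id in range(n_classes):
        base = make_glyph(class_id, shape=shape, seed=seed)
        # place the glyph's right edge one pixel short of the occluder
        cols = np.where(base.sum(axis=0) > 1e-9)[0]
        margin = cols.max() - (c0 - 1)
        if margin > 0:
            base = _shift_int(base, 0, -int(margin))
        seq = make_sequence(
            base, "translate", n_frames=n_frames, step=step, label=class_id
        )
        sequences.append(apply_occluder(seq, region))
    return Dataset(sequences=sequences, n_classes=n_classes, image_shape=tuple(shape))


def shuffle_frame_order(sequence: StimulusSequence, seed: int = 0) -> StimulusSequence:
    """Permute the frames of a sequence (breaks spatial, keeps set content)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sequence.n_frames)
    return replace(
        sequence,
        frames=sequence.frames[perm],
        occluder_mask=None
        if sequence.occluder_mask is None
        else sequence.occluder_mask[perm],
        ground_truth=None
        if sequence.ground_truth is None
        else sequence.ground_truth[perm],
    )


def export_frames_png(sequence: StimulusSequence, out_dir, prefix: str = "frame"):
    """Write each frame as a grayscale PNG for visual inspection."""
    from pathlib import Path

    import matplotlib.image as mpimg

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(sequence.frames):
        p = out / f"{prefix}_{i:02d}.png"
        mpimg.imsave(p, frame, cmap="gray", vmin=0.0, vmax=1.0)
        paths.append(p)
    return paths


def sequence_overlap(sequence: StimulusSequence) -> float:
    """Mean overlap of consecutive frames.

    Cosine similarity of the flattened pixelwise product terms — a
    scale-free measure of how much consecutive images share, so that the
    "fast" (larger-step) condition scores lower for every transform kind.
    """
    f = sequence.flat()
    num = np.sum(f[:-1] * f[1:], axis=1)
    den = np.linalg.norm(f[:-1], axis=1) * np.linalg.norm(f[1:], axis=1)
    return float(np.mean(num / np.maximum(den, 1e-12)))
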