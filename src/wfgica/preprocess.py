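"""Session preprocessing: registration, downsampling, masking, dF/F0, high-pass.

Raw fluorescence stacks are (optionally) block-mean downsampled, registered
to a common reference frame via a similarity transform fixed by the bregma
and lambda landmarks, restricted to the field-of-view region common to all
sessions, normalized to percent dF/F0 against the per-pixel session mean,
and high-pass filtered at 0.1 Hz (zero-phase Butterworth) to remove slow
drifts. States recorded within one session are concatenated in time and
tracked as frame segments.

Coordinates are 0-based (row, col) with origin at the top-left; frame
ranges are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .states import Segment, validate_segments


@dataclass
class RawMovie:
    """One session's fluorescence stack with landmarks and state segments."""

    frames: np.ndarray  # (T, H, W) nonnegative intensities
    fps: float
    bregma: tuple[float, float]  # (row, col)
    lambda_: tuple[float, float]
    subject_id: str = ""
    session_id: str = ""
    segments: list[Segment] | None = None
    valid: np.ndarray | None = None  # (H, W) bool, usable field of view

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.segments:
            validate_segments(self.segments, self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class DffMovie:
    """Masked, normalized pixel x time matrix in % dF/F0."""

    data: np.ndarray  # (T, P)
    mask: np.ndarray  # (H, W) bool with P true pixels
    fps: float
    segments: list[Segment]
    f0: np.ndarray  # (P,) per-pixel baseline
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("data column count does not match mask pixel count")

    @property
    def pixel_order(self) -> np.ndarray:
        """Row-major linear indices of the masked pixels (fixed linearization)."""
        return np.flatnonzero(self.mask.ravel())

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    def to_images(self) -> np.ndarray:
        """Scatter (T, P) data back to (T, H, W) with zeros off-mask."""
        t = self.data.shape[0]
        out = np.zeros((t,) + self.mask.shape, dtype=self.data.dtype)
        out[:, self.mask] = self.data
        return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _similarity_from_pairs(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform (rotation+scale+translation) mapping two source
    points onto two destination points exactly, as an inverse-map
    ``input = M @ output + off`` in (row, col) convention for ndimage."""
    zs = src[:, 1] + 1j * src[:, 0]  # col + i*row
    zd = dst[:, 1] + 1j * dst[:, 0]
    if abs(zs[1] - zs[0]) < 1e-9 or abs(zd[1] - zd[0]) < 1e-9:
        raise ValueError("coincident landmarks give a degenerate transform")
    alpha = (zd[1] - zd[0]) / (zs[1] - zs[0])
    beta = zd[0] - alpha * zs[0]
    inv_a = 1.0 / alpha
    inv_b = -beta / alpha  # input = inv_a * output + inv_b
    a, b = inv_a.real, inv_a.imag
    # col_in = a*col_out - b*row_out + re(inv_b); row_in = b*col_out + a*row_out + im(inv_b)
    matrix = np.array([[a, b], [-b, a]])  # acting on (row, col)
    offset = np.array([inv_b.imag, inv_b.real])
    return matrix, offset


def register(
    movie: RawMovie,
    ref_bregma: tuple[float, float],
    ref_lambda: tuple[float, float],
) -> RawMovie:
    """Align the session onto the reference landmark pair.

    The 4-DOF similarity transform is determined exactly by the two landmark
    pairs and applied to every frame with bilinear interpolation; the output
    landmarks equal the reference ones. Frames whose landmarks already match
    the reference are passed through untouched.
    """
    src = np.asarray([movie.bregma, movie.lambda_], dtype=float)
    dst = np.asarray([ref_bregma, ref_lambda], dtype=float)
    if np.allclose(src[0], src[1]):
        raise ValueError("bregma and lambda coincide; degenerate transform")
    if np.allclose(dst[0], dst[1]):
        raise ValueError("reference landmarks coincide; degenerate transform")
    if np.allclose(src, dst, atol=1e-9):
        return replace(movie, bregma=tuple(dst[0]), lambda_=tuple(dst[1]))

    matrix, offset = _similarity_from_pairs(src, dst)
    t, h, w = movie.frames.shape
    valid = movie.valid if movie.valid is not None else np.ones((h, w), bool)

    pure_shift = np.allclose(matrix, np.eye(2), atol=1e-12) and np.allclose(
        offset, np.round(offset), atol=1e-9
    )
    if pure_shift:
        # integer translation: exact pixel copy, no interpolation
        dy, dx = -int(round(offset[0])), -int(round(offset[1]))
        frames = _shift2d(movie.frames, dy, dx)
        warped_valid = _shift2d(valid.astype(np.float32), dy, dx) > 0.5
    else:
        full_matrix = np.eye(3)
        full_matrix[1:, 1:] = matrix
        full_offset = np.array([0.0, offset[0], offset[1]])
        frames = ndimage.affine_transform(
            movie.frames, full_matrix, offset=full_offset, order=1,
            mode="constant", cval=0.0, output=np.float32,
        )
        warped_valid = ndimage.affine_transform(
            valid.astype(np.float32), matrix, offset=offset, order=1,
            mode="constant", cval=0.0,
        ) > 0.999
    return replace(movie, frames=frames, bregma=tuple(dst[0]), lambda_=tuple(dst[1]), valid=warped_valid)


def _shift2d(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift of the last two axes with zero fill."""
    out = np.zeros_like(arr)
    h, w = arr.shape[-2:]
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[..., yd, xd] = arr[..., ys, xs]
    return out


# ---------------------------------------------------------------------------
# downsampling / masking / normalization / filtering
# ---------------------------------------------------------------------------

def downsample(movie: RawMovie, factor: int = 4) -> RawMovie:
    """Spatial block-mean downsampling; landmarks rescale by 1/factor.

    Dimensions not divisible by ``factor`` are cropped at the bottom/right.
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return movie
    t, h, w = movie.frames.shape
    hc, wc = (h // factor) * factor, (w // factor) * factor
    f = movie.frames[:, :hc, :wc].reshape(t, hc // factor, factor, wc // factor, factor)
    frames = f.mean(axis=(2, 4))
    valid = movie.valid
    if valid is not None:
        v = valid[:hc, :wc].reshape(hc // factor, factor, wc // factor, factor)
        valid = v.mean(axis=(1, 3)) > 0.999
    scale = lambda p: (p[0] / factor, p[1] / factor)  # noqa: E731
    return replace(
        movie,
        frames=frames.astype(movie.frames.dtype),
        bregma=scale(movie.bregma),
        lambda_=scale(movie.lambda_),
        valid=valid,
    )


def common_mask(valids: list[np.ndarray], base: np.ndarray | None = None) -> np.ndarray:
    """Logical AND of per-session valid regions (optionally with a base mask,
    e.g. the atlas cortex mask). Raises if the intersection is empty."""
    if not valids:
        raise ValueError("no valid-region images supplied")
    out = np.ones_like(valids[0], dtype=bool) if base is None else base.astype(bool).copy()
    for v in valids:
        out &= v.astype(bool)
    if not out.any():
        raise ValueError("common field-of-view is empty")
    return out


def compute_dff(movie: RawMovie, mask: np.ndarray) -> DffMovie:
    """Percent dF/F0 against the per-pixel mean over the whole session."""
    t = movie.frames.shape[0]
    flat = movie.frames.reshape(t, -1).take(np.flatnonzero(mask.ravel()), axis=1)
    f0 = flat.mean(axis=0, dtype=np.float64)
    if np.any(f0 <= 0):
        raise ValueError("nonpositive baseline F0 inside the mask")
    data = (100.0 * (flat - f0) / f0).astype(np.float32)
    return DffMovie(
        data=data,
        mask=mask.copy(),
        fps=movie.fps,
        segments=list(movie.segments or []),
        f0=f0.astype(np.float32),
        subject_id=movie.subject_id,
        session_id=movie.session_id,
    )


def highpass(dff: DffMovie, cutoff: float = 0.1, order: int = 4) -> DffMovie:
    """Zero-phase Butterworth high-pass per pixel (forward-backward).

    The filtered traces are re-centered so each pixel has exactly zero
    temporal mean (the filter's DC gain is zero but finite-length traces
    keep a negligible residual). No explicit low-pass is applied: the
    acquisition Nyquist frequency bounds the band from above.
    """
    if cutoff >= dff.fps / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff, btype="highpass", fs=dff.fps, output="sos")
    data = signal.sosfiltfilt(sos, dff.data.astype(np.float64), axis=0)
    data -= data.mean(axis=0, keepdims=True)
    return replace(dff, data=data.astype(np.float32))


def concatenate_states(per_state: list[DffMovie]) -> DffMovie:
    """Stack per-state dF/F movies in time, recording segment boundaries.

    All inputs must share mask, pixel order and fps, and be supplied in
    deepest-to-awake order with exactly one state each.
    """
    if not per_state:
        raise ValueError("nothing to concatenate")
    first = per_state[0]
    segs: list[Segment] = []
    offset = 0
    for m in per_state:
        if not np.array_equal(m.mask, first.mask):
            raise ValueError("masks differ between states")
        if m.fps != first.fps:
            raise ValueError("fps differs between states")
        if len(m.segments) != 1:
            raise ValueError("each input must carry exactly one state segment")
        s = m.segments[0]
        segs.append(Segment(s.state, offset, offset + m.n_frames))
        offset += m.n_frames
    validate_segments(segs)
    data = np.concatenate([m.data for m in per_state], axis=0)
    return replace(first, data=data, segments=segs)


def preprocess_session(
    raw: RawMovie,
    ref_bregma: tuple[float, float],
    ref_lambda: tuple[float, float],
    mask: np.ndarray,
    downsample_factor: int = 1,
    cutoff: float = 0.1,
) -> DffMovie:
    """Full per-session chain: downsample -> register -> dF/F0 -> high-pass."""
    m = downsample(raw, downsample_factor)
    m = register(m, ref_bregma, ref_lambda)
    return highpass(compute_dff(m, mask), cutoff=cutoff)
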