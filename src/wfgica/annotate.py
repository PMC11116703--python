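"""Component tagging: atlas macro-group assignment, artifact flags, matching.

Each IC is named by the macro area under the pixel with the largest
absolute map weight. Components whose high-weight support sits mostly on
the midline band, or whose support is strongly elongated (vessel-like),
are flagged and excluded from the occurrence statistics. Back-reconstructed
and single-session component sets are paired by rectangular assignment
maximizing total |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .atlas import SyntheticAtlas


@dataclass
class ComponentLabel:
    ic_id: int
    peak_pixel: tuple[int, int]
    macro_group: str
    retained: bool
    exclusion_reason: str = "none"  # {midline, vessel, manual, none}

    def __post_init__(self) -> None:
        if self.retained != (self.exclusion_reason == "none"):
            raise ValueError("retained flag inconsistent with exclusion reason")


@dataclass
class MatchResult:
    """Injective pairing of set A components onto set B components."""

    pairs: list[tuple[int, int, float]]  # (a_idx, b_idx, signed r)
    unmatched_a: list[int]
    total_abs_r: float

    @property
    def abs_r(self) -> np.ndarray:
        return np.array([abs(r) for _, _, r in self.pairs])

    def b_for_a(self, a_idx: int) -> int | None:
        for a, b, _ in self.pairs:
            if a == a_idx:
                return b
        return None


def locate_peak(map_vec: np.ndarray, mask: np.ndarray) -> tuple[int, int]:
    """Pixel of the largest |weight|, sign-independent; row-major tie-break."""
    if not np.all(np.isfinite(map_vec)):
        raise ValueError("non-finite map weights")
    if np.ptp(map_vec) == 0:
        raise ValueError("constant map has no peak")
    pixel_order = np.flatnonzero(mask.ravel())
    flat = pixel_order[int(np.argmax(np.abs(map_vec)))]
    return int(flat // mask.shape[1]), int(flat % mask.shape[1])


def assign_group(peak: tuple[int, int], atlas: SyntheticAtlas) -> str:
    """Macro-group name of the atlas label at the exact peak pixel."""
    return atlas.group_of(*peak)


def _top_decile_support(map_vec: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """|weight| image of the largest connected component of the top-decile
    support (zero elsewhere).

    Working on the dominant connected blob keeps the support statistics
    (midline fraction, elongation) tied to the component's main structure
    rather than to noise pixels scattered over the mask.
    """
    w = np.abs(map_vec)
    img = np.zeros(mask.shape, dtype=float)
    img[mask] = np.where(w >= np.quantile(w, 0.9), w, 0.0)
    lab = measure.label(img > 0, connectivity=2)
    if lab.max() == 0:
        return img
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return np.where(lab == np.argmax(sizes), img, 0.0)


def _elongation(support: np.ndarray) -> float:
    """Weight-based major/minor axis ratio of the support structure.

    Second spatial moments are weighted by |map weight|, so a thin
    high-weight streak scores far above an edge-clipped compact blob
    (whose weights still concentrate isotropically around its peak).
    """
    rows, cols = np.nonzero(support)
    if len(rows) < 3:
        return 1.0
    w = support[rows, cols]
    mu_r = np.average(rows, weights=w)
    mu_c = np.average(cols, weights=w)
    cov = np.empty((2, 2))
    cov[0, 0] = np.average((rows - mu_r) ** 2, weights=w)
    cov[1, 1] = np.average((cols - mu_c) ** 2, weights=w)
    cov[0, 1] = cov[1, 0] = np.average((rows - mu_r) * (cols - mu_c), weights=w)
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 1e-9:
        return np.inf
    return float(np.sqrt(ev[1] / ev[0]))


def flag_artifacts(
    maps: np.ndarray,
    mask: np.ndarray,
    atlas: SyntheticAtlas,
    midline_frac_threshold: float = 0.5,
    elongation_threshold: float = 4.0,
    manual_exclude: tuple[int, ...] = (),
) -> list[ComponentLabel]:
    """Label every component and flag midline/vessel/manual artifacts.

    A component is midline-flagged when more than ``midline_frac_threshold``
    of the largest connected blob of its top-decile |weight| pixels falls on
    the midline column band, and vessel-flagged when that blob's major/minor
    axis ratio exceeds ``elongation_threshold``. The midline criterion is
    checked first.
    """
    if not (0 < midline_frac_threshold <= 1):
        raise ValueError("midline_frac_threshold must be in (0, 1]")
    if elongation_threshold < 1:
        raise ValueError("elongation_threshold must be >= 1")
    midline_cols = np.asarray(sorted(atlas.midline_columns.tolist()))
    labels: list[ComponentLabel] = []
    for k in range(maps.shape[0]):
        peak = locate_peak(maps[k], mask)
        group = atlas.group_of(*peak)
        support = _top_decile_support(maps[k], mask)
        cols = np.nonzero(support)[1]
        reason = "none"
        if k in manual_exclude:
            reason = "manual"
        elif len(cols) and np.isin(cols, midline_cols).mean() > midline_frac_threshold:
            reason = "midline"
        elif _elongation(support) > elongation_threshold:
            reason = "vessel"
        labels.append(
            ComponentLabel(
                ic_id=k, peak_pixel=peak, macro_group=group,
                retained=(reason == "none"), exclusion_reason=reason,
            )
        )
    return labels


def match_components(set_a: np.ndarray, set_b: np.ndarray) -> MatchResult:
    """Rectangular assignment of A-components onto B-components.

    Computes the Pearson correlation matrix R over pixels and solves the
    injective assignment maximizing the total |r| (each B component used at
    most once); signed r is reported per pair.
    """
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("empty component set")
    az = set_a - set_a.mean(1, keepdims=True)
    bz = set_b - set_b.mean(1, keepdims=True)
    az /= np.maximum(np.linalg.norm(az, axis=1, keepdims=True), 1e-12)
    bz /= np.maximum(np.linalg.norm(bz, axis=1, keepdims=True), 1e-12)
    r = az @ bz.T
    row, col = linear_sum_assignment(-np.abs(r))
    pairs = [(int(a), int(b), float(r[a, b])) for a, b in zip(row, col)]
    matched_a = {a for a, _, _ in pairs}
    unmatched = [a for a in range(set_a.shape[0]) if a not in matched_a]
    return MatchResult(pairs=pairs, unmatched_a=unmatched,
                       total_abs_r=float(np.abs(r[row, col]).sum()))
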