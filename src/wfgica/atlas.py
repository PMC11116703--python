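"""Synthetic dorsal-cortex label image.

A geometric stand-in for an anatomical reference atlas: an elliptical
dorsal-cortex mask split into five bilateral macro areas (somatomotor,
somatosensory, posterior parietal, visual, retrosplenial) plus a narrow
midline band that contains the bregma and lambda landmarks. Components
are tagged by the macro area under their peak pixel, and midline-confined
components are candidates for artifact exclusion, so the atlas only needs
macro-area topology, not anatomical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MACRO_GROUPS = (
    "PosteriorParietal",
    "Retrosplenial",
    "Somatomotor",
    "Somatosensory",
    "Visual",
    "Midline",
)

# label ids: midline is 1; bilateral areas get (left, right) pairs
_LABELS = {
    1: "Midline",
    2: "Somatomotor",
    3: "Somatomotor",
    4: "Somatosensory",
    5: "Somatosensory",
    6: "PosteriorParietal",
    7: "PosteriorParietal",
    8: "Visual",
    9: "Visual",
    10: "Retrosplenial",
    11: "Retrosplenial",
}


@dataclass
class SyntheticAtlas:
    """Integer label image plus legend and stereotaxic landmarks.

    labels  : (H, W) int array, 0 outside the cortical mask.
    legend  : label id -> macro-group name.
    bregma  : (row, col) pixel coordinates on the midline.
    lambda_ : (row, col) pixel coordinates on the midline, posterior to bregma.
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    bregma: tuple[float, float] = (0.0, 0.0)
    lambda_: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean cortical mask (any nonzero label)."""
        return self.labels > 0

    @property
    def midline_columns(self) -> np.ndarray:
        """Sorted column indices covered by the midline band."""
        midline_ids = [k for k, v in self.legend.items() if v == "Midline"]
        cols = np.unique(np.nonzero(np.isin(self.labels, midline_ids))[1])
        return cols

    def group_of(self, row: int, col: int) -> str:
        """Macro-group name at an exact pixel; raises if outside all labels."""
        lab = int(self.labels[row, col])
        if lab == 0:
            raise ValueError(f"pixel ({row}, {col}) lies outside every atlas label")
        return self.legend[lab]


def make_atlas(height: int, width: int, seed: int = 0) -> SyntheticAtlas:
    """Build a bilateral synthetic atlas on an ``height x width`` grid.

    The layout is deterministic given ``seed``; the seed only jitters the
    anterior-posterior band boundaries by at most one row, which keeps the
    left/right mirror symmetry about the midline column exact.
    """
    if height < 32 or width < 32:
        raise ValueError(f"atlas must be at least 32x32, got {height}x{width}")
    rng = np.random.default_rng(seed)
    jitter = rng.integers(-1, 2, size=3)  # row-band boundary jitter, symmetric in columns

    rows = np.arange(height)[:, None].astype(float)
    cols = np.arange(width)[None, :].astype(float)
    cx = width // 2
    dc = np.abs(cols - cx)  # distance from midline column; symmetric by construction

    # elliptical dorsal-cortex mask
    ry, rx = 0.46 * height, 0.44 * width
    mask = ((rows - 0.5 * height) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0

    half = max(1, round(0.025 * width))  # midline band half-width
    midline = dc <= half

    r_mot = int(0.38 * height) + int(jitter[0])
    r_post = int(0.62 * height) + int(jitter[1])
    r_vis = int(0.74 * height) + int(jitter[2])
    medial = dc <= 0.18 * width

    labels = np.zeros((height, width), dtype=np.int32)
    right = cols > cx
    in_cortex = mask & ~midline

    def put(region: np.ndarray, left_id: int, right_id: int) -> None:
        labels[region & ~right] = left_id
        labels[region & right] = right_id

    put(in_cortex & (rows < r_mot), 2, 3)
    put(in_cortex & (rows >= r_mot) & (rows < r_post), 4, 5)
    put(in_cortex & (rows >= r_post) & medial, 10, 11)  # retrosplenial: posterior-medial
    put(in_cortex & (rows >= r_post) & (rows < r_vis) & ~medial, 6, 7)
    put(in_cortex & (rows >= r_vis) & ~medial, 8, 9)
    labels[mask & midline] = 1

    bregma = (0.20 * height, float(cx))
    lambda_ = (0.80 * height, float(cx))
    legend = {k: v for k, v in _LABELS.items() if np.any(labels == k)}
    return SyntheticAtlas(labels=labels, legend=legend, bregma=bregma, lambda_=lambda_)
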