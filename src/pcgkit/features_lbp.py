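"""Local binary pattern code maps for the texture branch of the classifier.

The variant is pinned for reproducibility: radius 1, 8 neighbors, bit
``b_k = 1`` iff ``neighbor_k >= center``, neighbors ordered clockwise from
the top-left, ``code = sum b_k 2^k``, replicate padding at the borders.
Codes are non-uniform raw values in [0, 255]. LBP is invariant to any
strictly increasing intensity transform of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tfr import SpectroImage

#: (row, col) offsets, clockwise starting at the top-left neighbor
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


@dataclass
class LBPMap:
    codes: np.ndarray  # H x W ints in [0, 255]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.min() < 0 or self.codes.max() > 255:
            raise ValueError("LBP codes must lie in [0, 255]")

    @property
    def normalized(self) -> np.ndarray:
        return self.codes.astype(np.float64) / 255.0


def to_gray(img: SpectroImage | np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance: 0.299 R + 0.587 G + 0.114 B, in [0, 1]."""
    pixels = img.pixels if isinstance(img, SpectroImage) else np.asarray(img)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    return 0.299 * pixels[..., 0] + 0.587 * pixels[..., 1] + 0.114 * pixels[..., 2]


def lbp_map(gray: np.ndarray) -> LBPMap:
    """Vectorized 8-neighbor radius-1 LBP with replicate border padding."""
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("LBP needs a 2-D image of at least 3 x 3 pixels")
    padded = np.pad(gray, 1, mode="edge")
    h, w = gray.shape
    codes = np.zeros((h, w), dtype=np.int64)
    for k, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        neigh = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        codes += (neigh >= gray).astype(np.int64) << k
    return LBPMap(codes=codes)
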