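"""Small shared numerics: periodic minimum-image arithmetic."""

from __future__ import annotations

import numpy as np


def minimum_image(displacement: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the central rectangular image.

    `displacement` has shape (..., 3).  With no box the input is returned
    unchanged.
    """
    d = np.asarray(displacement, dtype=float)
    if box is None:
        return d
    return d - np.asarray(box) * np.round(d / np.asarray(box))


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray,
                                 box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances in nm."""
    d = minimum_image(a[:, None, :] - b[None, :, :], box)
    return np.linalg.norm(d, axis=-1)
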