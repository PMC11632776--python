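"""Minimum-image helpers for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement vectors into the nearest periodic image.

    Works on any array whose last axis is the 3 Cartesian components.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between points ``a`` and ``b``."""
    d = minimum_image(np.asarray(a) - np.asarray(b), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap positions into the primary cell [0, box)."""
    return np.mod(positions, box)
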