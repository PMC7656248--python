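"""Minimum-image distances in orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Displacement b - a wrapped to the nearest periodic image.

    Broadcasts over leading axes; ``box`` holds orthorhombic edge lengths
    along the last axis.
    """
    d = np.asarray(b, float) - np.asarray(a, float)
    box = np.asarray(box, float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Euclidean minimum-image distance between positions a and b."""
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)
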