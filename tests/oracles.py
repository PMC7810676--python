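"""Independent brute-force oracles used by the tests.

These deliberately avoid scipy.ndimage and the package's own code paths
so they can serve as cross-checks.
"""

from __future__ import annotations

import numpy as np


def runs_of(mask: np.ndarray) -> list:
    """Half-open (start, end) runs of True in a boolean array."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def brute_force_morphology(
    mask: np.ndarray, erosion_samples: int, dilation_per_side: int
) -> list:
    """Erode runs shorter than ``erosion_samples``, then widen survivors
    by ``dilation_per_side`` on each side, merging overlaps and
    discarding runs that touch either edge.  Returns (start, end) pairs.

    Erosion with a centred flat structuring element of width w shortens
    a run of length L to L - (w - 1); dilation with width 2d+1 restores
    d on each side.
    """
    n = len(mask)
    eroded = []
    for s, e in runs_of(mask):
        if e - s >= erosion_samples:
            k = (erosion_samples - 1) // 2
            eroded.append((s + k, e - k))
    dilated = [
        (max(s - dilation_per_side, 0), min(e + dilation_per_side, n))
        for s, e in eroded
    ]
    merged: list = []
    for s, e in sorted(dilated):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if s > 0 and e < n]
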