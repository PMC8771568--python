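"""Whole-volume Pearson colocalization between two fluorescence channels.

The coefficient is the sample Pearson correlation over all voxels of the
volume (2-D or 3-D), treating both channels as real-valued: |r| = 1 means a
perfect linear relationship, r near 0 no linear relationship. No intensity
threshold or automated masking is applied — every voxel counts — but an
optional boolean inclusion mask can exclude, e.g., zero-filled registration
borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    n_voxels: int


def pearson_coloc(ch1: np.ndarray, ch2: np.ndarray,
                  mask: np.ndarray | None = None) -> ColocResult:
    """Sample Pearson correlation of two same-shape channels over all
    included voxels.

    Raises when fewer than two voxels are included or when either channel is
    constant (zero variance makes the coefficient undefined).
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the channels")
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 included voxels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel: Pearson coefficient undefined "
                         "(zero variance)")
    r = stats.pearsonr(a, b).statistic
    return ColocResult(pearson_r=float(r), n_voxels=int(a.size))
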