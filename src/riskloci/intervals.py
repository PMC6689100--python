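"""Small 0-based half-open interval utilities used across stages."""

from __future__ import annotations

import numpy as np


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or abutting intervals; returns sorted (k, 2)."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.shape[0] == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def overlaps(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean per interval of ``a``: does it intersect any interval of ``b``?"""
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros(a.shape[0], dtype=bool)
    # half-open intersection: a.start < b.end and b.start < a.end
    return ((a[:, 0][:, None] < b[:, 1][None, :]) & (b[:, 0][None, :] < a[:, 1][:, None])).any(axis=1)


def contains_points(intervals: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Boolean per point: does it fall inside any interval?"""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    pts = np.asarray(points, dtype=np.int64)
    if iv.shape[0] == 0:
        return np.zeros(pts.shape, dtype=bool)
    return ((pts[..., None] >= iv[:, 0]) & (pts[..., None] < iv[:, 1])).any(axis=-1)
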