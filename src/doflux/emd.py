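"""Empirical mode decomposition by envelope sifting.

EMD splits a signal into intrinsic mode functions (IMFs) — locally
zero-mean oscillations obtained by repeatedly subtracting the mean of the
cubic-spline envelopes through the local maxima and minima — plus a
non-oscillatory residue.  The decomposition is exact by construction:
sum(IMFs) + residue == input.

Conventions here: envelopes use mirrored-extrema boundary extension; each
IMF's sifting stops once a Cauchy-type criterion sum(m^2)/sum(h^2) <
sd_thresh (default 0.2) is met AND the candidate has satisfied the IMF
zero-crossing property (|#extrema - #zero-crossings| <= 1) for ``s_number``
consecutive iterations, capped at ``max_sift`` iterations.  The energy-only
criterion alone stops too early when a strong oscillation remains in the
candidate (its power dominates the denominator), which mixes a tidal tone
across neighbouring modes; the zero-crossing streak is the standard guard.
IMFs are returned ordered slow -> fast (the reverse of extraction order),
so that dropping the last ``m`` entries removes the fastest modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["IMFSet", "emd"]


@dataclass
class IMFSet:
    """Ordered IMFs (slow -> fast) plus the residue of an EMD."""

    imfs: List[np.ndarray]
    residue: np.ndarray

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out = out + imf
        return out


def _local_extrema(y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    d = np.diff(y)
    # collapse flat steps by treating zero slopes as the preceding sign
    s = np.sign(d)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    turn = np.diff(s)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _mirrored_envelope(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, extended by mirroring.

    Up to two extrema are reflected across each end of the record so the
    spline brackets [0, n-1] without extrapolation artefacts.
    """
    left_mask = idx > 0
    left_t = -idx[left_mask][:2][::-1]
    left_v = val[left_mask][:2][::-1]
    right_mask = idx < n - 1
    right_t = 2 * (n - 1) - idx[right_mask][-2:][::-1]
    right_v = val[right_mask][-2:][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([left_v, val, right_v])
    # guard against coincident knots after mirroring
    t, keep = np.unique(t, return_index=True)
    v = v[keep]
    if t.size < 2:
        return np.full(n, v[0] if v.size else 0.0)
    if t.size < 4:
        return np.interp(np.arange(n), t, v)
    return CubicSpline(t, v)(np.arange(n))


def _zero_crossings(y: np.ndarray) -> int:
    s = np.sign(y)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def _sift(h: np.ndarray, sd_thresh: float, max_sift: int, s_number: int) -> np.ndarray:
    """Extract one IMF from ``h`` by iterative envelope-mean subtraction."""
    n = h.size
    streak = 0
    for _ in range(max_sift):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        upper = _mirrored_envelope(maxima, h[maxima], n)
        lower = _mirrored_envelope(minima, h[minima], n)
        m = 0.5 * (upper + lower)
        denom = float(np.sum(h * h))
        if denom == 0.0:
            break
        sd = float(np.sum(m * m)) / denom
        h = h - m
        nxt_max, nxt_min = _local_extrema(h)
        if abs(nxt_max.size + nxt_min.size - _zero_crossings(h)) <= 1:
            streak += 1
        else:
            streak = 0
        if sd < sd_thresh and streak >= s_number:
            break
    return h


def emd(
    y,
    sd_thresh: float = 0.2,
    max_sift: int = 50,
    max_imfs: int = 16,
    s_number: int = 2,
) -> IMFSet:
    """Decompose ``y`` into IMFs (ordered slow -> fast) plus a residue.

    A signal with fewer than two interior maxima or minima (e.g. a monotone
    trend) yields zero IMFs with residue equal to the input.  Requires at
    least 8 finite samples.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("emd expects a one-dimensional series")
    if y.size < 8:
        raise ValueError(f"series too short for EMD ({y.size} < 8 samples)")
    if not np.all(np.isfinite(y)):
        raise ValueError("emd requires finite values")

    residue = y.copy()
    imfs_fast_to_slow: List[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        imf = _sift(residue, sd_thresh, max_sift, s_number)
        if not np.any(imf):
            break
        imfs_fast_to_slow.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs_fast_to_slow[::-1], residue=residue)
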