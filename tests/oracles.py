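"""Independent brute-force oracles for the peak primitives.

These re-derive local maxima, topographic prominence and width by exhaustive
search (O(n^2) overall across peaks) rather than by the package's outward
scans, so they can certify the implementation exactly on small signals.
"""
from __future__ import annotations

import numpy as np


def local_maxima_oracle(y) -> list[int]:
    """All interior local maxima by exhaustive plateau enumeration.

    For every maximal run of equal values strictly above both neighbours,
    the (lower) middle index is reported.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    out: list[int] = []
    a = 0
    while a < n:
        b = a
        while b + 1 < n and y[b + 1] == y[a]:
            b += 1
        if a > 0 and b < n - 1 and y[a - 1] < y[a] and y[b + 1] < y[a]:
            out.append((a + b) // 2)
        a = b + 1
    return out


def prominence_oracle(y, i: int) -> tuple[float, int, int]:
    """Topographic prominence by exhaustive contour search.

    The left stretch runs from the nearest strictly-higher sample left of
    the apex (exclusive; or the signal start) up to the apex; its lowest
    value is the left minimum and the base index is the tied minimum closest
    to the apex. Symmetrically on the right. Prominence is apex height minus
    the higher of the two minima.
    """
    y = np.asarray(y, dtype=float)
    n = y.size

    higher_left = [j for j in range(i) if y[j] > y[i]]
    lo = (max(higher_left) + 1) if higher_left else 0
    left_stretch = np.arange(lo, i)
    left_min = y[left_stretch].min() if left_stretch.size else y[i]
    left_ties = [int(j) for j in left_stretch if y[j] == left_min]
    left_base = max(left_ties) if left_ties else i

    higher_right = [j for j in range(i + 1, n) if y[j] > y[i]]
    hi = (min(higher_right) - 1) if higher_right else n - 1
    right_stretch = np.arange(i + 1, hi + 1)
    right_min = y[right_stretch].min() if right_stretch.size else y[i]
    right_ties = [int(j) for j in right_stretch if y[j] == right_min]
    right_base = min(right_ties) if right_ties else i

    return float(y[i] - max(left_min, right_min)), left_base, right_base


def width_oracle(
    y, i: int, prominence: float, left_base: int, right_base: int, rel_height: float = 0.5
) -> tuple[float, float, float]:
    """Width at ``y[i] - rel_height * prominence`` by vectorised crossing search.

    On each side, the crossing nearest the apex where the signal falls to or
    below the evaluation height is linearly interpolated; without one the
    side is clamped at its prominence base.
    """
    y = np.asarray(y, dtype=float)
    eval_h = y[i] - rel_height * prominence

    at_or_below = np.nonzero(y[left_base:i] <= eval_h)[0]
    j = left_base + int(at_or_below.max()) if at_or_below.size else left_base
    left_ip = float(j)
    if y[j] < eval_h:
        left_ip = j + (eval_h - y[j]) / (y[j + 1] - y[j])

    at_or_below = np.nonzero(y[i + 1 : right_base + 1] <= eval_h)[0]
    j = i + 1 + int(at_or_below.min()) if at_or_below.size else right_base
    right_ip = float(j)
    if y[j] < eval_h:
        right_ip = j - (eval_h - y[j]) / (y[j - 1] - y[j])

    return right_ip - left_ip, left_ip, right_ip


def gaussian_area(height: float, sigma: float) -> float:
    """Closed-form integral of a unit-max Gaussian peak scaled to ``height``."""
    return height * sigma * np.sqrt(2.0 * np.pi)
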