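"""Independent brute-force peak-detection oracle.

A deliberately naive reimplementation of the detection contract using
plain loops and exhaustive scans, kept free of any pulsetrace imports so
it can serve as an independent cross-check of the package's detector.
"""

from __future__ import annotations


def brute_candidates(x) -> list[int]:
    """All plateau-collapsed strict local maxima, by exhaustive run scan."""
    n = len(x)
    out = []
    start = 0
    while start < n:
        end = start
        while end + 1 < n and x[end + 1] == x[start]:
            end += 1
        higher_left = start > 0 and x[start - 1] < x[start]
        higher_right = end < n - 1 and x[end + 1] < x[start]
        if higher_left and higher_right:
            out.append((start + end) // 2)
        start = end + 1
    return out


def brute_prominence(x, apex) -> tuple[float, int, int]:
    """Prominence by exhaustive search for the nearest higher samples."""
    n = len(x)
    left_stop = -1
    for i in range(apex - 1, -1, -1):
        if x[i] > x[apex]:
            left_stop = i
            break
    right_stop = n
    for i in range(apex + 1, n):
        if x[i] > x[apex]:
            right_stop = i
            break
    left_interval = list(range(left_stop + 1, apex))
    right_interval = list(range(apex + 1, right_stop))
    # empty interval (plateau shoulder) contributes the apex value itself
    left_min = min((x[i] for i in left_interval), default=x[apex])
    right_min = min((x[i] for i in right_interval), default=x[apex])
    left_base = apex
    for i in left_interval:
        if x[i] == left_min:
            left_base = i
            break
    right_base = apex
    for i in right_interval:
        if x[i] == right_min:
            right_base = i
            break
    prom = x[apex] - max(left_min, right_min)
    return prom, left_base, right_base


def brute_width(x, apex, prom, left_base, right_base):
    """Half-prominence width by scanning each adjacent pair outward."""
    ref = x[apex] - prom / 2.0
    left_cross = float(left_base)
    found_left = False
    for i in range(apex - 1, left_base - 1, -1):
        if x[i] <= ref:
            if x[i + 1] == x[i]:
                left_cross = float(i)
            else:
                left_cross = i + (ref - x[i]) / (x[i + 1] - x[i])
            found_left = True
            break
    right_cross = float(right_base)
    found_right = False
    for i in range(apex + 1, right_base + 1):
        if x[i] <= ref:
            if x[i - 1] == x[i]:
                right_cross = float(i)
            else:
                right_cross = (i - 1) + (x[i - 1] - ref) / (x[i - 1] - x[i])
            found_right = True
            break
    return right_cross - left_cross, found_left and found_right


def brute_detect(
    x,
    min_height: float,
    min_prominence: float,
    min_separation: float,
    min_width: float,
    max_width: float,
) -> list[int]:
    """Apex indices surviving every constraint, by exhaustive checking."""
    survivors = []
    for apex in brute_candidates(x):
        if x[apex] < min_height:
            continue
        prom, lb, rb = brute_prominence(x, apex)
        if prom < min_prominence:
            continue
        width, _found = brute_width(x, apex, prom, lb, rb)
        if width < min_width or width > max_width:
            continue
        survivors.append((apex, prom))
    ranked = sorted(survivors, key=lambda s: (-x[s[0]], -s[1], s[0]))
    kept: list[int] = []
    for apex, _prom in ranked:
        ok = True
        for other in kept:
            if abs(apex - other) < min_separation:
                ok = False
                break
        if ok:
            kept.append(apex)
    return sorted(kept)
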