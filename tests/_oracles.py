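"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit Python loops over pixels,
runs and thresholds) and shares no code with the package internals.
"""

import numpy as np

OFFSETS = {"H": (0, 1), "V": (1, 0), "Z": (-1, 1), "N": (-1, -1)}


def naive_glcm(levels, mask, direction, distance, n_levels):
    """Co-occurrence matrix by explicit pair enumeration on one slice."""
    dr, dc = (d * distance for d in OFFSETS[direction])
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
    sym = counts + counts.T
    total = sym.sum()
    return None if total == 0 else sym / total


def naive_runs(levels, mask, direction):
    """Sorted multiset of (level, run length) by explicit line walking."""
    h, w = levels.shape
    if direction == "H":
        starts = [(r, 0) for r in range(h)]
        step = (0, 1)
    elif direction == "V":
        starts = [(0, c) for c in range(w)]
        step = (1, 0)
    elif direction == "N":  # along (+1, +1)
        starts = [(r, 0) for r in range(h)] + [(0, c) for c in range(1, w)]
        step = (1, 1)
    elif direction == "Z":  # along (-1, +1): start at bottom edge / left edge
        starts = [(r, 0) for r in range(h)] + [(h - 1, c) for c in range(1, w)]
        step = (-1, 1)
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        cur_level, cur_len = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                if levels[r, c] == cur_level:
                    cur_len += 1
                else:
                    if cur_level is not None:
                        runs.append((int(cur_level), cur_len))
                    cur_level, cur_len = levels[r, c], 1
            else:
                if cur_level is not None:
                    runs.append((int(cur_level), cur_len))
                cur_level, cur_len = None, 0
            r, c = r + step[0], c + step[1]
        if cur_level is not None:
            runs.append((int(cur_level), cur_len))
    return sorted(runs)


def naive_rlm_features(runs, n_voxels, n_levels):
    """Run-length statistics from an explicit run list."""
    r_total = len(runs)
    per_level = {}
    per_length = {}
    shrt = lng = 0.0
    for level, length in runs:
        shrt += 1.0 / length**2
        lng += float(length**2)
        per_level[level] = per_level.get(level, 0) + 1
        per_length[length] = per_length.get(length, 0) + 1
    return {
        "ShrtREmp": shrt / r_total,
        "LngREmph": lng / r_total,
        "GLevNonU": sum(v**2 for v in per_level.values()) / r_total,
        "RLNonUni": sum(v**2 for v in per_length.values()) / r_total,
        "Fraction": r_total / n_voxels,
    }


def naive_poe(values, labels):
    """Minimum error of any single-threshold rule, by full enumeration."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = values.size
    vs = np.unique(values)
    thresholds = [vs[0] - 1.0, vs[-1] + 1.0]
    thresholds += [(a + b) / 2.0 for a, b in zip(vs[:-1], vs[1:])]
    best = n
    for t in thresholds:
        pred_high = values > t
        for pred in (pred_high, ~pred_high):
            best = min(best, int((pred != labels).sum()))
    return best / n
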