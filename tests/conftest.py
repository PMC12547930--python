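"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (python loops,
flood fill, exhaustive enumeration) and independent of the package's
vectorised kernels; they are the reference the kernels are tested
against.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_mask():
    """Filled disc radius 12 at the centre of a 64x64 grid."""
    rr, cc = np.mgrid[0:64, 0:64]
    return (rr - 32) ** 2 + (cc - 32) ** 2 <= 12**2


# ---------------------------------------------------------------------------
# texture-matrix oracles (exhaustive enumeration)
# ---------------------------------------------------------------------------

GLCM_DIRS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
NEIGH8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def oracle_glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric normalised GLCM per direction by explicit pair listing."""
    h, w = levels.shape
    out = np.zeros((4, ng, ng))
    for d, (dr, dc) in enumerate(GLCM_DIRS):
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    a, b = levels[r, c] - 1, levels[r2, c2] - 1
                    out[d, a, b] += 1
                    out[d, b, a] += 1
        if out[d].sum():
            out[d] /= out[d].sum()
    return out


def _oracle_lines(h: int, w: int, direction: int) -> list[list[tuple[int, int]]]:
    if direction == 0:  # rows
        return [[(r, c) for c in range(w)] for r in range(h)]
    if direction == 2:  # cols
        return [[(r, c) for r in range(h)] for c in range(w)]
    lines = []
    if direction == 1:  # 45 degrees: anti-diagonals walked in (-1, +1)
        for s in range(h + w - 1):
            line = [(r, c) for r in range(h - 1, -1, -1) for c in range(w)
                    if r + c == s]
            lines.append(line)
        return lines
    # 135 degrees: main diagonals walked in (-1, -1)
    for k in range(-(h - 1), w):
        line = [(r, c) for r in range(h - 1, -1, -1) for c in range(w)
                if c - r == k]
        lines.append(line)
    return lines


def oracle_glrlm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Run-length counts per direction by walking each line."""
    h, w = levels.shape
    jmax = max(h, w)
    out = np.zeros((4, ng, jmax))
    for d in range(4):
        for line in _oracle_lines(h, w, d):
            vals = [levels[r, c] for r, c in line]
            k = 0
            while k < len(vals):
                j = k
                while j + 1 < len(vals) and vals[j + 1] == vals[k]:
                    j += 1
                out[d, vals[k] - 1, (j - k + 1) - 1] += 1
                k = j + 1
    return out


def oracle_zones(levels: np.ndarray, ng: int):
    """8-connected constant-level zones via flood fill.

    Returns a list of (level, size, min border distance) triples.
    """
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0]:
                continue
            g = levels[r0, c0]
            stack = [(r0, c0)]
            seen[r0, c0] = True
            cells = []
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in NEIGH8:
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]
                            and levels[r2, c2] == g):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            dist = min(
                min(r, h - 1 - r, c, w - 1 - c) + 1 for r, c in cells
            )
            zones.append((int(g), len(cells), dist))
    return zones


def oracle_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    h, w = levels.shape
    out = np.zeros((ng, h * w))
    for g, size, _ in oracle_zones(levels, ng):
        out[g - 1, size - 1] += 1
    return out


def oracle_gldzm(levels: np.ndarray, ng: int) -> np.ndarray:
    h, w = levels.shape
    jd = (min(h, w) + 1) // 2
    out = np.zeros((ng, jd))
    for g, _, dist in oracle_zones(levels, ng):
        out[g - 1, dist - 1] += 1
    return out


def oracle_ngtdm(levels: np.ndarray, ng: int):
    h, w = levels.shape
    ni = np.zeros(ng)
    si = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            neigh = [
                levels[r + dr, c + dc]
                for dr, dc in NEIGH8
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            g = levels[r, c]
            ni[g - 1] += 1
            si[g - 1] += abs(g - float(np.mean(neigh)))
    return ni, si


def oracle_ngldm(levels: np.ndarray, ng: int) -> np.ndarray:
    h, w = levels.shape
    out = np.zeros((ng, 9))
    for r in range(h):
        for c in range(w):
            dep = 1 + sum(
                1
                for dr, dc in NEIGH8
                if 0 <= r + dr < h and 0 <= c + dc < w
                and levels[r + dr, c + dc] == levels[r, c]
            )
            out[levels[r, c] - 1, dep - 1] += 1
    return out


# ---------------------------------------------------------------------------
# evaluation oracles
# ---------------------------------------------------------------------------


def oracle_auc_paircount(labels, scores) -> float:
    """AUC by exhaustive positive/negative pair counting; ties count 0.5."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def oracle_youden(scores, labels):
    """All-cut-points Youden search (positive iff score >= threshold)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    best = None
    for t in sorted(set(s)):
        pred = s >= t
        sen = (pred & (y == 1)).sum() / (y == 1).sum()
        spe = (~pred & (y == 0)).sum() / (y == 0).sum()
        j = sen + spe - 1
        if best is None or j > best[3]:
            best = (t, sen, spe, j)
    return best[:3]


def oracle_point_in_convex(vertices: np.ndarray, point) -> bool:
    """Half-plane membership test for a convex polygon (CCW or CW),
    inclusive of the boundary."""
    v = np.asarray(vertices, dtype=float)
    p = np.asarray(point, dtype=float)
    signs = []
    for k in range(len(v)):
        a, b = v[k], v[(k + 1) % len(v)]
        cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        signs.append(cross)
    signs = np.asarray(signs)
    eps = 1e-9
    return bool((signs >= -eps).all() or (signs <= eps).all())
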