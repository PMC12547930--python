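"""Texture and intensity features for 8x8 rectal-wall subimages.

The extractor computes the 118-feature catalogue (see
:mod:`rwradiomics.catalogue`) per subimage.  All texture families are
computed in 2D on a per-subimage grey-level discretisation:

* GLCM: distance 1, four directions (0, 45, 90, 135 degrees),
  symmetric co-occurrences, one matrix per direction; features are
  computed per direction and averaged.
* GLRLM: the same four directions, feature-level averaging.
* GLSZM: zones are 8-connected components of constant level.
* GLDZM: zones as GLSZM; the zone distance is the minimum chessboard
  distance of any zone pixel to the outside of the subimage window
  (border pixels have distance 1).
* NGTDM / NGLDM: 8-neighbourhoods; averages use the neighbours that
  exist inside the window (no padding); the NGLDM coarseness parameter
  is alpha = 0 and the dependence count of a pixel is 1 plus the number
  of neighbours sharing its level.

First-order statistics are computed on the raw intensities, except for
mode, histogram entropy, uniformity and the four histogram-gradient
features, which use the discretised histogram.

Degenerate-input conventions (constant subimages) are fixed so that no
feature is ever non-finite: skewness, kurtosis, coefficient of
variation, GLCM correlation and both information-correlation features
are 0; NGTDM coarseness saturates at 1e6.

Everything is vectorised over a leading batch axis; the single-subimage
operations are thin wrappers around the batch kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .catalogue import (
    FEATURE_CODES,
    FOS_NAMES,
    GLCM_NAMES,
    GLDZM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    N_FEATURES,
    NGLDM_NAMES,
    NGTDM_NAMES,
)

# offsets for 0, 45, 90 and 135 degrees at distance 1, in (row, col)
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

NEIGHBOUR_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

COARSENESS_CAP = 1.0e6


@dataclass(frozen=True)
class DiscretisedSubimage:
    """Integer grey levels in 1..ng for one subimage."""

    levels: np.ndarray
    ng: int

    def __post_init__(self):
        lv = np.asarray(self.levels)
        if lv.ndim != 2 or lv.size == 0:
            raise ValueError("levels must be a non-empty 2D grid")
        if lv.min() < 1 or lv.max() > self.ng:
            raise ValueError("levels out of range 1..ng")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 118-feature vector with the catalogue's fixed naming."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {v.shape}")

    @property
    def names(self) -> list[str]:
        return list(FEATURE_CODES)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_CODES, np.asarray(self.values, dtype=float)))


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * np.log2(p[mask])
    return out


@lru_cache(maxsize=8)
def _nlog2n_table(size: int) -> np.ndarray:
    n = np.arange(size, dtype=float)
    out = np.zeros(size)
    out[1:] = n[1:] * np.log2(n[1:])
    return out


def _count_entropy_sum(counts: np.ndarray) -> np.ndarray:
    """sum of c*log2(c) per row of an integer count matrix (LUT-based)."""
    top = int(counts.max()) if counts.size else 0
    lut = _nlog2n_table(1 << max(top, 1).bit_length())
    return lut[counts].sum(axis=1)


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------


def discretise_batch(pixels: np.ndarray, ng: int) -> np.ndarray:
    """Fixed-bin-number discretisation over each subimage's own min-max range.

    ``pixels`` has shape (n, h, w); returns int levels in 1..ng with the
    same shape.  A constant subimage maps to level 1 everywhere.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    x = np.asarray(pixels, dtype=float)
    mn = x.min(axis=(-2, -1), keepdims=True)
    mx = x.max(axis=(-2, -1), keepdims=True)
    span = mx - mn
    safe = np.where(span > 0, span, 1.0)
    lv = np.floor(ng * (x - mn) / safe).astype(np.int64) + 1
    np.minimum(lv, ng, out=lv)
    return lv


def discretise(sub, ng: int = 8) -> DiscretisedSubimage:
    """Discretise one subimage (array or object with ``pixels``)."""
    pixels = getattr(sub, "pixels", sub)
    lv = discretise_batch(np.asarray(pixels, dtype=float)[None], ng)[0]
    return DiscretisedSubimage(levels=lv, ng=ng)


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------


def fos_features_batch(raw: np.ndarray, levels: np.ndarray, ng: int) -> np.ndarray:
    """23 first-order features; returns shape (n, 23)."""
    n = raw.shape[0]
    x = raw.reshape(n, -1).astype(float)
    npix = x.shape[1]

    mean = x.mean(axis=1)
    var = x.var(axis=1)  # population variance
    sd = np.sqrt(var)
    dev = x - mean[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        m3 = (dev**3).mean(axis=1)
        m4 = (dev**4).mean(axis=1)
        skew = np.where(var > 0, m3 / np.where(sd > 0, sd, 1) ** 3, 0.0)
        kurt = np.where(var > 0, m4 / np.where(var > 0, var, 1) ** 2 - 3.0, 0.0)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90], axis=1)
    mn = x.min(axis=1)
    mx = x.max(axis=1)
    iqr = p75 - p25
    rng_ = mx - mn

    mad = np.abs(dev).mean(axis=1)
    # robust MAD: mean absolute deviation of values within [p10, p90]
    inlier = (x >= p10[:, None]) & (x <= p90[:, None])
    cnt = inlier.sum(axis=1)
    rmean = np.where(cnt > 0, (x * inlier).sum(axis=1) / np.maximum(cnt, 1), mean)
    rmad = (np.abs(x - rmean[:, None]) * inlier).sum(axis=1) / np.maximum(cnt, 1)
    medad = np.abs(x - p50[:, None]).mean(axis=1)

    cov = np.where((var > 0) & (mean != 0), sd / np.where(mean != 0, mean, 1), 0.0)
    qsum = p75 + p25
    qcd = np.where(qsum != 0, iqr / np.where(qsum != 0, qsum, 1), 0.0)

    # discretised histogram
    code = np.arange(n)[:, None] * ng + (levels.reshape(n, -1) - 1)
    hist = np.bincount(code.ravel(), minlength=n * ng).reshape(n, ng).astype(float)
    p = hist / npix
    mode = hist.argmax(axis=1) + 1.0  # ties -> lowest level
    entropy = -_xlog2x(p).sum(axis=1)
    uniformity = (p**2).sum(axis=1)

    grad = np.zeros_like(hist)
    if ng >= 2:
        grad[:, 0] = hist[:, 1] - hist[:, 0]
        grad[:, -1] = hist[:, -1] - hist[:, -2]
        if ng > 2:
            grad[:, 1:-1] = (hist[:, 2:] - hist[:, :-2]) / 2.0
    maxgrad = grad.max(axis=1)
    maxgrad_lv = grad.argmax(axis=1) + 1.0
    mingrad = grad.min(axis=1)
    mingrad_lv = grad.argmin(axis=1) + 1.0

    return np.stack(
        [
            mean, var, skew, kurt, p50, mn, p10, p90, mx, mode, iqr, rng_,
            mad, rmad, medad, cov, qcd, entropy, uniformity,
            maxgrad, maxgrad_lv, mingrad, mingrad_lv,
        ],
        axis=1,
    )


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_counts_batch(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric co-occurrence counts per direction; shape (n, 4, ng, ng)."""
    n, h, w = levels.shape
    out = np.empty((n, 4, ng, ng), dtype=np.int64)
    base = np.arange(n) * (ng * ng)
    for d, (dr, dc) in enumerate(GLCM_OFFSETS):
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = levels[:, r0:r1, c0:c1] - 1
        b = levels[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc] - 1
        code = base[:, None, None] + a * ng + b
        cnt = np.bincount(code.ravel(), minlength=n * ng * ng)
        cnt = cnt.reshape(n, ng, ng)
        out[:, d] = cnt + cnt.transpose(0, 2, 1)
    return out


def glcm_matrices_batch(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric, per-direction-normalised GLCMs; shape (n, 4, ng, ng)."""
    cnt = glcm_counts_batch(levels, ng).astype(float)
    total = cnt.sum(axis=(2, 3), keepdims=True)
    return cnt / np.where(total > 0, total, 1.0)


@lru_cache(maxsize=8)
def _glcm_weights(ng: int):
    """Per-cell weight columns for the GLCM features linear in the matrix,
    plus one-hot aggregators for the difference / sum / row marginals."""
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    absdiff = np.abs(ii - jj)
    s = ii + jj
    inv_d2 = np.zeros_like(absdiff)
    off = absdiff > 0
    inv_d2[off] = 1.0 / absdiff[off] ** 2
    cols = [
        ii,                                  # joint average (symmetric)
        ii**2,                               # second moment -> joint variance
        (ii - jj) ** 2,                      # contrast
        absdiff,                             # dissimilarity
        1.0 / (1.0 + absdiff),               # inverse difference
        1.0 / (1.0 + absdiff / ng),          # normalised
        1.0 / (1.0 + (ii - jj) ** 2),        # inverse difference moment
        1.0 / (1.0 + (ii - jj) ** 2 / ng**2),
        inv_d2,                              # inverse variance
        ii * jj,                             # autocorrelation
        s, s**2, s**3, s**4,                 # sum powers for the cluster family
    ]
    W = np.stack([c.ravel() for c in cols], axis=1)
    D = np.stack([(absdiff == k).ravel() for k in range(ng)], axis=1)
    S = np.stack([(s == k).ravel() for k in range(2, 2 * ng + 1)], axis=1)
    R = np.kron(np.eye(ng), np.ones((ng, 1)))
    return W, D, S, R


def _glcm_assemble(
    lin: np.ndarray,
    joint_max: np.ndarray,
    asm: np.ndarray,
    joint_entropy: np.ndarray,
    p_diff: np.ndarray,
    de: np.ndarray,
    p_sum: np.ndarray,
    se: np.ndarray,
    hx: np.ndarray,
    ng: int,
) -> np.ndarray:
    (mu, i2p, contrast, dissim, inv_diff, inv_diff_n, idm, idmn, inv_var,
     autocorr, s1, s2, s3, s4) = lin.T
    sig2 = i2p - mu**2
    kd = np.arange(ng, dtype=float)
    da = p_diff @ kd
    dv = (p_diff * (kd[None, :] - da[:, None]) ** 2).sum(axis=1)
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    sa = s1
    sv = (p_sum * (ks[None, :] - sa[:, None]) ** 2).sum(axis=1)
    corr = np.where(sig2 > 0, (autocorr - mu**2) / np.where(sig2 > 0, sig2, 1), 0.0)
    clus_t = s2 - 4 * mu * s1 + 4 * mu**2
    clus_s = s3 - 6 * mu * s2 + 12 * mu**2 * s1 - 8 * mu**3
    clus_p = s4 - 8 * mu * s3 + 24 * mu**2 * s2 - 32 * mu**3 * s1 + 16 * mu**4
    # symmetric matrix: the product-marginal cross entropies HXY1 and HXY2
    # both reduce to twice the marginal entropy
    ic1 = np.where(hx > 0, (joint_entropy - 2 * hx) / np.where(hx > 0, hx, 1), 0.0)
    ic2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (2 * hx - joint_entropy)), 0.0, None))
    ic2 = np.where(hx > 0, ic2, 0.0)
    return np.stack(
        [
            joint_max, mu, sig2, joint_entropy, da, dv, de, sa, sv, se, asm,
            contrast, dissim, inv_diff, inv_diff_n, idm, idmn, inv_var, corr,
            autocorr, clus_t, clus_s, clus_p, ic1, ic2,
        ],
        axis=1,
    )


def glcm_features_from_matrix(P: np.ndarray) -> np.ndarray:
    """25 GLCM features from normalised symmetric matrices.

    ``P`` has shape (..., ng, ng); returns shape (..., 25).  Callers with
    per-direction matrices average over the direction axis afterwards.
    """
    P = np.asarray(P, dtype=float)
    ng = P.shape[-1]
    lead = P.shape[:-2]
    F = P.reshape(-1, ng * ng)
    W, D, S, R = _glcm_weights(ng)
    lin = F @ W
    p_diff = F @ D
    p_sum = F @ S
    px = F @ R
    out = _glcm_assemble(
        lin,
        F.max(axis=1),
        (F * F).sum(axis=1),
        -_xlog2x(F).sum(axis=1),
        p_diff,
        -_xlog2x(p_diff).sum(axis=1),
        p_sum,
        -_xlog2x(p_sum).sum(axis=1),
        -_xlog2x(px).sum(axis=1),
        ng,
    )
    return out.reshape(*lead, 25)


def _glcm_features_counts(C: np.ndarray) -> np.ndarray:
    """Fast path on integer count matrices (..., ng, ng); LUT entropies."""
    ng = C.shape[-1]
    lead = C.shape[:-2]
    F = C.reshape(-1, ng * ng)
    T = F.sum(axis=1)
    T_safe = np.where(T > 0, T, 1).astype(float)
    log2T = np.log2(T_safe)
    W, D, S, R = _glcm_weights(ng)
    lin = (F @ W) / T_safe[:, None]
    cd = F @ D.astype(np.int64)
    cs = F @ S.astype(np.int64)
    cx = F @ R.astype(np.int64)
    ent = lambda cnts: log2T - _count_entropy_sum(cnts) / T_safe  # noqa: E731
    out = _glcm_assemble(
        lin,
        F.max(axis=1) / T_safe,
        (F.astype(float) ** 2).sum(axis=1) / T_safe**2,
        ent(F),
        cd / T_safe[:, None],
        ent(cd),
        cs / T_safe[:, None],
        ent(cs),
        ent(cx),
        ng,
    )
    return out.reshape(*lead, 25)


def glcm_features_from_matrix(P: np.ndarray) -> np.ndarray:
    """25 GLCM features from normalised symmetric matrices.

    ``P`` has shape (..., ng, ng); returns shape (..., 25).  Callers with
    per-direction matrices average over the direction axis afterwards.
    """
    P = np.asarray(P, dtype=float)
    ng = P.shape[-1]
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None]
    jj = i[None, :]
    absdiff = np.abs(ii - jj)

    px = P.sum(axis=-1)  # marginal over columns; symmetric
    mu = (px * i).sum(axis=-1)
    sig2 = (px * (i - mu[..., None]) ** 2).sum(axis=-1)

    joint_max = P.max(axis=(-2, -1))
    joint_avg = mu
    joint_var = sig2
    joint_entropy = -_xlog2x(P).sum(axis=(-2, -1))

    kd = np.arange(ng, dtype=float)
    p_diff = np.stack(
        [(P * (absdiff == k)).sum(axis=(-2, -1)) for k in range(ng)], axis=-1
    )
    da = (p_diff * kd).sum(axis=-1)
    dv = (p_diff * (kd - da[..., None]) ** 2).sum(axis=-1)
    de = -_xlog2x(p_diff).sum(axis=-1)

    ks = np.arange(2, 2 * ng + 1, dtype=float)
    sums = ii + jj
    p_sum = np.stack(
        [(P * (sums == k)).sum(axis=(-2, -1)) for k in range(2, 2 * ng + 1)], axis=-1
    )
    sa = (p_sum * ks).sum(axis=-1)
    sv = (p_sum * (ks - sa[..., None]) ** 2).sum(axis=-1)
    se = -_xlog2x(p_sum).sum(axis=-1)

    asm = (P**2).sum(axis=(-2, -1))
    contrast = (P * (ii - jj) ** 2).sum(axis=(-2, -1))
    dissim = (P * absdiff).sum(axis=(-2, -1))
    inv_diff = (P / (1.0 + absdiff)).sum(axis=(-2, -1))
    inv_diff_n = (P / (1.0 + absdiff / ng)).sum(axis=(-2, -1))
    idm = (P / (1.0 + (ii - jj) ** 2)).sum(axis=(-2, -1))
    idmn = (P / (1.0 + (ii - jj) ** 2 / ng**2)).sum(axis=(-2, -1))
    offdiag = absdiff > 0
    with np.errstate(divide="ignore"):
        inv_d2 = np.where(offdiag, 1.0 / np.where(offdiag, absdiff, 1) ** 2, 0.0)
    inv_var = (P * inv_d2).sum(axis=(-2, -1))

    autocorr = (P * ii * jj).sum(axis=(-2, -1))
    corr = np.where(sig2 > 0, (autocorr - mu**2) / np.where(sig2 > 0, sig2, 1), 0.0)

    cdev = ii + jj - 2 * mu[..., None, None]
    clus_t = (P * cdev**2).sum(axis=(-2, -1))
    clus_s = (P * cdev**3).sum(axis=(-2, -1))
    clus_p = (P * cdev**4).sum(axis=(-2, -1))

    hx = -_xlog2x(px).sum(axis=-1)
    pxpy = px[..., :, None] * px[..., None, :]
    mask = P > 0
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(P * log_pxpy * mask).sum(axis=(-2, -1))
    hxy2 = -_xlog2x(pxpy).sum(axis=(-2, -1))
    ic1 = np.where(hx > 0, (joint_entropy - hxy1) / np.where(hx > 0, hx, 1), 0.0)
    ic2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, None))
    # a constant image has a single-cell matrix: define both as 0
    ic2 = np.where(hx > 0, ic2, 0.0)

    return np.stack(
        [
            joint_max, joint_avg, joint_var, joint_entropy, da, dv, de,
            sa, sv, se, asm, contrast, dissim, inv_diff, inv_diff_n,
            idm, idmn, inv_var, corr, autocorr, clus_t, clus_s, clus_p,
            ic1, ic2,
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _line_index_tables(h: int, w: int) -> tuple[np.ndarray, ...]:
    """Gather-index tables (one per direction) mapping lines to flat pixel
    indices; padding slots point at index h*w (a sentinel)."""
    flat = np.arange(h * w).reshape(h, w)
    pad = h * w

    def pack(lines):
        L = max(len(l) for l in lines)
        out = np.full((len(lines), L), pad, dtype=np.int64)
        for k, l in enumerate(lines):
            out[k, : len(l)] = l
        return out

    horiz = pack([flat[r] for r in range(h)])
    vert = pack([flat[:, c] for c in range(w)])
    # 45 degrees: direction (-1, +1) -> anti-diagonals
    flipped = flat[::-1]
    diag45 = pack([flipped.diagonal(k) for k in range(-(h - 1), w)])
    # 135 degrees: direction (-1, -1) -> main diagonals
    diag135 = pack([flat.diagonal(k) for k in range(-(h - 1), w)])
    return horiz, diag45, vert, diag135


def glrlm_matrices_batch(levels: np.ndarray, ng: int) -> np.ndarray:
    """Run-length count matrices per direction; shape (n, 4, ng, max(h, w))."""
    n, h, w = levels.shape
    jmax = max(h, w)
    tables = _line_index_tables(h, w)
    lv_pad = np.concatenate(
        [levels.reshape(n, h * w), np.zeros((n, 1), dtype=levels.dtype)], axis=1
    )
    out = np.zeros((n, 4, ng, jmax), dtype=np.int64)
    for d, idx in enumerate(tables):
        nl, L = idx.shape
        lines = lv_pad[:, idx]  # (n, nl, L)
        block = np.concatenate(
            [lines, np.zeros((n, nl, 1), dtype=lines.dtype)], axis=2
        )
        flat = block.reshape(-1)
        prev = np.empty_like(flat)
        prev[0] = -1
        prev[1:] = flat[:-1]
        starts = np.flatnonzero(flat != prev)
        lengths = np.diff(starts, append=flat.size)
        vals = flat[starts]
        keep = vals > 0
        vals = vals[keep].astype(np.int64)
        lengths = lengths[keep]
        sub = (starts[keep] // (nl * (L + 1))).astype(np.int64)
        code = (sub * ng + (vals - 1)) * jmax + (lengths - 1)
        cnt = np.bincount(code, minlength=n * ng * jmax)
        out[:, d] = cnt.reshape(n, ng, jmax)
    return out


# ---------------------------------------------------------------------------
# generic run/zone/dependence feature block
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _rzm_joint_weights(ng: int, J: int) -> np.ndarray:
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, J + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    cols = [1.0 / (ii**2 * jj**2), ii**2 / jj**2, jj**2 / ii**2, ii**2 * jj**2]
    return np.stack([c.ravel() for c in cols], axis=1)


def _rzm_features(M: np.ndarray, nv: float) -> np.ndarray:
    """The 16-feature block shared by GLRLM/GLSZM/GLDZM-style matrices.

    ``M`` holds counts with shape (..., ng, J); the second index is the
    run length, zone size, zone distance or dependence count (value =
    index + 1).  Order: the eight joint emphases, the two grey-level and
    two second-index non-uniformities, percentage (vs ``nv`` pixels),
    grey level variance, second-index variance, entropy.
    """
    M = np.asarray(M)
    ng, J = M.shape[-2:]
    lead = M.shape[:-2]
    F = M.reshape(-1, ng * J)
    Mr = M.reshape(-1, ng, J)
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, J + 1, dtype=float)
    ns = F.sum(axis=1).astype(float)
    ns_safe = np.where(ns > 0, ns, 1.0)
    mg = Mr.sum(axis=2).astype(float)
    mj = Mr.sum(axis=1).astype(float)

    sre = mj @ (1.0 / j**2) / ns_safe
    lre = mj @ (j**2) / ns_safe
    lgle = mg @ (1.0 / i**2) / ns_safe
    hgle = mg @ (i**2) / ns_safe
    joint = (F @ _rzm_joint_weights(ng, J)) / ns_safe[:, None]
    srlgle, srhgle, lrlgle, lrhgle = joint.T
    glnu = (mg**2).sum(axis=1) / ns_safe
    glnun = glnu / ns_safe
    rlnu = (mj**2).sum(axis=1) / ns_safe
    rlnun = rlnu / ns_safe
    perc = ns / nv

    pg = mg / ns_safe[:, None]
    pj = mj / ns_safe[:, None]
    mu_i = pg @ i
    glv = (pg * (i[None, :] - mu_i[:, None]) ** 2).sum(axis=1)
    mu_j = pj @ j
    rlv = (pj * (j[None, :] - mu_j[:, None]) ** 2).sum(axis=1)
    # sum p*log2(p) = (sum c*log2(c))/Ns - log2(Ns), LUT-fast on counts
    if np.issubdtype(M.dtype, np.integer):
        entropy = np.log2(ns_safe) - _count_entropy_sum(F) / ns_safe
    else:
        p = F / ns_safe[:, None]
        entropy = -_xlog2x(p).sum(axis=1)

    out = np.stack(
        [
            sre, lre, lgle, hgle, srlgle, srhgle, lrlgle, lrhgle,
            glnu, glnun, rlnu, rlnun, perc, glv, rlv, entropy,
        ],
        axis=1,
    )
    return out.reshape(*lead, 16)


# ---------------------------------------------------------------------------
# GLSZM / GLDZM
# ---------------------------------------------------------------------------


def _border_distance_map(h: int, w: int) -> np.ndarray:
    """Chessboard distance to outside the window; border pixels are 1."""
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    return np.minimum(np.minimum(r, h - 1 - r), np.minimum(c, w - 1 - c)) + 1


def zone_matrices_batch(
    levels: np.ndarray, ng: int
) -> tuple[np.ndarray, np.ndarray]:
    """GLSZM and GLDZM count matrices for a batch.

    Returns ``(szm, dzm)`` with shapes (n, ng, h*w) and (n, ng, dmax).
    Zones are 8-connected components of constant grey level; the zone
    distance is the minimum border distance over the zone's pixels.
    """
    n, h, w = levels.shape
    jz = h * w
    jd = (min(h, w) + 1) // 2
    # stack subimages vertically with a background separator row; 8-connected
    # components cannot cross the gap
    canvas = np.zeros((n, h + 1, w), dtype=levels.dtype)
    canvas[:, :h] = levels
    canvas = canvas.reshape(n * (h + 1), w)
    sub_map = np.repeat(np.arange(n), h + 1)[:, None] * np.ones((1, w), dtype=int)
    dist_tile = np.zeros((h + 1, w), dtype=float)
    dist_tile[:h] = _border_distance_map(h, w)
    dist_map = np.tile(dist_tile, (n, 1))

    structure = np.ones((3, 3), dtype=int)
    szm = np.zeros((n, ng, jz), dtype=np.int64)
    dzm = np.zeros((n, ng, jd), dtype=np.int64)
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(canvas == g, structure=structure)
        if nlab == 0:
            continue
        index = np.arange(1, nlab + 1)
        sizes = np.bincount(lab.ravel())[1:]
        subs = ndimage.minimum(sub_map, lab, index).astype(int)
        dists = ndimage.minimum(dist_map, lab, index).astype(int)
        np.add.at(szm, (subs, g - 1, sizes - 1), 1)
        np.add.at(dzm, (subs, g - 1, dists - 1), 1)
    return szm, dzm


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_matrix_batch(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts ``n_i`` and difference sums ``s_i``.

    ``s_i`` sums |i - mean(8-neighbour levels)| over pixels with level i;
    averages use only the neighbours inside the window.
    """
    n, h, w = levels.shape
    lv = levels.astype(float)
    nb_sum = np.zeros((n, h, w), dtype=float)
    nb_cnt = np.zeros((n, h, w), dtype=float)
    for dr, dc in NEIGHBOUR_OFFSETS:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        nb_sum[:, r0:r1, c0:c1] += lv[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        nb_cnt[:, r0:r1, c0:c1] += 1.0
    diff = np.abs(lv - nb_sum / nb_cnt)
    code = (np.arange(n)[:, None, None] * ng + levels - 1).ravel()
    ni = np.bincount(code, minlength=n * ng).reshape(n, ng).astype(float)
    si = np.bincount(code, weights=diff.ravel(), minlength=n * ng).reshape(n, ng)
    return ni, si


def ngtdm_features_from_matrix(ni: np.ndarray, si: np.ndarray) -> np.ndarray:
    """The five NGTDM features; inputs shaped (..., ng)."""
    ni = np.asarray(ni, dtype=float)
    si = np.asarray(si, dtype=float)
    ng = ni.shape[-1]
    nv = ni.sum(axis=-1)
    p = ni / nv[..., None]
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = present.sum(axis=-1).astype(float)

    ps = (p * si).sum(axis=-1)
    coarseness = np.where(ps > 0, 1.0 / np.where(ps > 0, ps, 1.0), COARSENESS_CAP)

    pij = p[..., :, None] * p[..., None, :]
    d2 = (i[:, None] - i[None, :]) ** 2
    pair_norm = ngp * (ngp - 1)
    contrast = np.where(
        pair_norm > 0,
        (pij * d2).sum(axis=(-2, -1)) / np.where(pair_norm > 0, pair_norm, 1.0),
        0.0,
    ) * (si.sum(axis=-1) / nv)

    ip = i * p
    both = present[..., :, None] & present[..., None, :]
    dip = np.abs(ip[..., :, None] - ip[..., None, :]) * both
    denom_b = dip.sum(axis=(-2, -1))
    busyness = np.where(denom_b > 0, ps / np.where(denom_b > 0, denom_b, 1.0), 0.0)

    psum = p[..., :, None] + p[..., None, :]
    psisj = p[..., :, None] * si[..., :, None] + p[..., None, :] * si[..., None, :]
    absdiff = np.abs(i[:, None] - i[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        cterm = np.where(both, absdiff * psisj / np.where(both, psum, 1.0), 0.0)
    complexity = cterm.sum(axis=(-2, -1)) / nv

    s_tot = si.sum(axis=-1)
    sterm = (psum * d2 * both).sum(axis=(-2, -1))
    strength = np.where(s_tot > 0, sterm / np.where(s_tot > 0, s_tot, 1.0), 0.0)

    return np.stack([coarseness, contrast, busyness, complexity, strength], axis=-1)


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------


def ngldm_matrix_batch(levels: np.ndarray, ng: int) -> np.ndarray:
    """Dependence count matrices, shape (n, ng, 9).

    Dependence count of a pixel = 1 + number of 8-neighbours inside the
    window with exactly the same level (alpha = 0).
    """
    n, h, w = levels.shape
    dep = np.ones((n, h, w), dtype=np.int64)
    for dr, dc in NEIGHBOUR_OFFSETS:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        dep[:, r0:r1, c0:c1] += (
            levels[:, r0:r1, c0:c1] == levels[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        )
    jmax = 9
    code = ((np.arange(n)[:, None, None] * ng + levels - 1) * jmax + dep - 1).ravel()
    cnt = np.bincount(code, minlength=n * ng * jmax)
    return cnt.reshape(n, ng, jmax)


def ngldm_features_from_matrix(M: np.ndarray, nv: float) -> np.ndarray:
    """The 17 NGLDM features from dependence count matrices (..., ng, 9)."""
    block = _rzm_features(M, nv)
    ns = np.asarray(M, dtype=float).sum(axis=(-2, -1))
    p = M / np.where(ns > 0, ns, 1.0)[..., None, None]
    energy = (p**2).sum(axis=(-2, -1))
    return np.concatenate([block, energy[..., None]], axis=-1)


# ---------------------------------------------------------------------------
# top-level extraction
# ---------------------------------------------------------------------------


def _extract_chunk(raw: np.ndarray, ng: int) -> np.ndarray:
    n, h, w = raw.shape
    levels = discretise_batch(raw, ng)
    nv = float(h * w)

    fos = fos_features_batch(raw, levels, ng)
    glcm = _glcm_features_counts(glcm_counts_batch(levels, ng)).mean(axis=1)
    glrlm = _rzm_features(glrlm_matrices_batch(levels, ng), nv).mean(axis=1)
    szm, dzm = zone_matrices_batch(levels, ng)
    glszm = _rzm_features(szm, nv)
    gldzm = _rzm_features(dzm, nv)
    ngtdm = ngtdm_features_from_matrix(*ngtdm_matrix_batch(levels, ng))
    ngldm = ngldm_features_from_matrix(ngldm_matrix_batch(levels, ng), nv)

    return np.concatenate([fos, glcm, glrlm, glszm, gldzm, ngtdm, ngldm], axis=1)


def extract_features_batch(
    subimages: np.ndarray, ng: int = 8, chunk: int = 8192
) -> np.ndarray:
    """Extract the 118-feature catalogue for a stack of subimages.

    ``subimages`` has shape (n, h, w); returns (n, 118) in catalogue order.
    """
    raw = np.asarray(subimages, dtype=float)
    if raw.ndim != 3:
        raise ValueError("subimages must have shape (n, h, w)")
    n = raw.shape[0]
    if n == 0:
        return np.empty((0, N_FEATURES))
    parts = [
        _extract_chunk(raw[lo : lo + chunk], ng) for lo in range(0, n, chunk)
    ]
    out = np.concatenate(parts, axis=0)
    assert out.shape == (n, N_FEATURES)
    return out


def extract_feature_vector(sub, ng: int = 8) -> FeatureVector:
    """118-feature vector for a single subimage (array or ``Subimage``)."""
    pixels = np.asarray(getattr(sub, "pixels", sub), dtype=float)
    return FeatureVector(values=extract_features_batch(pixels[None], ng=ng)[0])


# ---------------------------------------------------------------------------
# single-image operations (inspection / testing surface)
# ---------------------------------------------------------------------------

TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "GLDZM", "NGTDM", "NGLDM")


def fos_features(sub, disc: DiscretisedSubimage | None = None, ng: int = 8):
    """Named first-order features for one subimage."""
    pixels = np.asarray(getattr(sub, "pixels", sub), dtype=float)
    if disc is None:
        disc = discretise(pixels, ng)
    vals = fos_features_batch(pixels[None], disc.levels[None], disc.ng)[0]
    return dict(zip(FOS_NAMES, vals))


def texture_matrix(disc: DiscretisedSubimage, family: str):
    """Build the texture matrix structure for one discretised subimage.

    Returns per family: GLCM -> (4, ng, ng) normalised symmetric
    matrices; GLRLM -> (4, ng, jmax) run counts; GLSZM/GLDZM ->
    (ng, jmax) zone counts; NGTDM -> ``(n_i, s_i)``; NGLDM -> (ng, 9)
    dependence counts.
    """
    lv = np.asarray(disc.levels)[None]
    ng = disc.ng
    family = family.upper()
    if family == "GLCM":
        return glcm_matrices_batch(lv, ng)[0]
    if family == "GLRLM":
        return glrlm_matrices_batch(lv, ng)[0]
    if family == "GLSZM":
        return zone_matrices_batch(lv, ng)[0][0]
    if family == "GLDZM":
        return zone_matrices_batch(lv, ng)[1][0]
    if family == "NGTDM":
        ni, si = ngtdm_matrix_batch(lv, ng)
        return ni[0], si[0]
    if family == "NGLDM":
        return ngldm_matrix_batch(lv, ng)[0]
    raise ValueError(f"unknown texture family: {family}")


def texture_features(matrix, family: str, nv: float | None = None):
    """Named features from a matrix built by :func:`texture_matrix`.

    ``nv`` (pixel count) is needed for the zone/dependence percentages;
    it defaults to the value recoverable from the matrix (GLRLM, GLSZM,
    NGTDM, NGLDM) or to 64 for GLDZM (the 8x8 window).
    """
    family = family.upper()
    if family == "GLCM":
        P = np.asarray(matrix, dtype=float)
        vals = glcm_features_from_matrix(P).mean(axis=0) if P.ndim == 3 else (
            glcm_features_from_matrix(P)
        )
        return dict(zip(GLCM_NAMES, vals))
    if family == "GLRLM":
        M = np.asarray(matrix, dtype=float)
        if M.ndim == 2:
            M = M[None]
        j = np.arange(1, M.shape[-1] + 1, dtype=float)
        if nv is None:
            nv = float((M[0].sum(axis=0) * j).sum())
        return dict(zip(GLRLM_NAMES, _rzm_features(M, nv).mean(axis=0)))
    if family == "GLSZM":
        M = np.asarray(matrix, dtype=float)
        j = np.arange(1, M.shape[-1] + 1, dtype=float)
        if nv is None:
            nv = float((M.sum(axis=0) * j).sum())
        return dict(zip(GLSZM_NAMES, _rzm_features(M, nv)))
    if family == "GLDZM":
        if nv is None:
            nv = 64.0
        return dict(zip(GLDZM_NAMES, _rzm_features(np.asarray(matrix, float), nv)))
    if family == "NGTDM":
        ni, si = matrix
        return dict(zip(NGTDM_NAMES, ngtdm_features_from_matrix(ni, si)))
    if family == "NGLDM":
        M = np.asarray(matrix, dtype=float)
        if nv is None:
            nv = float(M.sum())
        return dict(zip(NGLDM_NAMES, ngldm_features_from_matrix(M, nv)))
    raise ValueError(f"unknown texture family: {family}")
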