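"""3D gray-level texture matrices and the 39-feature lesion signature.

Four second-order matrix families are computed over a quantized lesion VOI:

* GLCM  — joint distribution of gray-level pairs at a fixed voxel offset,
  aggregated over the 13 unique 3D directions (8 features);
* GLRLM — counts of maximal collinear runs of equal gray level, per
  direction, summed over the 13 directions (13 features);
* GLSZM — counts of 26-connected zones of equal gray level by size
  (13 features);
* NGTDM — per-level summed absolute difference between a voxel and the mean
  of its in-mask 26-neighborhood (5 features).

All offsets live in voxel index space (anisotropic spacing is ignored for
neighborhood definitions, consistent with slice-stacked lesion masks).
Counts are summed over directions first and normalized once.  Conservation
identities: GLCM probabilities sum to 1; GLRLM run lengths weighted by count
sum to N x n_directions; GLSZM zone sizes weighted by count sum to N; NGTDM
level probabilities sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .volumes import QuantizedVOI

__all__ = [
    "OFFSETS_13",
    "GLCMatrix",
    "GLRLMatrix",
    "GLSZMatrix",
    "NGTDMComponents",
    "TextureFeatureVector",
    "FEATURE_NAMES",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "compute_glszm",
    "glszm_features",
    "compute_ngtdm",
    "ngtdm_features",
    "extract_all",
]

_EPS = 1e-12

# The 13 unique 3D offsets: all 26-neighborhood directions up to sign
# (first nonzero component positive).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


def _shifted_slices(shape, offset):
    """Index slices (dst, src) so that dst[v] pairs with src[v + offset]."""
    dst, src = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            dst.append(slice(0, n - d))
            src.append(slice(d, n))
        else:
            dst.append(slice(-d, n))
            src.append(slice(0, n + d))
    return tuple(dst), tuple(src)


@dataclass
class GLCMatrix:
    """Normalized gray-level co-occurrence probabilities, Ng x Ng."""

    P: np.ndarray
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs > 0 and abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM probabilities must sum to 1")


@dataclass
class GLRLMatrix:
    """Run counts R[i, j]: runs of level i+1 with length j+1, all directions."""

    R: np.ndarray
    directions: tuple[tuple[int, int, int], ...]
    n_voxels: int


@dataclass
class GLSZMatrix:
    """Zone counts Z[i, s]: 26-connected zones of level i+1 with size s+1."""

    Z: np.ndarray
    connectivity: int
    n_voxels: int


@dataclass
class NGTDMComponents:
    """Per-level neighborhood gray-tone difference sums and probabilities."""

    s: np.ndarray  # summed |level - neighborhood mean| per level, length Ng
    p: np.ndarray  # level probabilities over valid voxels, length Ng
    n: np.ndarray  # valid voxel counts per level, length Ng
    n_valid: int  # voxels with at least one in-mask neighbor

    @property
    def n_levels_present(self) -> int:
        return int((self.p > 0).sum())


def compute_glcm(
    q: QuantizedVOI,
    distance: int = 1,
    symmetric: bool = True,
    offsets: tuple[tuple[int, int, int], ...] | None = None,
) -> GLCMatrix:
    """Co-occurrence matrix over in-mask voxel pairs at the given distance.

    Pairs are counted for each offset ``distance * u`` with ``u`` ranging
    over the 13 unique 3D directions (or the provided subset), restricted to
    pairs whose both endpoints are inside the mask, symmetrized, and
    normalized to probabilities.  A VOI with no valid pair yields the
    single-entry degenerate matrix ``[[1.0]]`` at the modal level.
    """
    if distance < 1:
        raise ConfigurationError(f"distance must be >= 1, got {distance}")
    offs = OFFSETS_13 if offsets is None else tuple(offsets)
    ng = q.n_bins
    lv = q.levels
    mask = q.mask.data
    counts = np.zeros(ng * ng, dtype=np.int64)
    for u in offs:
        d = tuple(distance * c for c in u)
        dst, src = _shifted_slices(lv.shape, d)
        valid = mask[dst] & mask[src]
        a = lv[dst][valid] - 1
        b = lv[src][valid] - 1
        counts += np.bincount(a * ng + b, minlength=ng * ng)
    C = counts.reshape(ng, ng).astype(np.float64)
    if symmetric:
        C = C + C.T
    n_pairs = int(C.sum())
    if n_pairs == 0:
        # single voxel or offsets leaving the mask entirely: degenerate
        modal = int(np.bincount(lv[mask]).argmax())
        P = np.zeros((ng, ng))
        P[modal - 1, modal - 1] = 1.0
        return GLCMatrix(P=P, offsets=offs, symmetric=symmetric, n_pairs=0)
    return GLCMatrix(P=C / C.sum(), offsets=offs, symmetric=symmetric, n_pairs=n_pairs)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The 8 co-occurrence features (classic Haralick subset)."""
    P = m.P
    ng = P.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(1, ng + 1) * px).sum())
    mu_y = float((np.arange(1, ng + 1) * py).sum())
    var_x = float(((np.arange(1, ng + 1) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(1, ng + 1) - mu_y) ** 2 * py).sum())
    diff = i - j
    if var_x * var_y > _EPS:
        corr = float(((i - mu_x) * (j - mu_y) * P).sum() / np.sqrt(var_x * var_y))
    else:
        corr = 1.0  # a constant VOI is perfectly self-correlated
    nz = P[P > 0]
    return {
        "energy": float((P**2).sum()),
        "contrast": float((P * diff**2).sum()),
        "correlation": corr,
        "variance": float((P * (i - mu_x) ** 2).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "dissimilarity": float((P * np.abs(diff)).sum()),
        "maximum_probability": float(P.max()),
    }


def compute_glrlm(
    q: QuantizedVOI,
    directions: tuple[tuple[int, int, int], ...] | None = None,
) -> GLRLMatrix:
    """Maximal-run counts per direction, summed over the 13 directions.

    For each direction a run is a maximal set of collinear in-mask voxels of
    equal level; every in-mask voxel belongs to exactly one run per
    direction, so ``sum_j (j+1) R[i, j] == N * n_directions``.
    """
    dirs = OFFSETS_13 if directions is None else tuple(directions)
    lv = q.levels
    mask = q.mask.data
    ng = q.n_bins
    max_len = int(max(lv.shape))
    R = np.zeros((ng, max_len), dtype=np.int64)
    for d in dirs:
        # cont[v] : voxel v continues a run from v - d
        dst, src = _shifted_slices(lv.shape, tuple(-c for c in d))
        cont = np.zeros(lv.shape, dtype=bool)
        cont[dst] = mask[dst] & mask[src] & (lv[dst] == lv[src])
        # run length ending at v: 1 + #consecutive predecessors in the run
        runlen = np.ones(lv.shape, dtype=np.int32)
        chain = cont.copy()
        k = 1
        while chain.any():
            runlen[chain] += 1
            # chain_{k+1}(v) = chain_k(v) & cont(v - k*d)
            kd = tuple(-k * c for c in d)
            dst_k, src_k = _shifted_slices(lv.shape, kd)
            nxt = np.zeros(lv.shape, dtype=bool)
            nxt[dst_k] = chain[dst_k] & cont[src_k]
            chain = nxt
            k += 1
        # a run is counted at its last voxel: v in mask, v + d not continuing
        dst2, src2 = _shifted_slices(lv.shape, d)
        continues_fwd = np.zeros(lv.shape, dtype=bool)
        continues_fwd[dst2] = cont[src2]
        ends = mask & ~continues_fwd
        lvls = lv[ends] - 1
        lens = runlen[ends] - 1
        np.add.at(R, (lvls, lens), 1)
    # trim trailing all-zero run-length columns
    used = np.nonzero(R.any(axis=0))[0]
    lmax = int(used.max()) + 1 if used.size else 1
    return GLRLMatrix(R=R[:, :lmax], directions=dirs, n_voxels=q.voxel_count)


def glrlm_features(m: GLRLMatrix) -> dict[str, float]:
    """The 13 run-length features from the direction-aggregated matrix."""
    R = m.R.astype(np.float64)
    ng, lmax = R.shape
    i = np.arange(1, ng + 1)[:, None].astype(np.float64)
    j = np.arange(1, lmax + 1)[None, :].astype(np.float64)
    nr = R.sum()
    mu_i = (R * i).sum() / nr
    mu_j = (R * j).sum() / nr
    return {
        "sre": float((R / j**2).sum() / nr),
        "lre": float((R * j**2).sum() / nr),
        "gln": float((R.sum(axis=1) ** 2).sum() / nr),
        "rln": float((R.sum(axis=0) ** 2).sum() / nr),
        "rp": float(nr / (m.n_voxels * len(m.directions))),
        "lgre": float((R / i**2).sum() / nr),
        "hgre": float((R * i**2).sum() / nr),
        "srlge": float((R / (i**2 * j**2)).sum() / nr),
        "srhge": float((R * i**2 / j**2).sum() / nr),
        "lrlge": float((R * j**2 / i**2).sum() / nr),
        "lrhge": float((R * i**2 * j**2).sum() / nr),
        "glv": float((R * (i - mu_i) ** 2).sum() / nr),
        "rlv": float((R * (j - mu_j) ** 2).sum() / nr),
    }


def compute_glszm(q: QuantizedVOI, connectivity: int = 26) -> GLSZMatrix:
    """Zone counts: 26-connected components of equal gray level.

    ``sum_s (s+1) Z[i, s] == N`` — every in-mask voxel is in exactly one zone.
    """
    if connectivity not in (6, 18, 26):
        raise ConfigurationError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(3, rank)
    lv = q.levels
    mask = q.mask.data
    ng = q.n_bins
    zones: list[tuple[int, int]] = []  # (level-1, size)
    for g in np.unique(lv[mask]):
        lab, n_lab = ndimage.label((lv == g) & mask, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g) - 1, int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    Z = np.zeros((ng, smax), dtype=np.int64)
    for g0, s in zones:
        Z[g0, s - 1] += 1
    return GLSZMatrix(Z=Z, connectivity=connectivity, n_voxels=q.voxel_count)


def glszm_features(m: GLSZMatrix) -> dict[str, float]:
    """The 13 size-zone features (same algebra as run-length, size for length)."""
    Z = m.Z.astype(np.float64)
    ng, smax = Z.shape
    i = np.arange(1, ng + 1)[:, None].astype(np.float64)
    s = np.arange(1, smax + 1)[None, :].astype(np.float64)
    nz = Z.sum()
    mu_i = (Z * i).sum() / nz
    mu_s = (Z * s).sum() / nz
    return {
        "sze": float((Z / s**2).sum() / nz),
        "lze": float((Z * s**2).sum() / nz),
        "gln": float((Z.sum(axis=1) ** 2).sum() / nz),
        "zsn": float((Z.sum(axis=0) ** 2).sum() / nz),
        "zp": float(nz / m.n_voxels),
        "lgze": float((Z / i**2).sum() / nz),
        "hgze": float((Z * i**2).sum() / nz),
        "szlge": float((Z / (i**2 * s**2)).sum() / nz),
        "szhge": float((Z * i**2 / s**2).sum() / nz),
        "lzlge": float((Z * s**2 / i**2).sum() / nz),
        "lzhge": float((Z * i**2 * s**2).sum() / nz),
        "glv": float((Z * (i - mu_i) ** 2).sum() / nz),
        "zsv": float((Z * (s - mu_s) ** 2).sum() / nz),
    }


def compute_ngtdm(q: QuantizedVOI) -> NGTDMComponents:
    """Neighborhood gray-tone difference components.

    The neighborhood is the in-mask 3x3x3 box around each voxel, center
    excluded.  Voxels with no in-mask neighbor are dropped from both the
    difference sums and the level probabilities.
    """
    lv = q.levels.astype(np.float64)
    mask = q.mask.data
    ng = q.n_bins
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(lv * mask, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    if valid.any():
        diff = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
        lvls = q.levels[valid] - 1
        np.add.at(s, lvls, diff)
        np.add.at(n, lvls, 1)
    n_valid = int(valid.sum())
    p = n / n_valid if n_valid else np.zeros(ng)
    return NGTDMComponents(s=s, p=p, n=n, n_valid=n_valid)


def ngtdm_features(m: NGTDMComponents) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength (Amadasun-King).

    Zero denominators are epsilon-guarded; the degenerate value of busyness,
    complexity, contrast and strength for a flat VOI is 0.
    """
    p, s = m.p, m.s
    nv = m.n_valid
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, p.size + 1, dtype=np.float64)
    ps = float((p * s).sum())
    coarseness = 1.0 / (_EPS + ps)
    if ngp > 1 and nv > 0:
        ii = i[present][:, None]
        jj = i[present][None, :]
        pi = p[present][:, None]
        pj = p[present][None, :]
        si = s[present][:, None]
        sj = s[present][None, :]
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / nv
        den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / den if den > _EPS else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / nv
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / (_EPS + float(s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


_GLCM_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "entropy",
    "dissimilarity",
    "maximum_probability",
)
_GLRLM_NAMES = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)
_GLSZM_NAMES = (
    "sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
    "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv",
)
_NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

#: Fixed order of the 39 features: 8 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"glcm_{n}" for n in _GLCM_NAMES)
    + tuple(f"glrlm_{n}" for n in _GLRLM_NAMES)
    + tuple(f"glszm_{n}" for n in _GLSZM_NAMES)
    + tuple(f"ngtdm_{n}" for n in _NGTDM_NAMES)
)


@dataclass
class TextureFeatureVector:
    """The 39 named texture features for one lesion.

    ``quality_flag`` is set for degenerate VOIs (fewer than 2 voxels or a
    single effective gray level); their feature values are the defined
    degenerate fallbacks, never NaN.
    """

    values: np.ndarray
    names: tuple[str, ...]
    quality_flag: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __len__(self) -> int:
        return len(self.values)


def extract_all(q: QuantizedVOI, glcm_distance: int = 1) -> TextureFeatureVector:
    """Compute all 39 features in the fixed :data:`FEATURE_NAMES` order."""
    glcm = glcm_features(compute_glcm(q, distance=glcm_distance))
    glrlm = glrlm_features(compute_glrlm(q))
    glszm = glszm_features(compute_glszm(q))
    ngtdm = ngtdm_features(compute_ngtdm(q))
    vals = (
        [glcm[n] for n in _GLCM_NAMES]
        + [glrlm[n] for n in _GLRLM_NAMES]
        + [glszm[n] for n in _GLSZM_NAMES]
        + [ngtdm[n] for n in _NGTDM_NAMES]
    )
    flag = q.voxel_count < 2 or q.n_effective_levels < 2
    arr = np.asarray(vals, dtype=np.float64)
    assert np.all(np.isfinite(arr))
    return TextureFeatureVector(values=arr, names=FEATURE_NAMES, quality_flag=flag)
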