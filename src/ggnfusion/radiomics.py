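"""Compact IBSI-style radiomic feature engine for pulmonary nodule CT.

Operates on 3-D attenuation grids (Hounsfield units) with binary region-of-
interest masks.  Covers the feature families used by the fusion pipeline:
shape descriptors, first-order statistics, grey-level co-occurrence (GLCM)
and run-length (GLRLM) texture features, Laplacian-of-Gaussian filtering,
growth metrics and per-day delta features.  Intensities are discretised with
a fixed 25-HU bin width anchored at -1024 HU so that bins carry absolute
physical meaning across scans and centres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "NoduleScan",
    "GrowthMetrics",
    "resample_isotropic",
    "compute_volume",
    "esd",
    "discretise",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "log_filter",
    "growth_metrics",
    "delta_features",
    "log1p_rates",
    "extract_features",
    "save_scan",
    "load_scan",
    "UNIT_DIRECTIONS_3D",
]

DAYS_PER_YEAR = 365.25
HU_BIN_WIDTH = 25.0
HU_BIN_ANCHOR = -1024.0

#: The 13 unique unit-offset directions of a 3-D 26-neighbourhood (one per
#: antipodal pair), used for direction-merged texture matrices.
UNIT_DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(UNIT_DIRECTIONS_3D) == 13


@dataclass
class NoduleScan:
    """One time point of a segmented nodule: HU grid, ROI mask, voxel spacing.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Attenuation in Hounsfield units.
    mask : ndarray of bool, same shape
        Region of interest.
    spacing : tuple of float
        Voxel spacing (x, y, z) in millimetres.
    """

    grid: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if self.grid.shape != self.mask.shape:
            raise ValueError("grid and mask shapes differ")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def roi_values(self) -> np.ndarray:
        return self.grid[self.mask]


@dataclass
class GrowthMetrics:
    """Volume/attenuation change summaries between baseline and follow-up."""

    v0: float
    v1: float
    dt_days: float
    daily_rate: float
    annualised_rate: float
    vdt: float
    vdt_undefined: bool
    delta_mean_hu_per_day: float


# ---------------------------------------------------------------------------
# geometry / resampling


def resample_isotropic(scan: NoduleScan, target_mm: float = 1.0) -> NoduleScan:
    """Resample a scan to isotropic voxels (trilinear grid, nearest mask)."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    factors = tuple(s / target_mm for s in scan.spacing)
    if any(not math.isfinite(f) or f <= 0 for f in factors):
        raise ValueError("degenerate spacing")
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return NoduleScan(scan.grid.copy(), scan.mask.copy(), (target_mm,) * 3)
    grid = ndimage.zoom(scan.grid, factors, order=1, mode="nearest")
    mask = ndimage.zoom(scan.mask.astype(np.uint8), factors, order=0, mode="nearest")
    return NoduleScan(grid, mask.astype(bool), (target_mm,) * 3)


def compute_volume(mask: np.ndarray, spacing) -> float:
    """ROI volume in mm^3: voxel count within the ROI times voxel volume."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        warnings.warn("empty mask: volume is 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return n * float(np.prod(np.asarray(spacing, dtype=float)))


def esd(volume: float) -> float:
    """Equivalent spherical diameter (mm) of a volume in mm^3."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# discretisation and first-order statistics


def discretise(values, bin_width: float = HU_BIN_WIDTH, anchor: float = HU_BIN_ANCHOR) -> np.ndarray:
    """Fixed-bin-width discretisation: bin(x) = floor((x - anchor)/w) + 1.

    The anchor is a global constant (default -1024 HU) so the same attenuation
    always falls in the same bin, with no per-image normalisation.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    return np.floor((values - anchor) / bin_width).astype(np.int64) + 1


def first_order_features(values, bin_width: float = HU_BIN_WIDTH) -> dict[str, float]:
    """First-order intensity statistics of the ROI voxels.

    Entropy is computed over the occupied fixed-width bins in bits; variance
    is the population variance; skewness/kurtosis follow the Fisher
    definition and are flagged undefined (NaN) on constant input.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values")
    out: dict[str, float] = {
        "firstorder.mean": float(np.mean(x)),
        "firstorder.median": float(np.median(x)),
        "firstorder.variance": float(np.var(x)),
        "firstorder.energy": float(np.sum(x**2)),
        "firstorder.p10": float(np.percentile(x, 10)),
        "firstorder.p90": float(np.percentile(x, 90)),
        "firstorder.range": float(np.ptp(x)),
    }
    if np.ptp(x) == 0:
        out["firstorder.skewness"] = float("nan")
        out["firstorder.kurtosis"] = float("nan")
    else:
        out["firstorder.skewness"] = float(sps.skew(x))
        out["firstorder.kurtosis"] = float(sps.kurtosis(x))  # Fisher
    bins = discretise(x, bin_width=bin_width)
    _, counts = np.unique(bins, return_counts=True)
    p = counts / counts.sum()
    out["firstorder.entropy"] = float(-np.sum(p * np.log2(p)))
    return out


# ---------------------------------------------------------------------------
# texture matrices (direction-merged over the 13 unique 3-D offsets)


def _glcm_matrix(bins: np.ndarray, mask: np.ndarray,
                 directions=UNIT_DIRECTIONS_3D) -> np.ndarray:
    """Symmetric co-occurrence matrix merged over the given directions."""
    levels = np.unique(bins[mask])
    index = {g: i for i, g in enumerate(levels)}
    L = len(levels)
    P = np.zeros((L, L), dtype=float)
    lab = np.full(bins.shape, -1, dtype=np.int64)
    lab[mask] = [index[g] for g in bins[mask]]
    for d in directions:
        a = lab
        b = np.roll(lab, tuple(-np.array(d)), axis=(0, 1, 2))
        valid = np.ones(lab.shape, dtype=bool)
        for ax, step in enumerate(d):
            if step > 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(lab.shape[ax] - step, None)
                valid[tuple(sl)] = False
            elif step < 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(None, -step)
                valid[tuple(sl)] = False
        pair = valid & (a >= 0) & (b >= 0)
        ii, jj = a[pair], b[pair]
        np.add.at(P, (ii, jj), 1.0)
        np.add.at(P, (jj, ii), 1.0)  # symmetric
    return P


def glcm_features(bins: np.ndarray, mask: np.ndarray,
                  directions=UNIT_DIRECTIONS_3D) -> dict[str, float]:
    """Contrast, correlation, joint entropy and inverse difference moment
    of the direction-merged symmetric GLCM."""
    bins = np.asarray(bins)
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        return {k: float("nan") for k in (
            "glcm.contrast", "glcm.correlation", "glcm.joint_entropy", "glcm.idm")}
    P = _glcm_matrix(bins, mask, directions)
    total = P.sum()
    if total == 0:  # isolated voxels only
        return {k: float("nan") for k in (
            "glcm.contrast", "glcm.correlation", "glcm.joint_entropy", "glcm.idm")}
    P = P / total
    levels = np.unique(bins[mask]).astype(float)
    i = levels[:, None]
    j = levels[None, :]
    contrast = float(np.sum(P * (i - j) ** 2))
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))
    nz = P[P > 0]
    joint_entropy = float(-np.sum(nz * np.log2(nz)))
    mu_i = float(np.sum(P * i))
    mu_j = float(np.sum(P * j))
    var_i = float(np.sum(P * (i - mu_i) ** 2))
    var_j = float(np.sum(P * (j - mu_j) ** 2))
    if var_i <= 0 or var_j <= 0:
        correlation = float("nan")
    else:
        correlation = float(np.sum(P * (i - mu_i) * (j - mu_j)) / math.sqrt(var_i * var_j))
    return {
        "glcm.contrast": contrast,
        "glcm.correlation": correlation,
        "glcm.joint_entropy": joint_entropy,
        "glcm.idm": idm,
    }


def _shifted(arr: np.ndarray, d: tuple[int, int, int], fill):
    """out[x] = arr[x + d], with `fill` outside the grid."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(d):
        if step > 0:
            src[ax] = slice(step, None)
            dst[ax] = slice(None, -step)
        elif step < 0:
            src[ax] = slice(None, step)
            dst[ax] = slice(-step, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _runs_along(bins: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]):
    """(grey level, run length) arrays for maximal runs along direction d,
    by vectorised dynamic programming over shifted grids."""
    same_next = mask & _shifted(mask, d, False) & (bins == _shifted(bins, d, bins.min() - 1))
    same_prev = mask & _shifted(mask, tuple(-s for s in d), False) \
        & (bins == _shifted(bins, tuple(-s for s in d), bins.min() - 1))
    starts = mask & ~same_prev
    # L[x] = 1 + L[x+d] where the run continues; iterate to a fixed point
    L = np.ones(bins.shape, dtype=np.int64)
    while True:
        L_new = np.where(same_next, 1 + _shifted(L, d, 0), 1)
        if np.array_equal(L_new, L):
            break
        L = L_new
    return bins[starts], L[starts]


def glrlm_features(
    bins: np.ndarray,
    mask: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = UNIT_DIRECTIONS_3D,
) -> dict[str, float]:
    """Run-length features of run matrices merged over the given directions.

    Run percentage is runs per ROI voxel per direction, so a single run of
    length L along one direction yields 1/L.
    """
    bins = np.asarray(bins)
    mask = np.asarray(mask).astype(bool)
    nv = int(mask.sum())
    if nv < 2:
        return {k: float("nan") for k in (
            "glrlm.sre", "glrlm.lre", "glrlm.run_percentage", "glrlm.gln")}
    from collections import Counter

    runs: Counter = Counter()
    for d in directions:
        gs, ls = _runs_along(bins, mask, d)
        pairs, counts = np.unique(np.stack([gs, ls]), axis=1, return_counts=True)
        for (g, length), c in zip(pairs.T, counts):
            runs[(int(g), int(length))] += int(c)
    nr = sum(runs.values())
    sre = sum(c / (l**2) for (_, l), c in runs.items()) / nr
    lre = sum(c * l**2 for (_, l), c in runs.items()) / nr
    rp = nr / (nv * len(directions))
    by_level: dict[int, float] = {}
    for (g, _), c in runs.items():
        by_level[g] = by_level.get(g, 0.0) + c
    gln = sum(v**2 for v in by_level.values()) / nr
    return {
        "glrlm.sre": float(sre),
        "glrlm.lre": float(lre),
        "glrlm.run_percentage": float(rp),
        "glrlm.gln": float(gln),
    }


# ---------------------------------------------------------------------------
# filtering


def log_filter(grid: np.ndarray, sigma_mm: float, spacing_mm: float = 1.0) -> np.ndarray:
    """Laplacian-of-Gaussian response of an isotropic grid.

    Linear in the input: ``log_filter(a*I) == a*log_filter(I)``. The grid is
    demeaned before filtering: the ideal LoG operator annihilates constants,
    but the truncated discrete kernel does not quite, and demeaning removes
    that offset artifact exactly without affecting structure.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    g = np.asarray(grid, dtype=float)
    return ndimage.gaussian_laplace(g - g.mean(), sigma=sigma_mm / spacing_mm)


# ---------------------------------------------------------------------------
# growth and delta features


def growth_metrics(v0: float, v1: float, dt_days: float, hu0: float = float("nan"),
                   hu1: float = float("nan")) -> GrowthMetrics:
    """Daily absolute relative volume-change rate, annualised rate, signed
    volume doubling time and per-day attenuation change.

    daily_rate = |v1 - v0| / (v0 * dt); annualised = daily * 365.25 * 100 (%/yr);
    VDT = dt * ln 2 / ln(v1/v0), undefined when the volume is unchanged.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if v1 <= 0:
        raise ValueError("v1 must be positive")
    if dt_days < 1:
        raise ValueError("dt_days must be >= 1")
    daily = abs(v1 - v0) / (v0 * dt_days)
    annualised = daily * DAYS_PER_YEAR * 100.0
    if v1 == v0:
        vdt, undef = float("nan"), True
    else:
        vdt, undef = dt_days * math.log(2.0) / math.log(v1 / v0), False
    dhu = (hu1 - hu0) / dt_days
    return GrowthMetrics(
        v0=float(v0), v1=float(v1), dt_days=float(dt_days),
        daily_rate=float(daily), annualised_rate=float(annualised),
        vdt=float(vdt), vdt_undefined=undef, delta_mean_hu_per_day=float(dhu),
    )


def delta_features(f0: dict[str, float], f1: dict[str, float], dt_days: float) -> dict[str, float]:
    """Per-day rate of change of each feature between baseline and follow-up."""
    if dt_days < 1:
        raise ValueError("dt_days must be >= 1")
    if set(f0) != set(f1):
        raise ValueError("feature name mismatch between time points")
    return {name: (f1[name] - f0[name]) / dt_days for name in f0}


def log1p_rates(features: dict[str, float], rate_prefixes: tuple[str, ...] = ("delta.", "rate.")) -> dict[str, float]:
    """Signed log(1+x) compression of rate-type features.

    Non-negative magnitudes map through ln(1+x); signed deltas through
    sign(x)*ln(1+|x|), preserving monotonicity and zero.
    """
    out = {}
    for name, x in features.items():
        if any(name.startswith(p) or f".{p}" in name for p in rate_prefixes):
            out[name] = float(np.sign(x) * np.log1p(abs(x))) if np.isfinite(x) else x
        else:
            out[name] = x
    return out


# ---------------------------------------------------------------------------
# full extraction


def _shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    vol = compute_volume(mask, spacing)
    out = {"shape.volume_mm3": vol, "shape.esd_mm": esd(vol) if vol > 0 else float("nan")}
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing, dtype=float)
    if len(coords) >= 2:
        cov = np.cov(coords.T)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ev = np.clip(ev, 0, None)
        out["shape.elongation"] = float(math.sqrt(ev[1] / ev[0])) if ev[0] > 0 else float("nan")
        out["shape.flatness"] = float(math.sqrt(ev[2] / ev[0])) if ev[0] > 0 else float("nan")
        out["shape.max_extent_mm"] = float(np.ptp(coords, axis=0).max())
    else:
        out.update({"shape.elongation": float("nan"), "shape.flatness": float("nan"),
                    "shape.max_extent_mm": float("nan")})
    return out


def extract_features(scan: NoduleScan, log_sigmas_mm: tuple[float, ...] = (2.0,),
                     resample: bool = True) -> dict[str, float]:
    """Full feature vector of one scan: shape (unfiltered image only),
    first-order, GLCM, GLRLM, and first-order statistics of LoG responses."""
    if scan.mask.sum() == 0:
        raise ValueError("empty mask")
    if resample:
        scan = resample_isotropic(scan)
    vals = scan.roi_values
    feats: dict[str, float] = {}
    feats.update(_shape_features(scan.mask, scan.spacing))
    feats.update(first_order_features(vals))
    bins = discretise(scan.grid)
    feats.update(glcm_features(bins, scan.mask))
    feats.update(glrlm_features(bins, scan.mask))
    for sigma in log_sigmas_mm:
        filtered = log_filter(scan.grid, sigma, spacing_mm=scan.spacing[0])
        fo = first_order_features(filtered[scan.mask], bin_width=HU_BIN_WIDTH)
        feats.update({f"log_sigma{sigma:g}.{k}": v for k, v in fo.items()})
    vol = feats["shape.volume_mm3"]
    feats["derived.volume_mm3"] = vol
    feats["derived.esd_mm"] = feats["shape.esd_mm"]
    feats["derived.mean_hu"] = feats["firstorder.mean"]
    return feats


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_scan(scan: NoduleScan, grid_path: str | Path, mask_path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(scan.spacing) + [1.0])
    nib.save(nib.Nifti1Image(scan.grid.astype(np.float32), affine), str(grid_path))
    nib.save(nib.Nifti1Image(scan.mask.astype(np.uint8), affine), str(mask_path))


def load_scan(grid_path: str | Path, mask_path: str | Path) -> NoduleScan:
    import nibabel as nib

    img = nib.load(str(grid_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return NoduleScan(np.asarray(img.dataobj, dtype=float),
                      np.asarray(msk.dataobj) > 0, spacing)
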