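"""Map-space postprocessing: cropping, soft masks, FSC, resolution criteria,
directional FRC, B-factor sharpening, and a small real-space projector /
Fourier-insertion backprojector used for geometry validation.

Conventions
-----------
Volumes are cubic numpy arrays indexed ``[z, y, x]``.  Rotations are ZYZ
Euler triples (see :mod:`xtal2p.ctfgeom`); ``project(vol, e)`` resamples the
volume with sampling matrix ``M = e.matrix()`` (output voxel ``x`` reads
input voxel ``M (x - c) + c`` with ``c = (n-1)/2``) and sums along z, so in
Fourier space the projection is the central slice of the volume transform on
the plane spanned by ``M @ ex, M @ ey``.  Fourier shells are integer-radius
bins in voxel frequency units; the DC term is excluded from shell 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ctfgeom import EulerTriple

__all__ = [
    "Volume3D",
    "FSCCurve",
    "crop_subvolume",
    "soft_spherical_mask",
    "fsc",
    "frc",
    "volume_correct_fsc",
    "resolution_at_threshold",
    "halfbit_curve",
    "directional_frc",
    "bfactor_sharpen",
    "project",
    "backproject",
]


@dataclass
class Volume3D:
    """A cubic density map with its sampling in A/voxel."""

    data: np.ndarray
    pixel_size: float
    origin: tuple = (0, 0, 0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("Volume3D requires a cubic 3D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def box(self) -> int:
        return self.data.shape[0]


def _vol(v) -> np.ndarray:
    return v.data if isinstance(v, Volume3D) else np.asarray(v, dtype=float)


@dataclass
class FSCCurve:
    """Per-shell correlation between two half-maps.

    freq : shell center spatial frequencies (1/A), strictly increasing
    values : correlation per shell, in [-1, 1]
    n_voxels : number of Fourier voxels per shell
    """

    freq: np.ndarray
    values: np.ndarray
    n_voxels: np.ndarray
    pixel_size: float = 1.0
    box: int = field(default=0)

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")


def crop_subvolume(vol: Volume3D, center_shift=(0, 0, 0), size: int = None) -> Volume3D:
    """Extract a ``size``^3 sub-box around the (shifted) volume center.

    ``center_shift`` is (dx, dy, dz) in voxels added to the geometric center
    ``box // 2``; used e.g. to recenter a map on one molecule before masking.
    """
    data = _vol(vol)
    n = data.shape[0]
    if size is None:
        size = n
    dx, dy, dz = center_shift
    starts = []
    for axis_shift, _ in ((dz, 0), (dy, 1), (dx, 2)):
        c = n // 2 + int(axis_shift)
        lo = c - size // 2
        if lo < 0 or lo + size > n:
            raise ValueError(
                f"crop of size {size} at shifted center {c} exceeds box {n}"
            )
        starts.append(lo)
    z0, y0, x0 = starts
    out = data[z0 : z0 + size, y0 : y0 + size, x0 : x0 + size].copy()
    px = vol.pixel_size if isinstance(vol, Volume3D) else 1.0
    return Volume3D(out, px)


def soft_spherical_mask(box: int, radius: float, edge: float = 6.0) -> np.ndarray:
    """Soft-edged spherical mask: 1 out to ``radius``, cosine fall to 0 at
    ``radius + edge``, 0 beyond.  Values in [0, 1].

    Warns if the soft edge is clipped by the box corner-to-center distance.
    The mask is centered on voxel ``box // 2``, the package-wide map center.
    """
    if radius < 0 or edge < 0:
        raise ValueError("radius and edge must be non-negative")
    if radius + edge > box / 2 * np.sqrt(3):
        warnings.warn("soft mask extends beyond the box and will be clipped")
    c = float(box // 2)
    zz, yy, xx = np.indices((box, box, box))
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2)
    m = np.zeros((box,) * 3)
    m[r <= radius] = 1.0
    on_edge = (r > radius) & (r < radius + edge) if edge > 0 else np.zeros_like(m, bool)
    m[on_edge] = 0.5 * (1.0 + np.cos(np.pi * (r[on_edge] - radius) / edge))
    return m


def _shell_index(shape) -> tuple[np.ndarray, int]:
    """Integer shell index per unshifted-FFT voxel and number of shells."""
    grids = [np.fft.fftfreq(n) * n for n in shape]
    r = np.sqrt(sum(g.reshape([-1 if i == j else 1 for j in range(len(shape))]) ** 2
                    for i, g in enumerate(grids)))
    idx = np.rint(r).astype(int)
    return idx, min(shape) // 2


def _shell_correlation(f1: np.ndarray, f2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx, nshell = _shell_index(f1.shape)
    flat = idx.ravel()
    num = np.bincount(flat, weights=(f1 * np.conj(f2)).real.ravel())
    p1 = np.bincount(flat, weights=np.abs(f1.ravel()) ** 2)
    p2 = np.bincount(flat, weights=np.abs(f2.ravel()) ** 2)
    counts = np.bincount(flat)
    shells = np.arange(1, nshell + 1)
    denom = np.sqrt(p1[shells] * p2[shells])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, num[shells] / denom, 0.0)
    return np.clip(vals, -1.0, 1.0), counts[shells]


def fsc(half1, half2, mask: np.ndarray = None, pixel_size: float = None) -> FSCCurve:
    """Fourier shell correlation between two half-maps.

    An optional real-space mask (values in [0, 1]) is applied to both maps
    before transforming.  Shells are integer-radius bins; shell ``s`` of a
    box-``n`` map sits at frequency ``s / (n * pixel)`` 1/A.
    """
    a, b = _vol(half1), _vol(half2)
    if a.shape != b.shape:
        raise ValueError("half-maps must have identical shapes")
    if pixel_size is None:
        pixel_size = half1.pixel_size if isinstance(half1, Volume3D) else 1.0
    if mask is not None:
        mask = _vol(mask)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the half-maps")
        a, b = a * mask, b * mask
    f1, f2 = np.fft.fftn(a), np.fft.fftn(b)
    vals, counts = _shell_correlation(f1, f2)
    n = a.shape[0]
    shells = np.arange(1, len(vals) + 1)
    return FSCCurve(shells / (n * pixel_size), vals, counts, pixel_size, n)


def frc(img1: np.ndarray, img2: np.ndarray, pixel_size: float = 1.0) -> FSCCurve:
    """Fourier ring correlation between two 2D images (same binning rules)."""
    a, b = np.asarray(img1, float), np.asarray(img2, float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    vals, counts = _shell_correlation(np.fft.fft2(a), np.fft.fft2(b))
    n = a.shape[0]
    shells = np.arange(1, len(vals) + 1)
    return FSCCurve(shells / (n * pixel_size), vals, counts, pixel_size, n)


def volume_correct_fsc(curve: FSCCurve, v_mask: float, v_particle: float) -> FSCCurve:
    """Correct an FSC curve for the mask-to-particle volume ratio.

    A soft mask much larger than the particle dilutes correlated signal with
    uncorrelated solvent; with ``f = v_mask / v_particle`` the corrected
    per-shell value is ``f FSC / (1 + (f - 1) FSC)``, clamped to [-1, 1].
    Identity at f = 1; never decreases |FSC| for f > 1.  Non-positive shell
    values (noise) are passed through unchanged — the correction formula is
    derived for genuine shared signal and diverges as FSC approaches
    ``-1 / (f - 1)``.
    """
    if v_particle <= 0 or v_mask <= 0:
        raise ValueError("volumes must be positive")
    if v_mask < v_particle:
        raise ValueError("v_mask must be >= v_particle")
    f = v_mask / v_particle
    v = curve.values
    corrected = np.where(
        v > 0, np.clip(f * v / (1.0 + (f - 1.0) * v), -1.0, 1.0), v
    )
    return FSCCurve(curve.freq.copy(), corrected, curve.n_voxels.copy(),
                    curve.pixel_size, curve.box)


def resolution_at_threshold(curve: FSCCurve, threshold=0.143) -> float:
    """Resolution (A) where the curve first drops below the threshold.

    ``threshold`` may be a scalar (e.g. 0.143) or a per-shell array (e.g. the
    1/2-bit curve).  The crossing frequency is linearly interpolated between
    the bracketing shells; if the curve never crosses, the Nyquist-limited
    resolution ``2 * pixel_size`` is returned.
    """
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), curve.values.shape)
    diff = curve.values - thr
    below = np.nonzero(diff < 0)[0]
    if below.size == 0:
        return 2.0 * curve.pixel_size
    k = below[0]
    if k == 0:
        warnings.warn("curve is below threshold in the lowest-frequency shell")
        return 1.0 / curve.freq[0]
    f0, f1 = curve.freq[k - 1], curve.freq[k]
    d0, d1 = diff[k - 1], diff[k]
    fc = f0 + (f1 - f0) * d0 / (d0 - d1)
    return float(1.0 / fc)


def halfbit_curve(
    curve: FSCCurve,
    particle_diameter: float,
    symmetry_order: int = 1,
    box: int = None,
    pixel_size: float = None,
) -> np.ndarray:
    """Per-shell 1/2-bit significance threshold.

    The effective number of independent Fourier voxels per shell is reduced
    by the particle filling only part of the box and by imposed point-group
    symmetry: ``n_eff = n_voxels * (d / (box * pixel))^2 / symmetry``, clamped
    to >= 1.  The threshold is
    ``(0.2071 + 1.9102 / sqrt(n_eff)) / (1.2071 + 0.9102 / sqrt(n_eff))``,
    which tends to 1 as n_eff -> 1 and to 0.1716 as n_eff -> infinity.
    """
    box = box or curve.box
    pixel_size = pixel_size or curve.pixel_size
    if particle_diameter > box * pixel_size:
        raise ValueError("particle diameter exceeds the box")
    frac = particle_diameter / (box * pixel_size)
    n_eff = np.maximum(curve.n_voxels * frac**2 / symmetry_order, 1.0)
    rt = 1.0 / np.sqrt(n_eff)
    return (0.2071 + 1.9102 * rt) / (1.2071 + 0.9102 * rt)


_PLANES = {"xy": 0, "xz": 1, "yz": 2}


def directional_frc(half1, half2, plane: str = "xy") -> FSCCurve:
    """Ring correlation between matching central real-space slices.

    Extracts the central slice (index ``box // 2`` along the orthogonal axis)
    in the named plane from each half-map and computes the 2D FRC — a cheap
    probe of resolution anisotropy, e.g. the missing-cone smearing of planar
    samples along z.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    a, b = _vol(half1), _vol(half2)
    if a.shape != b.shape:
        raise ValueError("half-maps must have identical shapes")
    px = half1.pixel_size if isinstance(half1, Volume3D) else 1.0
    c = a.shape[0] // 2
    axis = _PLANES[plane]
    if axis == 0:  # xy plane: fix z
        s1, s2 = a[c], b[c]
    elif axis == 1:  # xz plane: fix y
        s1, s2 = a[:, c, :], b[:, c, :]
    else:  # yz plane: fix x
        s1, s2 = a[:, :, c], b[:, :, c]
    return frc(s1, s2, px)


def bfactor_sharpen(
    vol: Volume3D,
    bfactor: float,
    lowpass: float = None,
    edge_shells: float = 2.0,
) -> Volume3D:
    """Scale Fourier amplitudes by exp(-B s^2 / 4) and low-pass filter.

    Negative ``bfactor`` (A^2) sharpens.  ``lowpass`` is a resolution cutoff
    in A; the filter is 1 up to the cutoff frequency and falls as a cosine to
    0 over ``edge_shells`` Fourier shells beyond it.  A cutoff at (or beyond)
    Nyquist disables filtering entirely.
    """
    data = _vol(vol)
    px = vol.pixel_size if isinstance(vol, Volume3D) else 1.0
    n = data.shape[0]
    grids = [np.fft.fftfreq(m, d=px) for m in data.shape]
    s2 = sum(g.reshape([-1 if i == j else 1 for j in range(data.ndim)]) ** 2
             for i, g in enumerate(grids))
    s = np.sqrt(s2)
    filt = np.exp(-bfactor * s2 / 4.0)
    if lowpass is not None:
        if lowpass < 2 * px:
            raise ValueError("low-pass cutoff cannot be finer than Nyquist")
        s_cut = 1.0 / lowpass
        nyq = 1.0 / (2 * px)
        if s_cut < nyq:
            w = edge_shells / (n * px)
            lp = np.ones_like(s)
            fall = (s > s_cut) & (s < s_cut + w)
            lp[fall] = 0.5 * (1.0 + np.cos(np.pi * (s[fall] - s_cut) / w))
            lp[s >= s_cut + w] = 0.0
            filt = filt * lp
    out = np.fft.ifftn(np.fft.fftn(data) * filt).real
    return Volume3D(out, px)


def _index_matrix(m: np.ndarray) -> np.ndarray:
    """Convert a matrix acting on (x, y, z) to one acting on (z, y, x)."""
    return m[::-1, ::-1]


def project(vol, euler: EulerTriple, order: int = 1) -> np.ndarray:
    """Project a volume along z after resampling with the Euler rotation.

    Output pixel (y, x) integrates the density along the rotated z direction;
    trilinear (order=1) interpolation about the center ``n // 2`` (the same
    center the FFT-based machinery uses; identical to ``(n-1)/2`` for odd
    boxes, which is why phantoms default to odd boxes).
    """
    data = _vol(vol)
    n = data.shape[0]
    m = _index_matrix(euler.matrix())
    c = float(n // 2)
    center = np.full(3, c)
    rotated = ndimage.affine_transform(
        data, m, offset=center - m @ center, order=order, mode="constant", cval=0.0,
    )
    return rotated.sum(axis=0)


def backproject(
    images: np.ndarray,
    eulers: list,
    shifts: np.ndarray = None,
    pixel_size: float = 1.0,
) -> Volume3D:
    """Direct Fourier-inversion reconstruction from projections.

    Each image's 2D transform is inserted as a central slice of the 3D
    transform on the plane defined by its Euler triple (trilinear spreading);
    the accumulated grid is divided by the sampling weight and inverted.
    ``shifts`` (per image, in px, (dx, dy)) are removed with phase ramps
    before insertion — pass the sub-pixel remainders of windowed particles.
    This is a validation-grade reconstructor: no CTF weighting, no gridding
    kernel correction.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise ValueError("expected a stack of square images")
    nimg, n, _ = images.shape
    if len(eulers) != nimg:
        raise ValueError("one Euler triple per image required")
    # Centered frequency indices; object center assumed at n // 2.
    k = np.fft.fftshift(np.fft.fftfreq(n)) * n
    ky, kx = np.meshgrid(k, k, indexing="ij")
    kplane = np.stack([kx.ravel(), ky.ravel()], axis=1)

    acc = np.zeros((n, n, n), dtype=complex)
    wgt = np.zeros((n, n, n))
    half = n // 2
    for i in range(nimg):
        img = images[i]
        f2 = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        if shifts is not None:
            dx, dy = shifts[i]
            ramp = np.exp(2j * np.pi * (kx * dx + ky * dy) / n)
            f2 = f2 * ramp
        mmat = eulers[i].matrix()
        # 3D frequency of each in-plane frequency: kx * (M ex) + ky * (M ey)
        p3 = kplane @ np.stack([mmat[:, 0], mmat[:, 1]], axis=0)  # (n^2, 3) x,y,z
        # to (z, y, x) index order, origin at half
        coords = p3[:, ::-1] + half
        base = np.floor(coords).astype(int)
        frac = coords - base
        vals = f2.ravel()
        for dz in (0, 1):
            for dyy in (0, 1):
                for dxx in (0, 1):
                    w = (
                        (frac[:, 0] if dz else 1 - frac[:, 0])
                        * (frac[:, 1] if dyy else 1 - frac[:, 1])
                        * (frac[:, 2] if dxx else 1 - frac[:, 2])
                    )
                    iz, iy, ix = base[:, 0] + dz, base[:, 1] + dyy, base[:, 2] + dxx
                    ok = (
                        (iz >= 0) & (iz < n)
                        & (iy >= 0) & (iy < n)
                        & (ix >= 0) & (ix < n)
                        & (w > 0)
                    )
                    np.add.at(acc, (iz[ok], iy[ok], ix[ok]), vals[ok] * w[ok])
                    np.add.at(wgt, (iz[ok], iy[ok], ix[ok]), w[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(wgt > 1e-8, acc / np.maximum(wgt, 1e-8), 0.0)
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))).real
    return Volume3D(vol, pixel_size)
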