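"""Synthetic tilted, disordered 2D-crystal micrographs with full ground truth.

The generator emulates the imaging cascade of a membrane-protein 2D crystal:
a C4-symmetric phantom (standing in for a tetrameric channel) is tiled on a
real-space lattice, each unit cell is perturbed by in-plane positional
jitter and a small out-of-plane orientation wobble, the whole crystal is
tilted by a global tilt geometry which makes defocus vary linearly across
the image, a smooth out-of-plane height field ("membrane bumps") adds a
per-cell defocus offset, every cell projection is CTF-modulated with its own
local defocus, and Gaussian noise is added.  Every per-cell value that the
downstream pipeline tries to recover (center, Euler triple, defocus pair) is
recorded in a ground-truth table.

Random draw order (one seeded generator per render): phantom blobs first
(separate seed); then per crystal the height-field direction and phase; then
per unit cell in (h, k) lexicographic order an occupancy draw (consumed only
when occupancy < 1), then — for occupied cells only — jitter-x, jitter-y,
wobble axis, wobble magnitude; image noise last.  Identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctfgeom import CTFParams, EulerTriple, local_defocus, matrix_to_euler
from .maps import Volume3D, project, soft_spherical_mask
from .pick import Lattice2D

__all__ = [
    "PhantomSpec",
    "DisorderSpec",
    "GroundTruth",
    "make_phantom",
    "render_crystal",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the blob-built test protein.

    n_blobs Gaussian blobs of width ``blob_sigma`` px are scattered inside a
    soft support and replicated by ``symmetry_order`` rotations about z, so
    the volume is exactly invariant under rotation by 360/order degrees
    (exact on the voxel grid for orders 1, 2 and 4).  ``box`` is the cube
    side in voxels — odd boxes put the symmetry axis on a voxel center.
    """

    n_blobs: int = 6
    blob_sigma: float = 2.2
    blob_weights: tuple = None
    symmetry_order: int = 4
    box: int = 49
    pixel_size: float = 1.3
    blob_offsets: tuple = None  # optional explicit (dx, dy, dz) from center

    def __post_init__(self):
        if self.box <= 0:
            raise ValueError("box must be positive")
        if self.blob_sigma <= 0:
            raise ValueError("blob_sigma must be positive")
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")


@dataclass(frozen=True)
class DisorderSpec:
    """Per-unit-cell crystal disorder.

    inplane_sigma : std of lateral displacement (px)
    height_amplitude / height_wavelength : smooth out-of-plane displacement
        field, amplitude in A (rendered as a defocus offset) and wavelength
        in px
    wobble_sigma : std of per-cell out-of-plane tilt perturbation (deg)
    occupancy : probability that a unit cell carries a molecule; vacancies
        are not rendered and do not appear in the ground truth
    """

    inplane_sigma: float = 2.0
    height_amplitude: float = 0.0
    height_wavelength: float = 200.0
    wobble_sigma: float = 2.0
    occupancy: float = 1.0

    def __post_init__(self):
        if min(self.inplane_sigma, self.height_amplitude, self.wobble_sigma) < 0:
            raise ValueError("disorder magnitudes must be >= 0")
        if self.height_wavelength <= 0:
            raise ValueError("height_wavelength must be positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-unit-cell truth table plus the global lattice and tilt.

    ``table`` has one row per rendered unit cell with columns
    h, k, x, y (px, fractional), phi, theta, psi (deg), df1, df2 (A).
    """

    table: pd.DataFrame
    lattice: "Lattice2D"
    tilt: object
    lattice_image: "Lattice2D" = None
    noise_sigma: float = 0.0
    signal_var: float = 0.0


def make_phantom(spec: PhantomSpec, seed: int = 0) -> Volume3D:
    """Build the symmetric blob phantom.

    Blob centers are drawn inside a sphere of radius box/5 about the volume
    center (or taken from ``spec.blob_offsets``); each blob is evaluated
    analytically together with all its symmetry mates, so the symmetry is
    exact up to floating point.  The volume is apodized by a soft spherical
    support and mean-subtracted.
    """
    rng = np.random.default_rng(seed)
    n = spec.box
    c = (n - 1) / 2.0
    if spec.blob_offsets is not None:
        offsets = np.asarray(spec.blob_offsets, dtype=float).reshape(-1, 3)
    else:
        offsets = np.empty((spec.n_blobs, 3))
        rmax = n / 5.0
        for i in range(spec.n_blobs):
            while True:
                p = rng.uniform(-rmax, rmax, size=3)
                if np.linalg.norm(p) <= rmax:
                    offsets[i] = p
                    break
    weights = (
        np.asarray(spec.blob_weights, dtype=float)
        if spec.blob_weights is not None
        else np.ones(len(offsets))
    )
    if len(weights) != len(offsets):
        raise ValueError("blob_weights length must match n_blobs")

    zz, yy, xx = np.indices((n, n, n)).astype(float)
    vol = np.zeros((n, n, n))
    order = spec.symmetry_order
    for (dx, dy, dz), w in zip(offsets, weights):
        for k in range(order):
            ang = 2.0 * np.pi * k / order
            rx = dx * np.cos(ang) - dy * np.sin(ang)
            ry = dx * np.sin(ang) + dy * np.cos(ang)
            r2 = (xx - c - rx) ** 2 + (yy - c - ry) ** 2 + (zz - c - dz) ** 2
            vol += (w / order) * np.exp(-r2 / (2.0 * spec.blob_sigma**2))
    support = soft_spherical_mask(n, n / 2.0 - 2.0, 2.0)
    vol *= support
    vol -= vol.mean()
    return Volume3D(vol, spec.pixel_size)


def _wobble_matrix(axis_deg: float, mag_deg: float) -> np.ndarray:
    """Small out-of-plane rotation: tilt by mag about an in-plane axis."""
    from .ctfgeom import TiltGeometry

    return TiltGeometry(tltaxis=axis_deg, tltang=mag_deg, taxa=-axis_deg).matrix()


def render_crystal(
    phantom: Volume3D,
    lattice: Lattice2D,
    tilt,
    disorder: DisorderSpec,
    ctf: CTFParams,
    noise_sigma: float,
    image_size: int,
    seed: int,
    hk_max: int = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one micrograph of a tilted, disordered 2D crystal.

    ``lattice`` holds the crystal-plane lattice vectors; their image-plane
    appearance (compressed by cos(tltang) perpendicular to the tilt axis,
    the measured quantity on real data) is returned in
    ``GroundTruth.lattice_image``.  Each unit cell at its image lattice
    position (+ jitter) is
    projected with its own orientation (per-cell wobble composed onto the
    global tilt), CTF-modulated with the defocus of its own position on the
    tilted plane (plus the local height-field offset), pasted into the image,
    and Gaussian noise of std ``noise_sigma`` is added.  Cells whose phantom
    box would cross the image border are not rendered and do not appear in
    the ground truth.  ``hk_max`` limits the crystal to lattice indices
    ``|h|, |k| <= hk_max`` (a finite crystal patch); None tiles the whole
    image.
    """
    a_cry = np.asarray(lattice.a_vec, dtype=float)
    b_cry = np.asarray(lattice.b_vec, dtype=float)
    if abs(a_cry[0] * b_cry[1] - a_cry[1] * b_cry[0]) < 1e-9:
        raise ValueError("lattice vectors must be linearly independent")
    box = phantom.box
    if image_size < box:
        raise ValueError("image_size must be at least the phantom box")

    # Tilt foreshortening of the lattice: the crystal-plane vectors appear in
    # the image compressed by cos(tltang) perpendicular to the tilt axis,
    # with the a vector rotated by taxa away from the axis.
    axr = np.deg2rad(tilt.tltaxis)
    txr = np.deg2rad(tilt.taxa)
    rot_ax = np.array([[np.cos(axr), -np.sin(axr)], [np.sin(axr), np.cos(axr)]])
    rot_taxa = np.array([[np.cos(txr), -np.sin(txr)], [np.sin(txr), np.cos(txr)]])
    compress = np.diag([1.0, np.cos(np.deg2rad(tilt.tltang))])
    proj2 = rot_ax @ compress @ rot_taxa
    a = proj2 @ a_cry
    b = proj2 @ b_cry
    lattice_image = Lattice2D(
        tuple(a), tuple(b), tuple(lattice.origin), lattice.crystal_id
    )

    rng = np.random.default_rng(seed)
    # crystal-level height field draws come first
    hdir = rng.uniform(0.0, 2.0 * np.pi)
    hphase = rng.uniform(0.0, 2.0 * np.pi)
    ux, uy = np.cos(hdir), np.sin(hdir)

    ainv = np.linalg.inv(np.stack([a, b], axis=1))
    corners = np.array(
        [[0, 0], [image_size, 0], [0, image_size], [image_size, image_size]],
        dtype=float,
    )
    hk = (corners - np.asarray(lattice.origin, dtype=float)) @ ainv.T
    hmin, kmin = np.floor(hk.min(axis=0)).astype(int) - 1
    hmax, kmax = np.ceil(hk.max(axis=0)).astype(int) + 1
    if hk_max is not None:
        hmin, kmin = max(hmin, -hk_max), max(kmin, -hk_max)
        hmax, kmax = min(hmax, hk_max), min(kmax, hk_max)

    r_global = tilt.matrix()
    image = np.zeros((image_size, image_size))
    rows = []
    half = box // 2
    # CTF modulation happens in a padded box so the oscillatory point-spread
    # tails are not wrapped circularly into the tiny unit-cell patch
    pad_box = box + 64
    pad_half = pad_box // 2
    pad_lo = pad_half - half
    kfy = np.fft.fftfreq(pad_box)[:, None]
    kfx = np.fft.fftfreq(pad_box)[None, :]
    center_img = image_size / 2.0

    proj_cache: dict = {}
    for h in range(hmin, hmax + 1):
        for k in range(kmin, kmax + 1):
            if disorder.occupancy < 1.0 and rng.uniform() >= disorder.occupancy:
                continue
            base = np.asarray(lattice.origin, dtype=float) + h * a + k * b
            jx = rng.normal(0.0, disorder.inplane_sigma) if disorder.inplane_sigma else 0.0
            jy = rng.normal(0.0, disorder.inplane_sigma) if disorder.inplane_sigma else 0.0
            waxis = rng.uniform(0.0, 360.0)
            wmag = rng.normal(0.0, disorder.wobble_sigma) if disorder.wobble_sigma else 0.0
            x, y = base[0] + jx, base[1] + jy
            xi, yi = int(np.floor(x)), int(np.floor(y))
            if xi - half < 0 or yi - half < 0:
                continue
            if xi - half + box > image_size or yi - half + box > image_size:
                continue

            if wmag:
                r_cell = _wobble_matrix(waxis, wmag) @ r_global
            else:
                r_cell = r_global
            euler = matrix_to_euler(r_cell)

            key = (round(euler.phi, 3), round(euler.theta, 3), round(euler.psi, 3))
            if key in proj_cache:
                proj = proj_cache[key]
            else:
                proj = project(phantom.data, euler)
                proj_cache[key] = proj

            height = disorder.height_amplitude * np.sin(
                2.0 * np.pi * (x * ux + y * uy) / disorder.height_wavelength + hphase
            )
            ctf_cell = local_defocus(
                ctf, tilt, x - center_img, y - center_img, phantom.pixel_size
            ).with_defocus_offset(float(height))

            # CTF modulation and sub-pixel placement in one FFT round trip.
            # The projection center box//2 must land at image position
            # (x, y); the padded patch is clip-pasted around it.
            sx = x - xi  # sub-pixel remainder
            sy = y - yi
            from .ctfgeom import ctf_grid

            padded = np.zeros((pad_box, pad_box))
            padded[pad_lo : pad_lo + box, pad_lo : pad_lo + box] = proj
            ft = np.fft.fft2(padded)
            ft *= ctf_grid((pad_box, pad_box), phantom.pixel_size, ctf_cell)
            ft *= np.exp(-2j * np.pi * (kfx * sx + kfy * sy))
            patch = np.fft.ifft2(ft).real

            y0, x0 = yi - pad_half, xi - pad_half
            dy0, dy1 = max(y0, 0), min(y0 + pad_box, image_size)
            dx0, dx1 = max(x0, 0), min(x0 + pad_box, image_size)
            image[dy0:dy1, dx0:dx1] += patch[dy0 - y0 : dy1 - y0, dx0 - x0 : dx1 - x0]
            rows.append(
                dict(
                    h=h, k=k, x=x, y=y,
                    phi=euler.phi, theta=euler.theta, psi=euler.psi,
                    df1=ctf_cell.df1, df2=ctf_cell.df2,
                )
            )

    signal_var = float(image.var())
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    truth = GroundTruth(
        pd.DataFrame(rows), lattice, tilt, lattice_image=lattice_image,
        noise_sigma=noise_sigma, signal_var=signal_var,
    )
    return image, truth
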