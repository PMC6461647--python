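"""Tilt geometry, Euler angle conventions, and contrast transfer function models.

A 2D crystal in the microscope is described by three angles (the 2dx/TLTAXIS
parameterization): ``tltaxis`` is the direction of the tilt axis in the image
plane (degrees, counter-clockwise from the image x axis), ``tltang`` is the
tilt magnitude about that axis, and ``taxa`` is the angle between the tilt
axis and the crystal *a* lattice vector measured in the crystal plane.  Every
unit cell of a tilted crystal therefore shares one projection direction, and
its defocus varies linearly with position across the image.

Euler angles use the ZYZ intrinsic convention: ``matrix(phi, theta, psi) =
Rz(phi) @ Ry(theta) @ Rz(psi)`` acting on (x, y, z) column vectors, with
theta in [0, 180].  This is the ordering used by the FREALIGN/RELION family
of single-particle packages.  Defocus is underfocus-positive, in Angstrom.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TiltGeometry",
    "CTFParams",
    "EulerTriple",
    "euler_to_matrix",
    "matrix_to_euler",
    "tilt_to_euler",
    "local_defocus",
    "electron_wavelength",
    "ctf_eval",
    "ctf_grid",
    "ctf_correct",
]


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class TiltGeometry:
    """Crystal tilt parameterization (degrees)."""

    tltaxis: float = 0.0
    tltang: float = 0.0
    taxa: float = 0.0

    def __post_init__(self):
        if not -90.0 <= self.tltang <= 90.0:
            raise ValueError(f"tltang must be in [-90, 90], got {self.tltang}")

    def matrix(self) -> np.ndarray:
        """Rotation matrix Rz(-tltaxis) @ Ry(tltang) @ Rz(tltaxis + taxa)."""
        return _rz(-self.tltaxis) @ _ry(self.tltang) @ _rz(self.tltaxis + self.taxa)


@dataclass(frozen=True)
class CTFParams:
    """Microscope CTF parameters.

    df1, df2 : defocus along/perpendicular to the astigmatism axis
        (Angstrom, underfocus positive, df1 >= df2)
    ast_angle : angle of the df1 axis (degrees)
    voltage : acceleration voltage (kV)
    cs : spherical aberration (mm)
    amp_contrast : amplitude contrast fraction in [0, 1]
    phase_shift : additional phase shift, e.g. from a phase plate (degrees)
    """

    df1: float
    df2: float
    ast_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7
    amp_contrast: float = 0.07
    phase_shift: float = 0.0

    def __post_init__(self):
        if self.df1 < self.df2:
            raise ValueError(f"df1 ({self.df1}) must be >= df2 ({self.df2})")
        if not 0.0 <= self.amp_contrast <= 1.0:
            raise ValueError("amp_contrast must be in [0, 1]")

    def with_defocus_offset(self, dz: float) -> "CTFParams":
        """Both defoci offset by dz (Angstrom); astigmatism unchanged."""
        return dataclasses.replace(self, df1=self.df1 + dz, df2=self.df2 + dz)


@dataclass(frozen=True)
class EulerTriple:
    """ZYZ intrinsic Euler angles in degrees, theta in [0, 180]."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.phi, self.theta, self.psi)


def euler_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix Rz(phi) @ Ry(theta) @ Rz(psi) on (x, y, z) vectors."""
    return _rz(phi) @ _ry(theta) @ _rz(psi)


def matrix_to_euler(m: np.ndarray) -> EulerTriple:
    """Decompose a proper rotation into ZYZ Euler angles.

    Degenerate theta = 0 / 180 cases put the whole in-plane rotation into
    phi (psi = 0), the standard gimbal-lock convention.
    """
    m = np.asarray(m, dtype=float)
    ct = float(np.clip(m[2, 2], -1.0, 1.0))
    theta = np.rad2deg(np.arccos(ct))
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    if st > 1e-9:
        phi = np.rad2deg(np.arctan2(m[1, 2], m[0, 2]))
        psi = np.rad2deg(np.arctan2(m[2, 1], -m[2, 0]))
    elif ct > 0:  # theta ~ 0: m is Rz(phi + psi)
        phi = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        psi = 0.0
    else:  # theta ~ 180: m is Rz(phi - psi) @ Ry(180)
        phi = np.rad2deg(np.arctan2(-m[1, 0], -m[0, 0]))
        psi = 0.0
    return EulerTriple(phi, theta, psi)


def tilt_to_euler(t: TiltGeometry) -> EulerTriple:
    """Euler angles of the projection direction implied by crystal tilt.

    The triple satisfies matrix(tilt_to_euler(t)) == t.matrix() to numerical
    precision; all unit cells of a rigid tilted crystal share it.
    """
    return matrix_to_euler(t.matrix())


def local_defocus(
    center_ctf: CTFParams,
    t: TiltGeometry,
    dx: float,
    dy: float,
    pixel: float,
) -> CTFParams:
    """Defocus at a particle offset (dx, dy) px from the micrograph center.

    The specimen is a plane tilted by ``tltang`` about an axis at ``tltaxis``;
    the height of a point above that axis is its signed in-plane distance from
    the axis times tan(tltang).  Both defoci are offset by

        dz = tan(tltang) * (-dx sin(tltaxis) + dy cos(tltaxis)) * pixel

    (Angstrom); astigmatism magnitude and angle are inherited unchanged.
    The sign convention makes defocus increase on the side of the axis with
    positive perpendicular coordinate for positive tilt.
    """
    if pixel <= 0:
        raise ValueError("pixel size must be positive")
    if abs(t.tltang) >= 90.0:
        raise ValueError("|tltang| must be < 90 degrees for a finite defocus gradient")
    ax = np.deg2rad(t.tltaxis)
    dz = np.tan(np.deg2rad(t.tltang)) * (-dx * np.sin(ax) + dy * np.cos(ax)) * pixel
    return center_ctf.with_defocus_offset(float(dz))


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def _defocus_at(p: CTFParams, alpha_rad):
    """Astigmatic defocus z(alpha): mean plus cos(2(alpha - ast)) modulation."""
    ast = np.deg2rad(p.ast_angle)
    return 0.5 * (
        p.df1 + p.df2 + (p.df1 - p.df2) * np.cos(2.0 * (alpha_rad - ast))
    )


def ctf_eval(s, alpha, p: CTFParams):
    """CTF value at spatial frequency s (1/A) and direction alpha (deg).

    Returns -[sqrt(1 - A^2) sin(chi) + A cos(chi)] with
    chi = pi lambda z s^2 - (pi/2) Cs lambda^3 s^4 + phase_shift.
    At s = 0 this is -A; values lie in [-1, 1].  Accepts arrays.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("spatial frequency must be >= 0")
    lam = electron_wavelength(p.voltage)
    cs_a = p.cs * 1e7  # mm -> Angstrom
    z = _defocus_at(p, np.deg2rad(np.asarray(alpha, dtype=float)))
    chi = (
        np.pi * lam * z * s**2
        - 0.5 * np.pi * cs_a * lam**3 * s**4
        + np.deg2rad(p.phase_shift)
    )
    a = p.amp_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_grid(shape: tuple, pixel: float, p: CTFParams) -> np.ndarray:
    """CTF evaluated on the 2D FFT frequency grid of an image.

    ``shape`` is (ny, nx) of the real image; the result matches the layout of
    ``np.fft.fft2`` (unshifted).  ``pixel`` is the sampling in A/px.
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel)[:, None]
    fx = np.fft.fftfreq(nx, d=pixel)[None, :]
    s = np.hypot(fx, fy)
    alpha = np.rad2deg(np.arctan2(fy, fx))
    c = ctf_eval(s, alpha, p)
    # the direction of a folded Nyquist frequency is ambiguous (+/- f_Nyq are
    # the same bin); averaging with the Friedel partner restores the exact
    # conjugate symmetry a real image requires
    ky, kx = np.indices(shape)
    return 0.5 * (c + c[(-ky) % ny, (-kx) % nx])


_CTF_MODES = ("phaseflip", "multiply", "wiener")


def ctf_correct(
    particle_ft: np.ndarray,
    p: CTFParams,
    mode: str,
    pixel: float,
    wiener_c: float = 0.1,
) -> np.ndarray:
    """Apply a CTF correction to a particle's 2D Fourier transform.

    mode 'phaseflip' multiplies by sign(CTF), 'multiply' by CTF, and 'wiener'
    by CTF / (CTF^2 + wiener_c).  The DC component is treated like any other
    frequency using CTF(0) = -amp_contrast.  The amplitude spectrum is exactly
    preserved by phase flipping, and all modes keep Friedel symmetry so the
    corrected image stays real.
    """
    if mode not in _CTF_MODES:
        raise ValueError(f"unknown CTF correction mode {mode!r}; choose from {_CTF_MODES}")
    c = ctf_grid(particle_ft.shape, pixel, p)
    if mode == "phaseflip":
        return particle_ft * np.sign(c)
    if mode == "multiply":
        return particle_ft * c
    if wiener_c <= 0:
        raise ValueError("wiener_c must be positive")
    return particle_ft * (c / (c * c + wiener_c))
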