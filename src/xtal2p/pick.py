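"""Unit-cell particle picking from 2D crystal micrographs.

The crystallographic unbending idea re-cast for single-particle work: unit
cell positions are predicted from the lattice vectors and phase origin,
refined against a normalized cross-correlation map of the micrograph with a
reference patch, selected by a CC threshold (default: the micrograph's mean
peak value), optionally shifted by a fraction of a unit cell (a 180 deg
phase-origin shift puts a protein instead of a fourfold axis at the box
center), and windowed into a particle stack.

Coordinates are 0-based pixels with position (x, y) mapping to
``micrograph[y, x]``; a box of side ``b`` around center ``x`` covers the
half-open window ``[floor(x) - b//2, floor(x) - b//2 + b)`` and the
sub-pixel remainder ``x - floor(x)`` is carried in the particle record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

__all__ = [
    "Lattice2D",
    "CCProfile",
    "PickSet",
    "SecondLatticeError",
    "compute_cc_map",
    "predict_positions",
    "select_peaks",
    "shift_phase_origin",
    "window_particles",
    "build_reference",
    "pick_micrograph",
]


class SecondLatticeError(ValueError):
    """Raised when more than one lattice is supplied for a micrograph.

    Overlapping lattices in one image would duplicate particles and inflate
    resolution estimates, so the pipeline accepts exactly one lattice per
    micrograph and rejects the rest explicitly.
    """


@dataclass(frozen=True)
class Lattice2D:
    """Real-space lattice vectors and phase origin of one crystal."""

    a_vec: tuple
    b_vec: tuple
    origin: tuple
    crystal_id: str = "xtal0"

    def __post_init__(self):
        a, b = np.asarray(self.a_vec, float), np.asarray(self.b_vec, float)
        if abs(a[0] * b[1] - a[1] * b[0]) < 1e-9:
            raise ValueError("degenerate lattice: a_vec and b_vec are parallel")


@dataclass
class CCProfile:
    """Normalized cross-correlation map plus located lattice peaks."""

    map: np.ndarray
    peaks: list = field(default_factory=list)  # (x, y, cc, h, k)


@dataclass
class PickSet:
    """Selected unit-cell positions for one crystal."""

    positions: np.ndarray  # (n, 2) float, (x, y)
    cc: np.ndarray
    hk: np.ndarray  # (n, 2) int
    crystal_id: str
    box_size: int
    dropped_edge: int = 0

    def __len__(self):
        return len(self.positions)


def compute_cc_map(micrograph: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of the micrograph with a reference patch.

    Local (per-window) mean and variance normalization, computed via FFT
    correlation; the value at (y, x) is the correlation coefficient of the
    reference with the micrograph patch centered there, in [-1, 1].
    """
    micrograph = np.asarray(micrograph, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] > micrograph.shape[0] or reference.shape[1] > micrograph.shape[1]:
        raise ValueError("reference must not be larger than the micrograph")
    if reference.std() == 0:
        raise ValueError("reference has zero variance; correlation is undefined")
    cc = match_template(micrograph, reference, pad_input=True)
    return np.clip(cc.astype(float), -1.0, 1.0)


def predict_positions(
    lattice: Lattice2D, image_size: int, box_size: int
) -> np.ndarray:
    """All lattice positions origin + h a + k b boxable inside the image.

    Returns an array of rows (h, k, x, y); a position is boxable when
    ``box/2 <= x, y <= image_size - box/2``.
    """
    a = np.asarray(lattice.a_vec, float)
    b = np.asarray(lattice.b_vec, float)
    o = np.asarray(lattice.origin, float)
    ainv = np.linalg.inv(np.stack([a, b], axis=1))
    corners = np.array(
        [[0, 0], [image_size, 0], [0, image_size], [image_size, image_size]], float
    )
    hk = (corners - o) @ ainv.T
    hmin, kmin = np.floor(hk.min(axis=0)).astype(int) - 1
    hmax, kmax = np.ceil(hk.max(axis=0)).astype(int) + 1
    rows = []
    lo, hi = box_size / 2.0, image_size - box_size / 2.0
    for h in range(hmin, hmax + 1):
        for k in range(kmin, kmax + 1):
            p = o + h * a + k * b
            if lo <= p[0] <= hi and lo <= p[1] <= hi:
                rows.append((h, k, p[0], p[1]))
    return np.array(rows, dtype=float).reshape(-1, 4)


def _parabolic_refine(cc: np.ndarray, iy: int, ix: int) -> tuple[float, float, float]:
    """Sub-pixel peak position from a separable parabola on the 3x3 patch."""

    def offset(vm, v0, vp):
        denom = vm - 2 * v0 + vp
        if denom >= 0:  # not a maximum; keep integer position
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    ny, nx = cc.shape
    dx = dy = 0.0
    if 0 < ix < nx - 1:
        dx = offset(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    if 0 < iy < ny - 1:
        dy = offset(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    return ix + dx, iy + dy, float(cc[iy, ix])


def select_peaks(
    cc: np.ndarray | CCProfile,
    predicted: np.ndarray,
    search_radius: float = 5.0,
    threshold="mean",
    box_size: int = None,
    crystal_id: str = "xtal0",
) -> PickSet:
    """Refine predicted positions against the CC map and apply the threshold.

    For each predicted lattice position the CC maximum within
    ``search_radius`` px is located and refined to sub-pixel precision with a
    parabolic fit.  Peaks with cc >= threshold are kept, where the default
    threshold mode ``"mean"`` is the mean of all found peak values for this
    micrograph; a float applies a fixed cutoff.  Refined peaks whose box
    would leave the image are dropped and counted.
    """
    ccmap = cc.map if isinstance(cc, CCProfile) else np.asarray(cc, float)
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    predicted = np.asarray(predicted, float).reshape(-1, 4)
    if box_size is None:
        box_size = 0
    if len(predicted) == 0:
        warnings.warn("no predicted positions; returning an empty pick set")
        return PickSet(
            np.empty((0, 2)), np.empty(0), np.empty((0, 2), int),
            crystal_id, box_size,
        )

    ny, nx = ccmap.shape
    r = int(np.ceil(search_radius))
    found = []
    for h, k, px, py in predicted:
        x0, y0 = int(round(px)), int(round(py))
        xs, xe = max(x0 - r, 0), min(x0 + r + 1, nx)
        ys, ye = max(y0 - r, 0), min(y0 + r + 1, ny)
        if xs >= xe or ys >= ye:
            continue
        win = ccmap[ys:ye, xs:xe].copy()
        wy, wx = np.indices(win.shape)
        dist2 = (wx + xs - px) ** 2 + (wy + ys - py) ** 2
        win[dist2 > search_radius**2] = -np.inf
        if not np.isfinite(win).any():
            continue
        iy, ix = np.unravel_index(np.argmax(win), win.shape)
        fx, fy, val = _parabolic_refine(ccmap, iy + ys, ix + xs)
        found.append((fx, fy, val, int(h), int(k)))

    found = np.array(found, float).reshape(-1, 5)
    if threshold == "mean":
        thr = float(found[:, 2].mean()) if len(found) else 0.0
    else:
        thr = float(threshold)
    # >= with a float-jitter guard so exactly-equal peak sets are all kept
    keep = found[:, 2] >= thr - 1e-9 * max(1.0, abs(thr))
    found = found[keep]

    dropped = 0
    if box_size:
        half = box_size // 2
        xi = np.floor(found[:, 0]).astype(int)
        yi = np.floor(found[:, 1]).astype(int)
        inside = (
            (xi - half >= 0) & (yi - half >= 0)
            & (xi - half + box_size <= nx) & (yi - half + box_size <= ny)
        )
        dropped = int((~inside).sum())
        found = found[inside]

    # de-duplicate peaks that converged to the same position
    if len(found):
        order = np.argsort(-found[:, 2], kind="stable")
        found = found[order]
        rounded = np.round(found[:, :2]).astype(int)
        _, first = np.unique(rounded, axis=0, return_index=True)
        found = found[np.sort(first)]

    return PickSet(
        positions=found[:, :2].copy(),
        cc=found[:, 2].copy(),
        hk=found[:, 3:5].astype(int),
        crystal_id=crystal_id,
        box_size=box_size,
        dropped_edge=dropped,
    )


def shift_phase_origin(
    pick: PickSet,
    lattice: Lattice2D,
    frac: tuple,
    image_shape: tuple = None,
) -> PickSet:
    """Translate every pick by ``fa * a_vec + fb * b_vec``.

    ``frac = (0.5, 0)`` is the 180 deg phase-origin shift along the first
    lattice vector that re-centers boxes on a molecule half a unit cell away
    from the crystallographic origin.  Boxes that leave the image after the
    shift are dropped and counted in ``dropped_edge``.
    """
    fa, fb = frac
    if not (-1.0 <= fa <= 1.0 and -1.0 <= fb <= 1.0):
        raise ValueError("frac components must be in [-1, 1]")
    shift = fa * np.asarray(lattice.a_vec, float) + fb * np.asarray(lattice.b_vec, float)
    pos = pick.positions + shift
    cc, hk = pick.cc, pick.hk
    dropped = pick.dropped_edge
    if image_shape is not None and pick.box_size:
        ny, nx = image_shape
        half = pick.box_size // 2
        xi, yi = np.floor(pos[:, 0]).astype(int), np.floor(pos[:, 1]).astype(int)
        inside = (
            (xi - half >= 0) & (yi - half >= 0)
            & (xi - half + pick.box_size <= nx) & (yi - half + pick.box_size <= ny)
        )
        dropped += int((~inside).sum())
        pos, cc, hk = pos[inside], cc[inside], hk[inside]
    return PickSet(pos, cc.copy(), hk.copy(), pick.crystal_id, pick.box_size, dropped)


def window_particles(
    micrograph: np.ndarray,
    pick: PickSet,
    box: int,
    pixel_size: float = 1.0,
    micrograph_name: str = "micrograph",
):
    """Window one box per pick into a particle stack.

    Extraction is a pure pixel copy over the half-open window
    ``[floor(x) - box/2, floor(x) + box/2)``; the sub-pixel remainder of the
    center is stored in each record for downstream Fourier-space shifts.
    Stack order matches pick order; overlapping boxes share identical pixels.
    """
    from .stack import ParticleRecord, ParticleStack

    if box % 2:
        raise ValueError("box size must be even")
    micrograph = np.asarray(micrograph, dtype=float)
    ny, nx = micrograph.shape
    half = box // 2
    images = np.empty((len(pick), box, box))
    records = []
    for i, ((x, y), cc_val, (h, k)) in enumerate(
        zip(pick.positions, pick.cc, pick.hk)
    ):
        xi, yi = int(np.floor(x)), int(np.floor(y))
        if xi - half < 0 or yi - half < 0 or xi + half > nx or yi + half > ny:
            raise ValueError("pick box exceeds the micrograph; PickSet invariant broken")
        images[i] = micrograph[yi - half : yi + half, xi - half : xi + half]
        records.append(
            ParticleRecord(
                particle_id=i,
                crystal_id=pick.crystal_id,
                micrograph=micrograph_name,
                x=float(x), y=float(y),
                rx=float(x - xi), ry=float(y - yi),
                cc=float(cc_val), h=int(h), k=int(k),
            )
        )
    return ParticleStack(images=images, records=records, pixel_size=pixel_size)


def build_reference(
    micrograph: np.ndarray,
    lattice: Lattice2D,
    box: int,
    lowpass_frac: float = 0.25,
) -> np.ndarray:
    """First-pass CC reference: average of patches at predicted positions.

    Patches are extracted at the unrefined lattice positions, averaged, and
    low-pass filtered (cosine edge at ``lowpass_frac`` of Nyquist) — a cheap
    stand-in for the Fourier-filtered lattice average of classical
    unbending.  One unit cell is the default reference size.
    """
    micrograph = np.asarray(micrograph, dtype=float)
    predicted = predict_positions(lattice, micrograph.shape[0], box)
    if len(predicted) == 0:
        raise ValueError("no boxable lattice positions for the reference")
    half = box // 2
    acc = np.zeros((box, box))
    n = 0
    for _, _, x, y in predicted:
        xi, yi = int(np.floor(x)), int(np.floor(y))
        acc += micrograph[yi - half : yi + half + (box % 2),
                          xi - half : xi + half + (box % 2)][:box, :box]
        n += 1
    avg = acc / n
    fy = np.fft.fftfreq(box)[:, None]
    fx = np.fft.fftfreq(box)[None, :]
    s = np.hypot(fx, fy)  # cycles/px, Nyquist 0.5
    cut = 0.5 * lowpass_frac
    w = 0.5 * cut
    filt = np.ones_like(s)
    fall = (s > cut) & (s < cut + w)
    filt[fall] = 0.5 * (1 + np.cos(np.pi * (s[fall] - cut) / w))
    filt[s >= cut + w] = 0.0
    return np.fft.ifft2(np.fft.fft2(avg) * filt).real


def pick_micrograph(
    micrograph: np.ndarray,
    lattice,
    box: int,
    reference: np.ndarray = None,
    search_radius: float = 5.0,
    threshold="mean",
    frac_shift: tuple = (0.0, 0.0),
) -> PickSet:
    """Full picking pass for one micrograph and exactly one lattice.

    Passing more than one lattice raises :class:`SecondLatticeError` — images
    carrying a second lattice must be excluded to avoid duplicated particles.
    """
    if isinstance(lattice, (list, tuple)):
        if len(lattice) != 1:
            raise SecondLatticeError(
                f"{len(lattice)} lattices supplied; exactly one lattice per "
                "micrograph is allowed"
            )
        lattice = lattice[0]
    micrograph = np.asarray(micrograph, dtype=float)
    ref_box = min(box, *(int(round(np.linalg.norm(v)))
                         for v in (lattice.a_vec, lattice.b_vec)))
    ref_box -= ref_box % 2
    if reference is None:
        reference = build_reference(micrograph, lattice, ref_box)
    ccmap = compute_cc_map(micrograph, reference)
    predicted = predict_positions(lattice, micrograph.shape[0], box)
    picks = select_peaks(
        ccmap, predicted, search_radius, threshold, box, lattice.crystal_id
    )
    if frac_shift != (0.0, 0.0):
        picks = shift_phase_origin(picks, lattice, frac_shift, micrograph.shape)
    return picks
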