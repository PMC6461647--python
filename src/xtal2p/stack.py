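"""Particle stacks and refinement-ready metadata.

Half-set bookkeeping is crystal-aware: boxes windowed from one 2D crystal
overlap heavily, so letting one crystal straddle both half-sets would make
the two "independent" reconstructions share pixels and inflate the FSC.
All particles of a crystal therefore go to the same half-set, with crystals
balanced greedily (largest first) between the halves.

Metadata exports: a RELION-flavoured STAR writer (full-precision floats,
bit-identical round trip) and a fixed-width FREALIGN v9 PAR writer (FILM =
crystal index; round-trips to the printed precision of the format).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ctfgeom import CTFParams, EulerTriple, ctf_correct
from .maps import Volume3D, project
from . import io as xio

__all__ = [
    "ParticleRecord",
    "ParticleStack",
    "assign_halfsets",
    "crystal_average",
    "phase_flip_stack",
    "fourier_crop",
    "subtract_neighbors",
    "export_star",
    "read_star",
    "export_par",
    "read_par",
]


@dataclass
class ParticleRecord:
    """Everything known about one windowed unit-cell patch."""

    particle_id: int
    crystal_id: str
    micrograph: str = "micrograph"
    x: float = 0.0
    y: float = 0.0
    rx: float = 0.0  # sub-pixel remainder of the center, [0, 1)
    ry: float = 0.0
    euler: EulerTriple = field(default_factory=EulerTriple)
    ctf: CTFParams = None
    cc: float = 0.0
    halfset: int = 0  # 0 = unassigned, else 1 or 2
    h: int = 0
    k: int = 0


@dataclass
class ParticleStack:
    """Aligned images and records; uniform box, one pixel size."""

    images: np.ndarray  # (n, box, box)
    records: list
    pixel_size: float = 1.0

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a stack of square boxes")
        if len(self.records) != len(self.images):
            raise ValueError("records and images must have the same length")

    @property
    def box(self) -> int:
        return self.images.shape[1]

    def __len__(self):
        return len(self.records)


def assign_halfsets(records: list) -> list:
    """Assign crystal-aware half-sets, greedily balancing particle counts.

    Crystals are sorted by descending particle count (ties by crystal id) and
    each goes to the currently smaller half-set; every record of a crystal
    shares one half-set.  Returns new records; input order is preserved.
    """
    counts: dict = {}
    for r in records:
        counts[r.crystal_id] = counts.get(r.crystal_id, 0) + 1
    order = sorted(counts, key=lambda cid: (-counts[cid], str(cid)))
    totals = {1: 0, 2: 0}
    side: dict = {}
    for cid in order:
        h = 1 if totals[1] <= totals[2] else 2
        side[cid] = h
        totals[h] += counts[cid]
    if len(counts) < 2:
        warnings.warn(
            "only one crystal present: both half-sets cannot be independent; "
            "FSC on this split is not meaningful"
        )
    return [replace(r, halfset=side[r.crystal_id]) for r in records]


def _subpixel_shift(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Shift an image by (dx, dy) px with a Fourier phase ramp (circular)."""
    ny, nx = img.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    ramp = np.exp(-2j * np.pi * (fx * dx + fy * dy))
    return np.fft.ifft2(np.fft.fft2(img) * ramp).real


def crystal_average(stack: ParticleStack, crystal_id: str) -> tuple[np.ndarray, int]:
    """Mean of all particles of one crystal after sub-pixel re-centering.

    Each image is shifted by minus its stored sub-pixel remainder (Fourier
    phase ramp) so all unit-cell centers coincide at pixel box//2 before
    averaging.  Callers wanting the classical correlation average should
    phase-flip the stack first (see :func:`phase_flip_stack`).  Returns
    (average, particle count); zero particles is an error.
    """
    idx = [i for i, r in enumerate(stack.records) if r.crystal_id == crystal_id]
    if not idx:
        raise ValueError(f"no particles for crystal {crystal_id!r}")
    acc = np.zeros((stack.box, stack.box))
    for i in idx:
        r = stack.records[i]
        acc += _subpixel_shift(stack.images[i], -r.rx, -r.ry)
    return acc / len(idx), len(idx)


def phase_flip_stack(stack: ParticleStack) -> ParticleStack:
    """CTF-correct every particle by phase flipping with its local CTF."""
    out = np.empty_like(stack.images)
    for i, r in enumerate(stack.records):
        if r.ctf is None:
            raise ValueError(f"particle {r.particle_id} has no CTF parameters")
        ft = np.fft.fft2(stack.images[i])
        out[i] = np.fft.ifft2(
            ctf_correct(ft, r.ctf, "phaseflip", stack.pixel_size)
        ).real
    return ParticleStack(out, list(stack.records), stack.pixel_size)


def _crop_ft(arr: np.ndarray, new_n: int) -> np.ndarray:
    """Central Fourier crop of a square/cubic array to side new_n."""
    nd = arr.ndim
    old_n = arr.shape[0]
    ft = np.fft.fftshift(np.fft.fftn(arr))
    lo = old_n // 2 - new_n // 2
    sl = tuple(slice(lo, lo + new_n) for _ in range(nd))
    cropped = ft[sl]
    scale = (new_n / old_n) ** nd
    return np.fft.ifftn(np.fft.ifftshift(cropped)).real * scale


def fourier_crop(obj, old_pixel: float, new_pixel: float):
    """Downsample by retaining the central region of the Fourier transform.

    Works on a 2D image, a 3D volume, or an image stack (first axis = index).
    The new box is ``old_box * old_pixel / new_pixel`` and must come out an
    even integer; the image mean (DC term) is preserved exactly.
    """
    if new_pixel < old_pixel:
        raise ValueError("new_pixel must be >= old_pixel (downsampling only)")
    if isinstance(obj, ParticleStack):
        new_images = fourier_crop(obj.images, old_pixel, new_pixel)
        return ParticleStack(new_images, list(obj.records), new_pixel)
    arr = np.asarray(obj, dtype=float)
    is_stack = arr.ndim == 3 and arr.shape[1] == arr.shape[2] and arr.shape[0] != arr.shape[1]
    n = arr.shape[1] if is_stack else arr.shape[0]
    new_n_f = n * old_pixel / new_pixel
    new_n = int(round(new_n_f))
    if abs(new_n_f - new_n) > 1e-8 or new_n % 2:
        m = max(2, int(new_n_f) - int(new_n_f) % 2)
        examples = [old_pixel * n / mm for mm in (m + 2, m, max(2, m - 2))]
        raise ValueError(
            f"pixel ratio {new_pixel}/{old_pixel} gives box {new_n_f:.4f}; "
            f"the new box must be an even integer — nearby valid new_pixel "
            f"values: {', '.join(f'{e:.6g}' for e in dict.fromkeys(examples))}"
        )
    if new_n == n:
        return arr.copy()
    if is_stack:
        return np.stack([_crop_ft(im, new_n) for im in arr])
    return _crop_ft(arr, new_n)


def subtract_neighbors(
    stack: ParticleStack,
    reference_map: Volume3D,
    central_mask: np.ndarray,
    records: list = None,
) -> ParticleStack:
    """Subtract the CTF-modulated projection of everything outside the mask.

    For each particle the reference map times (1 - central_mask) — i.e. the
    neighboring molecules — is projected at the record's Euler angles,
    shifted by the record's sub-pixel remainder, imaged through the record's
    CTF (multiplication: the physical forward model), and subtracted.  What
    remains is, ideally, the central molecule plus noise, ready for focused
    classification.
    """
    records = records if records is not None else stack.records
    mask = np.asarray(central_mask, dtype=float)
    if mask.shape != reference_map.data.shape:
        raise ValueError("mask shape must match the reference map")
    if np.nanmin(mask) < 0 or np.nanmax(mask) > 1:
        raise ValueError("mask values must be in [0, 1]")
    if reference_map.box != stack.box:
        raise ValueError("reference map box must match the particle box")
    neighbors = reference_map.data * (1.0 - mask)
    out = np.empty_like(stack.images)
    box = stack.box
    # CTF modulation in a padded box: the oscillatory CTF point spread is
    # much wider than one unit cell, and wrapping it circularly inside the
    # particle box would corrupt the forward model
    pad = box + 64
    lo = pad // 2 - box // 2
    fy = np.fft.fftfreq(pad)[:, None]
    fx = np.fft.fftfreq(pad)[None, :]
    for i, r in enumerate(records):
        if r.ctf is None:
            raise ValueError(f"particle {r.particle_id} has no CTF parameters")
        proj = project(neighbors, r.euler)
        padded = np.zeros((pad, pad))
        padded[lo : lo + box, lo : lo + box] = proj
        ft = np.fft.fft2(padded)
        ft *= np.exp(-2j * np.pi * (fx * r.rx + fy * r.ry))
        ft = ctf_correct(ft, r.ctf, "multiply", stack.pixel_size)
        model = np.fft.ifft2(ft).real[lo : lo + box, lo : lo + box]
        out[i] = stack.images[i] - model
    return ParticleStack(out, list(records), stack.pixel_size)


def _check_halfset_integrity(records: list) -> None:
    seen: dict = {}
    for r in records:
        if r.crystal_id in seen and seen[r.crystal_id] != r.halfset:
            raise ValueError(
                f"crystal {r.crystal_id!r} appears in both half-sets"
            )
        seen[r.crystal_id] = r.halfset


_STAR_COLUMNS = [
    "particle_id", "crystal_id", "micrograph", "x", "y", "rx", "ry",
    "phi", "theta", "psi", "df1", "df2", "ast_angle", "voltage", "cs",
    "amp_contrast", "phase_shift", "cc", "halfset", "h", "k",
]


def _records_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.ctf or CTFParams(0.0, 0.0)
        rows.append(
            dict(
                particle_id=r.particle_id, crystal_id=r.crystal_id,
                micrograph=r.micrograph, x=r.x, y=r.y, rx=r.rx, ry=r.ry,
                phi=r.euler.phi, theta=r.euler.theta, psi=r.euler.psi,
                df1=c.df1, df2=c.df2, ast_angle=c.ast_angle,
                voltage=c.voltage, cs=c.cs, amp_contrast=c.amp_contrast,
                phase_shift=c.phase_shift, cc=r.cc, halfset=r.halfset,
                h=r.h, k=r.k,
            )
        )
    return pd.DataFrame(rows, columns=_STAR_COLUMNS)


def _frame_records(df: pd.DataFrame) -> list:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ParticleRecord(
                particle_id=int(row.particle_id),
                crystal_id=str(row.crystal_id),
                micrograph=str(row.micrograph),
                x=float(row.x), y=float(row.y),
                rx=float(row.rx), ry=float(row.ry),
                euler=EulerTriple(float(row.phi), float(row.theta), float(row.psi)),
                ctf=CTFParams(
                    float(row.df1), float(row.df2), float(row.ast_angle),
                    float(row.voltage), float(row.cs), float(row.amp_contrast),
                    float(row.phase_shift),
                ),
                cc=float(row.cc), halfset=int(row.halfset),
                h=int(row.h), k=int(row.k),
            )
        )
    return out


def export_star(records: list, path) -> None:
    """Write particle metadata as a STAR table (bit-identical round trip)."""
    _check_halfset_integrity(records)
    xio.write_star_table(path, _records_frame(records), block_name="particles")


def read_star(path) -> list:
    """Read records written by :func:`export_star`."""
    df = xio.read_star_table(path)
    return _frame_records(df)


_PAR_HEADER = (
    "C           PSI   THETA     PHI       SHX       SHY     MAG  FILM"
    "      DF1      DF2  ANGAST  PSHIFT     OCC      LOGP      SIGMA   SCORE"
    "  CHANGE"
)


def export_par(records: list, path, mag: float = 10000.0) -> None:
    """Write a FREALIGN v9 fixed-width PAR file.

    FILM carries the crystal index (order of first appearance); the even/odd
    parity of FILM+halfset bookkeeping is preserved because all records of a
    crystal share one half-set.  SHX/SHY hold the sub-pixel remainders in px.
    Values round-trip at the printed precision of the format (0.01 deg/A).
    """
    _check_halfset_integrity(records)
    film_ids: dict = {}
    lines = [_PAR_HEADER]
    for i, r in enumerate(records, start=1):
        c = r.ctf or CTFParams(0.0, 0.0)
        film = film_ids.setdefault(r.crystal_id, len(film_ids) + 1)
        lines.append(
            f"{i:7d}{r.euler.psi:8.2f}{r.euler.theta:8.2f}{r.euler.phi:8.2f}"
            f"{r.rx:10.2f}{r.ry:10.2f}{mag:8.0f}{film:6d}"
            f"{c.df1:9.1f}{c.df2:9.1f}{c.ast_angle:8.2f}{c.phase_shift:8.2f}"
            f"{100.0:8.2f}{-500:10d}{1.0:11.4f}{r.cc * 100:8.2f}{0.0:8.2f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_par(path) -> pd.DataFrame:
    """Read a FREALIGN v9 PAR file into a DataFrame (one row per particle)."""
    names = [
        "particle_id", "psi", "theta", "phi", "shx", "shy", "mag", "film",
        "df1", "df2", "ast_angle", "phase_shift", "occ", "logp", "sigma",
        "score", "change",
    ]
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("C") or not line.strip():
                continue
            rows.append([float(v) for v in line.split()])
    df = pd.DataFrame(rows, columns=names)
    for c in ("particle_id", "film", "logp"):
        df[c] = df[c].astype(int)
    return df
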