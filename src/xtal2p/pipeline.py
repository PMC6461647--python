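"""End-to-end demo pipeline on simulated data, and run-configuration handling.

``run_demo`` exercises the whole chain — simulate tilted disordered
crystals, pick unit cells, window particles, assign crystal-aware
half-sets, backproject per-half reconstructions, and measure FSC
resolution — and reports picking recall/precision, the tilt recovered from
the defocus plane, and the half-map resolution.  Identical configs and
seeds give identical reports.

The global seed is expanded into independent per-stage streams with
``numpy.random.SeedSequence(seed).spawn``; stream order is phantom first,
then one render stream and one noise stream per crystal, in crystal order.
"""

from __future__ import annotations

import copy

import numpy as np

from . import sim, pick, stack, maps
from .ctfgeom import CTFParams, TiltGeometry, tilt_to_euler, local_defocus

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_demo", "fit_defocus_plane"]


DEFAULT_CONFIG = {
    "sim": {
        "phantom": {
            "n_blobs": 6,
            "blob_sigma": 2.2,
            "symmetry_order": 4,
            "box": 49,
            "pixel_size": 1.3,
        },
        "lattice": {"a": [52.0, 0.0], "b": [0.0, 52.0]},
        "image_size": 512,
        "tilts": [
            {"tltaxis": 30.0, "tltang": 25.0, "taxa": 10.0},
            {"tltaxis": -20.0, "tltang": 35.0, "taxa": 40.0},
        ],
        "disorder": {
            "inplane_sigma": 2.0,
            "wobble_sigma": 2.0,
            "height_amplitude": 50.0,
            "height_wavelength": 200.0,
        },
        "ctf": {
            "df1": 15000.0,
            "df2": 14000.0,
            "ast_angle": 20.0,
            "voltage": 300.0,
            "cs": 2.7,
            "amp_contrast": 0.07,
        },
        "snr": 1.0,
    },
    # the demo crystals are fully occupied, so the CC threshold's only job is
    # junk rejection; the paper-style "mean" rule is for vacancy masking
    "pick": {
        "box": 48,
        "search_radius": 5.0,
        "threshold": 0.0,
        "frac_shift": [0.0, 0.0],
    },
    "post": {
        "mask_radius": 16.0,
        "mask_edge": 4.0,
        "fsc_threshold": 0.143,
    },
}


def _check_keys(cfg: dict, ref: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in ref:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(ref[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            _check_keys(val, ref[key], path + key + ".")


def validate_config(config: dict = None) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        _check_keys(config, DEFAULT_CONFIG)

        def merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict):
                    merge(dst[k], v)
                else:
                    dst[k] = v

        merge(merged, config)
    if len(merged["sim"]["tilts"]) < 1:
        raise ValueError("at least one crystal (tilt entry) is required")
    return merged


def fit_defocus_plane(xs, ys, defoci, pixel: float, image_size: int):
    """Recover (tltang, tltaxis) from defocus sampled across the image.

    Fits df = c + gx dx + gy dy over centered pixel offsets and inverts the
    tilted-plane relation dz = tan(tltang) (-dx sin(tltaxis) + dy
    cos(tltaxis)) pixel.  Returns (tltang_deg, tltaxis_deg).
    """
    dx = np.asarray(xs, float) - image_size / 2.0
    dy = np.asarray(ys, float) - image_size / 2.0
    a = np.stack([np.ones_like(dx), dx, dy], axis=1)
    coef, *_ = np.linalg.lstsq(a, np.asarray(defoci, float), rcond=None)
    gx, gy = coef[1] / pixel, coef[2] / pixel
    tltang = np.rad2deg(np.arctan(np.hypot(gx, gy)))
    tltaxis = np.rad2deg(np.arctan2(-gx, gy))
    return float(tltang), float(tltaxis)


def _match_picks(truth_xy: np.ndarray, pick_xy: np.ndarray, tol: float = 2.0):
    """Greedy one-to-one matching of picks to truth centers within tol px."""
    if len(pick_xy) == 0 or len(truth_xy) == 0:
        return 0
    d = np.linalg.norm(truth_xy[:, None, :] - pick_xy[None, :, :], axis=2)
    matched = 0
    used_t, used_p = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ti, pi in order:
        if d[ti, pi] > tol:
            break
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matched += 1
    return matched


def run_demo(config: dict = None, seed: int = 0) -> dict:
    """Run the simulate-pick-reconstruct demo and return a report dict.

    Report keys: n_crystals, n_true, n_picked, picking_recall,
    picking_precision, tilt_angle_error_deg, tilt_axis_error_deg,
    resolution_A, noise_sigma.  All internal consistency checks (half-set
    integrity, box bounds) raise on failure.
    """
    cfg = validate_config(config)
    scfg = cfg["sim"]
    n_crystals = len(scfg["tilts"])
    streams = np.random.SeedSequence(seed).spawn(1 + 2 * n_crystals)
    phantom_seed = streams[0].generate_state(1)[0] % (2**31)

    phantom = sim.make_phantom(
        sim.PhantomSpec(**scfg["phantom"]), seed=int(phantom_seed)
    )
    disorder = sim.DisorderSpec(**scfg["disorder"])
    ctf = CTFParams(**scfg["ctf"])
    pixel = scfg["phantom"]["pixel_size"]
    image_size = scfg["image_size"]
    pcfg = cfg["pick"]

    all_records = []
    all_images = []
    n_true = 0
    n_picked = 0
    n_matched = 0
    tilt_ang_err = 0.0
    tilt_axis_err = 0.0
    noise_sigmas = []

    for ci, tcfg in enumerate(scfg["tilts"]):
        tilt = TiltGeometry(**tcfg)
        lattice = pick.Lattice2D(
            tuple(scfg["lattice"]["a"]),
            tuple(scfg["lattice"]["b"]),
            (image_size / 2.0, image_size / 2.0),
            crystal_id=f"xtal{ci}",
        )
        render_seed = streams[1 + 2 * ci].generate_state(1)[0] % (2**31)
        image, truth = sim.render_crystal(
            phantom, lattice, tilt, disorder, ctf,
            noise_sigma=0.0, image_size=image_size, seed=int(render_seed),
        )
        noise_sigma = (
            float(np.sqrt(truth.signal_var / scfg["snr"])) if scfg["snr"] > 0 else 0.0
        )
        noise_sigmas.append(noise_sigma)
        if noise_sigma > 0:
            noise_rng = np.random.default_rng(streams[2 + 2 * ci])
            image = image + noise_rng.normal(0.0, noise_sigma, image.shape)

        # pick with the image-plane (foreshortened) lattice, as measured by
        # unbending on real data
        picks = pick.pick_micrograph(
            image, truth.lattice_image, box=pcfg["box"],
            search_radius=pcfg["search_radius"], threshold=pcfg["threshold"],
            frac_shift=tuple(pcfg["frac_shift"]),
        )
        truth_xy = truth.table[["x", "y"]].to_numpy()
        n_true += len(truth_xy)
        n_picked += len(picks)
        n_matched += _match_picks(truth_xy, picks.positions, tol=2.0)

        # tilt recovered from the ground-truth defocus plane
        ta, tx = fit_defocus_plane(
            truth.table["x"], truth.table["y"],
            0.5 * (truth.table["df1"] + truth.table["df2"]),
            pixel, image_size,
        )
        tilt_ang_err = max(tilt_ang_err, abs(ta - tilt.tltang))
        tilt_axis_err = max(
            tilt_axis_err, abs((tx - tilt.tltaxis + 180) % 360 - 180)
        )

        pstack = pick.window_particles(
            image, picks, pcfg["box"], pixel, micrograph_name=f"sim_{ci}.mrc"
        )
        euler = tilt_to_euler(tilt)
        for r in pstack.records:
            r.euler = euler
            r.ctf = local_defocus(
                ctf, tilt, r.x - image_size / 2.0, r.y - image_size / 2.0, pixel
            )
        all_records.extend(pstack.records)
        all_images.append(pstack.images)

    images = np.concatenate(all_images, axis=0)
    pstack = stack.ParticleStack(images, all_records, pixel)
    pstack = stack.phase_flip_stack(pstack)
    records = stack.assign_halfsets(pstack.records)
    pstack = stack.ParticleStack(pstack.images, records, pixel)

    halves = []
    for hs in (1, 2):
        idx = [i for i, r in enumerate(records) if r.halfset == hs]
        if not idx:
            raise RuntimeError("empty half-set; need at least two crystals")
        vol = maps.backproject(
            pstack.images[idx],
            [records[i].euler for i in idx],
            shifts=np.array([[records[i].rx, records[i].ry] for i in idx]),
            pixel_size=pixel,
        )
        halves.append(vol)

    pcfg2 = cfg["post"]
    mask = maps.soft_spherical_mask(
        halves[0].box, pcfg2["mask_radius"], pcfg2["mask_edge"]
    )
    curve = maps.fsc(halves[0], halves[1], mask=mask)
    resolution = maps.resolution_at_threshold(curve, pcfg2["fsc_threshold"])

    return {
        "n_crystals": n_crystals,
        "n_true": int(n_true),
        "n_picked": int(n_picked),
        "picking_recall": n_matched / n_true if n_true else 0.0,
        "picking_precision": n_matched / n_picked if n_picked else 0.0,
        "tilt_angle_error_deg": tilt_ang_err,
        "tilt_axis_error_deg": tilt_axis_err,
        "resolution_A": resolution,
        "noise_sigma": noise_sigmas,
    }
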