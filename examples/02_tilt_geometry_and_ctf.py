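"""From crystal tilt geometry to per-particle Euler angles and local defocus.

A tilted 2D crystal gives every unit cell the same projection direction but
a position-dependent defocus.  This script converts a tilt geometry to the
ZYZ Euler triple, evaluates the defocus a particle 300 px off-center sees,
and recovers the tilt back from defoci sampled across the image.
"""

import numpy as np

from xtal2p.ctfgeom import CTFParams, TiltGeometry, ctf_eval, local_defocus, tilt_to_euler
from xtal2p.pipeline import fit_defocus_plane

tilt = TiltGeometry(tltaxis=40.0, tltang=35.0, taxa=15.0)
euler = tilt_to_euler(tilt)
print(f"tilt (axis {tilt.tltaxis} deg, angle {tilt.tltang} deg, taxa {tilt.taxa} deg)")
print(f"-> Euler angles phi={euler.phi:.2f} theta={euler.theta:.2f} "
      f"psi={euler.psi:.2f} deg (ZYZ)")

ctf = CTFParams(df1=18000.0, df2=17000.0, ast_angle=30.0)
loc = local_defocus(ctf, tilt, dx=300.0, dy=0.0, pixel=1.3)
print(f"defocus at center     : {ctf.df1:.0f}/{ctf.df2:.0f} A")
print(f"defocus 300 px along x: {loc.df1:.0f}/{loc.df2:.0f} A "
      f"(gradient from the tilted specimen plane)")

xs, ys, dfs = [], [], []
for x in np.linspace(64, 960, 8):
    for y in np.linspace(64, 960, 8):
        c = local_defocus(ctf, tilt, x - 512, y - 512, 1.3)
        xs.append(x), ys.append(y), dfs.append(0.5 * (c.df1 + c.df2))
ang, ax = fit_defocus_plane(xs, ys, dfs, 1.3, 1024)
print(f"plane fit over an 8x8 grid recovers: tilt angle {ang:.3f} deg, "
      f"axis {ax:.3f} deg")

s = 0.1  # 1/A
print(f"CTF at s = {s} 1/A along the astigmatism axis: "
      f"{ctf_eval(s, ctf.ast_angle, ctf):+.3f}")
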