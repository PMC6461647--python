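import numpy as np
import pandas as pd
import pytest

from xtal2p import sim, pick
from xtal2p.ctfgeom import CTFParams, TiltGeometry


@pytest.fixture(scope="session")
def phantom():
    return sim.make_phantom(sim.PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def square_lattice():
    return pick.Lattice2D((52.0, 0.0), (0.0, 52.0), (256.0, 256.0))


@pytest.fixture(scope="session")
def clean_crystal(phantom, square_lattice):
    """Noiseless, untilted, disorder-free 512^2 crystal with ground truth."""
    image, truth = sim.render_crystal(
        phantom, square_lattice, TiltGeometry(),
        sim.DisorderSpec(0.0, 0.0, 200.0, 0.0),
        CTFParams(15000.0, 15000.0), noise_sigma=0.0, image_size=512, seed=2,
    )
    return image, truth


def make_toy_model(label: str, n_res: int = 40, seed: int = 0, chains=("A",)):
    """Random-walk C-alpha chains plus a CB atom per residue."""
    rng = np.random.default_rng(seed)
    rows = []
    for chain in chains:
        pos = rng.normal(0, 5, 3)
        for res in range(1, n_res + 1):
            pos = pos + rng.normal(3.8 / np.sqrt(3), 0.5, 3)
            rows.append(dict(chain=chain, resnum=res, atom="CA", element="C",
                             x=pos[0], y=pos[1], z=pos[2]))
            cb = pos + rng.normal(0, 1.0, 3)
            rows.append(dict(chain=chain, resnum=res, atom="CB", element="C",
                             x=cb[0], y=cb[1], z=cb[2]))
    from xtal2p.ensemble import ModelCoordinates

    return ModelCoordinates(label, pd.DataFrame(rows))
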