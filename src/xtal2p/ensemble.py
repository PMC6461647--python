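"""Conformational-ensemble comparison of atomic models.

Models refined into different 3D class maps are compared by least-squares
(Kabsch) superposition over a residue selection, pairwise C-alpha RMSD,
single-linkage agglomerative clustering of the RMSD matrix, and ranking of
the most dissimilar model pairs.  Aligning everything on a small rigid
anchor (e.g. a channel's selectivity filter) instead of globally exposes
where the flexible domains move.

Atoms pair strictly by (chain, residue number, atom name); alternate
locations resolve to the highest-occupancy conformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ModelCoordinates",
    "RMSDMatrix",
    "read_model",
    "superpose",
    "pairwise_rmsd",
    "single_linkage",
    "rank_pairs",
]


@dataclass
class ModelCoordinates:
    """Atom table of one model: chain, resnum, atom, element, x, y, z."""

    label: str
    atoms: pd.DataFrame

    def __post_init__(self):
        need = {"chain", "resnum", "atom", "element", "x", "y", "z"}
        if not need.issubset(self.atoms.columns):
            raise ValueError(f"atom table must have columns {sorted(need)}")
        if not np.isfinite(self.atoms[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        dup = self.atoms.duplicated(subset=["chain", "resnum", "atom"])
        if dup.any():
            raise ValueError("duplicate (chain, resnum, atom) entries")

    def ca(self) -> pd.DataFrame:
        return self.atoms[self.atoms["atom"] == "CA"]

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "ModelCoordinates":
        xyz = self.atoms[["x", "y", "z"]].to_numpy() @ np.asarray(rot).T + trans
        out = self.atoms.copy()
        out[["x", "y", "z"]] = xyz
        return ModelCoordinates(self.label, out)


def read_model(path, label: str = None) -> ModelCoordinates:
    """Read a PDB or mmCIF file (first model; highest-occupancy altlocs)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            best: dict = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                rows.append(
                    dict(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        atom=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    )
                )
    return ModelCoordinates(label or st.name or str(path), pd.DataFrame(rows))


@dataclass
class RMSDMatrix:
    """Symmetric pairwise RMSD matrix with model labels."""

    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T, atol=1e-10) or np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValueError("matrix must be symmetric with a zero diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _select(model: ModelCoordinates, selection) -> pd.DataFrame:
    """Resolve a selection to an atom subset.

    "all-CA" -> all C-alpha atoms; "all-atom" -> everything; a (start, end)
    tuple -> C-alpha atoms with start <= resnum <= end in every chain.
    """
    if selection == "all-CA":
        return model.ca()
    if selection == "all-atom":
        return model.atoms
    start, end = selection
    ca = model.ca()
    return ca[(ca["resnum"] >= start) & (ca["resnum"] <= end)]


def _paired_coords(mobile, target, selection):
    ma = _select(mobile, selection)
    ta = _select(target, selection)
    merged = ma.merge(ta, on=["chain", "resnum", "atom"], suffixes=("_m", "_t"))
    if len(merged) < 3:
        raise ValueError(
            f"selection resolves to {len(merged)} paired atoms; need >= 3"
        )
    p = merged[["x_m", "y_m", "z_m"]].to_numpy()
    q = merged[["x_t", "y_t", "z_t"]].to_numpy()
    return p, q


def _kabsch(p: np.ndarray, q: np.ndarray):
    """Least-squares proper rotation + translation mapping p onto q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    return rot, trans


def superpose(
    mobile: ModelCoordinates,
    target: ModelCoordinates,
    selection="all-CA",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid least-squares superposition over the selection.

    Returns (rotation, translation, rmsd) with the proper rotation
    (det = +1) and translation such that ``rot @ p + trans`` maps mobile
    atoms onto the target; the RMSD is over the selected atom pairs after
    the transform.  No outlier trimming is performed.
    """
    p, q = _paired_coords(mobile, target, selection)
    rot, trans = _kabsch(p, q)
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(((moved - q) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def pairwise_rmsd(models: list, selection="all-CA") -> RMSDMatrix:
    """Symmetric matrix of superposition RMSDs over all model pairs."""
    if len(models) < 2:
        raise ValueError("need at least two models")
    n = len(models)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = superpose(models[i], models[j], selection)
            m[i, j] = m[j, i] = rmsd
    return RMSDMatrix([mod.label for mod in models], m)


def single_linkage(matrix: RMSDMatrix) -> np.ndarray:
    """Single-linkage merge tree of the RMSD matrix.

    Returns the standard (n-1, 4) linkage array: at each step the two
    clusters merged (original labels are indices into ``matrix.labels``),
    the merge height (minimum inter-cluster RMSD), and the new cluster size.
    Merge heights are non-decreasing; ties resolve deterministically by
    label order.
    """
    return linkage(squareform(matrix.matrix, checks=False), method="single")


def rank_pairs(matrix: RMSDMatrix) -> pd.DataFrame:
    """Off-diagonal pairs sorted by descending RMSD (ties by label order).

    The top-ranked pair identifies the two most different conformers in the
    ensemble — the endpoints of the dominant conformational trajectory.
    """
    rows = []
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append((matrix.labels[i], matrix.labels[j], matrix.matrix[i, j]))
    df = pd.DataFrame(rows, columns=["model_a", "model_b", "rmsd"])
    return (
        df.sort_values(["rmsd", "model_a", "model_b"],
                       ascending=[False, True, True], kind="stable")
        .reset_index(drop=True)
    )
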