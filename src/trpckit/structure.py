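"""Structural comparison metrics: superposition RMSD, buried interface
area and domain rotation angles.

Operates on atomic models (PDB/mmCIF) of tetrameric channel complexes
such as TRPC5 with bound G-protein alpha subunits.  Superposition uses
the Kabsch least-squares rotation (proper rotation enforced), solvent-
accessible surface areas use Shrake-Rupley point sampling, and domain
motions between conformational classes are reported as an axis-angle
rotation with the screw translation along the axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import biotite.structure as bst
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "StructureModel",
    "Selection",
    "SuperpositionResult",
    "DomainMotion",
    "read_structure",
    "superpose",
    "buried_interface_area",
    "domain_rotation",
]

# Bondi-style van der Waals radii (Angstrom); unknown elements fall back
# to the generic 1.7 A carbon radius.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "CA": 2.31, "MG": 1.73, "NA": 2.27,
    "K": 2.75, "FE": 2.00, "MN": 2.00, "CU": 1.40,
}
_DEFAULT_RADIUS = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class StructureModel:
    """Flat atom-table representation of an atomic model.

    Arrays are index-aligned per atom: chain id, residue number, residue
    name, atom name, element symbol, coordinates (N, 3) in Angstrom and
    van der Waals radius in Angstrom.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    radius: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.char.upper(np.asarray(self.element, dtype="U2"))
        self.coord = np.asarray(self.coord, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coordinates must be finite")
        if self.radius is None:
            self.radius = np.array(
                [VDW_RADII.get(e, _DEFAULT_RADIUS) for e in self.element])
        else:
            self.radius = np.asarray(self.radius, dtype=float)
            if np.any(self.radius <= 0):
                raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return self.coord.shape[0]

    def subset(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask, dtype=bool)
        return StructureModel(
            self.chain_id[mask], self.res_id[mask], self.res_name[mask],
            self.atom_name[mask], self.element[mask], self.coord[mask],
            self.radius[mask])

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        out = self.subset(np.ones(len(self), bool))
        out.coord = out.coord @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def atom_keys(self) -> list[tuple]:
        """(chain, res_id, atom_name) key per atom, for pairing."""
        return list(zip(self.chain_id.tolist(), self.res_id.tolist(),
                        self.atom_name.tolist()))

    def to_atom_array(self) -> bst.AtomArray:
        arr = bst.AtomArray(len(self))
        arr.coord = self.coord.copy()
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_id
        arr.res_name = self.res_name.astype("U5")
        arr.atom_name = self.atom_name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = np.zeros(len(self), bool)
        return arr

    def write_pdb(self, path) -> None:
        import biotite.structure.io.pdb as pdb
        f = pdb.PDBFile()
        f.set_structure(self.to_atom_array())
        f.write(str(path))


@dataclass(frozen=True)
class Selection:
    """Atom selection by chain, residue range and atom-name predicates.

    ``chains``/``atom_names`` of None mean "all"; ``res_range`` is an
    inclusive (first, last) residue-number interval.
    """

    chains: frozenset | None = None
    res_range: tuple[int, int] | None = None
    atom_names: frozenset | None = None

    @classmethod
    def ca(cls, chains=None, res_range=None) -> "Selection":
        return cls(chains=frozenset(chains) if chains else None,
                   res_range=res_range, atom_names=frozenset({"CA"}))

    def mask(self, model: StructureModel) -> np.ndarray:
        m = np.ones(len(model), dtype=bool)
        if self.chains is not None:
            m &= np.isin(model.chain_id, list(self.chains))
        if self.res_range is not None:
            lo, hi = self.res_range
            m &= (model.res_id >= lo) & (model.res_id <= hi)
        if self.atom_names is not None:
            m &= np.isin(model.atom_name, list(self.atom_names))
        if not m.any():
            raise ValueError("selection resolves to zero atoms")
        return m


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # applied as x @ R.T + t
    rmsd: float
    n_atoms: int
    n_dropped: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DomainMotion:
    angle_deg: float
    axis: np.ndarray
    translation_along_axis: float
    frame_rmsd: float
    domain_rmsd: float


def read_structure(path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Alternate locations keep the highest-occupancy conformer; waters are
    retained (callers typically exclude them through selections).
    Elements missing from the file are inferred from the atom name with
    a warning.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chain_id, res_id, res_name, atom_name, element, coord = [], [], [], [], [], []
    inferred = 0
    model = st[0]
    for chain in model:
        for res in chain:
            # highest-occupancy altloc per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                cur = best.get(atom.name)
                if cur is None or atom.occ > cur.occ:
                    best[atom.name] = atom
            for atom in best.values():
                el = atom.element.name.upper()
                if el in ("", "X"):
                    el = "".join(c for c in atom.name if c.isalpha())[:1].upper()
                    inferred += 1
                chain_id.append(chain.name)
                res_id.append(res.seqid.num)
                res_name.append(res.name)
                atom_name.append(atom.name)
                element.append(el)
                coord.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coord:
        raise ValueError(f"no atoms parsed from {path}")
    if inferred:
        warnings.warn(f"{inferred} atoms lacked an element; inferred from name")
    return StructureModel(chain_id, res_id, res_name, atom_name, element,
                          np.array(coord))


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation/translation mapping mobile onto reference.

    Classic SVD solution of the orthogonal Procrustes problem with the
    determinant sign correction that enforces a proper rotation.
    """
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - mc, reference - rc
    U, _, Vt = np.linalg.svd(P.T @ Q)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - mc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose(mobile: StructureModel, reference: StructureModel,
              selection: Selection | None = None) -> SuperpositionResult:
    """Least-squares (Kabsch) superposition of paired atoms.

    Atoms are paired by (chain, residue number, atom name); residues
    present in only one model are dropped and counted.  By default all
    atoms that the selection resolves in both models are used.
    """
    msel = selection.mask(mobile) if selection else np.ones(len(mobile), bool)
    rsel = selection.mask(reference) if selection else np.ones(len(reference), bool)
    mob, ref = mobile.subset(msel), reference.subset(rsel)
    mkeys = {k: i for i, k in enumerate(mob.atom_keys())}
    rkeys = {k: i for i, k in enumerate(ref.atom_keys())}
    common = [k for k in mkeys if k in rkeys]
    n_dropped = (len(mkeys) - len(common)) + (len(rkeys) - len(common))
    if len(common) < 3:
        raise ValueError("need at least 3 paired atoms to superpose")
    P = mob.coord[[mkeys[k] for k in common]]
    Q = ref.coord[[rkeys[k] for k in common]]
    if np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("paired atoms are collinear")
    R, t, rmsd = _kabsch(P, Q)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=len(common), n_dropped=n_dropped)


def sasa(model: StructureModel, probe: float = 1.4,
         n_points: int = 960, include_waters: bool = False) -> float:
    """Total Shrake-Rupley solvent-accessible surface area in A^2."""
    keep = np.ones(len(model), bool)
    if not include_waters:
        keep &= ~np.isin(model.res_name, list(_WATER_NAMES))
    sub = model.subset(keep)
    arr = sub.to_atom_array()
    per_atom = bst.sasa(arr, probe_radius=probe, point_number=n_points,
                        vdw_radii=sub.radius, ignore_ions=False)
    return float(np.nansum(per_atom))


def buried_interface_area(model: StructureModel, groupA: Selection | np.ndarray,
                          groupB: Selection | np.ndarray, probe: float = 1.4,
                          n_points: int = 960) -> dict:
    """Solvent-accessible area buried between two atom groups.

    Computes SASA(A), SASA(B) and SASA(A u B) by Shrake-Rupley sampling
    and reports the per-side buried ("contact") area
    (SASA_A + SASA_B - SASA_AB) / 2 together with the total dSASA.
    Waters are excluded.
    """
    maskA = groupA.mask(model) if isinstance(groupA, Selection) else np.asarray(groupA, bool)
    maskB = groupB.mask(model) if isinstance(groupB, Selection) else np.asarray(groupB, bool)
    if not maskA.any() or not maskB.any():
        raise ValueError("both groups must be non-empty")
    if (maskA & maskB).any():
        raise ValueError("groups overlap")
    a = sasa(model.subset(maskA), probe=probe, n_points=n_points)
    b = sasa(model.subset(maskB), probe=probe, n_points=n_points)
    ab = sasa(model.subset(maskA | maskB), probe=probe, n_points=n_points)
    delta = max(a + b - ab, 0.0)
    return {
        "buried_per_side_A2": delta / 2.0,
        "delta_sasa_A2": delta,
        "sasa_A_A2": a,
        "sasa_B_A2": b,
        "sasa_AB_A2": ab,
    }


def _twist_angle(R: np.ndarray, axis: np.ndarray) -> float:
    """Rotation component (degrees) about a given unit axis (swing-twist)."""
    q = Rotation.from_matrix(R).as_quat()  # x, y, z, w
    v, w = q[:3], q[3]
    proj = np.dot(v, axis)
    twist = np.degrees(2.0 * np.arctan2(proj, w))
    # wrap to (-180, 180]
    twist = (twist + 180.0) % 360.0 - 180.0
    return float(twist)


def domain_rotation(modelA: StructureModel, modelB: StructureModel,
                    frame_selection: Selection, domain_selection: Selection,
                    axis: np.ndarray | None = None) -> DomainMotion:
    """Rotation of a domain between two conformations, in a common frame.

    Model A is first superposed onto model B using the frame selection
    (e.g. the transmembrane domain).  The optimal rigid transform mapping
    the frame-aligned domain of A onto the domain of B is then decomposed
    into an axis-angle rotation; when a reference axis is supplied (e.g.
    the channel four-fold axis) the twist about that axis and the screw
    translation along it are reported, signed by the axis orientation.
    """
    frame_fit = superpose(modelA, modelB, frame_selection)
    A_aligned = modelA.transformed(frame_fit.rotation, frame_fit.translation)
    dom_fit = superpose(A_aligned, modelB, domain_selection)
    rot = Rotation.from_matrix(dom_fit.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if axis is not None:
        u = np.asarray(axis, float)
        u = u / np.linalg.norm(u)
        angle = _twist_angle(dom_fit.rotation, u)
        d = float(np.dot(dom_fit.translation, u))
        used_axis = u
    else:
        used_axis = (rotvec / np.linalg.norm(rotvec)
                     if np.linalg.norm(rotvec) > 0 else np.array([0.0, 0.0, 1.0]))
        d = float(np.dot(dom_fit.translation, used_axis))
    return DomainMotion(angle_deg=angle, axis=used_axis,
                        translation_along_axis=d,
                        frame_rmsd=frame_fit.rmsd, domain_rmsd=dom_fit.rmsd)
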