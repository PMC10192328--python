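"""Beta-solenoid geometry: superposition, helix parameters, stagger,
hydrogen-bond candidates and buried sheet-on-sheet area.

The central object is :class:`SolenoidModel`: an atomic structure
(biotite ``AtomArray``) plus per-residue maps assigning each residue to
a repeat, a consensus motif position (1..23; -1 for insertions or
unmapped residues) and a sheet (``sheet1`` = motif a, ``sheet2`` =
motif b, ``arc`` = connectors).

Superposition is a closed-form least-squares (Kabsch) fit restricted to
proper rotations; reflections are rejected, so mirroring a structure
flips the reported handedness rather than being absorbed silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import anatomy
from .mining import SubunitAnnotation

__all__ = [
    "SolenoidModel",
    "RepeatTransform",
    "HelixParams",
    "BuriedArea",
    "GeometryReport",
    "GeometryError",
    "AlignmentError",
    "FormatError",
    "assemble_model",
    "assemble_backbone_model",
    "read_structure",
    "write_pdb",
    "superpose",
    "consecutive_repeat_rmsd",
    "repeat_helix_params",
    "measure_stagger",
    "hbond_candidates_per_repeat",
    "buried_area_per_repeat",
    "geometry_report",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# motif positions whose side chains face the solvent: $ positions plus
# arc residues other than the conserved glycines
SURFACE_MOTIF_POSITIONS = frozenset(anatomy.SURFACE_POSITIONS) | (
    frozenset(range(8, 12)) | frozenset(range(19, 32))
) - {anatomy.ARC1_G, anatomy.ARC2_G}

HBOND_CUTOFF = 3.5        # donor-acceptor heavy-atom distance, Angstrom
TWIST_HANDEDNESS_FLOOR = 0.2   # deg/repeat below which winding rule decides


class GeometryError(ValueError):
    """Geometric computation impossible (degenerate transform etc.)."""


class AlignmentError(ValueError):
    """Annotation cannot be index-aligned onto the coordinates."""


class FormatError(ValueError):
    """Coordinate file could not be parsed."""


@dataclass
class RepeatTransform:
    """Rigid transform mapping repeat i onto repeat i+1."""

    rotation: np.ndarray          # 3x3, proper
    translation: np.ndarray       # 3-vector, Angstrom
    rise: float                   # translation along the screw axis
    twist: float                  # signed degrees; + right-handed
    axis: np.ndarray              # unit 3-vector along propagation

    def apply(self, coords: np.ndarray, n: int = 1) -> np.ndarray:
        out = np.asarray(coords, dtype=float)
        for _ in range(n):
            out = out @ self.rotation.T + self.translation
        return out


@dataclass
class SolenoidModel:
    """Atomic model with repeat / motif / sheet maps (all per residue)."""

    atoms: struc.AtomArray
    res_repeat: np.ndarray        # repeat index per residue, -1 unmapped
    res_motif: np.ndarray         # 1-based consensus position, -1 if none
    res_sheet: np.ndarray         # 'sheet1' | 'sheet2' | 'arc' | 'unmapped'
    model_id: str = "model"
    half_repeats: frozenset[int] = frozenset()
    missing_atoms: list = field(default_factory=list)
    truth_transform: RepeatTransform | None = None
    exact_coords: np.ndarray | None = None    # float64 generator coordinates

    def __post_init__(self) -> None:
        n_res = len(self.res_repeat)
        if not (len(self.res_motif) == len(self.res_sheet) == n_res):
            raise ValueError("residue maps disagree in length")

    @property
    def n_residues(self) -> int:
        return len(self.res_repeat)

    @property
    def repeat_ids(self) -> list[int]:
        ids = sorted({int(r) for r in self.res_repeat if r >= 0})
        return ids

    @property
    def full_repeat_ids(self) -> list[int]:
        return [r for r in self.repeat_ids if r not in self.half_repeats]

    def atom_residue_index(self) -> np.ndarray:
        """Per-atom residue index 0..n_res-1 (chain order)."""
        res_ids, inverse = np.unique(self.atoms.res_id, return_inverse=True)
        # res_id is monotonically increasing by construction/reading
        return inverse

    def residue_mask(self, repeat: int) -> np.ndarray:
        return self.res_repeat == repeat

    def mainchain_coords(self, repeat: int) -> dict[tuple[int, str], np.ndarray]:
        """(motif position, atom name) -> coordinate, for one repeat."""
        idx = self.atom_residue_index()
        out = {}
        for ai in np.flatnonzero(np.isin(idx, np.flatnonzero(self.residue_mask(repeat)))):
            ri = idx[ai]
            pos = int(self.res_motif[ri])
            name = self.atoms.atom_name[ai]
            if pos > 0 and name in BACKBONE_ATOMS:
                out[(pos, name)] = self.atoms.coord[ai]
        return out

    def repeat_centroid(self, repeat: int) -> np.ndarray:
        idx = self.atom_residue_index()
        mask = np.isin(idx, np.flatnonzero(self.residue_mask(repeat)))
        return self.atoms.coord[mask].mean(axis=0)

    def ca_coords(self, repeat: int, sheet: str | None = None) -> np.ndarray:
        idx = self.atom_residue_index()
        res_mask = self.residue_mask(repeat)
        if sheet is not None:
            res_mask = res_mask & (self.res_sheet == sheet)
        mask = np.isin(idx, np.flatnonzero(res_mask)) & (self.atoms.atom_name == "CA")
        return self.atoms.coord[mask]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chain_id: str | None = None) -> "SolenoidModel":
        atoms = self.atoms.copy()
        atoms.coord = atoms.coord @ np.asarray(rotation).T + translation
        if chain_id is not None:
            atoms.chain_id = np.full(atoms.array_length(), chain_id)
        return SolenoidModel(
            atoms, self.res_repeat.copy(), self.res_motif.copy(),
            self.res_sheet.copy(), self.model_id, self.half_repeats,
        )


def assemble_model(coords: np.ndarray, atom_names: np.ndarray,
                   elements: np.ndarray, atom_res_index: np.ndarray,
                   repeat_of: np.ndarray, motif_pos: np.ndarray,
                   sheet_of: np.ndarray,
                   model_id: str = "model") -> SolenoidModel:
    """Wrap per-atom coordinates plus residue maps into a SolenoidModel.

    ``atom_res_index`` assigns each atom to a residue 0..n_res-1 (chain
    order); the three per-residue maps have length n_res.  A trailing
    repeat consisting of motif a alone is marked as a half repeat.
    """
    n_atoms = len(coords)
    arr = struc.AtomArray(n_atoms)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.full(n_atoms, "A", dtype="U4")
    arr.res_id = np.asarray(atom_res_index, dtype=int) + 1
    arr.res_name = np.full(n_atoms, "GLY", dtype="U5")
    arr.atom_name = np.asarray(atom_names, dtype="U6")
    arr.element = np.asarray(elements, dtype="U2")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    half = frozenset()
    last = int(np.max(repeat_of))
    last_positions = set(int(p) for p in np.asarray(motif_pos)[np.asarray(repeat_of) == last])
    if last_positions and max(last_positions) <= anatomy.MOTIF_A[-1]:
        half = frozenset({last})
    return SolenoidModel(
        arr,
        np.asarray(repeat_of, dtype=int),
        np.asarray(motif_pos, dtype=int),
        np.asarray(sheet_of, dtype=object),
        model_id=model_id,
        half_repeats=half,
    )


def assemble_backbone_model(xyz: np.ndarray, repeat_of: np.ndarray,
                            motif_pos: np.ndarray, sheet_of: np.ndarray,
                            model_id: str = "model") -> SolenoidModel:
    """Wrap per-residue (N, CA, C, O) coordinates into a SolenoidModel."""
    n_res = len(repeat_of)
    if xyz.shape != (n_res * 4, 3):
        raise ValueError("expected 4 backbone atoms per residue")
    return assemble_model(
        xyz,
        np.tile(np.array(BACKBONE_ATOMS, dtype="U6"), n_res),
        np.tile(np.array(["N", "C", "C", "O"], dtype="U2"), n_res),
        np.repeat(np.arange(n_res), 4),
        repeat_of, motif_pos, sheet_of, model_id,
    )


# ---------------------------------------------------------------------------
# structure I/O


def write_pdb(model: SolenoidModel, path) -> None:
    from biotite.structure.io.pdb import PDBFile
    f = PDBFile()
    f.set_structure(model.atoms)
    f.write(str(path))


def _load_atoms(path) -> struc.AtomArray:
    path = Path(path)
    try:
        if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
            from biotite.structure.io.pdbx import CIFFile, get_structure
            atoms = get_structure(CIFFile.read(str(path)), model=1)
        else:
            from biotite.structure.io.pdb import PDBFile
            atoms = PDBFile.read(str(path)).get_structure(model=1)
    except Exception as exc:
        raise FormatError(f"cannot parse coordinate file {path}: {exc}") from exc
    return atoms[~atoms.hetero]


def read_structure(path, annotation: SubunitAnnotation | None = None,
                   repeat_ranges: list[tuple[int, int]] | None = None,
                   model_id: str | None = None) -> SolenoidModel:
    """Read PDB/mmCIF coordinates and map residues to curlin repeats.

    Repeat assignment comes from a sequence annotation (index-aligned:
    residue i of the chain is sequence position i) or from explicit
    0-based half-open residue ranges.  Residues missing main-chain
    atoms are listed in ``model.missing_atoms``.
    """
    atoms = _load_atoms(path)
    res_ids = np.unique(atoms.res_id)
    n_res = len(res_ids)

    if annotation is not None:
        if annotation.length != n_res:
            raise AlignmentError(
                f"annotation covers {annotation.length} residues, "
                f"structure has {n_res}")
        repeats = annotation.repeats
        half = frozenset(i for i, r in enumerate(repeats) if r.half)
        ranges = [(r.start, r.end) for r in repeats]
    elif repeat_ranges is not None:
        ranges = list(repeat_ranges)
        half = frozenset()
    else:
        raise AlignmentError("need an annotation or explicit repeat ranges")

    res_repeat = np.full(n_res, -1, dtype=int)
    res_motif = np.full(n_res, -1, dtype=int)
    res_sheet = np.full(n_res, "unmapped", dtype=object)
    for k, (start, end) in enumerate(ranges):
        if end > n_res:
            raise AlignmentError(f"repeat {k} range {start}:{end} exceeds chain")
        for i in range(start, end):
            res_repeat[i] = k
            pos = i - start + 1
            res_motif[i] = pos if pos <= 31 else -1
            if pos in anatomy.MOTIF_A:
                res_sheet[i] = "sheet1"
            elif pos in anatomy.MOTIF_B:
                res_sheet[i] = "sheet2"
            else:
                res_sheet[i] = "arc"

    missing = []
    for i, rid in enumerate(res_ids):
        if res_repeat[i] < 0:
            continue
        names = set(atoms.atom_name[atoms.res_id == rid])
        absent = [a for a in BACKBONE_ATOMS if a not in names]
        if absent:
            missing.append((int(rid), absent))

    return SolenoidModel(
        atoms, res_repeat, res_motif, res_sheet,
        model_id=model_id or Path(path).stem,
        half_repeats=half, missing_atoms=missing,
    )


# ---------------------------------------------------------------------------
# superposition


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (reflections rejected).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 paired points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    delta = P @ R.T + t - Q
    rmsd = math.sqrt(float(np.mean(np.sum(delta**2, axis=1))))
    return R, t, rmsd


# below this rotation angle (radians) the fitted rotation axis is noise;
# the screw axis is then taken from the translation direction instead
_AXIS_FROM_ROTATION_FLOOR = 1e-3


def _axis_and_twist(R: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float]:
    """Screw axis (oriented along the translation) and signed twist (deg)."""
    rv = Rotation.from_matrix(R).as_rotvec()
    theta = float(np.linalg.norm(rv))
    if theta < _AXIS_FROM_ROTATION_FLOOR:
        nt = float(np.linalg.norm(t))
        if nt < 1e-9:
            raise GeometryError("degenerate (zero-translation) repeat transform")
        axis = t / nt
        return axis, math.degrees(float(np.dot(rv, axis)))
    axis = rv / theta
    twist = math.degrees(theta)
    if float(np.dot(t, axis)) < 0:
        axis, twist = -axis, -twist
    return axis, twist


def _paired_mainchain(model: SolenoidModel, rep_a: int, rep_b: int):
    """Positionally equivalent main-chain coordinates of two repeats."""
    ca = model.mainchain_coords(rep_a)
    cb = model.mainchain_coords(rep_b)
    keys = sorted(set(ca) & set(cb))
    if len(keys) < 3:
        return None, None
    return (np.array([ca[k] for k in keys]),
            np.array([cb[k] for k in keys]))


def consecutive_repeat_rmsd(model: SolenoidModel) -> tuple[float, float]:
    """Mean +- SD of main-chain RMSD between adjacent full repeats."""
    reps = model.full_repeat_ids
    if len(reps) < 2:
        raise GeometryError("need >= 2 mapped full repeats")
    rmsds = []
    for a, b in zip(reps, reps[1:]):
        P, Q = _paired_mainchain(model, a, b)
        if P is None:
            warnings.warn(f"repeat pair ({a},{b}) has <3 equivalent residues; skipped")
            continue
        rmsds.append(superpose(P, Q)[2])
    if not rmsds:
        raise GeometryError("no superposable repeat pairs")
    mean = float(np.mean(rmsds))
    sd = float(np.std(rmsds, ddof=1)) if len(rmsds) > 1 else 0.0
    return mean, sd


@dataclass
class HelixParams:
    transform: RepeatTransform
    rise: float                    # Angstrom per repeat (mean over pairs)
    twist: float                   # signed degrees per repeat
    handedness: str                # left | right | indeterminate
    per_pair: list = field(default_factory=list)


def _winding_sign(model: SolenoidModel) -> float:
    """Chirality of the strand/sheet/axis frame, averaged over repeats."""
    reps = model.full_repeat_ids
    signs = []
    for a, b in zip(reps, reps[1:]):
        z = model.repeat_centroid(b) - model.repeat_centroid(a)
        nz = np.linalg.norm(z)
        if nz == 0:
            continue
        z /= nz
        mc = model.mainchain_coords(a)
        if (anatomy.Q_POS_A, "CA") not in mc or (anatomy.N_POS_A, "CA") not in mc:
            continue
        s = mc[(anatomy.Q_POS_A, "CA")] - mc[(anatomy.N_POS_A, "CA")]
        sheet1 = model.ca_coords(a, "sheet1")
        sheet2 = model.ca_coords(a, "sheet2")
        if len(sheet1) == 0 or len(sheet2) == 0:
            continue
        c = sheet2.mean(axis=0) - sheet1.mean(axis=0)
        signs.append(np.sign(np.dot(np.cross(s, c), z)))
    if not signs:
        return 0.0
    return float(np.sign(np.mean(signs)))


def repeat_helix_params(model: SolenoidModel) -> HelixParams:
    """Per-repeat rise, twist and handedness from adjacent-repeat transforms.

    The screw axis is oriented along the propagation direction (positive
    rise); twist is the signed rotation about it (right-hand rule), so
    positive twist means a right-handed solenoid.  Near-zero twists fall
    back to the winding chirality of the strand-sheet-axis frame.
    """
    reps = model.full_repeat_ids
    if len(reps) < 2:
        raise GeometryError("need >= 2 mapped repeats")
    centroids = np.array([model.repeat_centroid(r) for r in reps])
    propagation = centroids[-1] - centroids[0]
    if float(np.linalg.norm(propagation)) < 1e-6:
        raise GeometryError("degenerate (zero-translation) repeat transform")

    pairs = []
    for a, b in zip(reps, reps[1:]):
        P, Q = _paired_mainchain(model, a, b)
        if P is None:
            continue
        R, t, _ = superpose(P, Q)
        pairs.append((R, t, Rotation.from_matrix(R).as_rotvec()))
    if not pairs:
        raise GeometryError("no superposable repeat pairs")

    # screw axis: the mean pair rotation vector when the twist is
    # resolvable (exact screw axis, noise averaged over pairs); at
    # near-zero twist the rotation axis is noise, but the centroid path
    # is then a straight line and its principal direction is robust
    mean_rv = np.mean([rv for _, _, rv in pairs], axis=0)
    if float(np.linalg.norm(mean_rv)) >= _AXIS_FROM_ROTATION_FLOOR:
        axis0 = mean_rv / np.linalg.norm(mean_rv)
    else:
        _, _, vt = np.linalg.svd(centroids - centroids.mean(axis=0))
        axis0 = vt[0]
    if float(np.dot(axis0, propagation)) < 0:
        axis0 = -axis0

    per_pair = []
    transforms = []
    for R, t, rv in pairs:
        twist = math.degrees(float(np.dot(rv, axis0)))
        rise = float(np.dot(t, axis0))
        if abs(rise) < 1e-6:
            raise GeometryError("degenerate (zero-translation) repeat transform")
        per_pair.append({"rise": rise, "twist": twist})
        transforms.append((R, t))

    rise = float(np.mean([p["rise"] for p in per_pair]))
    twist = float(np.mean([p["twist"] for p in per_pair]))
    R0, t0 = transforms[0]
    if abs(twist) >= TWIST_HANDEDNESS_FLOOR:
        handedness = "right" if twist > 0 else "left"
    else:
        w = _winding_sign(model)
        handedness = {1.0: "right", -1.0: "left"}.get(w, "indeterminate")
    transform = RepeatTransform(
        rotation=R0, translation=t0, rise=rise, twist=twist, axis=axis0,
    )
    return HelixParams(transform, rise, twist, handedness, per_pair)


def measure_stagger(model: SolenoidModel) -> float:
    """Mean axial offset between the two sheets' strands within repeats."""
    if not set(model.res_sheet) & {"sheet1", "sheet2"}:
        raise GeometryError("no sheet assignment available")
    axis = repeat_helix_params(model).transform.axis
    offsets = []
    for rep in model.full_repeat_ids:
        s1 = model.ca_coords(rep, "sheet1")
        s2 = model.ca_coords(rep, "sheet2")
        if len(s1) == 0 or len(s2) == 0:
            continue
        offsets.append(float(np.mean(s2 @ axis) - np.mean(s1 @ axis)))
    if not offsets:
        raise GeometryError("no repeat carries both sheets")
    return abs(float(np.mean(offsets)))


def _polar_atom_mask(model: SolenoidModel, core_only: bool) -> np.ndarray:
    arr = model.atoms
    mask = np.isin(arr.element, ("N", "O"))
    if core_only:
        idx = model.atom_residue_index()
        sidechain = ~np.isin(arr.atom_name, BACKBONE_ATOMS)
        surface_res = np.isin(model.res_motif[idx],
                              sorted(SURFACE_MOTIF_POSITIONS))
        mask &= ~(sidechain & surface_res)
    return mask


def hbond_candidates_per_repeat(model: SolenoidModel, core_only: bool = False,
                                cutoff: float = HBOND_CUTOFF) -> float:
    """Donor/acceptor (N, O) heavy-atom pairs within ``cutoff``, per repeat.

    Pairs within one residue, and the peptide-bond C(i)-N(i+1) contact,
    are excluded; remaining pairs count when separated by >= 2 residues
    in sequence or when they bridge the two sheets.  With ``core_only``
    the side chains of surface-facing positions are ignored (main-chain
    atoms always count).
    """
    mask = _polar_atom_mask(model, core_only)
    if not mask.any():
        warnings.warn("no polar atoms in model; H-bond count is 0")
        return 0.0
    arr = model.atoms
    idx = model.atom_residue_index()
    coords = arr.coord[mask]
    res = idx[mask]
    names = arr.atom_name[mask]
    sheets = model.res_sheet[res]
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    count = 0
    for i, j in pairs:
        ri, rj = int(res[i]), int(res[j])
        if ri == rj:
            continue
        sep = abs(ri - rj)
        if sep == 1:
            lo, hi = (i, j) if ri < rj else (j, i)
            if names[lo] == "C" and names[hi] == "N":
                continue     # peptide bond
            if sheets[i] == sheets[j]:
                continue
        count += 1
    n_full = len(model.full_repeat_ids)
    if n_full == 0:
        raise GeometryError("no full repeats mapped")
    return count / n_full


@dataclass
class BuriedArea:
    per_repeat: float             # Angstrom^2 per full repeat
    probe_radius: float
    point_number: int
    approximate: bool             # True for backbone-only models


def _sasa(arr: struc.AtomArray, probe: float, points: int) -> float:
    vals = struc.sasa(arr, probe_radius=probe, point_number=points,
                      vdw_radii="Single")
    return float(np.nansum(vals))


def buried_area_per_repeat(model: SolenoidModel, probe_radius: float = 1.4,
                           point_number: int = 500) -> BuriedArea:
    """Sheet-on-sheet buried SASA per repeat: (A1 + A2 - A12) / 2 / n.

    Sheet 1 and sheet 2 are taken as the strand residues of motifs a and
    b; arc residues belong to neither sheet and are excluded from all
    three SASA evaluations.  Backbone-only models are flagged
    approximate.
    """
    idx = model.atom_residue_index()
    m1 = np.isin(idx, np.flatnonzero(model.res_sheet == "sheet1"))
    m2 = np.isin(idx, np.flatnonzero(model.res_sheet == "sheet2"))
    if not m1.any() or not m2.any():
        raise GeometryError("sheet assignment required for buried area")
    arr = model.atoms
    a1 = _sasa(arr[m1], probe_radius, point_number)
    a2 = _sasa(arr[m2], probe_radius, point_number)
    a12 = _sasa(arr[m1 | m2], probe_radius, point_number)
    n_full = len(model.full_repeat_ids)
    buried = (a1 + a2 - a12) / 2.0 / n_full
    # models without real side chains (pseudo-CB at most) are approximate
    backbone_only = bool(np.isin(arr.atom_name, BACKBONE_ATOMS + ("CB",)).all())
    return BuriedArea(buried, probe_radius, point_number, backbone_only)


@dataclass
class GeometryReport:
    model_id: str
    mean_consecutive_rmsd: float
    rmsd_sd: float
    rise_per_repeat: float
    twist_per_repeat: float
    handedness: str
    stagger: float
    hbond_per_repeat: float
    buried_area_per_repeat: float
    conventions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "mean_consecutive_rmsd": self.mean_consecutive_rmsd,
            "rmsd_sd": self.rmsd_sd,
            "rise_per_repeat": self.rise_per_repeat,
            "twist_per_repeat": self.twist_per_repeat,
            "handedness": self.handedness,
            "stagger": self.stagger,
            "hbond_per_repeat": self.hbond_per_repeat,
            "buried_area_per_repeat": self.buried_area_per_repeat,
            "conventions": self.conventions,
        }


def geometry_report(model: SolenoidModel, core_only: bool = True,
                    hbond_cutoff: float = HBOND_CUTOFF,
                    probe_radius: float = 1.4,
                    point_number: int = 500) -> GeometryReport:
    """Full geometric characterisation of one solenoid model."""
    mean_rmsd, sd = consecutive_repeat_rmsd(model)
    helix = repeat_helix_params(model)
    buried = buried_area_per_repeat(model, probe_radius, point_number)
    return GeometryReport(
        model_id=model.model_id,
        mean_consecutive_rmsd=mean_rmsd,
        rmsd_sd=sd,
        rise_per_repeat=helix.rise,
        twist_per_repeat=helix.twist,
        handedness=helix.handedness,
        stagger=measure_stagger(model),
        hbond_per_repeat=hbond_candidates_per_repeat(model, core_only,
                                                     hbond_cutoff),
        buried_area_per_repeat=buried.per_repeat,
        conventions={
            "hbond_cutoff": hbond_cutoff,
            "core_only": core_only,
            "sasa_probe_radius": buried.probe_radius,
            "sasa_point_number": buried.point_number,
            "sasa_approximate_backbone_only": buried.approximate,
        },
    )
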