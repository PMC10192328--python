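"""Ground-truth synthetic data: curlin sequences and parametric solenoids.

Sequences are assembled repeat-by-repeat from the consensus kernel
``N-$-Psi1-$-Psi2-$-Q`` (motifs a and b) joined by ``X-G-X-X(-X)`` arcs,
with controllable class (CS / NCS / D), terminal half repeat and an
N22-like leader.  Coordinates are built from an idealized beta-solenoid
template propagated by an exact screw transform, so every geometric
parameter downstream modules are meant to recover is known by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import anatomy
from .mining import CurlinRepeat, SubunitAnnotation

__all__ = [
    "SequenceSpec",
    "SolenoidSpec",
    "InvalidSpecError",
    "generate_curlin_sequence",
    "generate_curliome",
    "generate_solenoid_coords",
]


class InvalidSpecError(ValueError):
    """Generator specification violates a precondition."""


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for one synthetic curlin subunit.

    ``n_repeats`` may end in .5 for a terminal half repeat (motif a
    only).  ``insertion_rate`` is the fraction of repeats degraded in a
    D-class subunit; degenerate repeats get an arc-2 insertion of 1-8
    residues and/or a flanking N/Q substituted by G/A/L (never the
    motif-a Q, which all detection passes anchor on).
    """

    n_repeats: float
    class_label: str = "CS"
    arc2_length: int = 5
    insertion_rate: float = 0.0
    with_n22_leader: bool = False
    surface_alphabet: str = anatomy.SURFACE_ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise InvalidSpecError("n_repeats must be >= 1")
        if (2 * self.n_repeats) % 1 != 0:
            raise InvalidSpecError("n_repeats must be integer or half-integer")
        if self.class_label not in ("CS", "NCS", "D"):
            raise InvalidSpecError(f"unknown class {self.class_label!r}")
        if self.arc2_length not in (4, 5):
            raise InvalidSpecError("arc2_length must be 4 or 5")
        if not 0.0 <= self.insertion_rate <= 1.0:
            raise InvalidSpecError("insertion_rate must be a probability")

    @property
    def n_full(self) -> int:
        return int(self.n_repeats)

    @property
    def has_half(self) -> bool:
        return self.n_repeats % 1 == 0.5


def _motif(rng, psi1: str, psi2: str, surface: str, n_flank: str = "N",
           q_flank: str = "Q") -> str:
    s = lambda: rng.choice(list(surface))
    return "".join([n_flank, s(), psi1, s(), psi2, s(), q_flank])


def _arc(rng, length: int) -> str:
    xs = [str(rng.choice(list(anatomy.ARC_X_ALPHABET))) for _ in range(length - 1)]
    return xs[0] + "G" + "".join(xs[1:])


def _draw_psis(rng, class_label: str) -> tuple[str, str, str, str]:
    """(psi1_a, psi2_a, psi1_b, psi2_b) for one repeat."""
    if class_label == "NCS":
        return (
            str(rng.choice(list(anatomy.BULKY_HYDROPHOBIC))),
            str(rng.choice(list(anatomy.BULKY_HYDROPHOBIC))),
            str(rng.choice(list(anatomy.SMALL_HYDROPHOBIC))),
            str(rng.choice(list(anatomy.SMALL_HYDROPHOBIC))),
        )
    p1 = str(rng.choice(list(anatomy.PSI_ALPHABET)))
    p2 = str(rng.choice(list(anatomy.PSI_ALPHABET)))
    return p1, p2, p1, p2


def generate_curlin_sequence(spec: SequenceSpec) -> tuple[str, SubunitAnnotation]:
    """Build one sequence plus the exact truth annotation used to build it."""
    rng = np.random.default_rng(spec.seed)
    surface = spec.surface_alphabet

    # which repeats are degenerate: a deterministic count (rounded
    # rate * n, at least 1 for D) at random positions, so a D-class
    # subunit is guaranteed to carry its class signal
    degenerate = set()
    if spec.class_label == "D" and spec.insertion_rate > 0:
        k = max(1, round(spec.insertion_rate * spec.n_full))
        degenerate = set(rng.choice(spec.n_full, size=min(k, spec.n_full),
                                    replace=False).tolist())

    parts: list[str] = []
    repeats: list[CurlinRepeat] = []
    cursor = 0

    if spec.with_n22_leader:
        # degenerate 22-aa pseudo-repeat: all four flanks mutated to G,
        # remaining positions inert (no N/Q) so the leader cannot seed
        # a spurious repeat anchor
        inert = "TSDERY"
        p1, p2, p3, p4 = (str(rng.choice(list("AV"))) for _ in range(4))
        lead = (
            _motif(rng, p1, p2, inert, n_flank="G", q_flank="G")
            + _arc(rng, 4)
            + _motif(rng, p3, p4, inert, n_flank="G", q_flank="G")
            + _arc(rng, 4)
        )
        parts.append(lead)
        cursor = len(lead)

    for k in range(spec.n_full):
        psi1a, psi2a, psi1b, psi2b = _draw_psis(rng, spec.class_label)
        n_a, q_b = "N", "Q"
        arc2_len = spec.arc2_length
        insertion = 0
        if k in degenerate:
            # flank substitution always (the unambiguous class signal),
            # an arc-2 insertion of 1-8 residues in half the repeats
            if rng.random() < 0.5:
                insertion = int(rng.integers(1, 9))
            target = rng.choice(["n_a", "q_b"])
            sub = str(rng.choice(list("GAL")))
            if target == "n_a":
                n_a = sub
            else:
                q_b = sub
        motif_a = _motif(rng, psi1a, psi2a, surface, n_flank=n_a)
        motif_b = _motif(rng, psi1b, psi2b, surface, q_flank=q_b)
        arc2 = _arc(rng, arc2_len + insertion)
        rep_seq = motif_a + _arc(rng, 4) + motif_b + arc2
        pass_id = "kernel" if q_b == "Q" else "n_anchor"
        repeats.append(CurlinRepeat(
            cursor, cursor + len(rep_seq), pass_id,
            degenerate_n=n_a not in anatomy.ALLOWED_N_FLANK,
            degenerate_q=q_b not in anatomy.ALLOWED_Q_FLANK,
            insertion=insertion > 0,
        ))
        parts.append(rep_seq)
        cursor += len(rep_seq)

    if spec.has_half:
        psi1a, psi2a, _, _ = _draw_psis(rng, spec.class_label)
        half = _motif(rng, psi1a, psi2a, surface)
        repeats.append(CurlinRepeat(cursor, cursor + len(half), "kernel", half=True))
        parts.append(half)
        cursor += len(half)

    sequence = "".join(parts)
    truth = SubunitAnnotation(
        id=f"synthetic|{spec.class_label}|n{spec.n_repeats}|s{spec.seed}",
        length=len(sequence),
        repeats=repeats,
        n22_like=spec.with_n22_leader,
        class_label=spec.class_label,
        sequence=sequence,
    )
    return sequence, truth


def generate_curliome(
    n_sequences: int,
    repeat_count_distribution=None,
    seed: int = 0,
    *,
    class_labels: tuple[str, ...] = ("CS", "NCS"),
    arc2_length: int = 5,
    insertion_rate: float = 0.0,
    with_n22_leader: bool = False,
) -> list[tuple[str, SubunitAnnotation]]:
    """Generate a reproducible set of (sequence, truth) pairs.

    ``repeat_count_distribution`` is either a non-empty sequence of
    admissible repeat counts (sampled uniformly) or a callable taking
    the generator's RNG and returning one count.  The default is the
    uniform 4..30 range typical of mined curlin catalogues.
    """
    if n_sequences < 1:
        raise InvalidSpecError("n_sequences must be >= 1")
    if repeat_count_distribution is None:
        repeat_count_distribution = range(4, 31)
    rng = np.random.default_rng(seed)
    if callable(repeat_count_distribution):
        draw = lambda: repeat_count_distribution(rng)
    else:
        support = list(repeat_count_distribution)
        if not support:
            raise InvalidSpecError("empty repeat-count distribution support")
        draw = lambda: support[int(rng.integers(len(support)))]

    out = []
    for _ in range(n_sequences):
        spec = SequenceSpec(
            n_repeats=float(draw()),
            class_label=str(rng.choice(list(class_labels))),
            arc2_length=arc2_length,
            insertion_rate=insertion_rate,
            with_n22_leader=with_n22_leader,
            seed=int(rng.integers(2**31)),
        )
        out.append(generate_curlin_sequence(spec))
    return out


# ---------------------------------------------------------------------------
# parametric beta-solenoid coordinates


@dataclass(frozen=True)
class SolenoidSpec:
    """Recipe for an idealized beta-solenoid backbone.

    Defaults state the curli geometry: 4.8 A rise per repeat, 2.4 A
    inter-sheet stagger (half a strand spacing), ~10 A sheet spacing and
    no twist.  ``twist_per_repeat`` is signed: positive twists are
    right-handed screws about the propagation axis.
    """

    n_repeats: int
    rise_per_repeat: float = 4.8
    stagger: float = 2.4
    sheet_spacing: float = 10.0
    twist_per_repeat: float = 0.0
    handedness: str = "left"
    arc2_length: int = 5
    terminal_half: bool = False
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise InvalidSpecError("n_repeats must be >= 2")
        if self.rise_per_repeat <= 0:
            raise InvalidSpecError("rise_per_repeat must be positive")
        if self.handedness not in ("left", "right"):
            raise InvalidSpecError("handedness must be 'left' or 'right'")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


_CA_SPACING = 3.3      # idealized Calpha-Calpha distance along a beta strand
_ARC_BULGE = 4.0       # how far beta-arcs bow out beyond the strand ends
_ARC_PAD = 0.14        # arc endpoints pulled in from the strand termini
_CB_REACH = 2.8        # united side-chain pseudo-atom, CA -> core distance

# one residue = (atom name, element, xyz) triples
_Residue = list[tuple[str, str, np.ndarray]]


def _strand_residue(x: float, y: float, z: float, direction: float,
                    core_dir: float | None) -> _Residue:
    """Idealized strand residue; core-facing positions get a pseudo-CB."""
    res = [
        ("N", "N", np.array([x, y - 1.2 * direction, z - 1.0])),
        ("CA", "C", np.array([x, y, z])),
        ("C", "C", np.array([x, y + 1.2 * direction, z + 0.55])),
        # carbonyl O points up the fibril axis, toward the next rung's amide
        ("O", "O", np.array([x, y + 1.2 * direction, z + 1.75])),
    ]
    if core_dir is not None:
        res.append(("CB", "C", np.array([x + core_dir * _CB_REACH, y, z])))
    return res


def _arc_residues(p_from: np.ndarray, p_to: np.ndarray,
                  n_res: int, bulge_sign: float) -> list[_Residue]:
    """Geometric connector residues between two strand ends.

    The arc is padded away from both strand termini so that a seamless
    continuation (next repeat or next monomer) stays outside clash range.
    """
    a = p_from + _ARC_PAD * (p_to - p_from)
    b = p_to - _ARC_PAD * (p_to - p_from)
    tangent = (p_to - p_from) / np.linalg.norm(p_to - p_from)
    out = []
    for i in range(n_res):
        t = (i + 1) / (n_res + 1)
        ca = a + t * (b - a)
        ca = ca + np.array([0.0, bulge_sign * _ARC_BULGE * math.sin(math.pi * t), 0.0])
        out.append([
            ("N", "N", ca - 0.6 * tangent),
            ("CA", "C", ca),
            ("C", "C", ca + 0.6 * tangent),
            ("O", "O", ca + 0.6 * tangent + np.array([0.0, 0.0, 1.2])),
        ])
    return out


def _template_repeat(spec: SolenoidSpec) -> tuple[list[_Residue], list[int], list[str]]:
    """One repeat's residues, their motif positions, and sheet labels.

    The template is left-handed in the winding sense used by the
    geometry module; right-handed solenoids mirror it in x.
    """
    half = spec.sheet_spacing / 2.0
    res: list[_Residue] = []
    motif_pos: list[int] = []
    sheet: list[str] = []
    core = set(anatomy.CORE_A) | set(anatomy.CORE_B)

    # motif a (sheet 1), N -> C along +y at x = -half
    for i, pos in enumerate(anatomy.MOTIF_A):
        y = (i - 3) * _CA_SPACING
        res.append(_strand_residue(-half, y, 0.0, +1.0,
                                   +1.0 if pos in core else None))
        motif_pos.append(pos)
        sheet.append("sheet1")
    a_end = np.array([-half, 3 * _CA_SPACING, 0.0])
    b_start = np.array([+half, 3 * _CA_SPACING, spec.stagger])
    for r, pos in zip(_arc_residues(a_end, b_start, 4, +1.0), anatomy.ARC1):
        res.append(r)
        motif_pos.append(pos)
        sheet.append("arc")
    # motif b (sheet 2), antiparallel: along -y at x = +half, z = stagger
    for i, pos in enumerate(anatomy.MOTIF_B):
        y = (3 - i) * _CA_SPACING
        res.append(_strand_residue(+half, y, spec.stagger, -1.0,
                                   -1.0 if pos in core else None))
        motif_pos.append(pos)
        sheet.append("sheet2")
    b_end = np.array([+half, -3 * _CA_SPACING, spec.stagger])
    next_a = np.array([-half, -3 * _CA_SPACING, spec.rise_per_repeat])
    for i, r in enumerate(_arc_residues(b_end, next_a, spec.arc2_length, -1.0)):
        res.append(r)
        motif_pos.append(anatomy.ARC2_START + i)
        sheet.append("arc")

    if spec.handedness == "right":
        mirror = np.array([-1.0, 1.0, 1.0])
        res = [[(n, e, xyz * mirror) for n, e, xyz in r] for r in res]
    return res, motif_pos, sheet


def _screw_matrix(twist_deg: float) -> np.ndarray:
    t = math.radians(twist_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_solenoid_coords(spec: SolenoidSpec):
    """Build a :class:`~curlinkit.geometry.SolenoidModel` from a spec.

    Repeat ``k`` is the template transformed by the ground-truth screw
    (rotation ``k * twist`` about +z, translation ``k * rise`` along
    +z), so composing the returned transform n-1 times maps repeat 1
    exactly onto repeat n when ``noise_sd`` is zero.
    """
    from .geometry import RepeatTransform, assemble_model

    residues, motif_pos, sheet = _template_repeat(spec)
    t_coords = np.array([xyz for r in residues for _, _, xyz in r])
    t_names = np.array([n for r in residues for n, _, _ in r])
    t_elements = np.array([e for r in residues for _, e, _ in r])
    t_res_index = np.repeat(np.arange(len(residues)),
                            [len(r) for r in residues])
    n_res = len(residues)
    rot = _screw_matrix(spec.twist_per_repeat)
    shift = np.array([0.0, 0.0, spec.rise_per_repeat])

    coords, names, elements, res_index = [], [], [], []
    res_repeat, res_motif, res_sheet = [], [], []
    current = t_coords.copy()
    for k in range(spec.n_repeats):
        coords.append(current.copy())
        names.append(t_names)
        elements.append(t_elements)
        res_index.append(t_res_index + k * n_res)
        res_repeat.extend([k] * n_res)
        res_motif.extend(motif_pos)
        res_sheet.extend(sheet)
        current = current @ rot.T + shift

    if spec.terminal_half:
        # lone motif a (sheet 1) stacked one rise above the last repeat
        n_half = len(anatomy.MOTIF_A)
        sel = t_res_index < n_half
        coords.append(t_coords[sel]
                      @ np.linalg.matrix_power(rot, spec.n_repeats).T
                      + spec.n_repeats * shift)
        names.append(t_names[sel])
        elements.append(t_elements[sel])
        res_index.append(t_res_index[sel] + spec.n_repeats * n_res)
        res_repeat.extend([spec.n_repeats] * n_half)
        res_motif.extend(anatomy.MOTIF_A)
        res_sheet.extend(["sheet1"] * n_half)

    xyz = np.concatenate(coords, axis=0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        xyz = xyz + rng.normal(0.0, spec.noise_sd, xyz.shape)

    # compact residue numbering (the half repeat skips template slots)
    _, res_index_compact = np.unique(np.concatenate(res_index),
                                     return_inverse=True)
    truth = RepeatTransform(
        rotation=rot,
        translation=shift,
        rise=spec.rise_per_repeat,
        twist=spec.twist_per_repeat,
        axis=np.array([0.0, 0.0, 1.0]),
    )
    model = assemble_model(
        xyz,
        np.concatenate(names),
        np.concatenate(elements),
        res_index_compact,
        repeat_of=np.asarray(res_repeat),
        motif_pos=np.asarray(res_motif),
        sheet_of=np.asarray(res_sheet, dtype=object),
        model_id=f"synthetic-solenoid-n{spec.n_repeats}-s{spec.seed}",
    )
    model.truth_transform = truth
    model.exact_coords = xyz       # float64; AtomArray stores float32
    return model
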