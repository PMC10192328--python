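"""Consensus building and CS / NCS / D classification of curlin repeats.

The centrosymmetry call compares the four core-facing residues of motif
a (consensus positions 1, 3, 5, 7) with their counterparts in motif b
(12, 14, 16, 18) under coarse residue equivalence classes: {N}, {Q},
small hydrophobic/polar {A,V,S,T,G} and bulky hydrophobic {I,L,M,F}.  A
repeat is degenerate (D) when a flanking Asn/Gln column is broken or the
repeat is substantially longer than the canonical 23 residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anatomy
from .mining import CurlinRepeat, SubunitAnnotation

__all__ = [
    "PositionFrequencyMatrix",
    "CurlinClassCall",
    "ClassificationError",
    "build_pfm",
    "classify_repeat",
    "classify_subunit",
    "classify_dataset",
    "terminal_analysis",
]

# declared conventions of the subunit-level vote
D_FRACTION_THRESHOLD = 0.25
CS_FRACTION_THRESHOLD = 0.75


class ClassificationError(ValueError):
    pass


@dataclass
class PositionFrequencyMatrix:
    """Residue counts over 24-aa kernel windows."""

    counts: pd.DataFrame          # index: position 1..24; columns: residues
    n_windows: int

    @property
    def consensus(self) -> str:
        return "".join(self.counts.idxmax(axis=1))

    @property
    def info_content(self) -> np.ndarray:
        """Bits per column: log2(20) - Shannon entropy (no small-sample
        correction; raw counts are exported for logo tools that apply one)."""
        freqs = self.counts.to_numpy() / self.n_windows
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0),
                             axis=1)
        return math.log2(20) - ent

    def to_dict(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "consensus": self.consensus,
            "info_content": [round(float(x), 6) for x in self.info_content],
            "counts": {str(p): row.to_dict()
                       for p, row in self.counts.iterrows()},
        }


def build_pfm(windows: list[str]) -> PositionFrequencyMatrix:
    """Tabulate residue counts per position over 24-aa windows."""
    if not windows:
        raise ValueError("no windows to tabulate")
    if any(len(w) != anatomy.WINDOW_LEN for w in windows):
        raise ValueError("all windows must be exactly 24 residues")
    residues = list(anatomy.AMINO_ACIDS)
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, anatomy.WINDOW_LEN + 1, name="position"),
        columns=residues, dtype=int,
    )
    for w in windows:
        for p, aa in enumerate(w.upper(), start=1):
            counts.at[p, aa] += 1
    return PositionFrequencyMatrix(counts=counts, n_windows=len(windows))


@dataclass
class CurlinClassCall:
    class_label: str                 # CS | NCS | D
    core_a: str
    core_b: str
    evidence: dict = field(default_factory=dict)


def _residue_at(sequence: str, repeat: CurlinRepeat, position: int) -> str | None:
    i = repeat.start + anatomy.offset(position)
    if i >= repeat.end or i >= len(sequence):
        return None
    return sequence[i]


def classify_repeat(repeat: CurlinRepeat, sequence: str) -> CurlinClassCall:
    """Classify one full repeat as CS, NCS or D.

    Half repeats carry motif a only and are treated as CS-compatible.
    Repeats must contain both core quartets (>= 18 residues); the
    terminal repeat of a mature sequence may be a bare kernel.
    """
    seq = sequence.upper()
    if repeat.half:
        core_a = "".join(_residue_at(seq, repeat, p) or "-" for p in anatomy.CORE_A)
        return CurlinClassCall("CS", core_a, "", {"half": True})
    if repeat.length < anatomy.KERNEL_LEN:
        raise ClassificationError(
            f"repeat of {repeat.length} aa lacks the core quartets")

    core_a = "".join(_residue_at(seq, repeat, p) or "-" for p in anatomy.CORE_A)
    core_b = "".join(_residue_at(seq, repeat, p) or "-" for p in anatomy.CORE_B)

    n_ok = (core_a[0] in anatomy.ALLOWED_N_FLANK
            and core_b[0] in anatomy.ALLOWED_N_FLANK)
    q_ok = (core_a[3] in anatomy.ALLOWED_Q_FLANK
            and core_b[3] in anatomy.ALLOWED_Q_FLANK)
    too_long = repeat.length > anatomy.DEGENERATE_LENGTH
    evidence = {"flank_n_intact": n_ok, "flank_q_intact": q_ok,
                "too_long": too_long}
    if not n_ok or not q_ok or too_long:
        return CurlinClassCall("D", core_a, core_b, evidence)

    pairs_equivalent = [anatomy.core_equivalent(a, b)
                        for a, b in zip(core_a, core_b)]
    evidence["core_pairs_equivalent"] = pairs_equivalent
    label = "CS" if all(pairs_equivalent) else "NCS"
    return CurlinClassCall(label, core_a, core_b, evidence)


def classify_subunit(annotation: SubunitAnnotation,
                     sequence: str | None = None) -> str:
    """Subunit class by vote over per-repeat calls.

    D wins when >= 25% of full repeats are degenerate; CS requires
    >= 75% CS repeats; everything else (including ties) is NCS.
    """
    seq = sequence or annotation.sequence
    if seq is None:
        raise ClassificationError("annotation carries no sequence")
    full = annotation.full_repeats
    if not full:
        raise ClassificationError("no full repeats to classify")
    calls = [classify_repeat(r, seq).class_label for r in full]
    frac_d = calls.count("D") / len(calls)
    frac_cs = calls.count("CS") / len(calls)
    if frac_d >= D_FRACTION_THRESHOLD:
        return "D"
    if frac_cs >= CS_FRACTION_THRESHOLD:
        return "CS"
    return "NCS"


def classify_dataset(dataset: list[SubunitAnnotation]) -> list[SubunitAnnotation]:
    """Fill ``class_label`` on every annotation (in place) and return it."""
    for ann in dataset:
        if ann.full_repeats:
            ann.class_label = classify_subunit(ann)
    return dataset


def terminal_analysis(annotation: SubunitAnnotation) -> dict:
    """Terminal repeat type and the fibril symmetry it implies.

    A subunit ending in a full repeat presents motif a and motif b
    overhangs at opposite ends, compatible with pure translational
    head-to-tail stacking; a terminal half repeat leaves motif-a
    overhangs at both ends, demanding a two-fold screw between
    consecutive subunits.
    """
    terminal = annotation.terminal_type
    return {
        "terminal_type": terminal,
        "implied_symmetry": "screw_2_1" if terminal == "half" else "translation",
    }
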