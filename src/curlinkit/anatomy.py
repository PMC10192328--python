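"""Canonical anatomy of a curlin repeat.

A curlin repeat is a ~23-residue strand-arc-strand (beta-arch) unit::

    position  1  2  3  4  5  6  7 | 8  9 10 11 | 12 13 14 15 16 17 18 | 19 20 21 22 (23)
    motif a   N  $  P1 $  P2 $  Q | X  G  X  X | N  $  P1 $  P2 $  Q  | X  G  X  X  (X)
              `------ strand 1 ---' `-- arc1 --' `----- strand 2 -----' `---- arc2 ----'

where ``$`` positions face the solvent (polar/charged), ``Psi`` (P1/P2)
positions face the steric-zipper core, and the flanking Asn/Gln build the
N- and Q-ladders of the beta-arcade.  Motif a forms sheet 1 of the
solenoid, motif b sheet 2.  All constants here are 1-based positions
within a repeat; converters to 0-based offsets are provided.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# 1-based positions within a repeat (Fig-style consensus numbering)
N_POS_A, Q_POS_A = 1, 7
N_POS_B, Q_POS_B = 12, 18
CORE_A = (1, 3, 5, 7)
CORE_B = (12, 14, 16, 18)
SURFACE_POSITIONS = (2, 4, 6, 13, 15, 17)
MOTIF_A = tuple(range(1, 8))
MOTIF_B = tuple(range(12, 19))
ARC1 = (8, 9, 10, 11)
ARC1_G = 9
ARC2_START = 19
ARC2_G = 20

KERNEL_LEN = 18          # Q at 7 ... Q at 18 spans 18 residues from repeat start
MOTIF_LEN = 7            # one strand motif (also the half-repeat length)
REPEAT_LEN_MIN = 21      # arc2 may shrink to 3 residues
REPEAT_LEN_CANONICAL = 23
WINDOW_LEN = 24          # kernel window used for consensus building

# residue vocabularies
PSI_ALPHABET = "AIVLFST"          # core-facing: hydrophobic, Ser or Thr
SURFACE_ALPHABET = "TSDEQNRY"     # solvent-facing: polar / charged
BULKY_HYDROPHOBIC = "ILMF"
SMALL_HYDROPHOBIC = "AV"
# arc "X" positions: N/Q excluded so arcs cannot mimic repeat anchors
ARC_X_ALPHABET = "ADEGHST"

# residue equivalence classes used by the centrosymmetry call
CORE_EQUIVALENCE_CLASSES = (
    frozenset("N"),
    frozenset("Q"),
    frozenset("AVSTG"),   # small hydrophobic / small polar
    frozenset("ILMF"),    # bulky hydrophobic
)

# residues tolerated at the flanking N positions (Ser is the documented
# functional replacement of Asn in E. coli CsgA) and Q positions
ALLOWED_N_FLANK = frozenset("NS")
ALLOWED_Q_FLANK = frozenset("Q")

# repeats longer than this are degenerate by length (mean 23 + one SD)
DEGENERATE_LENGTH = 28


def core_equivalent(a: str, b: str) -> bool:
    """True if two core residues fall in the same equivalence class."""
    return any(a in cls and b in cls for cls in CORE_EQUIVALENCE_CLASSES)


def offset(position: int) -> int:
    """0-based offset within the repeat of a 1-based consensus position."""
    return position - 1
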