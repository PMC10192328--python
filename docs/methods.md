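# Methods

## The curlin repeat model

A curlin repeat is modelled as a 21–31 residue unit with the consensus
anatomy

```
position  1  2  3  4  5  6  7 | 8  9 10 11 | 12 13 14 15 16 17 18 | 19 20 21 22 (23)
          N  $  Ψ₁ $  Ψ₂ $  Q | X  G  X  X | N  $  Ψ₁ $  Ψ₂ $  Q  | X  G  X  X  (X)
          └──── motif a ─────┘ └── arc 1 ─┘ └───── motif b ──────┘ └──── arc 2 ────┘
```

Motifs a and b form strands 1 and 2 of a β-arch; motif a belongs to
sheet 1 of the solenoid and motif b to sheet 2. Ψ positions
({A,I,V,L,F,S,T}) face the steric-zipper core, $ positions (polar
{T,S,D,E,Q,N,R,Y}) face the solvent, and the flanking Asn/Gln build the
N- and Q-ladders of the β-arcade. Arc 2 is 4–5 residues in canonical
repeats; insertions extend it. A terminal *half repeat* is a lone
motif a.

## Repeat mining

Three passes run in precedence order, each only on residue spans not
claimed by an earlier pass:

1. **kernel** — Q at relative positions 7 and 18 (the Q-x₁₀-Q kernel);
2. **n_anchor** — N¹…Q⁷…G⁹ with the second Q absent (≥ 22 residues of
   room);
3. **degenerate** — the relaxed skeleton x-x-[AIVLSTG]-x-[IVLQTA]-x-Q-x-G.

Within a pass, scanning is left-to-right and the leftmost anchor wins.
The claimed repeat extends to the next plausible repeat start at
distance 21–31: downstream candidates that begin with Asn are preferred
(they are true repeat anchors), then bare anchor matches, smallest
distance first; with no downstream anchor the repeat takes a 4-residue
arc 2 (22 aa), clipped at the chain end (a C-terminal repeat may be a
bare 18-residue kernel, as in mature *E. coli* CsgA whose last repeat is
19 aa). A trailing lone motif a within 12 residues of the C-terminus is
emitted as a half repeat. All three passes anchor on the motif-a Q⁷, so
that column is the one position the cascade cannot tolerate losing.

**N22-like leaders.** A leading unclaimed segment of 20–26 residues in
which ≥ 2 of the four flank positions (1, 7, 12, 18) fall outside
{N, Q, S} is flagged `n22_like`. (A detection via the degenerate pass is
impossible by construction: that pass requires an intact Q⁷, which
N22-like segments have lost.)

**Repeat length estimator.** Residues-per-repeat is the mean ± SD of
per-sequence (mature length / detected repeat count) ratios, not an OLS
slope; for canonical synthetic curliomes it returns exactly 23.0.

**Kernel windows.** One 24-aa window per kernel-pass full repeat,
always starting at the repeat start so the first kernel Q occupies
window position 7. Windows that would overlap the previous window or
run past the chain are dropped rather than shifted: shifting would
drift the kernel frame by one column per window in tandem 23-aa arrays
and make the pooled consensus meaningless. In such arrays every other
repeat yields a window.

## Classification

Per repeat: **D** if a flanking column is broken (position 1/12 outside
{N, S} — Ser is the documented functional replacement of Asn — or
position 7/18 not Q) or if the repeat exceeds 28 aa (23 + one SD);
otherwise **CS** if all four core pairs (1↔12, 3↔14, 5↔16, 7↔18) fall in
the same equivalence class among {N}, {Q}, small {A,V,S,T,G}, bulky
{I,L,M,F}; otherwise **NCS**. Per subunit: D if ≥ 25% of full repeats
are D; else CS if ≥ 75% are CS; else NCS. The thresholds and
equivalence classes are declared conventions — the underlying notion of
"(nearly) identical" cores has no published metric — and are exported
with every classification run.

Terminal analysis maps a full terminal repeat to translational
head-to-tail stacking and a half terminal to a 2₁ screw: a half-terminal
subunit presents motif-a overhangs at both ends, and only a 180°
rotation between consecutive monomers lets the β-arcade continue.

## Geometry

**Superposition** is closed-form least-squares (SVD/Kabsch) on
positionally equivalent main-chain atoms (N, CA, C, O matched by motif
position; insertions skipped). Reflections are rejected (det = +1), so
mirroring a model flips the reported handedness instead of being
absorbed.

**Helix parameters.** Each adjacent repeat pair gives a rigid
transform. The screw axis is taken from the mean pair rotation vector
when the mean rotation exceeds 10⁻³ rad (the rotation axis is then
signal); below that the axis of the fitted rotation is numerically
meaningless and the principal direction of the repeat-centroid path is
used instead (at zero twist that path is a straight line). Rise is the
translation projected on the axis, twist the signed rotation about it
(right-hand rule, axis oriented along propagation): positive twist =
right-handed solenoid. Per-repeat values are averaged over pairs. When
|twist| < 0.2°/repeat the handedness falls back to a winding-chirality
rule: with ẑ the propagation direction, ŝ the motif-a N→C vector and ĉ
the sheet1→sheet2 vector, sign((ŝ × ĉ)·ẑ) < 0 is *left*. The sign
assignment is frozen against the package's own left-handed archetype,
which reproduces the published chirality of deposited curli models
(left-handed, negligible twist).

**Stagger** is the mean axial offset between sheet-2 and sheet-1 strand
Cα centroids within repeats (absolute value reported).

**H-bond candidates** are donor/acceptor heavy-atom (N, O) pairs within
3.5 Å, excluding intra-residue pairs and the peptide C(i)–N(i+1)
contact; pairs closer than two residues in sequence count only when
they bridge the two sheets. `core_only` drops side-chain atoms at
surface positions ($ columns and non-Gly arc positions). The 3.5 Å
cutoff with no angular term is a declared convention — published
"polar contact" counts come from visualisation tools with unstated
criteria — and is configurable and embedded in every report.

**Buried area** is (SASA₁ + SASA₂ − SASA₁₊₂)/2 per full repeat over the
strand residues of the two sheets (arc residues belong to neither and
are excluded), via Shrake–Rupley with probe 1.4 Å and a fixed,
deterministic point count (default 500), both reported with the result.
The per-side halving convention is declared; backbone-only models are
flagged approximate. Because the sampling sphere is fixed in the global
frame, SASA is rotation-invariant only to ~1%, unlike the other metrics
(exact to numerical precision).

## Fibril building

The junction transform is the monomer's own mean repeat transform so
the β-arcade continues at the intra-monomer spacing: per-monomer rise =
per-repeat rise × repeat units spanned, with *n* units for a
full-terminal and *n* + ½ for a half-terminal subunit (an idealized
15.5-repeat subunit steps 74.4 Å at 4.8 Å/repeat; deposited fibrils
refine slightly lower because their terminal arcs are compressed).
Screw mode adds exactly 180° about the fibril axis; sub-millidegree
solenoid twists are snapped to zero so the operator algebra
(screw ∘ screw = translation of 2 × rise) is exact. Builds are rejected
when inter-monomer heavy atoms come closer than 2.0 Å (configurable).
Antiparallel mode flips the monomer about the axis perpendicular to
both the fibril axis and the strand direction — reversing strand
polarity at the interface — and scans the axial offset in 0.2 Å steps
for maximal interface H-bonds; the scan optimises the dimer (tail-tail)
interface only.

The *stagger-pattern period* reported with interface metrics is the
shortest shift under which the sequence of axial gaps between
consecutive strand levels (both sheets pooled) repeats, at 0.3 Å
tolerance. Seamless head-to-tail fibrils give one strand level (2.4 Å);
antiparallel dimers break the uniform pattern and the period grows to
the order of the monomer span.

## Synthetic data: what it emulates, and what it does not

The sequence generator builds exact canonical repeats: CS draws one
Ψ₁/Ψ₂ pair reused in both motifs; NCS draws bulky {I,L,M,F} for motif a
and small {A,V} for motif b; $ positions are sampled uniformly from the
polar set (the empirical per-position composition of mined curliomes is
not published). Arc X positions are drawn from {A,D,E,G,H,S,T} — N and
Q excluded so arcs cannot fake a repeat anchor, which is what makes
exact miner round-trips achievable. D-class subunits degrade a
deterministic count (round(rate × n), ≥ 1) of randomly placed repeats,
each by substituting a flanking N¹ or Q¹⁸ with G/A/L (never Q⁷) plus an
arc-2 insertion of 1–8 residues in half of them; a literal per-repeat
binomial draw at rate 0.3 would leave the subunit-level call near
chance against the 25% threshold and cannot meet a 95% recovery bar.
The N22-like leader is one 22-aa pseudo-repeat with all four flanks
mutated to G and inert (non-N/Q) surface positions.

The coordinate generator propagates one idealized template repeat
(3.3 Å Cα spacing along strands, backbone N/CA/C/O plus a united
pseudo-Cβ reaching 2.8 Å into the core at the eight core positions,
geometric arc connectors) by an exact screw transform, so rise, twist,
handedness and stagger are known by construction; a float64 copy of the
coordinates is kept alongside the float32 structure so the
transform-composition invariant holds to 10⁻⁶ Å. It does **not**
emulate side-chain rotamers, the Gln/Asn amide ladders, Ramachandran-
valid arcs, or realistic SASA — so a green geometry test establishes
parameter recovery and metric self-consistency, not agreement with
full-atom model values (per-repeat H-bond counts and buried areas of
real subunits require full-atom coordinates).

## Numerical choices

- Twist below 10⁻³ rad total mean rotation: axis from centroid path;
  twist between noise floor and 0.2°/repeat is reported but handedness
  uses the winding rule.
- RMSD SD over pairs uses ddof = 1; a single pair reports SD 0.
- Superposition requires ≥ 3 paired residues; sparser pairs are skipped
  with a warning.
- PFM information content is log₂20 − Shannon entropy with no
  small-sample correction; raw counts are exported for logo tools that
  apply their own.
- All thresholds (H-bond cutoff, clash cutoff, CS/D rules, SASA probe
  and points) live in one configuration dict whose hash is embedded in
  every run manifest; machine outputs use 0-based half-open
  coordinates.

## Known limitations

- The mining cascade is tuned to the canonical anchor columns; repeats
  that lose Q⁷ are undetectable by construction (all three passes
  anchor on it), which mirrors the behaviour of the original motif
  expressions.
- Interface H-bond counts use the same distance-only criterion as the
  intra-monomer metric; they are comparable with each other but not
  directly with counts from angular-term detectors.
- The antiparallel builder optimises a dimer; extended antiparallel
  stacks alternate a second interface type it does not optimise.
- Backbone+pseudo-Cβ SASA underestimates buried area relative to
  full-atom models; the `approximate` flag marks this.
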