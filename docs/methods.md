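# Methods

This document describes the physical model, the algorithms, the default
parameters and the deliberate design decisions behind `pentassembly`.

## Scope and model

`pentassembly` analyses hydrogen-bond patterns in small assemblies of two
pentapeptides:

* **CREKA** — Cys-Arg-Glu-Lys-Ala;
* **CRE(NMe)KA** — the same sequence with an *N*-methylated glutamate at
  position 3 (residue code `MEG`). The backbone nitrogen of residue 3
  carries a methyl carbon (`CN`) instead of the amide hydrogen, so that
  nitrogen can never donate a hydrogen bond.

All internal coordinates are in **nanometres**; PDB files are read and
written in ångströms (conversion factor 10). Keeping the analysis in nm
means the hydrogen-bond cutoffs are used exactly as stated, with no unit
conversion at the comparison site.

## Hydrogen-bond criterion

A donor-H/acceptor triple is a hydrogen bond iff

* d(H···O) < 0.30 nm, **strictly**, and
* the angle N–H···O (vertex at the hydrogen) > 120.0°, **strictly**.

Both cutoffs are configurable (`InteractionConfig`); the defaults implement
the criterion above. Strict inequalities are deliberate: an observation
exactly at the cutoff is *not* a bond, so boundary behaviour is
deterministic and testable.

### Donor inventory (per CREKA chain)

| group | heavy atom | hydrogens | class |
|---|---|---|---|
| N-terminal ammonium | N (res 1) | H1, H2, H3 | side-group-like |
| backbone amides | N (res 2–5) | H | main chain |
| Arg guanidinium | NE, NH1, NH2 | HE, HH11/HH12, HH21/HH22 | side chain |
| Lys ammonium | NZ | HZ1–HZ3 | side chain |

For CRE(NMe)KA the residue-3 amide is removed from the inventory (no H to
donate); everything else is identical. The Cys thiol (S–H) is excluded by
default because the criterion is defined on N–H···O geometry; it can be
enabled via `InteractionConfig(include_cys_thiol=True)`.

`is_sidechain` on donors/acceptors means "not a backbone amide group":
the N-terminal ammonium and its hydrogens are flagged side-group-like even
though the nitrogen is a backbone atom, because an ammonium is chemically
not an amide and its bonds should not be confused with β-structure
main-chain bonds. The residue-5 carbonyl O remains main-chain; the terminal
carboxylate oxygen `OXT` is side-group-like.

### Acceptor inventory

Backbone carbonyl O of residues 1–5, Glu side-chain OE1/OE2, and the
terminal OXT: 8 distinct oxygen atoms per chain. A protonated Glu
(`glu_protonated=True` in the builder) keeps its oxygens as acceptors by
default; `charged_acceptors_only=True` removes them.

### Detection algorithm

Candidate H···O pairs come either from a KD-tree range query (`grid`,
default) or from an exhaustive all-pairs distance matrix (`brute`). The two
paths are required to return identical bond sets and are tested against
each other on randomized frames (oracle equivalence). A covalent guard
skips H–O pairs closer than 0.02 nm within the same residue. Output is
sorted deterministically.

Periodic boundary conditions (minimum-image, orthorhombic box) are
available via `use_pbc=True` on frames that carry a box; the default is
off because every synthetic fixture is generated in open space.

## Salt bridges

A salt bridge is a cation-N/anion-O heavy-atom pair closer than 0.40 nm:
cations are Arg NE/NH1/NH2, Lys NZ and the protonated N-terminus; anions
are Glu OE1/OE2 (unless protonated) and the C-terminal carboxylate O/OXT.
Multiple atom pairs between one residue pair are deduplicated, keeping the
shortest.

## Aggregates

Chains are nodes of a contact graph; two chains are linked when they share
an intermolecular hydrogen bond, a salt bridge, or any intermolecular
heavy-atom pair closer than 0.45 nm. Aggregates are the connected
components. The heavy-atom clause makes "aggregate" a superset of the
H-bonded clusters, so salt-bridge-only or packing-only dimers still count
as assembled.

## Bond classification (seven categories)

Within one chain (intramolecular):

* donor and acceptor both backbone amide groups, donor residue index −
  acceptor index = 3 → **beta_turn** (the i→i+3 bond);
* difference = 2 → **gamma_turn**;
* any other main-main difference → **other_intra_main**;
* at least one side group involved → **intra_side**.

Between chains (intermolecular):

* at least one side group involved → **inter_side**;
* both residues in the β region of the Ramachandran map → **beta_sheet**;
* otherwise → **main_main**.

Residue conformations come from (φ, ψ): the β region is
φ ∈ [−180°, −90°], ψ ∈ [90°, 180°] ∪ [−180°, −170°] (the ψ wrap-around
keeps the extended basin contiguous); the turn region is φ ∈ [−120°, −30°],
ψ ∈ [−80°, 30°]. The two regions are disjoint by construction. Terminal
residues lack φ or ψ and are labelled UNDEFINED — a bond donated by or
accepted at a terminal residue can therefore classify as main_main rather
than beta_sheet even in a perfect sheet. This is a deliberate conservative
choice: β-structure is only asserted where both partners measurably adopt
β dihedrals.

Pattern statistics stratify bond counts by the aggregate size of the donor
chain and normalize to percentages **per size bin**; pooled mode
accumulates counts over all frames before normalizing.

Strand orientation for a hydrogen-bonded pair is the sign of the dot
product of the Cα1→Cα5 end-to-end vectors: positive = parallel.

## Synthetic structures

The synthetic module builds idealized, not physically relaxed, structures.
What it does emulate: correct covalent topology and ideal bond
lengths/angles, requested backbone dihedrals, realizable hydrogen-bond and
salt-bridge geometries. What it does not emulate: thermal ensembles,
solvent, side-chain rotamer diversity, or energetic relaxation — the side
chains are fixed ideal rotamers.

* **Chains** grow by internal coordinates (NeRF placement) with standard
  backbone geometry (N–CA 0.1458 nm, CA–C 0.1525 nm, C–N 0.1329 nm,
  ω = 180°). Gaussian coordinate noise (`noise_sigma`, nm) is applied
  after construction, seeded and reproducible.
* **Sheet pairs** place a rigid copy of the first strand by a deterministic
  grid search over twist, stagger, separation and normal offset,
  maximizing the number of inter-main-chain hydrogen bonds; ties prefer
  placements that engage the residue-3 amide donor. The search runs once
  on the shared backbone geometry and the *same* rigid transform is applied
  for both sequences ("twin" construction), so the N-methylated variant
  differs from CREKA only by the missing residue-3 donor — this guarantees
  strictly fewer inter-main-chain bonds for CRE(NMe)KA by construction
  rather than by coincidence. Clash control is backbone-based (≥ 0.22 nm
  between N/CA/C/O atoms): ideal frozen side chains would otherwise veto
  genuinely realizable sheet geometries, and a backbone-only criterion is
  sequence-independent, which the twin construction requires.
* **Turn chains** use fixed φ/ψ presets that realize the i→i+3 (β-turn) or
  i→i+2 (γ-turn) backbone bond with margin above the cutoffs.
* **Salt-bridge dimers** search a small rotation/offset grid for a placement
  with ≥ 1 Arg···Glu bridge and zero inter-main-chain hydrogen bonds.
* **Minimum-bias boxes** rejection-sample random placements (random
  rotation + uniform centre) until all centre distances ≥ 1.8 nm and all
  inter-chain atom gaps ≥ 0.5 nm; chains are kept wholly inside the box.
  Defaults: 15 chains in 9.5 × 8.5 × 9.0 nm.

## Charge model

Titratable sites and pKa values: Glu side 4.2 (acid), Arg side 12.5 (base),
Lys side 10.5 (base), N-terminus 8.0 (base), C-terminus 3.0 (acid). The
dominant-state rule protonates a site iff pH < pKa (strict); acids
contribute 0/−1, bases +1/0. This gives net +2 at pH 4, +1 at pH 7, 0 at
pH 10, and the counterion bookkeeping (one chloride per positive unit
charge per chain) yields 15 chloride ions for 15 chains at pH 7. A
Henderson–Hasselbalch fractional charge is provided alongside for
continuous curves. The Cys thiol (pKa 8.3) is excluded from the default
site set so the ladder treats it as non-titrating; it can be enabled
explicitly.

## Dendrite model

A two-stage lattice embodiment of dendritic growth:

1. **DLA pre-nucleation** — classic on-lattice diffusion-limited
   aggregation. Walkers are launched on a circle of radius r_max + 5,
   discarded beyond three launch radii, and stick on first contact with
   probability `stickiness`. Far from the cluster the walk takes exact
   long radial jumps (first-passage sampling on a circle), a standard
   speed-up that leaves the harmonic measure unchanged.
2. **Coalescence fill** — particles deposit at perimeter sites with the
   most occupied neighbours (concave sites first), which preserves
   connectivity and never increases the perimeter-to-area ratio.

### Box-counting dimension

`fractal_dimension` fits the least-squares slope of log N(b) versus
log(1/b) over dyadic box sizes b, where N(b) is the number of occupied
boxes, and reports the slope with its standard error. Two standard
estimator practices are applied:

* **Minimal cover.** The box-counting dimension is defined through the
  *minimal* number of boxes covering the set; a fixed grid overestimates
  N(b) at coarse scales. N(b) is therefore minimized over a 4 × 4 grid-offset
  scan per scale.
* **Scale window.** Scales where the mean box occupancy A/N(b) < 10 are
  excluded: there the count saturates toward the site count and the local
  slope reflects the finite sampling of the set, not its geometry.
  Scales above half the cluster span are excluded as well (fewer than a
  handful of boxes carry no scaling information). At least four dyadic
  scales must survive, otherwise a precision error is raised.

The estimator is exact on the calibration limits (1.000 on a 512-site
line, 2.000 on a 64×64 filled square).

**Finite-size caveat.** The asymptotic dimension of 2-D lattice DLA is
≈ 1.71, but box counting on finite clusters is biased downward; at 5,000
particles individual seeds measure ≈ 1.57–1.66 with this estimator (a
naive full-range fit without the scale window reads ≈ 1.42). The
Monte-Carlo mean over seeds lands at ≈ 1.60, at the lower edge of the
classic [1.6, 1.8] window; a mass–radius fit on the same clusters gives
≈ 1.7, confirming the clusters themselves are proper DLA and the residual
shortfall is estimator finite-size bias, not a growth artefact. Larger
clusters converge upward.

## Error taxonomy

All package errors derive from `PentassemblyError`: `FormatError`
(unparsable files, reported with line numbers), `TopologyError` (wrong
sequence/atoms; `MissingHydrogenError` for absent amide hydrogens),
`ParameterError` (invalid arguments), `FeasibilityError` (builder cannot
satisfy constraints), `UsageError` (meaningless operation, e.g. orientation
of non-bonded strands), `ConsistencyError` (contradictory inputs),
`PrecisionError` (estimate would be unreliable).

## Reproducibility

Every stochastic routine takes an explicit seed and is bitwise
deterministic for a fixed seed. Report files contain no timestamps or
environment-dependent content, so repeated runs are byte-identical.

## Limitations

* Synthetic fixtures are idealized geometry, not thermodynamic samples;
  percentages measured on them characterize the pipeline, not the peptide.
* The conformation labelling is a coarse two-region Ramachandran gate;
  terminal residues are never labelled β.
* The aggregate contact cutoff (0.45 nm) and salt-bridge cutoff (0.40 nm)
  are conventional values, configurable but not fitted.
* The dendrite module is quantitatively generic: lattice units do not map
  onto physical lengths or concentrations.
* Box-counting at 5,000 particles underestimates the asymptotic DLA
  dimension (see above); treat reported dimensions as finite-size
  estimates.
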