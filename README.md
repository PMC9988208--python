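# pentassembly

Hydrogen-bond pattern analysis for the self-assembly of the CREKA-family
pentapeptides, with seeded synthetic structure generation, protonation-state
bookkeeping and a lattice dendrite-growth model.

## What it does

The tumor-homing pentapeptide **CREKA** (Cys-Arg-Glu-Lys-Ala) and its
backbone-engineered variant **CRE(NMe)KA** (*N*-methylated glutamate at
position 3) differ by a single amide hydrogen: the methylated backbone
nitrogen cannot donate a hydrogen bond, which hampers β-sheet stacking and
changes how the peptide assembles. This package provides the analysis
pipeline to quantify that difference on atomistic structures:

* **structures** — domain model for pentapeptide chains, frames and
  trajectories; multi-model PDB I/O with explicit hydrogens and the
  noncanonical `MEG` residue; backbone dihedrals and Ramachandran-region
  conformation labels.
* **interactions** — hydrogen-bond detection with the geometric criterion
  d(H···O) < 0.3 nm and ∠N–H···O > 120° (both strict), plus salt bridges.
* **assembly** — aggregate detection (connected components of a chain
  contact graph), a seven-way bond classifier (β-turn, γ-turn, other
  intra-main, intra-side, β-sheet, main-main, inter-side), strand
  orientation, and aggregate-size-stratified pattern tables.
* **synthetic** — seeded builders for idealized chains, two-stranded
  sheets (parallel/antiparallel, for both sequences), turn conformers,
  salt-bridged dimers, and minimum-bias multi-chain boxes.
* **charge** — dominant protonation state versus pH from a pKa ladder, and
  counterion bookkeeping.
* **dendrite** — two-stage lattice model of dendritic microstructure
  formation (DLA pre-nucleation + coalescence fill) with a box-counting
  fractal-dimension estimator.

See [docs/methods.md](docs/methods.md) for the model, parameters and design
decisions.

## Worked example

Net charge and counterions at neutral pH:

```console
$ pentassembly charge --ph 7 --n-chains 15
{
  "counterions": {
    "count": 15,
    "species": "chloride"
  },
  "fractional_net": 0.9105,
  "net": 1,
  "pH": 7.0,
  "per_site": {
    "Arg-side": 1,
    "C-term": -1,
    "Glu-side": -1,
    "Lys-side": 1,
    "N-term": 1
  }
}
```

Analyze a synthetic antiparallel CREKA sheet (any PDB file with explicit
hydrogens works the same way via `--input`):

```console
$ pentassembly analyze --preset antiparallel-sheet-creka --out report
report written to report
$ cat report/pattern.tsv
aggregate_size	beta_turn	gamma_turn	other_intra_main	intra_side	beta_sheet	main_main	inter_side
2	0.00	0.00	0.00	0.00	50.00	50.00	0.00
$ cat report/orientation.json
{
  "n_antiparallel": 1,
  "n_parallel": 0,
  "pairs": {
    "A-B": "ANTIPARALLEL"
  }
}
```

(The main_main share comes from sheet bonds anchored at terminal residues,
which carry no measurable φ/ψ pair and are never labelled β; see
docs/methods.md.)

The same pipeline as a library:

```python
from pentassembly import (
    Trajectory, build_sheet_pair, detect_hbonds, pattern_statistics,
)

frame = build_sheet_pair("ANTIPARALLEL", "CRE^N^KA")
bonds = detect_hbonds(frame)                      # strict 0.3 nm / 120 deg
table = pattern_statistics(Trajectory([frame]))
print(table.to_dataframe())
```

Grow and render a dendrite:

```sh
pentassembly dendrite --n 5000 --fill 1000 --seed 7 --png dendrite.png
```

## Tests

```sh
python -m pytest tests -q
```

`tests/test_acceptance.py` holds the headline checks (charge ladder,
counterions, minimum-bias box, detector oracle equivalence, classifier
fixtures, normalization, dendrite properties); the remaining files test
each module in depth, including property-based tests (hypothesis).

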