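"""Domain model, PDB round-trip, dihedrals and conformation labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentassembly.errors import (
    FormatError,
    MissingHydrogenError,
    TopologyError,
)
from pentassembly.geometry import dihedral, random_rotation_matrix
from pentassembly.structures import (
    Atom,
    ConformationLabel,
    ConformationRegions,
    PeptideChain,
    Residue,
    SystemFrame,
    Trajectory,
    assign_conformation,
    backbone_dihedrals,
    chain_conformations,
    copy_chain,
    read_structure,
    write_structure,
)
from pentassembly.synthetic import BuildSpec, build_chain

from conftest import EXTENDED


# ---------------------------------------------------------------------------
# domain model validation
# ---------------------------------------------------------------------------


def test_sequence_validation_rejects_wrong_residue(extended_chain):
    bad = copy_chain(extended_chain)
    bad.residues[2].code = "ALA"  # CRAKA is not a valid sequence
    with pytest.raises(TopologyError):
        bad.validate()


def test_meg_must_not_carry_amide_h():
    res = Residue(index=3, code="MEG", atoms=[
        Atom(1, "N", "N", (0, 0, 0)),
        Atom(2, "H", "H", (0.1, 0, 0)),
        Atom(3, "CN", "C", (0, 0.1, 0)),
    ])
    with pytest.raises(TopologyError):
        res.validate()


def test_meg_requires_cn():
    res = Residue(index=3, code="MEG", atoms=[Atom(1, "N", "N", (0, 0, 0))])
    with pytest.raises(TopologyError):
        res.validate()


def test_duplicate_chain_ids_rejected(extended_chain):
    frame = SystemFrame(0, [extended_chain, copy_chain(extended_chain)])
    with pytest.raises(TopologyError):
        frame.validate()


def test_atom_rejects_nonfinite_position():
    with pytest.raises(TopologyError):
        Atom(1, "CA", "C", (np.nan, 0, 0))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def test_pdb_roundtrip_single_frame(tmp_path, beta_turn_chain):
    path = tmp_path / "turn.pdb"
    traj = Trajectory([SystemFrame(0, [copy_chain(beta_turn_chain)])])
    write_structure(traj, path)
    back = read_structure(path)
    assert back.n_frames == 1
    chain = back.frames[0].chains[0]
    assert chain.sequence == beta_turn_chain.sequence
    assert chain.n_term_protonated and chain.c_term_deprotonated
    # PDB stores 3 decimals in Angstrom -> 1e-4 nm resolution
    np.testing.assert_allclose(
        chain.coordinates(), beta_turn_chain.coordinates(), atol=1e-3
    )


def test_pdb_roundtrip_multimodel(tmp_path, extended_chain, beta_turn_chain):
    path = tmp_path / "traj.pdb"
    f0 = SystemFrame(0, [copy_chain(extended_chain)])
    c1 = copy_chain(extended_chain)
    c1.set_coordinates(c1.coordinates() + np.array([1.0, 0.0, 0.0]))
    f1 = SystemFrame(1, [c1])
    write_structure(Trajectory([f0, f1]), path)
    back = read_structure(path)
    assert back.n_frames == 2
    np.testing.assert_allclose(
        back.frames[1].chains[0].coordinates() - back.frames[0].chains[0].coordinates(),
        np.tile([1.0, 0.0, 0.0], (len(extended_chain.coordinates()), 1)),
        atol=2e-3,
    )


def test_pdb_roundtrip_meg_chain(tmp_path):
    chain = build_chain(BuildSpec(sequence="CRE^N^KA", phi_psi=EXTENDED))
    path = tmp_path / "meg.pdb"
    write_structure(Trajectory([SystemFrame(0, [chain])]), path)
    back = read_structure(path)
    res3 = back.frames[0].chains[0].residues[2]
    assert res3.code == "MEG"
    assert res3.has_atom("CN") and not res3.has_atom("H")


def test_read_rejects_six_residues(tmp_path, extended_chain):
    path = tmp_path / "six.pdb"
    traj = Trajectory([SystemFrame(0, [copy_chain(extended_chain)])])
    write_structure(traj, path)
    text = path.read_text()
    extra = [
        line.replace(" ALA A   5 ", " ALA A   6 ")
        for line in text.splitlines()
        if " ALA A   5 " in line
    ]
    assert extra  # the injected sixth residue must exist
    path.write_text(text.rstrip("\n") + "\n" + "\n".join(extra) + "\n")
    with pytest.raises(TopologyError):
        read_structure(path)


def test_read_reports_corrupt_coordinates_with_line_number(tmp_path, extended_chain):
    path = tmp_path / "bad.pdb"
    write_structure(Trajectory([SystemFrame(0, [copy_chain(extended_chain)])]), path)
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines):
        if line.startswith("ATOM"):
            lines[i] = line[:30] + "  xx.xxx" + line[38:]
            broken = i + 1
            break
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(FormatError, match=str(broken)):
        read_structure(path)


def _strip_amide_h(path, res_field=" GLU A   3 "):
    lines = [
        line
        for line in path.read_text().splitlines()
        if not (res_field in line and line[12:16].strip() == "H")
    ]
    path.write_text("\n".join(lines) + "\n")


def test_missing_amide_h_strict(tmp_path, extended_chain):
    path = tmp_path / "noh.pdb"
    write_structure(Trajectory([SystemFrame(0, [copy_chain(extended_chain)])]), path)
    _strip_amide_h(path)
    with pytest.raises(MissingHydrogenError):
        read_structure(path, strict_h=True)


def test_missing_amide_h_reconstructed(tmp_path, extended_chain):
    path = tmp_path / "noh.pdb"
    write_structure(Trajectory([SystemFrame(0, [copy_chain(extended_chain)])]), path)
    _strip_amide_h(path)
    traj = read_structure(path, strict_h=False)
    res3 = traj.frames[0].chains[0].residues[2]
    assert res3.has_atom("H")
    d = np.linalg.norm(res3.atom("H").position - res3.atom("N").position)
    assert 0.09 < d < 0.11  # reconstructed at the amide N-H bond length


def test_meg_alias_accepted(tmp_path):
    chain = build_chain(BuildSpec(sequence="CRE^N^KA", phi_psi=EXTENDED))
    path = tmp_path / "alias.pdb"
    write_structure(Trajectory([SystemFrame(0, [chain])]), path)
    path.write_text(path.read_text().replace("MEG", "NMG"))
    traj = read_structure(path)
    assert traj.frames[0].chains[0].residues[2].code == "MEG"


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------


def test_builder_dihedrals_recovered(beta_turn_chain):
    """Measured phi/psi equal the requested internal coordinates."""
    from pentassembly.synthetic import BETA_TURN_PHI_PSI

    measured = backbone_dihedrals(beta_turn_chain)
    assert measured[0][0] is None and measured[-1][1] is None
    for (phi_t, psi_t), (phi_m, psi_m) in zip(BETA_TURN_PHI_PSI, measured):
        if phi_t is not None:
            assert phi_m == pytest.approx(phi_t, abs=1.0)
        if psi_t is not None and psi_m is not None:
            assert psi_m == pytest.approx(psi_t, abs=1.0)


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 2**31 - 1))
def test_dihedrals_invariant_under_rigid_motion(seed):
    chain = build_chain(BuildSpec(phi_psi=EXTENDED))
    rng = np.random.default_rng(seed)
    moved = chain.transformed(
        rotation=random_rotation_matrix(rng), translation=rng.uniform(-5, 5, 3)
    )
    for (p0, s0), (p1, s1) in zip(backbone_dihedrals(chain), backbone_dihedrals(moved)):
        if p0 is not None:
            assert p1 == pytest.approx(p0, abs=1e-6)
        if s0 is not None:
            assert s1 == pytest.approx(s0, abs=1e-6)


def test_dihedral_sign_convention():
    # right-angle torsion; sign convention agrees with biotite's dihedral
    p = np.array([1.0, 0.0, 0.0])
    q = np.array([0.0, 0.0, 0.0])
    r = np.array([0.0, 1.0, 0.0])
    s = np.array([0.0, 1.0, 1.0])
    assert dihedral(p, q, r, s) == pytest.approx(-90.0)
    assert dihedral(s, r, q, p) == pytest.approx(-90.0)  # palindromic invariance
    assert dihedral(p, q, r, np.array([0.0, 1.0, -1.0])) == pytest.approx(90.0)


# ---------------------------------------------------------------------------
# conformation labels
# ---------------------------------------------------------------------------


def test_beta_and_turn_regions_disjoint_defaults():
    regions = ConformationRegions()
    for phi in np.linspace(-180, 180, 37):
        for psi in np.linspace(-180, 180, 37):
            assert not (regions.in_beta(phi, psi) and regions.in_turn(phi, psi))


@pytest.mark.parametrize(
    "phi,psi,expected",
    [
        (-139.0, 135.0, ConformationLabel.BETA),
        (-119.0, 113.0, ConformationLabel.BETA),
        (-150.0, -175.0, ConformationLabel.BETA),  # psi wrap-around
        (-60.0, -30.0, ConformationLabel.TURN_REGION),
        (75.0, -65.0, ConformationLabel.OTHER),
        (60.0, 60.0, ConformationLabel.OTHER),
    ],
)
def test_assign_conformation(phi, psi, expected):
    assert assign_conformation(phi, psi) is expected


def test_chain_conformations_termini_undefined(extended_chain):
    labels = chain_conformations(extended_chain)
    assert labels[0] is ConformationLabel.UNDEFINED
    assert labels[-1] is ConformationLabel.UNDEFINED
    assert all(l is ConformationLabel.BETA for l in labels[1:4])
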