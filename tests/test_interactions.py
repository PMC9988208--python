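"""Donor/acceptor chemistry, the geometric H-bond criterion, salt bridges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentassembly.interactions import (
    InteractionConfig,
    detect_hbonds,
    detect_salt_bridges,
    enumerate_acceptors,
    enumerate_donors,
)
from pentassembly.structures import SystemFrame, copy_chain
from pentassembly.synthetic import BuildSpec, build_chain

from conftest import EXTENDED, make_random_frame


# ---------------------------------------------------------------------------
# donor / acceptor enumeration
# ---------------------------------------------------------------------------


def test_creka_donor_inventory(extended_chain):
    frame = SystemFrame(0, [extended_chain])
    donors = enumerate_donors(frame)
    by_heavy = {}
    for d, h in donors:
        by_heavy.setdefault((d.res_index, d.atom_name), []).append(h.atom_name)
    # terminal ammonium: 3 N-H pairs
    assert sorted(by_heavy[(1, "N")]) == ["H1", "H2", "H3"]
    # backbone amides on residues 2..5
    for i in (2, 3, 4, 5):
        assert by_heavy[(i, "N")] == ["H"]
    # Arg guanidinium: 5 N-H pairs on 3 nitrogens; Lys ammonium: 3
    assert sorted(by_heavy[(2, "NE")] + by_heavy[(2, "NH1")] + by_heavy[(2, "NH2")]) == [
        "HE", "HH11", "HH12", "HH21", "HH22",
    ]
    assert sorted(by_heavy[(4, "NZ")]) == ["HZ1", "HZ2", "HZ3"]
    assert len(donors) == 3 + 4 + 5 + 3  # 15 (donor, H) pairs in total


def test_crenka_loses_exactly_the_residue3_amide_donor(extended_chain):
    meg_chain = build_chain(BuildSpec(sequence="CRE^N^KA", phi_psi=EXTENDED))
    creka = {(d.res_index, d.atom_name, h.atom_name)
             for d, h in enumerate_donors(SystemFrame(0, [extended_chain]))}
    crenka = {(d.res_index, d.atom_name, h.atom_name)
              for d, h in enumerate_donors(SystemFrame(0, [meg_chain]))}
    assert creka - crenka == {(3, "N", "H")}
    assert crenka < creka


def test_meg_backbone_never_donates_property():
    """MEG residue-3 N is absent from the donor list in any conformation."""
    for seed in range(5):
        chain = build_chain(
            BuildSpec(sequence="CRE^N^KA", phi_psi=EXTENDED, noise_sigma=0.01, seed=seed)
        )
        donors = enumerate_donors(SystemFrame(0, [chain]))
        assert not any(d.res_index == 3 and d.atom_name == "N" for d, _ in donors)


def test_acceptor_inventory(extended_chain):
    frame = SystemFrame(0, [extended_chain])
    refs = enumerate_acceptors(frame)
    names = {(r.res_index, r.atom_name) for r in refs}
    # 5 backbone O (residue 5's O doubles as a carboxylate oxygen),
    # Glu OE1/OE2, terminal OXT: 8 distinct oxygen atoms
    assert names == {
        (1, "O"), (2, "O"), (3, "O"), (4, "O"), (5, "O"),
        (3, "OE1"), (3, "OE2"), (5, "OXT"),
    }
    assert len(refs) == 8


def test_protonated_glu_acceptor_config(extended_chain):
    chain = build_chain(BuildSpec(phi_psi=EXTENDED, glu_protonated=True))
    frame = SystemFrame(0, [chain])
    default = {(r.res_index, r.atom_name) for r in enumerate_acceptors(frame)}
    assert (3, "OE1") in default and (3, "OE2") in default  # still O acceptors
    charged_only = {
        (r.res_index, r.atom_name)
        for r in enumerate_acceptors(frame, InteractionConfig(charged_acceptors_only=True))
    }
    assert (3, "OE1") not in charged_only and (3, "OE2") not in charged_only


def test_cys_thiol_excluded_by_default(extended_chain):
    frame = SystemFrame(0, [extended_chain])
    assert not any(d.atom_name == "SG" for d, _ in enumerate_donors(frame))
    with_thiol = enumerate_donors(frame, InteractionConfig(include_cys_thiol=True))
    assert any(d.atom_name == "SG" and h.atom_name == "HG" for d, h in with_thiol)


# ---------------------------------------------------------------------------
# geometric criterion: strict boundaries
# ---------------------------------------------------------------------------


def _two_chain_frame(extended_chain, d_ho):
    """Second chain translated so one acceptor O sits exactly d_ho from an
    amide H along the N-H axis (angle 180 degrees)."""
    a = copy_chain(extended_chain, "A")
    b = copy_chain(extended_chain, "B")
    res3 = a.residues[2]
    n = res3.atom("N").position
    h = res3.atom("H").position
    axis = (h - n) / np.linalg.norm(h - n)
    target_o = h + d_ho * axis
    o2 = b.residues[0].atom("O").position
    b.set_coordinates(b.coordinates() + (target_o - o2) + 0.0)
    return SystemFrame(0, [a, b]), ("A", 3)


def _bond_at(frame, donor):
    cid, ri = donor
    return [
        b for b in detect_hbonds(frame)
        if b.donor_chain == cid and b.donor_heavy.res_index == ri
        and not b.donor_is_sidechain and not b.is_intra
        and b.acceptor.res_index == 1 and b.acceptor.atom_name == "O"
    ]


def test_distance_cutoff_boundary(extended_chain):
    frame, donor = _two_chain_frame(extended_chain, 0.299)
    bonds = _bond_at(frame, donor)
    assert bonds and bonds[0].d_ho == pytest.approx(0.299, abs=1e-9)
    # strictness: a cutoff exactly at the measured distance excludes the bond
    assert not [
        b for b in detect_hbonds(frame, d_cut=bonds[0].d_ho)
        if (b.donor_heavy, b.acceptor) == (bonds[0].donor_heavy, bonds[0].acceptor)
    ]
    frame, donor = _two_chain_frame(extended_chain, 0.301)
    assert not _bond_at(frame, donor)


def test_angle_cutoff_is_strict(extended_chain):
    a = copy_chain(extended_chain, "A")
    res3 = a.residues[2]
    n = res3.atom("N").position
    h = res3.atom("H").position
    axis = (h - n) / np.linalg.norm(h - n)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    for ang_deg, expect in ((150.0, True), (121.0, True), (110.0, False)):
        b = copy_chain(extended_chain, "B")
        theta = np.radians(180.0 - ang_deg)  # deviation from linear
        target_o = h + 0.25 * (np.cos(theta) * axis + np.sin(theta) * perp)
        o2 = b.residues[0].atom("O").position
        b.set_coordinates(b.coordinates() + (target_o - o2))
        frame = SystemFrame(0, [a, b])
        got = [
            x for x in _bond_at(frame, ("A", 3))
            if x.acceptor.res_index == 1 and x.acceptor_chain == "B"
        ]
        assert bool(got) == expect, f"angle {ang_deg}"
        if got:
            bond = got[0]
            assert bond.angle_dha == pytest.approx(ang_deg, abs=2.0)
            assert bond.d_ho == pytest.approx(0.25, abs=1e-6)
            # strictness: a cutoff exactly at the measured values excludes the bond
            assert not [
                x for x in detect_hbonds(frame, ang_cut=bond.angle_dha)
                if (x.donor_heavy, x.acceptor) == (bond.donor_heavy, bond.acceptor)
            ]
            assert not [
                x for x in detect_hbonds(frame, d_cut=bond.d_ho)
                if (x.donor_heavy, x.acceptor) == (bond.donor_heavy, bond.acceptor)
            ]


def test_bond_count_monotone_in_cutoffs(anti_sheet_creka):
    frame = anti_sheet_creka
    n_tight = len(detect_hbonds(frame, d_cut=0.25, ang_cut=140.0))
    n_default = len(detect_hbonds(frame, d_cut=0.30, ang_cut=120.0))
    n_loose = len(detect_hbonds(frame, d_cut=0.35, ang_cut=100.0))
    assert n_tight <= n_default <= n_loose
    assert n_default > 0


# ---------------------------------------------------------------------------
# oracle equivalence (acceptance criterion 4)
# ---------------------------------------------------------------------------


def test_grid_equals_brute_on_50_random_frames():
    for seed in range(50):
        frame = make_random_frame(seed, n_chains=4)
        grid = detect_hbonds(frame, method="grid")
        brute = detect_hbonds(frame, method="brute")
        assert grid == brute, f"seed {seed}"


def test_detection_invariant_under_rigid_motion(anti_sheet_creka):
    from pentassembly.geometry import random_rotation_matrix

    rng = np.random.default_rng(5)
    rot = random_rotation_matrix(rng)
    shift = rng.uniform(-3, 3, 3)
    moved = SystemFrame(
        0, [c.transformed(rotation=rot, translation=shift) for c in anti_sheet_creka.chains]
    )
    ref = detect_hbonds(anti_sheet_creka)
    got = detect_hbonds(moved)
    assert [(b.donor_heavy, b.hydrogen, b.acceptor) for b in got] == [
        (b.donor_heavy, b.hydrogen, b.acceptor) for b in ref
    ]
    for b_ref, b_got in zip(ref, got):
        assert b_got.d_ho == pytest.approx(b_ref.d_ho, abs=1e-9)
        assert b_got.angle_dha == pytest.approx(b_ref.angle_dha, abs=1e-6)


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 2**31 - 1))
def test_grid_equals_brute_property(seed):
    frame = make_random_frame(seed % 100000, n_chains=3)
    assert detect_hbonds(frame, method="grid") == detect_hbonds(frame, method="brute")


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------


def _bridge_frame(extended_chain, d):
    a = copy_chain(extended_chain, "A")
    b = copy_chain(extended_chain, "B")
    nh1 = a.residues[1].atom("NH1").position
    direction = np.array([1.0, 0.0, 0.0])
    target = nh1 + d * direction
    oe1 = b.residues[2].atom("OE1").position
    b.set_coordinates(b.coordinates() + (target - oe1) + np.array([0.0, 0.0, 0.0]))
    # push everything else away along z so only the engineered pair is close
    return SystemFrame(0, [a, b])


def test_salt_bridge_detected_at_035(extended_chain):
    frame = _bridge_frame(extended_chain, 0.35)
    bridges = detect_salt_bridges(frame)
    inter = [sb for sb in bridges if not sb.same_chain]
    # the Arg(A) guanidinium / Glu(B) carboxylate pair is bridged; dedup keeps
    # the closest atom pair, which must be within the engineered 0.35 nm
    arg_glu = [
        sb for sb in inter
        if sb.cation_atom.res_index == 2 and sb.anion_atom.res_index == 3
    ]
    assert len(arg_glu) == 1
    assert arg_glu[0].cation_atom.atom_name in ("NE", "NH1", "NH2")
    assert arg_glu[0].d <= 0.35 + 1e-9


def test_no_salt_bridge_at_055(extended_chain):
    frame = _bridge_frame(extended_chain, 0.55)
    assert all(
        sb.d < 0.40 for sb in detect_salt_bridges(frame)
    )
    assert not [
        sb for sb in detect_salt_bridges(frame)
        if not sb.same_chain and sb.cation_atom.res_index == 2
        and sb.anion_atom.res_index == 3
    ]


def test_salt_bridge_dedup_one_per_residue_pair(extended_chain):
    frame = _bridge_frame(extended_chain, 0.30)
    inter = [sb for sb in detect_salt_bridges(frame) if not sb.same_chain]
    keys = [(sb.chains, sb.cation_atom.res_index, sb.anion_atom.res_index) for sb in inter]
    assert len(keys) == len(set(keys))
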