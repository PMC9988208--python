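"""Synthetic pentapeptide structure generators.

Everything the analysis pipeline consumes can be generated here: single
chains at prescribed backbone dihedrals, two-stranded beta-sheets (parallel
or antiparallel), turn conformers, salt-bridged dimers, and "minimum-bias"
multi-chain boxes in which chains are placed at random but kept far enough
apart to be non-interacting.

Chains are grown from internal coordinates with ideal bond lengths and
angles (N-CA 0.1458 nm, CA-C 0.1525 nm, C-N 0.1329 nm, omega = 180 deg);
explicit polar hydrogens are attached (amide H, terminal ammonium H1-H3,
Arg guanidinium, Lys ammonium, Cys thiol).  Non-polar hydrogens are omitted:
the hydrogen-bond criterion only involves N-H donors and O acceptors.
N-methyl-glutamate (MEG) carries a methyl carbon CN on the backbone nitrogen
and no amide H.
"""

from __future__ import annotations

import functools
import string
from dataclasses import dataclass

import numpy as np

from .errors import FeasibilityError, ParameterError
from .geometry import place_atom, random_rotation_matrix, rotation_about_axis
from .structures import (
    Atom,
    PeptideChain,
    Residue,
    SystemFrame,
    CREKA_CODES,
    CRENKA_CODES,
)

# ideal backbone geometry, nm / degrees
B_N_CA = 0.1458
B_CA_C = 0.1525
B_C_N = 0.1329
B_C_O = 0.1231
B_N_H = 0.1010
B_N_CN = 0.1449  # backbone N to N-methyl carbon
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_CA_N_H = 118.5
OMEGA = 180.0

#: canonical dihedral presets (not fitted to anything; textbook values)
ANTIPARALLEL_STRAND = (-139.0, 135.0)
PARALLEL_STRAND = (-119.0, 113.0)


def parse_sequence(sequence) -> tuple[str, ...]:
    """Accept 'CREKA', 'CRE^N^KA' (and common spellings) or a 5-tuple of codes."""
    if isinstance(sequence, (tuple, list)):
        seq = tuple(sequence)
    else:
        s = str(sequence).upper().replace("^", "").replace("(NME)", "N")
        if s == "CREKA":
            seq = CREKA_CODES
        elif s in ("CRENKA", "CRE_N_KA", "CREnKA".upper()):
            seq = CRENKA_CODES
        else:
            raise ParameterError(f"unknown sequence {sequence!r}")
    if seq not in (CREKA_CODES, CRENKA_CODES):
        raise ParameterError(f"sequence {seq} is neither CREKA nor CRE(NMe)KA")
    return seq


@dataclass(frozen=True)
class BuildSpec:
    """Recipe for one chain: sequence, per-residue (phi, psi), noise, seed."""

    sequence: tuple[str, ...] | str = "CREKA"
    phi_psi: tuple = tuple([ANTIPARALLEL_STRAND] * 5)
    noise_sigma: float = 0.0
    seed: int = 0
    chain_id: str = "A"
    n_term_protonated: bool = True
    c_term_deprotonated: bool = True
    glu_protonated: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if len(self.phi_psi) != 5:
            raise ParameterError("phi_psi must have 5 entries")


@dataclass(frozen=True)
class BoxSpec:
    """Recipe for a minimum-bias multi-chain box."""

    n_chains: int = 15
    box: tuple[float, float, float] = (9.5, 8.5, 9.0)
    min_spacing: float = 1.8  # centre-to-centre, nm
    seed: int = 0
    sequence: tuple[str, ...] | str = "CREKA"
    min_atom_gap: float = 0.5  # closest allowed inter-chain heavy-atom approach
    phi_psi: tuple = tuple([ANTIPARALLEL_STRAND] * 5)

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ParameterError("n_chains must be >= 1")
        if any(b <= 0 for b in self.box):
            raise ParameterError("box components must be positive")


# ---------------------------------------------------------------------------
# single-chain construction
# ---------------------------------------------------------------------------


def _grow_backbone(phi_psi) -> list[dict]:
    """Backbone N/CA/C positions for 5 residues at the requested dihedrals."""
    res: list[dict] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    th = np.pi - np.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, 5):
        phi = phi_psi[i][0]
        psi_prev = phi_psi[i - 1][1]
        if psi_prev is None:
            psi_prev = 135.0
        if phi is None:
            phi = -139.0
        prev = res[i - 1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, OMEGA)
        c = place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, phi)
        res.append({"N": n, "CA": ca, "C": c})
    return res


def _sidechain_atoms(code: str, bb: dict, prev_c: np.ndarray | None,
                     glu_protonated: bool) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, position) for the side chain of one residue."""
    n, ca, c = bb["N"], bb["CA"], bb["C"]
    out: list[tuple[str, str, np.ndarray]] = []
    if code == "GLY":  # not used, kept for completeness of the growth rules
        return out
    cb = place_atom(c, n, ca, 0.1530, 110.4, 122.0)
    out.append(("CB", "C", cb))

    def p(a, b, c_, bond, ang, tor):
        return place_atom(a, b, c_, bond, ang, tor)

    if code == "ALA":
        return out
    if code == "CYS":
        sg = p(n, ca, cb, 0.1810, 114.0, -60.0)
        hg = p(ca, cb, sg, 0.1340, 96.0, 180.0)
        out += [("SG", "S", sg), ("HG", "H", hg)]
        return out
    if code == "ARG":
        cg = p(n, ca, cb, 0.1520, 114.0, -65.0)
        cd = p(ca, cb, cg, 0.1520, 111.0, 180.0)
        ne = p(cb, cg, cd, 0.1460, 112.0, 180.0)
        cz = p(cg, cd, ne, 0.1330, 124.0, 180.0)
        he = p(cg, cd, ne, 0.1010, 118.0, 0.0)
        nh1 = p(cd, ne, cz, 0.1330, 120.0, 0.0)
        nh2 = p(cd, ne, cz, 0.1330, 120.0, 180.0)
        hh11 = p(ne, cz, nh1, 0.1010, 120.0, 0.0)
        hh12 = p(ne, cz, nh1, 0.1010, 120.0, 180.0)
        hh21 = p(ne, cz, nh2, 0.1010, 120.0, 0.0)
        hh22 = p(ne, cz, nh2, 0.1010, 120.0, 180.0)
        out += [
            ("CG", "C", cg), ("CD", "C", cd), ("NE", "N", ne), ("HE", "H", he),
            ("CZ", "C", cz), ("NH1", "N", nh1), ("HH11", "H", hh11),
            ("HH12", "H", hh12), ("NH2", "N", nh2), ("HH21", "H", hh21),
            ("HH22", "H", hh22),
        ]
        return out
    if code in ("GLU", "MEG"):
        cg = p(n, ca, cb, 0.1520, 114.0, -60.0)
        cd = p(ca, cb, cg, 0.1520, 112.0, 180.0)
        oe1 = p(cb, cg, cd, 0.1250, 118.0, 0.0)
        oe2 = p(cb, cg, cd, 0.1250, 118.0, 180.0)
        out += [("CG", "C", cg), ("CD", "C", cd), ("OE1", "O", oe1), ("OE2", "O", oe2)]
        if glu_protonated:
            he2 = p(cg, cd, oe2, 0.0980, 106.0, 180.0)
            out.append(("HE2", "H", he2))
        return out
    if code == "LYS":
        cg = p(n, ca, cb, 0.1520, 114.0, -60.0)
        cd = p(ca, cb, cg, 0.1520, 111.0, 180.0)
        ce = p(cb, cg, cd, 0.1520, 111.0, 180.0)
        nz = p(cg, cd, ce, 0.1490, 112.0, 180.0)
        hz = [p(cd, ce, nz, 0.1030, 109.5, t) for t in (60.0, 180.0, -60.0)]
        out += [
            ("CG", "C", cg), ("CD", "C", cd), ("CE", "C", ce), ("NZ", "N", nz),
            ("HZ1", "H", hz[0]), ("HZ2", "H", hz[1]), ("HZ3", "H", hz[2]),
        ]
        return out
    raise ParameterError(f"no side-chain growth rule for {code!r}")


def build_chain(spec: BuildSpec) -> PeptideChain:
    """All-atom (polar-hydrogen) pentapeptide chain at the requested dihedrals.

    Deterministic per seed; at ``noise_sigma = 0`` the requested phi/psi are
    realised within ~1 degree.
    """
    seq = parse_sequence(spec.sequence)
    phi_psi = tuple(
        (None, None) if pp is None else tuple(pp) for pp in spec.phi_psi
    )
    bb = _grow_backbone(phi_psi)
    psi_last = phi_psi[4][1] if phi_psi[4][1] is not None else 135.0

    residues: list[Residue] = []
    serial = 0

    def add(atoms_out, name, element, pos):
        nonlocal serial
        serial += 1
        atoms_out.append(Atom(serial=serial, name=name, element=element,
                              position=np.asarray(pos, dtype=float)))

    for i, code in enumerate(seq):
        atoms: list[Atom] = []
        n, ca, c = bb[i]["N"], bb[i]["CA"], bb[i]["C"]
        add(atoms, "N", "N", n)
        if i == 0:
            # terminal ammonium (or amine) hydrogens, staggered about CA-N
            torsions = (60.0, 180.0, -60.0) if spec.n_term_protonated else (60.0, -60.0)
            for k, tor in enumerate(torsions, start=1):
                h = place_atom(c, ca, n, 0.1030, 109.5, tor)
                add(atoms, f"H{k}", "H", h)
        elif code == "MEG":
            cn = place_atom(bb[i - 1]["C"], ca, n, B_N_CN, 119.0, 180.0)
            add(atoms, "CN", "C", cn)
        else:
            h = place_atom(bb[i - 1]["C"], ca, n, B_N_H, A_CA_N_H, 180.0)
            add(atoms, "H", "H", h)
        add(atoms, "CA", "C", ca)
        for name, el, pos in _sidechain_atoms(
            code, bb[i], bb[i - 1]["C"] if i else None, spec.glu_protonated
        ):
            add(atoms, name, el, pos)
        add(atoms, "C", "C", c)
        if i < 4:
            o = place_atom(n, ca, c, B_C_O, A_CA_C_O, phi_psi[i][1] + 180.0
                           if phi_psi[i][1] is not None else -45.0)
            add(atoms, "O", "O", o)
        else:
            o = place_atom(n, ca, c, 0.1250, 117.0, psi_last + 180.0)
            add(atoms, "O", "O", o)
            if spec.c_term_deprotonated:
                oxt = place_atom(n, ca, c, 0.1250, 117.0, psi_last)
                add(atoms, "OXT", "O", oxt)
            else:
                oxt = place_atom(n, ca, c, 0.1340, 111.0, psi_last)
                hxt = place_atom(ca, c, oxt, 0.0980, 107.0, 180.0)
                add(atoms, "OXT", "O", oxt)
                add(atoms, "HXT", "H", hxt)
        residues.append(Residue(index=i + 1, code=code, atoms=atoms))

    chain = PeptideChain(
        chain_id=spec.chain_id,
        residues=residues,
        n_term_protonated=spec.n_term_protonated,
        c_term_deprotonated=spec.c_term_deprotonated,
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords = chain.coordinates()
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        chain.set_coordinates(coords)
    chain.validate()
    return chain


# ---------------------------------------------------------------------------
# two-stranded sheets
# ---------------------------------------------------------------------------


def _strand_frame(chain: PeptideChain) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame: u along the strand, v/w perpendicular."""
    ca = chain.ca_positions()
    u = ca[-1] - ca[0]
    u = u / np.linalg.norm(u)
    # least-squares normal of the C-alpha trace
    centred = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    w = vt[-1]
    w = w - np.dot(w, u) * u
    w = w / np.linalg.norm(w)
    v = np.cross(w, u)
    return u, v, w


def _count_inter_mainchain(frame: SystemFrame) -> int:
    from .interactions import detect_hbonds

    bonds = detect_hbonds(frame)
    return sum(
        1
        for b in bonds
        if b.donor_chain != b.acceptor_chain
        and not b.donor_is_sidechain
        and not b.acceptor_is_sidechain
    )


def _min_interchain_dist(a: PeptideChain, b: PeptideChain) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(a.coordinates(), b.coordinates()).min())


def _amide_geometry(chain: PeptideChain):
    """(H positions, H->N unit-ish vectors) of backbone amide donors and
    backbone carbonyl O positions."""
    h_pos, hd_vec = [], []
    for res in chain.residues[1:]:
        if res.has_atom("H"):
            h = res.atom("H").position
            h_pos.append(h)
            hd_vec.append(res.atom("N").position - h)
    o_pos = [r.atom("O").position for r in chain.residues if r.has_atom("O")]
    return np.array(h_pos), np.array(hd_vec), np.array(o_pos)


def _backbone_centre(chain: PeptideChain) -> np.ndarray:
    pts = [
        atom.position
        for _, atom in chain.iter_atoms()
        if atom.name in ("N", "CA", "C", "O")
    ]
    return np.mean(pts, axis=0)


@functools.lru_cache(maxsize=64)
def _sheet_transform(orientation_value: str, separation: float):
    """Deterministic search for the rigid transform placing a second ideal
    strand against the first so that inter-main-chain hydrogen bonds are
    maximised.

    The search runs on the CREKA backbone (the two sequences share identical
    backbone geometry), so the same transform defines the CREKA sheet and
    its N-methylated twin; the twin then simply realises fewer bonds because
    residue 3 cannot donate.  Candidates: twist about the strand axis
    (30-degree grid), combined for the antiparallel case with a flip about
    the sheet normal, then a translation grid along the strand, across it
    near the nominal separation (+/- 0.10 nm) and out of plane.  Returns
    (rotation, translation, bond count) about the backbone centre, or
    (None, None, 0) when nothing clash-free exists.
    """
    parallel = orientation_value == "PARALLEL"
    preset = PARALLEL_STRAND if parallel else ANTIPARALLEL_STRAND
    spec_a = BuildSpec(sequence="CREKA", phi_psi=tuple([preset] * 5), chain_id="A")
    chain_a = build_chain(spec_a)
    u, v, w = _strand_frame(chain_a)
    centre = _backbone_centre(chain_a)
    coords_a = chain_a.coordinates()
    hA, hdA, aA = _amide_geometry(chain_a)
    # steric feasibility is judged on the backbone only, which is shared by
    # both sequences
    bb_idx = np.array(
        [
            k
            for k, (_, atom) in enumerate(chain_a.iter_atoms())
            if atom.name in ("N", "CA", "C", "O")
        ]
    )

    # translation grid
    du_vals = np.arange(-1.2, 1.2001, 0.05)
    sep_vals = np.concatenate(
        [s * np.arange(separation - 0.10, separation + 0.0601, 0.02) for s in (1, -1)]
    )
    dw_vals = np.arange(-0.4, 0.4001, 0.1)
    grid = np.array(
        [
            du * u + sv * v + dw * w
            for du in du_vals
            for sv in sep_vals
            for dw in dw_vals
        ]
    )
    # preference for placements close to the nominal geometry (tie-break)
    tidiness = np.array(
        [
            -(abs(abs(sv) - separation) * 4 + abs(du) + abs(dw))
            for du in du_vals
            for sv in sep_vals
            for dw in dw_vals
        ]
    )

    rotations = []
    for theta in range(0, 360, 30):
        rot = rotation_about_axis(u, float(theta))
        if not parallel:
            rot = rot @ rotation_about_axis(w, 180.0)
        rotations.append(rot)

    candidates = []  # (count, tidiness, -rot_idx, -grid_idx)
    for ri, rot in enumerate(rotations):
        hB = (hA - centre) @ rot.T + centre
        hdB = hdA @ rot.T
        aB = (aA - centre) @ rot.T + centre

        def directed(h, hd, a, sign):
            # acceptors move by +t (sign=1) or donors move by +t (sign=-1,
            # equivalent to acceptors moving by -t); returns per-donor counts
            ho = a[None, :, None, :] + sign * grid[None, None, :, :] - h[:, None, None, :]
            d = np.linalg.norm(ho, axis=3)
            hd_n = hd / np.linalg.norm(hd, axis=1, keepdims=True)
            cos = np.einsum("ijkl,il->ijk", ho, hd_n) / np.maximum(d, 1e-12)
            ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
            return ((d < 0.30) & (ang > 120.0)).sum(axis=1)

        per_donor = directed(hA, hdA, aB, 1) + directed(hB, hdB, aA, -1)
        counts = per_donor.sum(axis=0)
        # bonds donated by the residue-3 amide (row 1 of the res-2..5 donors):
        # preferred as a tie-break, because an in-register sheet engages the
        # middle amide -- exactly the donor that N-methylation removes
        counts_mid = per_donor[1]
        if counts.max() == 0:
            continue
        hits = np.where(counts >= 1)[0]
        # keep the best few hundred per rotation; clashes are resolved later
        order = sorted(
            hits, key=lambda gi: (-counts[gi], -counts_mid[gi], -tidiness[gi])
        )[:300]
        for gi in order:
            candidates.append(
                (int(counts[gi]), int(counts_mid[gi]), tidiness[gi], -ri, -int(gi))
            )

    candidates.sort(reverse=True)
    from scipy.spatial.distance import cdist

    for count, _, _, neg_ri, neg_gi in candidates:
        rot = rotations[-neg_ri]
        t = grid[-neg_gi]
        coords_b = (coords_a - centre) @ rot.T + centre + t
        if cdist(coords_a[bb_idx], coords_b[bb_idx]).min() >= 0.22:
            return rot, t, count
    return None, None, 0


def copy_with_id(chain: PeptideChain, chain_id: str) -> PeptideChain:
    from .structures import copy_chain

    return copy_chain(chain, chain_id)


def build_sheet_pair(
    orientation,
    sequence="CREKA",
    separation: float = 0.50,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> SystemFrame:
    """Two-stranded beta-sheet (PARALLEL or ANTIPARALLEL) as one frame.

    The second strand is a rigid copy of the first, placed by a deterministic
    grid search (run once on the shared backbone geometry) that maximises
    inter-main-chain hydrogen bonds under the default geometric criterion.
    The same placement serves both sequences, so a CRE(NMe)KA sheet is the
    exact geometric twin of the CREKA one minus the residue-3 donor.  CREKA
    realises at least two amide-amide bonds, the N-methylated twin at least
    one.
    """
    if not 0.40 <= separation <= 0.60:
        raise ParameterError(
            f"separation {separation} nm outside the realizable 0.40-0.60 range"
        )
    seq = parse_sequence(sequence)
    ori = getattr(orientation, "value", str(orientation)).upper()
    if ori not in ("PARALLEL", "ANTIPARALLEL"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    rot, t, score = _sheet_transform(ori, round(separation, 4))
    required = 2 if seq == CREKA_CODES else 1
    if rot is None or score < required:
        raise ParameterError(
            f"no placement with >= {required} inter-main-chain H-bonds at "
            f"separation {separation} nm"
        )
    preset = PARALLEL_STRAND if ori == "PARALLEL" else ANTIPARALLEL_STRAND
    chain_a = build_chain(BuildSpec(sequence=seq, phi_psi=tuple([preset] * 5), chain_id="A"))
    chain_b = copy_with_id(chain_a, "B")
    centre = _backbone_centre(chain_a)
    chain_b.set_coordinates((chain_b.coordinates() - centre) @ rot.T + centre + t)
    frame = SystemFrame(frame_index=0, chains=[chain_a, chain_b])
    required_realised = _count_inter_mainchain(frame)
    if required_realised < required:
        raise ParameterError(
            f"placement realises only {required_realised} inter-main-chain "
            f"H-bonds for {''.join(c[0] for c in seq)}"
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for c in frame.chains:
            c.set_coordinates(c.coordinates() + rng.normal(0, noise_sigma, (len(c.coordinates()), 3)))
    return frame


# ---------------------------------------------------------------------------
# turn conformers
# ---------------------------------------------------------------------------

#: phi/psi presets realising the i -> i+3 (beta) and i -> i+2 (gamma) backbone
#: hydrogen bond; turn residues carry textbook type-I beta-turn / classic
#: gamma-turn angles, the flanking entries close the loop geometrically.
BETA_TURN_PHI_PSI = ((None, 120.0), (-60.0, -30.0), (-90.0, 0.0), (-120.0, 130.0), (-139.0, 135.0))
GAMMA_TURN_PHI_PSI = ((None, 140.0), (75.0, -65.0), (-110.0, 130.0), (-139.0, 135.0), (-139.0, 135.0))


def build_turn_chain(kind, sequence="CREKA", seed: int = 0,
                     noise_sigma: float = 0.0, chain_id: str = "A") -> PeptideChain:
    """Chain exhibiting the beta-turn (O1...H-N4) or gamma-turn (O1...H-N3)
    backbone hydrogen bond under the default criterion."""
    kind_val = getattr(kind, "value", str(kind)).upper()
    if kind_val == "BETA_TURN":
        phi_psi = BETA_TURN_PHI_PSI
    elif kind_val == "GAMMA_TURN":
        phi_psi = GAMMA_TURN_PHI_PSI
    else:
        raise ParameterError(f"unknown turn kind {kind!r}")
    return build_chain(
        BuildSpec(sequence=sequence, phi_psi=phi_psi, seed=seed,
                  noise_sigma=noise_sigma, chain_id=chain_id)
    )


# ---------------------------------------------------------------------------
# salt-bridged dimer
# ---------------------------------------------------------------------------


def build_salt_bridge_dimer(sequence="CREKA", seed: int = 0) -> SystemFrame:
    """Two turn-conformation chains associated only through an Arg...Glu
    salt bridge (no inter-main-chain hydrogen bond)."""
    from .interactions import detect_salt_bridges

    chain_a = build_turn_chain("BETA_TURN", sequence=sequence, chain_id="A")
    template = build_turn_chain("BETA_TURN", sequence=sequence, chain_id="B")

    nh1 = chain_a.residues[1].atom("NH1").position
    centre_a = chain_a.center()
    out_dir = nh1 - centre_a
    out_dir = out_dir / np.linalg.norm(out_dir)

    for rot_deg in (180.0, 150.0, 210.0, 120.0, 90.0, 60.0, 240.0):
        for gap in (0.32, 0.35, 0.30, 0.37):
            cand = copy_with_id(template, "B")
            rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), rot_deg)
            coords = cand.coordinates()
            coords = (coords - cand.center()) @ rot.T
            cand.set_coordinates(coords)
            # bring the candidate's carboxylate oxygen onto the target point
            oe1 = cand.residues[2].atom("OE1").position
            target = nh1 + gap * out_dir
            cand.set_coordinates(cand.coordinates() + (target - oe1))
            if _min_interchain_dist(chain_a, cand) < 0.22:
                continue
            frame = SystemFrame(frame_index=0, chains=[chain_a, cand])
            if _count_inter_mainchain(frame) != 0:
                continue
            if len(detect_salt_bridges(frame)) >= 1:
                return frame
    raise FeasibilityError("could not construct a salt-bridge dimer")


# ---------------------------------------------------------------------------
# minimum-bias box
# ---------------------------------------------------------------------------


def build_minimum_bias_box(spec: BoxSpec) -> SystemFrame:
    """Randomly place identical chains in a box with all centre-to-centre
    distances >= min_spacing and all inter-chain atom pairs >= min_atom_gap,
    so the starting configuration is essentially non-interacting."""
    seq = parse_sequence(spec.sequence)
    template = build_chain(BuildSpec(sequence=seq, phi_psi=spec.phi_psi, chain_id="A"))
    base = template.coordinates() - template.center()
    radius = float(np.linalg.norm(base, axis=1).max())
    box = np.asarray(spec.box, dtype=float)
    lo = np.full(3, radius)
    hi = box - radius
    if np.any(hi <= lo):
        raise FeasibilityError("box too small to contain a chain")
    # crude capacity check before attempting placement
    if spec.n_chains * (4 / 3) * np.pi * (spec.min_spacing / 2) ** 3 > 2.0 * np.prod(box):
        raise FeasibilityError("requested spacing cannot fit n_chains in the box")

    rng = np.random.default_rng(spec.seed)
    ids = _chain_ids(spec.n_chains)
    max_restarts = 50
    for _ in range(max_restarts):
        centres: list[np.ndarray] = []
        placed_coords: list[np.ndarray] = []
        ok = True
        for _ci in range(spec.n_chains):
            for _attempt in range(2000):
                rot = random_rotation_matrix(rng)
                centre = lo + rng.random(3) * (hi - lo)
                coords = base @ rot.T + centre
                if centres:
                    d2 = np.linalg.norm(np.array(centres) - centre, axis=1)
                    if d2.min() < spec.min_spacing:
                        continue
                    near = np.where(d2 < spec.min_spacing + 2 * radius)[0]
                    clash = False
                    for j in near:
                        from scipy.spatial.distance import cdist

                        if cdist(coords, placed_coords[j]).min() < spec.min_atom_gap:
                            clash = True
                            break
                    if clash:
                        continue
                centres.append(centre)
                placed_coords.append(coords)
                break
            else:
                ok = False
                break
        if ok:
            chains = []
            for cid, coords in zip(ids, placed_coords):
                c = copy_with_id(template, cid)
                c.set_coordinates(coords)
                chains.append(c)
            frame = SystemFrame(frame_index=0, chains=chains, box=box)
            frame.validate()
            return frame
    raise FeasibilityError(
        f"failed to place {spec.n_chains} chains at spacing {spec.min_spacing} nm"
    )


def _chain_ids(n: int) -> list[str]:
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    if n > len(alphabet):
        raise ParameterError(f"cannot label {n} chains with single characters")
    return list(alphabet[:n])


def nearest_neighbor_distances(frame: SystemFrame) -> np.ndarray:
    """Per-chain nearest-neighbour centre-of-geometry distance, nm."""
    centres = np.array([c.center() for c in frame.chains])
    if len(centres) < 2:
        return np.array([])
    from scipy.spatial.distance import cdist

    d = cdist(centres, centres)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)
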