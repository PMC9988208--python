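"""Hydrogen-bond and salt-bridge detection.

The hydrogen-bond criterion is geometric and strict: an N-H...O contact
counts iff the H...O distance is shorter than 0.30 nm AND the angle at the
hydrogen (donor-heavy -- H -- acceptor) exceeds 120.0 degrees.  Donors are
nitrogen-bound hydrogens (backbone amides except the N-methylated one,
Arg guanidinium, Lys ammonium, the N-terminal ammonium); acceptors are
oxygens (backbone carbonyls, Glu/MEG carboxylates, the C-terminal
carboxylate).

For pattern classification each donor/acceptor carries an "is_sidechain"
flag meaning "not a backbone amide group": side chains AND the ionized
terminal groups count as side groups, so the main-chain categories cover
amide-amide bonds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .structures import PeptideChain, SystemFrame


@dataclass(frozen=True)
class AtomRef:
    """Stable reference to one atom: (chain, residue index, atom name)."""

    chain_id: str
    res_index: int
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.res_index}/{self.atom_name}"


@dataclass(frozen=True)
class HBond:
    donor_heavy: AtomRef
    hydrogen: AtomRef
    acceptor: AtomRef
    d_ho: float  # nm
    angle_dha: float  # degrees, vertex at the hydrogen
    donor_is_sidechain: bool
    acceptor_is_sidechain: bool

    @property
    def donor_chain(self) -> str:
        return self.donor_heavy.chain_id

    @property
    def acceptor_chain(self) -> str:
        return self.acceptor.chain_id

    @property
    def is_intra(self) -> bool:
        return self.donor_chain == self.acceptor_chain


@dataclass(frozen=True)
class SaltBridge:
    cation_atom: AtomRef
    anion_atom: AtomRef
    d: float  # nm, heavy-atom N...O
    chains: tuple[str, str]

    @property
    def same_chain(self) -> bool:
        return self.chains[0] == self.chains[1]


@dataclass(frozen=True)
class InteractionConfig:
    """Donor/acceptor chemistry and cutoffs; defaults follow the geometric
    criterion above."""

    d_cut: float = 0.30  # nm, H...O
    ang_cut: float = 120.0  # degrees, at H
    salt_bridge_cut: float = 0.40  # nm, N...O heavy atom
    contact_cut: float = 0.45  # nm, aggregate heavy-atom contact
    include_cys_thiol: bool = False
    charged_acceptors_only: bool = False
    include_sidechain_donors: bool = True
    use_pbc: bool = False
    max_acceptors_per_h: int | None = None


DEFAULT_CONFIG = InteractionConfig()

# hydrogens attached to each side-chain donor nitrogen
_SIDECHAIN_DONORS = {
    "ARG": (("NE", ("HE",)), ("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))),
    "LYS": (("NZ", ("HZ1", "HZ2", "HZ3")),),
}
_THIOL_DONOR = ("SG", ("HG",))


def _chain_donors(chain: PeptideChain, config: InteractionConfig):
    """Yield (donor_ref, h_ref, donor_pos, h_pos, is_sidechain)."""
    for i, res in enumerate(chain.residues):
        cid = chain.chain_id
        if i == 0:
            # terminal ammonium: counted separately from backbone amides and,
            # not being an amide group, flagged as a side group for patterns
            n_atom = res.atom("N")
            for hname in ("H1", "H2", "H3", "H"):
                if res.has_atom(hname):
                    h = res.atom(hname)
                    yield (
                        AtomRef(cid, res.index, "N"),
                        AtomRef(cid, res.index, hname),
                        n_atom.position,
                        h.position,
                        True,
                    )
        elif not res.n_methylated and res.has_atom("H"):
            yield (
                AtomRef(cid, res.index, "N"),
                AtomRef(cid, res.index, "H"),
                res.atom("N").position,
                res.atom("H").position,
                False,
            )
        if not config.include_sidechain_donors:
            continue
        entries = list(_SIDECHAIN_DONORS.get(res.code, ()))
        if config.include_cys_thiol and res.code == "CYS":
            entries.append(_THIOL_DONOR)
        for heavy_name, h_names in entries:
            if not res.has_atom(heavy_name):
                continue
            heavy = res.atom(heavy_name)
            for hname in h_names:
                if res.has_atom(hname):
                    yield (
                        AtomRef(cid, res.index, heavy_name),
                        AtomRef(cid, res.index, hname),
                        heavy.position,
                        res.atom(hname).position,
                        True,
                    )


def _chain_acceptors(chain: PeptideChain, config: InteractionConfig):
    """Yield (ref, pos, is_sidechain)."""
    cid = chain.chain_id
    last = len(chain.residues) - 1
    for i, res in enumerate(chain.residues):
        if res.has_atom("O"):
            # the residue-5 carbonyl O doubles as one carboxylate oxygen but
            # keeps its main-chain role for pattern purposes
            yield AtomRef(cid, res.index, "O"), res.atom("O").position, False
        if res.code in ("GLU", "MEG"):
            protonated = res.has_atom("HE2")
            if not (protonated and config.charged_acceptors_only):
                for name in ("OE1", "OE2"):
                    if res.has_atom(name):
                        yield AtomRef(cid, res.index, name), res.atom(name).position, True
        if i == last and res.has_atom("OXT"):
            protonated = res.has_atom("HXT") or not chain.c_term_deprotonated
            if not (protonated and config.charged_acceptors_only):
                yield AtomRef(cid, res.index, "OXT"), res.atom("OXT").position, True


def enumerate_donors(
    frame: SystemFrame, config: InteractionConfig = DEFAULT_CONFIG
) -> list[tuple[AtomRef, AtomRef]]:
    """(donor-heavy, hydrogen) pairs over all chains of the frame."""
    out = []
    for chain in frame.chains:
        for d_ref, h_ref, _, _, _ in _chain_donors(chain, config):
            out.append((d_ref, h_ref))
    return out


def enumerate_acceptors(
    frame: SystemFrame, config: InteractionConfig = DEFAULT_CONFIG
) -> list[AtomRef]:
    """Acceptor oxygen atoms over all chains of the frame."""
    return [ref for chain in frame.chains for ref, _, _ in _chain_acceptors(chain, config)]


def _collect_arrays(frame: SystemFrame, config: InteractionConfig):
    d_refs, h_refs, d_pos, h_pos, d_side = [], [], [], [], []
    for chain in frame.chains:
        for d_ref, h_ref, dp, hp, side in _chain_donors(chain, config):
            d_refs.append(d_ref)
            h_refs.append(h_ref)
            d_pos.append(dp)
            h_pos.append(hp)
            d_side.append(side)
    a_refs, a_pos, a_side = [], [], []
    for chain in frame.chains:
        for ref, pos, side in _chain_acceptors(chain, config):
            a_refs.append(ref)
            a_pos.append(pos)
            a_side.append(side)
    return (
        d_refs,
        h_refs,
        np.array(d_pos).reshape(-1, 3),
        np.array(h_pos).reshape(-1, 3),
        d_side,
        a_refs,
        np.array(a_pos).reshape(-1, 3),
        a_side,
    )


def _minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def detect_hbonds(
    frame: SystemFrame,
    d_cut: float = 0.30,
    ang_cut: float = 120.0,
    config: InteractionConfig | None = None,
    method: str = "grid",
) -> list[HBond]:
    """All hydrogen bonds with d(H...O) < d_cut (strict) and the angle at H
    > ang_cut (strict).

    ``method`` selects the neighbour search: "grid" (KD-tree) or "brute"
    (exhaustive all-pairs); both give identical bond sets.
    """
    if d_cut <= 0 or ang_cut <= 0:
        raise ParameterError("cutoffs must be positive")
    cfg = config or DEFAULT_CONFIG
    if cfg.use_pbc and frame.box is not None:
        method = "brute"
    (d_refs, h_refs, d_pos, h_pos, d_side, a_refs, a_pos, a_side) = _collect_arrays(
        frame, cfg
    )
    if not d_refs or not a_refs:
        return []

    box = frame.box if (cfg.use_pbc and frame.box is not None) else None
    pairs: list[tuple[int, int]] = []
    if method == "brute":
        diff = a_pos[None, :, :] - h_pos[:, None, :]
        if box is not None:
            diff = diff - box * np.round(diff / box)
        dist = np.linalg.norm(diff, axis=2)
        ii, jj = np.where(dist < d_cut)
        pairs = list(zip(ii.tolist(), jj.tolist()))
    elif method == "grid":
        tree = cKDTree(a_pos)
        hits = tree.query_ball_point(h_pos, r=d_cut)
        for i, js in enumerate(hits):
            for j in js:
                pairs.append((i, j))
    else:
        raise ParameterError(f"unknown method {method!r}")

    bonds: list[HBond] = []
    for i, j in pairs:
        d_ref, h_ref, a_ref = d_refs[i], h_refs[i], a_refs[j]
        # never bond within one functional group (acceptor covalently bonded
        # to the donor heavy atom in the same residue)
        if (
            a_ref.chain_id == d_ref.chain_id
            and a_ref.res_index == d_ref.res_index
        ):
            sep = a_pos[j] - d_pos[i]
            if box is not None:
                sep = _minimum_image(sep, box)
            if np.linalg.norm(sep) < 0.20:
                continue
        ho = a_pos[j] - h_pos[i]
        if box is not None:
            ho = _minimum_image(ho, box)
        d_ho = float(np.linalg.norm(ho))
        if not d_ho < d_cut:
            continue
        hd = d_pos[i] - h_pos[i]
        if box is not None:
            hd = _minimum_image(hd, box)
        cosang = np.dot(hd, ho) / (np.linalg.norm(hd) * d_ho)
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if not ang > ang_cut:
            continue
        bonds.append(
            HBond(
                donor_heavy=d_ref,
                hydrogen=h_ref,
                acceptor=a_ref,
                d_ho=d_ho,
                angle_dha=ang,
                donor_is_sidechain=d_side[i],
                acceptor_is_sidechain=a_side[j],
            )
        )
    if cfg.max_acceptors_per_h is not None:
        by_h: dict[AtomRef, list[HBond]] = {}
        for b in bonds:
            by_h.setdefault(b.hydrogen, []).append(b)
        bonds = [
            b
            for hb in by_h.values()
            for b in sorted(hb, key=lambda x: x.d_ho)[: cfg.max_acceptors_per_h]
        ]
    bonds.sort(key=lambda b: (str(b.hydrogen), str(b.acceptor)))
    return bonds


# charged-nitrogen / carboxylate-oxygen groups for salt bridges
_CATION_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}


def detect_salt_bridges(
    frame: SystemFrame,
    cut: float = 0.40,
    config: InteractionConfig | None = None,
) -> list[SaltBridge]:
    """Charged-N ... carboxylate-O contacts below ``cut`` nm, deduplicated to
    the minimum-distance pair per residue pair."""
    cfg = config or DEFAULT_CONFIG
    cations = []  # (ref, pos, group key)
    anions = []
    for chain in frame.chains:
        cid = chain.chain_id
        for i, res in enumerate(chain.residues):
            for name in _CATION_ATOMS.get(res.code, ()):
                if res.has_atom(name):
                    cations.append(
                        (AtomRef(cid, res.index, name), res.atom(name).position,
                         (cid, res.index))
                    )
            if i == 0 and chain.n_term_protonated and res.has_atom("N"):
                cations.append(
                    (AtomRef(cid, res.index, "N"), res.atom("N").position,
                     (cid, 0))  # group 0: the terminus, distinct from Cys side
                )
            if res.code in ("GLU", "MEG") and not res.has_atom("HE2"):
                for name in ("OE1", "OE2"):
                    if res.has_atom(name):
                        anions.append(
                            (AtomRef(cid, res.index, name), res.atom(name).position,
                             (cid, res.index))
                        )
            if i == len(chain.residues) - 1 and chain.c_term_deprotonated:
                for name in ("O", "OXT"):
                    if res.has_atom(name):
                        anions.append(
                            (AtomRef(cid, res.index, name), res.atom(name).position,
                             (cid, -res.index))  # negative: terminal group key
                        )
    best: dict[tuple, SaltBridge] = {}
    box = frame.box if (cfg.use_pbc and frame.box is not None) else None
    for c_ref, c_pos, c_key in cations:
        for a_ref, a_pos, a_key in anions:
            sep = a_pos - c_pos
            if box is not None:
                sep = _minimum_image(sep, box)
            d = float(np.linalg.norm(sep))
            if d >= cut:
                continue
            key = (c_key, a_key)
            if key not in best or d < best[key].d:
                best[key] = SaltBridge(
                    cation_atom=c_ref,
                    anion_atom=a_ref,
                    d=d,
                    chains=(c_ref.chain_id, a_ref.chain_id),
                )
    return sorted(best.values(), key=lambda b: (str(b.cation_atom), str(b.anion_atom)))


def hbonds_to_tsv(bonds: list[HBond], path) -> None:
    """One row per bond: identifiers, distance (nm, 4 dp), angle (deg, 2 dp)."""
    import pandas as pd

    rows = [
        {
            "donor_chain": b.donor_chain,
            "donor_res": b.donor_heavy.res_index,
            "donor_atom": b.donor_heavy.atom_name,
            "hydrogen": b.hydrogen.atom_name,
            "acceptor_chain": b.acceptor_chain,
            "acceptor_res": b.acceptor.res_index,
            "acceptor_atom": b.acceptor.atom_name,
            "d_ho_nm": f"{b.d_ho:.4f}",
            "angle_deg": f"{b.angle_dha:.2f}",
            "donor_sidechain": b.donor_is_sidechain,
            "acceptor_sidechain": b.acceptor_is_sidechain,
            "intra": b.is_intra,
        }
        for b in bonds
    ]
    pd.DataFrame(
        rows,
        columns=[
            "donor_chain", "donor_res", "donor_atom", "hydrogen",
            "acceptor_chain", "acceptor_res", "acceptor_atom",
            "d_ho_nm", "angle_deg", "donor_sidechain", "acceptor_sidechain",
            "intra",
        ],
    ).to_csv(path, sep="\t", index=False)
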