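"""Domain model for CREKA / CRE(NMe)KA pentapeptide systems.

The two molecules handled here are the tumor-homing pentapeptide CREKA
(Cys-Arg-Glu-Lys-Ala) and its backbone N-methylated variant in which Glu is
replaced by N-methyl-glutamate (residue code ``MEG``).  N-methylation removes
the backbone amide hydrogen of residue 3, so that nitrogen can never act as a
hydrogen-bond donor.

Internal units are nanometres everywhere; structure files (PDB) use angstroms
and are converted on read/write.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, MissingHydrogenError, TopologyError
from .geometry import dihedral

A_PER_NM = 10.0

#: residue codes admissible in a pentapeptide chain
CREKA_CODES = ("CYS", "ARG", "GLU", "LYS", "ALA")
CRENKA_CODES = ("CYS", "ARG", "MEG", "LYS", "ALA")

#: default aliases under which N-methyl-glutamate may appear in files
DEFAULT_MEG_ALIASES = ("MEG", "MGL", "NMG")

_ONE_LETTER = {"CYS": "C", "ARG": "R", "GLU": "E", "MEG": "e", "LYS": "K", "ALA": "A"}


@dataclass
class Atom:
    """A single atom: PDB-style name, element and position in nm."""

    serial: int
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise TopologyError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise TopologyError(f"atom {self.name}: empty element symbol")


@dataclass
class Residue:
    """One of the five residues of a pentapeptide chain.

    ``MEG`` (N-methyl-glutamate) carries a methyl carbon ``CN`` on the
    backbone nitrogen instead of the amide hydrogen ``H``.
    """

    index: int  # 1..5 within the chain
    code: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def n_methylated(self) -> bool:
        return self.code == "MEG"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise TopologyError(f"residue {self.code}{self.index}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def validate(self) -> None:
        if not 1 <= self.index <= 5:
            raise TopologyError(f"residue index {self.index} outside 1..5")
        if self.code not in _ONE_LETTER:
            raise TopologyError(f"unknown residue code {self.code!r}")
        if self.n_methylated:
            if self.has_atom("H"):
                raise TopologyError("MEG backbone N must not carry an amide H")
            if not self.has_atom("CN"):
                raise TopologyError("MEG must carry the N-methyl carbon CN")


@dataclass
class PeptideChain:
    """A single pentapeptide chain (CREKA or CRE(NMe)KA)."""

    chain_id: str
    residues: list[Residue]
    n_term_protonated: bool = True
    c_term_deprotonated: bool = True

    def validate(self) -> None:
        codes = tuple(r.code for r in self.residues)
        if codes not in (CREKA_CODES, CRENKA_CODES):
            raise TopologyError(
                f"chain {self.chain_id}: sequence {codes} is neither CREKA nor "
                "CRE(NMe)KA"
            )
        for r in self.residues:
            r.validate()

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.residues)

    @property
    def is_n_methylated(self) -> bool:
        return self.sequence == CRENKA_CODES

    def iter_atoms(self):
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for _, a in self.iter_atoms()])

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for (_, atom), xyz in zip(self.iter_atoms(), coords, strict=True):
            atom.position = np.array(xyz, dtype=float)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    chain_id: str | None = None) -> "PeptideChain":
        """Rigidly transformed deep copy (rotation about the origin first)."""
        new = copy_chain(self, chain_id or self.chain_id)
        coords = new.coordinates()
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        new.set_coordinates(coords)
        return new

    def center(self) -> np.ndarray:
        """Center of geometry over all atoms, nm."""
        return self.coordinates().mean(axis=0)

    def ca_positions(self) -> np.ndarray:
        return np.array([r.atom("CA").position for r in self.residues])


def copy_chain(chain: PeptideChain, chain_id: str | None = None) -> PeptideChain:
    residues = [
        Residue(
            index=r.index,
            code=r.code,
            atoms=[replace(a, position=a.position.copy()) for a in r.atoms],
        )
        for r in chain.residues
    ]
    return PeptideChain(
        chain_id=chain_id or chain.chain_id,
        residues=residues,
        n_term_protonated=chain.n_term_protonated,
        c_term_deprotonated=chain.c_term_deprotonated,
    )


@dataclass
class SystemFrame:
    """One snapshot: a set of chains with an optional orthorhombic box (nm)."""

    frame_index: int
    chains: list[PeptideChain]
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def validate(self) -> None:
        if self.frame_index < 0:
            raise TopologyError("frame_index must be >= 0")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise TopologyError(f"duplicate chain ids in frame: {ids}")
        if self.box is not None and not np.all(self.box > 0):
            raise TopologyError("box components must all be positive")
        for c in self.chains:
            c.validate()

    def chain(self, chain_id: str) -> PeptideChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass
class Trajectory:
    """Ordered frames sharing a chain topology (same ids and sequences)."""

    frames: list[SystemFrame]

    def validate(self) -> None:
        if not self.frames:
            raise TopologyError("trajectory has no frames")
        ref = [(c.chain_id, c.sequence) for c in self.frames[0].chains]
        for fr in self.frames:
            fr.validate()
            if [(c.chain_id, c.sequence) for c in fr.chains] != ref:
                raise TopologyError("frames do not share chain topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


class ConformationLabel(enum.Enum):
    BETA = "BETA"
    TURN_REGION = "TURN_REGION"
    OTHER = "OTHER"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class ConformationRegions:
    """Ramachandran regions used to label residues.

    The beta region covers the extended-strand basin (including the
    wrap-around of psi past +180); the turn region covers the alpha/turn
    basin.  Membership is mutually exclusive by construction.
    """

    beta_phi: tuple[float, float] = (-180.0, -90.0)
    beta_psi: tuple[float, float] = (90.0, 180.0)
    beta_psi_wrap: tuple[float, float] = (-180.0, -170.0)
    turn_phi: tuple[float, float] = (-120.0, -30.0)
    turn_psi: tuple[float, float] = (-80.0, 30.0)

    def in_beta(self, phi: float, psi: float) -> bool:
        lo, hi = self.beta_phi
        if not lo <= phi <= hi:
            return False
        plo, phi_ = self.beta_psi
        wlo, whi = self.beta_psi_wrap
        return (plo <= psi <= phi_) or (wlo <= psi <= whi)

    def in_turn(self, phi: float, psi: float) -> bool:
        lo, hi = self.turn_phi
        plo, phi_ = self.turn_psi
        return lo <= phi <= hi and plo <= psi <= phi_


DEFAULT_REGIONS = ConformationRegions()


def assign_conformation(
    phi: float, psi: float, regions: ConformationRegions = DEFAULT_REGIONS
) -> ConformationLabel:
    """Label a residue from its (phi, psi) pair; total on (-180, 180]^2."""
    if regions.in_beta(phi, psi):
        return ConformationLabel.BETA
    if regions.in_turn(phi, psi):
        return ConformationLabel.TURN_REGION
    return ConformationLabel.OTHER


def backbone_dihedrals(chain: PeptideChain) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue in degrees; phi is None for residue 1 and psi
    is None for residue 5."""
    n = len(chain.residues)
    for r in chain.residues:
        for name in ("N", "CA", "C"):
            if not r.has_atom(name):
                raise TopologyError(
                    f"chain {chain.chain_id} residue {r.code}{r.index}: "
                    f"missing backbone atom {name}"
                )
    out: list[tuple[float | None, float | None]] = []
    for i, r in enumerate(chain.residues):
        phi = psi = None
        if i > 0:
            prev_c = chain.residues[i - 1].atom("C").position
            phi = dihedral(
                prev_c, r.atom("N").position, r.atom("CA").position, r.atom("C").position
            )
        if i < n - 1:
            next_n = chain.residues[i + 1].atom("N").position
            psi = dihedral(
                r.atom("N").position, r.atom("CA").position, r.atom("C").position, next_n
            )
        out.append((phi, psi))
    return out


def chain_conformations(
    chain: PeptideChain, regions: ConformationRegions = DEFAULT_REGIONS
) -> list[ConformationLabel]:
    """Per-residue conformation labels; UNDEFINED at the termini."""
    labels = []
    for phi, psi in backbone_dihedrals(chain):
        if phi is None or psi is None:
            labels.append(ConformationLabel.UNDEFINED)
        else:
            labels.append(assign_conformation(phi, psi, regions))
    return labels


# ---------------------------------------------------------------------------
# PDB I/O (biotite handles the fixed-width format; we map to the domain model)
# ---------------------------------------------------------------------------


def _reconstruct_amide_h(res: Residue, prev_res: Residue) -> Atom:
    """Place a missing backbone amide H on the bisector of CA-N and C(prev)-N."""
    n = res.atom("N").position
    ca = res.atom("CA").position
    cprev = prev_res.atom("C").position
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (n - cprev) / np.linalg.norm(n - cprev)
    d = u + v
    d = d / np.linalg.norm(d)
    return Atom(serial=0, name="H", element="H", position=n + 0.101 * d)


def read_structure(
    path,
    strict_h: bool = True,
    meg_aliases: tuple[str, ...] = DEFAULT_MEG_ALIASES,
) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory, converting A -> nm.

    With ``strict_h`` every non-MEG backbone nitrogen must carry at least one
    explicit hydrogen; with ``strict_h=False`` missing amide hydrogens on
    residues 2-5 are reconstructed from the N, CA, C(prev) geometry.
    """
    import biotite.structure.io.pdb as pdb

    path = str(path)
    # cheap pre-scan so coordinate corruption is reported with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise FormatError(
                        f"{path}: unparsable coordinate record at line {lineno}"
                    ) from None
    try:
        pdb_file = pdb.PDBFile.read(path)
        stack = pdb_file.get_structure(model=None)
    except FormatError:
        raise
    except Exception as exc:  # biotite parse failure
        raise FormatError(f"{path}: {exc}") from exc

    alias_map = {a: "MEG" for a in meg_aliases}
    frames: list[SystemFrame] = []
    for fi in range(stack.stack_depth()):
        arr = stack[fi]
        chains: list[PeptideChain] = []
        seen: list[str] = []
        for cid in arr.chain_id:
            if cid not in seen:
                seen.append(cid)
        for cid in seen:
            sub = arr[arr.chain_id == cid]
            res_ids = []
            for rid in sub.res_id:
                if rid not in res_ids:
                    res_ids.append(rid)
            if len(res_ids) != 5:
                raise TopologyError(
                    f"chain {cid}: expected 5 residues, found {len(res_ids)}"
                )
            residues = []
            for ri, rid in enumerate(res_ids, start=1):
                mask = sub.res_id == rid
                raw_code = str(sub.res_name[mask][0])
                code = alias_map.get(raw_code, raw_code)
                if code not in _ONE_LETTER:
                    raise TopologyError(
                        f"chain {cid} residue {rid}: unknown residue code {raw_code!r}"
                    )
                atoms = [
                    Atom(
                        serial=int(k + 1),
                        name=str(nm),
                        element=str(el) if el else str(nm)[0],
                        position=np.asarray(xyz, dtype=float) / A_PER_NM,
                    )
                    for k, (nm, el, xyz) in enumerate(
                        zip(sub.atom_name[mask], sub.element[mask], sub.coord[mask])
                    )
                ]
                residues.append(Residue(index=ri, code=code, atoms=atoms))
            first = residues[0]
            n_term_prot = sum(
                first.has_atom(h) for h in ("H1", "H2", "H3")
            ) >= 3 or first.has_atom("H3")
            last = residues[-1]
            c_term_deprot = last.has_atom("OXT") and not last.has_atom("HXT")
            chain = PeptideChain(
                chain_id=str(cid),
                residues=residues,
                n_term_protonated=bool(n_term_prot),
                c_term_deprotonated=bool(c_term_deprot),
            )
            _check_hydrogens(chain, strict_h)
            chains.append(chain)
        frames.append(SystemFrame(frame_index=fi, chains=chains))
    traj = Trajectory(frames=frames)
    traj.validate()
    return traj


def _check_hydrogens(chain: PeptideChain, strict_h: bool) -> None:
    for i, res in enumerate(chain.residues):
        if res.n_methylated:
            continue
        if i == 0:
            has_h = any(res.has_atom(h) for h in ("H", "H1", "H2", "H3"))
            if not has_h and strict_h:
                raise MissingHydrogenError(
                    f"chain {chain.chain_id} residue 1: terminal N carries no hydrogen"
                )
            continue
        if not res.has_atom("H"):
            if strict_h:
                raise MissingHydrogenError(
                    f"chain {chain.chain_id} residue {res.code}{res.index}: "
                    "backbone N lacks an amide hydrogen"
                )
            res.atoms.insert(1, _reconstruct_amide_h(res, chain.residues[i - 1]))


def write_structure(traj: Trajectory, path) -> None:
    """Write a Trajectory as a (multi-model) PDB file, converting nm -> A.

    Output is deterministic for a fixed input.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    traj.validate()

    def frame_to_array(frame: SystemFrame) -> "struc.AtomArray":
        n_atoms = sum(len(r.atoms) for c in frame.chains for r in c.residues)
        arr = struc.AtomArray(n_atoms)
        k = 0
        for chain in frame.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    arr.chain_id[k] = chain.chain_id
                    arr.res_id[k] = res.index
                    arr.res_name[k] = res.code
                    arr.atom_name[k] = atom.name
                    arr.element[k] = atom.element
                    arr.coord[k] = atom.position * A_PER_NM
                    k += 1
        arr.hetero[:] = False
        return arr

    arrays = [frame_to_array(f) for f in traj.frames]
    pdb_file = pdb.PDBFile()
    if len(arrays) == 1:
        pdb_file.set_structure(arrays[0])
    else:
        stack = struc.stack(arrays)
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))
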