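"""Aggregate detection, hydrogen-bond pattern classification, strand
orientation, and aggregate-size-stratified pattern statistics.

Every detected hydrogen bond falls into exactly one of seven categories:

* intramolecular, main-chain amide to amide:
  - BETA_TURN   : acceptor residue i, donor residue i+3
  - GAMMA_TURN  : acceptor residue i, donor residue i+2
  - OTHER_INTRA_MAIN : any other intramolecular amide-amide pattern
* intramolecular with a side group involved: INTRA_SIDE
* intermolecular, main-chain amide to amide:
  - BETA_SHEET  : both flanking residues in beta-strand conformation
  - MAIN_MAIN   : strands without defined beta conformation
* intermolecular with a side group involved: INTER_SIDE

Aggregates are connected components of the chain-contact graph; a chain in
a size-1 aggregate is not part of any assembly.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, UsageError
from .interactions import (
    DEFAULT_CONFIG,
    HBond,
    InteractionConfig,
    detect_hbonds,
    detect_salt_bridges,
)
from .structures import (
    ConformationLabel,
    ConformationRegions,
    DEFAULT_REGIONS,
    PeptideChain,
    SystemFrame,
    Trajectory,
    chain_conformations,
)


class HBondCategory(enum.Enum):
    BETA_TURN = "beta_turn"
    GAMMA_TURN = "gamma_turn"
    OTHER_INTRA_MAIN = "other_intra_main"
    INTRA_SIDE = "intra_side"
    BETA_SHEET = "beta_sheet"
    MAIN_MAIN = "main_main"
    INTER_SIDE = "inter_side"


class Orientation(enum.Enum):
    PARALLEL = "PARALLEL"
    ANTIPARALLEL = "ANTIPARALLEL"


@dataclass(frozen=True)
class Aggregate:
    chain_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.chain_ids)


def find_aggregates(
    frame: SystemFrame,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> list[Aggregate]:
    """Partition the chains into aggregates (connected components).

    Two chains are in contact when they share at least one intermolecular
    hydrogen bond or salt bridge, or when any intermolecular heavy-atom pair
    is closer than the contact cutoff (0.45 nm by default).
    """
    g = nx.Graph()
    for chain in frame.chains:
        g.add_node(chain.chain_id)

    # heavy-atom proximity
    positions, labels = [], []
    for ci, chain in enumerate(frame.chains):
        for _, atom in chain.iter_atoms():
            if atom.element != "H":
                positions.append(atom.position)
                labels.append(ci)
    if positions:
        positions = np.array(positions)
        labels = np.array(labels)
        tree = cKDTree(positions)
        for i, j in tree.query_pairs(r=config.contact_cut):
            if labels[i] != labels[j]:
                g.add_edge(
                    frame.chains[labels[i]].chain_id, frame.chains[labels[j]].chain_id
                )

    for b in detect_hbonds(frame, config.d_cut, config.ang_cut, config):
        if not b.is_intra:
            g.add_edge(b.donor_chain, b.acceptor_chain)
    for sb in detect_salt_bridges(frame, config.salt_bridge_cut, config):
        if not sb.same_chain:
            g.add_edge(*sb.chains)

    comps = [Aggregate(frozenset(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda a: (-a.size, sorted(a.chain_ids)))
    return comps


def classify_hbond(
    hb: HBond,
    conformations: dict[str, list[ConformationLabel]],
    same_aggregate: bool,
) -> HBondCategory:
    """Assign one of the seven pattern categories to a hydrogen bond.

    ``conformations`` maps chain id -> per-residue labels (index 0 = residue 1).
    """
    if hb.is_intra:
        if not same_aggregate:
            raise ConsistencyError(
                f"intramolecular bond {hb.hydrogen} -> {hb.acceptor} flagged as "
                "crossing aggregates"
            )
        if hb.donor_is_sidechain or hb.acceptor_is_sidechain:
            return HBondCategory.INTRA_SIDE
        diff = hb.donor_heavy.res_index - hb.acceptor.res_index
        if diff == 3:
            return HBondCategory.BETA_TURN
        if diff == 2:
            return HBondCategory.GAMMA_TURN
        return HBondCategory.OTHER_INTRA_MAIN
    if hb.donor_is_sidechain or hb.acceptor_is_sidechain:
        return HBondCategory.INTER_SIDE
    donor_label = conformations[hb.donor_chain][hb.donor_heavy.res_index - 1]
    acc_label = conformations[hb.acceptor_chain][hb.acceptor.res_index - 1]
    if donor_label is ConformationLabel.BETA and acc_label is ConformationLabel.BETA:
        return HBondCategory.BETA_SHEET
    return HBondCategory.MAIN_MAIN


def strand_orientation(
    chain_i: PeptideChain,
    chain_j: PeptideChain,
    hbonds: list[HBond] | None = None,
) -> Orientation:
    """PARALLEL iff the Ca(1)->Ca(5) end-to-end vectors point the same way.

    When a bond list is supplied, the pair must share at least one
    inter-main-chain hydrogen bond (the notion of sheet orientation is only
    meaningful for hydrogen-bonded strand pairs).
    """
    if hbonds is not None:
        ids = {chain_i.chain_id, chain_j.chain_id}
        shared = any(
            {b.donor_chain, b.acceptor_chain} == ids
            and not b.donor_is_sidechain
            and not b.acceptor_is_sidechain
            for b in hbonds
        )
        if not shared:
            raise UsageError(
                f"chains {chain_i.chain_id}/{chain_j.chain_id} share no "
                "inter-main-chain hydrogen bond"
            )
    vi = chain_i.ca_positions()[-1] - chain_i.ca_positions()[0]
    vj = chain_j.ca_positions()[-1] - chain_j.ca_positions()[0]
    return Orientation.PARALLEL if float(np.dot(vi, vj)) > 0 else Orientation.ANTIPARALLEL


def sheet_orientations(
    frame: SystemFrame, hbonds: list[HBond] | None = None,
    config: InteractionConfig = DEFAULT_CONFIG,
) -> dict[tuple[str, str], Orientation]:
    """Orientation of every chain pair sharing an inter-main-chain bond."""
    if hbonds is None:
        hbonds = detect_hbonds(frame, config.d_cut, config.ang_cut, config)
    pairs = set()
    for b in hbonds:
        if (
            not b.is_intra
            and not b.donor_is_sidechain
            and not b.acceptor_is_sidechain
        ):
            pairs.add(tuple(sorted((b.donor_chain, b.acceptor_chain))))
    return {
        p: strand_orientation(frame.chain(p[0]), frame.chain(p[1]))
        for p in sorted(pairs)
    }


@dataclass
class AnalysisParams:
    """Knobs of the pattern-statistics pipeline."""

    config: InteractionConfig = DEFAULT_CONFIG
    regions: ConformationRegions = DEFAULT_REGIONS
    mode: str = "pooled"  # pooled | last-frame

    def __post_init__(self) -> None:
        if self.mode not in ("pooled", "last-frame"):
            raise UsageError(f"unknown pooling mode {self.mode!r}")


CATEGORY_ORDER = [
    HBondCategory.BETA_TURN,
    HBondCategory.GAMMA_TURN,
    HBondCategory.OTHER_INTRA_MAIN,
    HBondCategory.INTRA_SIDE,
    HBondCategory.BETA_SHEET,
    HBondCategory.MAIN_MAIN,
    HBondCategory.INTER_SIDE,
]


@dataclass
class PatternTable:
    """Counts and percentages of bond categories per aggregate-size bin."""

    counts: dict[tuple[HBondCategory, int], int] = field(default_factory=dict)
    n_frames: int = 0

    @property
    def sizes(self) -> list[int]:
        return sorted({s for _, s in self.counts})

    @property
    def percent(self) -> dict[tuple[HBondCategory, int], float]:
        totals = {}
        for (cat, size), c in self.counts.items():
            totals[size] = totals.get(size, 0) + c
        return {
            (cat, size): 100.0 * c / totals[size]
            for (cat, size), c in self.counts.items()
            if totals[size] > 0
        }

    @property
    def total_bonds(self) -> int:
        return sum(self.counts.values())

    def to_dataframe(self, values: str = "percent"):
        import pandas as pd

        data = self.percent if values == "percent" else self.counts
        rows = {}
        for size in self.sizes:
            rows[size] = {
                cat.value: data.get((cat, size), 0.0 if values == "percent" else 0)
                for cat in CATEGORY_ORDER
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "aggregate_size"
        return df

    def to_tsv(self, path) -> None:
        df = self.to_dataframe("percent")
        df.map(lambda v: f"{v:.2f}").to_csv(path, sep="\t")


def classify_frame(
    frame: SystemFrame, params: AnalysisParams
) -> list[tuple[HBond, HBondCategory, int]]:
    """Detect, classify and size-attribute all bonds of one frame.

    Each bond is attributed to the aggregate size of its donor chain.
    """
    cfg = params.config
    bonds = detect_hbonds(frame, cfg.d_cut, cfg.ang_cut, cfg)
    aggregates = find_aggregates(frame, cfg)
    size_of = {cid: agg.size for agg in aggregates for cid in agg.chain_ids}
    member = {cid: i for i, agg in enumerate(aggregates) for cid in agg.chain_ids}
    conformations = {
        c.chain_id: chain_conformations(c, params.regions) for c in frame.chains
    }
    out = []
    for b in bonds:
        same_agg = member[b.donor_chain] == member[b.acceptor_chain]
        cat = classify_hbond(b, conformations, same_agg)
        out.append((b, cat, size_of[b.donor_chain]))
    return out


def pattern_statistics(traj: Trajectory, params: AnalysisParams | None = None) -> PatternTable:
    """Aggregate-size-stratified hydrogen-bond pattern percentages.

    In "pooled" mode counts accumulate over all frames before normalisation;
    "last-frame" uses only the final snapshot.  Frames without bonds
    contribute nothing.
    """
    params = params or AnalysisParams()
    frames = traj.frames[-1:] if params.mode == "last-frame" else traj.frames
    table = PatternTable(n_frames=len(frames))
    for frame in frames:
        for _, cat, size in classify_frame(frame, params):
            key = (cat, size)
            table.counts[key] = table.counts.get(key, 0) + 1
    return table


def aggregates_to_json(aggregates: list[Aggregate], path=None) -> str:
    payload = [
        {"size": a.size, "chains": sorted(a.chain_ids)} for a in aggregates
    ]
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
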