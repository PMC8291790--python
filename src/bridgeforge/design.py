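"""Homolog-guided mutation design from salt bridges mapped onto an alignment.

The comparative strategy: align a target enzyme with thermostable homologs,
project every homolog's salt-bridge residues onto alignment columns, and look
for *hotspots* — columns where several homologs keep a charged bridge residue
but the target forms no bridge.  Copying the homologs' charge into the target
at those columns, plus mutating the *coordinating* positions that must supply
the partner charge (e.g. a Lys that must become the bidentate Arg partnering
two acidic residues), yields a set of candidate stabilizing mutations.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .bridges import (
    BridgeDiff,
    BridgeSet,
    SaltBridge,
    MutationMap,
    build_networks,
    check_network_preserved,
    detect_bridges,
    diff_bridge_sets,
    split_label,
)
from .errors import ParseError, ValidationError
from .structure import Structure

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}

#: Tie-break preference when homolog residues at a column are split evenly.
_RESIDUE_PREFERENCE = "EDKR"


class AlignmentColumnMap:
    """Per-sequence residue-position ↔ alignment-column maps (both 1-based).

    ``starts`` gives the residue number of each sequence's first residue
    (default 1), so positions follow each protein's report numbering — e.g. a
    mature enzyme numbered from 23.
    """

    def __init__(self, records: dict[str, str], starts: dict[str, int] | None = None):
        if not records:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            ragged = [i for i, s in records.items() if len(s) != max(lengths)]
            raise ParseError(f"ragged alignment; offending sequence(s): {ragged}")
        self.ids = list(records)
        self.aligned = dict(records)
        self.starts = {i: (starts or {}).get(i, 1) for i in self.ids}
        self.length = lengths.pop()
        self._pos2col: dict[str, dict[int, int]] = {}
        self._col2pos: dict[str, dict[int, int]] = {}
        for sid, seq in records.items():
            p2c: dict[int, int] = {}
            c2p: dict[int, int] = {}
            pos = self.starts[sid] - 1
            for col, ch in enumerate(seq, start=1):
                if ch in GAP_CHARS:
                    continue
                pos += 1
                p2c[pos] = col
                c2p[col] = pos
            self._pos2col[sid] = p2c
            self._col2pos[sid] = c2p

    def col_of(self, seq_id: str, position: int) -> int:
        try:
            return self._pos2col[seq_id][position]
        except KeyError:
            raise ValidationError(
                f"position {position} not present in sequence {seq_id!r}"
            ) from None

    def pos_of(self, seq_id: str, column: int) -> int | None:
        """Residue position at a column, or None if the sequence gaps there."""
        return self._col2pos[seq_id].get(column)

    def residue_at(self, seq_id: str, column: int) -> str | None:
        ch = self.aligned[seq_id][column - 1]
        return None if ch in GAP_CHARS else ch.upper()

    def positions(self, seq_id: str) -> list[int]:
        return sorted(self._pos2col[seq_id])


def read_alignment(
    path: str | Path,
    format: str = "aligned-fasta",
    starts: dict[str, int] | None = None,
) -> AlignmentColumnMap:
    """Read an aligned FASTA or Clustal file into an :class:`AlignmentColumnMap`."""
    fmt = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValidationError(f"unknown alignment format: {format!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ParseError(f"cannot parse alignment {path}: {exc}") from exc
    records: dict[str, str] = {}
    for rec in aln:
        if rec.id in records:
            raise ParseError(f"duplicate sequence id {rec.id!r} in alignment")
        records[rec.id] = str(rec.seq)
    return AlignmentColumnMap(records, starts)


@dataclass(frozen=True)
class Participation:
    """One bridge endpoint projected onto an alignment column."""

    enzyme_id: str
    bridge: SaltBridge
    role: str  # "acidic" | "basic"
    residue: str  # label, e.g. "D52"

    @property
    def partner(self) -> str:
        return self.bridge.basic if self.role == "acidic" else self.bridge.acidic


@dataclass
class ParticipationTable:
    """Per-column bridge participation, with the column map it was built from."""

    cmap: AlignmentColumnMap
    by_column: dict[int, list[Participation]]

    def enzymes_at(self, column: int) -> set[str]:
        return {p.enzyme_id for p in self.by_column.get(column, [])}


def map_bridges_to_columns(
    cmap: AlignmentColumnMap, bridge_sets: dict[str, BridgeSet]
) -> ParticipationTable:
    """Project both endpoints of every bridge onto alignment columns."""
    by_column: dict[int, list[Participation]] = {}
    for sid, bset in bridge_sets.items():
        if sid not in cmap.aligned:
            raise ValidationError(f"bridge set {sid!r} has no sequence in the alignment")
        for bridge in bset:
            for role, label in (("acidic", bridge.acidic), ("basic", bridge.basic)):
                _, pos = split_label(label)
                try:
                    col = cmap.col_of(sid, pos)
                except ValidationError:
                    raise ValidationError(
                        f"bridge {bridge} of {sid!r}: residue {label} outside sequence range"
                    ) from None
                by_column.setdefault(col, []).append(
                    Participation(sid, bridge, role, label)
                )
    return ParticipationTable(cmap, by_column)


@dataclass
class Hotspot:
    """An alignment column where homologs bridge but the target does not."""

    column: int
    supporting: list[Participation]
    target_position: int | None


@dataclass
class CoordinatingSite:
    """A target position that must supply the partner charge of hotspot bridges."""

    position: int
    column: int
    needed_res: str
    supporting: list[Participation]


def _majority_residue(letters: list[str]) -> str | None:
    """Most common charged residue type; ties broken by preference E>D>K>R."""
    votes = [ch for ch in letters if ch in _RESIDUE_PREFERENCE]
    if not votes:
        return None
    counts = Counter(votes)
    best = max(counts.values())
    return min(
        (ch for ch, n in counts.items() if n == best),
        key=_RESIDUE_PREFERENCE.index,
    )


def find_hotspots(
    table: ParticipationTable, target_id: str, support: int = 2
) -> list[Hotspot]:
    """Columns where ≥ ``support`` homologs contribute a bridge residue and the
    target contributes none; sorted by column."""
    if target_id not in table.cmap.aligned:
        raise ValidationError(f"target {target_id!r} not present in the alignment")
    hotspots = []
    for col in sorted(table.by_column):
        entries = table.by_column[col]
        homologs = {p.enzyme_id for p in entries if p.enzyme_id != target_id}
        if len(homologs) < support:
            continue
        if any(p.enzyme_id == target_id for p in entries):
            continue
        hotspots.append(
            Hotspot(
                column=col,
                supporting=[p for p in entries if p.enzyme_id != target_id],
                target_position=table.cmap.pos_of(target_id, col),
            )
        )
    return hotspots


def find_coordinating_positions(
    hotspots: list[Hotspot],
    table: ParticipationTable,
    target_id: str,
) -> list[CoordinatingSite]:
    """Partner columns required by hotspot bridges where the target lacks the
    needed residue.

    For every bridge supporting a hotspot, the partner endpoint's column is
    located; the residue the target must carry there is the majority partner
    residue type across homologs (e.g. Arg when homologs use a bidentate Arg).
    The position is reported only when the target residue differs from it.
    """
    cmap = table.cmap
    partners: dict[int, list[Participation]] = {}
    hotspot_cols = {h.column for h in hotspots}
    for h in hotspots:
        for p in h.supporting:
            _, ppos = split_label(p.partner)
            pcol = cmap.col_of(p.enzyme_id, ppos)
            partner_role = "basic" if p.role == "acidic" else "acidic"
            partners.setdefault(pcol, []).append(
                Participation(p.enzyme_id, p.bridge, partner_role, p.partner)
            )
    sites = []
    for pcol in sorted(partners):
        if pcol in hotspot_cols:
            continue
        tpos = cmap.pos_of(target_id, pcol)
        if tpos is None:
            logger.warning("target gaps at partner column %d; skipped", pcol)
            continue
        needed = _majority_residue([split_label(p.residue)[0] for p in partners[pcol]])
        if needed is None:
            continue
        if cmap.residue_at(target_id, pcol) == needed:
            continue
        sites.append(CoordinatingSite(tpos, pcol, needed, partners[pcol]))
    return sites


@dataclass(frozen=True)
class MutationProposal:
    position: int
    from_res: str
    to_res: str
    kind: str  # "hotspot" | "coordinating"
    evidence: tuple[str, ...] = ()

    def __str__(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"


def propose_mutations(
    hotspots: list[Hotspot],
    coordinating: list[CoordinatingSite],
    cmap: AlignmentColumnMap,
    target_id: str,
) -> list[MutationProposal]:
    """One charged-residue proposal per hotspot / coordinating position.

    At a hotspot the proposed residue copies the majority charge observed in
    the supporting homologs (ties prefer E over D and K over R); histidine
    supporters do not vote since the copied charge should be pH-robust.
    Proposals are deduplicated by position (hotspot role wins) and positions
    already carrying the proposed residue are dropped.
    """
    proposals: dict[int, MutationProposal] = {}
    for h in hotspots:
        if h.target_position is None:
            logger.warning("target gaps at hotspot column %d; skipped", h.column)
            continue
        to_res = _majority_residue([split_label(p.residue)[0] for p in h.supporting])
        if to_res is None:
            continue
        from_res = cmap.residue_at(target_id, h.column)
        if from_res == to_res:
            continue
        proposals[h.target_position] = MutationProposal(
            position=h.target_position,
            from_res=from_res,
            to_res=to_res,
            kind="hotspot",
            evidence=tuple(f"{p.enzyme_id}:{p.residue}" for p in h.supporting),
        )
    for site in coordinating:
        if site.position in proposals:
            continue
        from_res = cmap.residue_at(target_id, site.column)
        if from_res == site.needed_res:
            continue
        proposals[site.position] = MutationProposal(
            position=site.position,
            from_res=from_res,
            to_res=site.needed_res,
            kind="coordinating",
            evidence=tuple(f"{p.enzyme_id}:{p.residue}" for p in site.supporting),
        )
    return [proposals[p] for p in sorted(proposals)]


def design_mutations(
    cmap: AlignmentColumnMap,
    bridge_sets: dict[str, BridgeSet],
    target_id: str,
    support: int = 2,
) -> tuple[list[Hotspot], list[CoordinatingSite], list[MutationProposal]]:
    """Full comparative-design chain: participation table → hotspots →
    coordinating positions → mutation proposals."""
    table = map_bridges_to_columns(cmap, bridge_sets)
    hotspots = find_hotspots(table, target_id, support=support)
    coordinating = find_coordinating_positions(hotspots, table, target_id)
    proposals = propose_mutations(hotspots, coordinating, cmap, target_id)
    return hotspots, coordinating, proposals


@dataclass
class DesignReport:
    """Outcome of a wild-vs-mutant comparison against a set of proposals."""

    diff: BridgeDiff
    proposal_outcomes: list[tuple[MutationProposal, bool]]
    networks_preserved: list[tuple[set[str], bool]]

    def to_dict(self) -> dict:
        return {
            "schema": 1,
            "gained": sorted(str(b) for b in self.diff.gained),
            "lost": sorted(str(b) for b in self.diff.lost),
            "proposals": [
                {"mutation": str(p), "kind": p.kind, "productive": ok}
                for p, ok in self.proposal_outcomes
            ],
            "networks": [
                {"members": sorted(members), "preserved": ok}
                for members, ok in self.networks_preserved
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, ensure_ascii=False)


def evaluate_mutant(
    wild: Structure | BridgeSet,
    mutant: Structure | BridgeSet,
    proposals: list[MutationProposal] | None = None,
    mutations: MutationMap | None = None,
    cutoff: float = 3.2,
    include_his: bool = True,
) -> DesignReport:
    """Diff mutant vs wild bridges, score proposals, and check wild networks.

    Structures are reduced to bridge sets with identical detection parameters;
    declared bridge sets are used as-is.  A proposal is *productive* when at
    least one gained bridge touches its position.
    """
    if isinstance(wild, Structure) and isinstance(mutant, Structure):
        if wild.numbering_offset != mutant.numbering_offset:
            raise ValidationError(
                "wild and mutant structures use different numbering offsets; "
                "renumber before comparison"
            )
    wild_set = (
        detect_bridges(wild, cutoff=cutoff, include_his=include_his)
        if isinstance(wild, Structure)
        else wild
    )
    mut_set = (
        detect_bridges(mutant, cutoff=cutoff, include_his=include_his)
        if isinstance(mutant, Structure)
        else mutant
    )
    diff = diff_bridge_sets(wild_set, mut_set, mutations)
    outcomes = []
    for p in proposals or []:
        touched = any(p.position in b.positions for b in diff.gained)
        outcomes.append((p, touched))
    networks = build_networks(wild_set)
    preserved = check_network_preserved(networks, mut_set, mutations)
    return DesignReport(
        diff=diff,
        proposal_outcomes=outcomes,
        networks_preserved=[(n.members, ok) for n, ok in zip(networks, preserved)],
    )
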