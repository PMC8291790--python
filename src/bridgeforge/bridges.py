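"""Salt-bridge detection, printed-list parsing, networks, and set diffs.

A salt bridge is an acidic side-chain carboxylate oxygen (Asp OD1/OD2,
Glu OE1/OE2) within a distance cutoff of a basic side-chain nitrogen
(Lys NZ; Arg NE/NH1/NH2; His ND1/NE2).  The 3.2 Å default selects the
"strong" bridges commonly used when comparing thermophilic homologs.
A bridge is a residue-pair event: however many atom pairs qualify, one
bridge is reported with the minimum qualifying distance.

Bridges are identified by residue labels in one-letter + report-number
form, e.g. ``D59``.  Textual lists in that notation ("D59–R156, E61–R156")
can be parsed directly, which lets published bridge tables be analyzed
without coordinates.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParseError, ValidationError
from .structure import Structure

logger = logging.getLogger(__name__)

ACIDIC_TYPES = frozenset("DE")
BASIC_TYPES = frozenset("KRH")

#: Side-chain charged-group atoms considered on each side of a bridge.
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

_LABEL_RE = re.compile(r"^([DEKRH])(\d+)$")
_TOKEN_RE = re.compile(r"^([A-Z])(\d+)[–—-]([A-Z])(\d+)$")


def split_label(label: str) -> tuple[str, int]:
    """Split a residue label like ``D59`` into ``('D', 59)``."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValidationError(f"bad residue label {label!r} (expected e.g. 'D59')")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class SaltBridge:
    """An acidic–basic residue pairing; ``min_distance`` is None for declared bridges."""

    acidic: str
    basic: str
    min_distance: float | None = None

    def __post_init__(self) -> None:
        a_type, _ = split_label(self.acidic)
        b_type, _ = split_label(self.basic)
        if a_type not in ACIDIC_TYPES:
            raise ValidationError(f"{self.acidic!r} is not an acidic residue (D/E)")
        if b_type not in BASIC_TYPES:
            raise ValidationError(f"{self.basic!r} is not a basic residue (K/R/H)")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.acidic, self.basic)

    @property
    def positions(self) -> tuple[int, int]:
        return (split_label(self.acidic)[1], split_label(self.basic)[1])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.acidic}–{self.basic}"

    def __eq__(self, other: object) -> bool:
        # identity by residue pair; the recorded distance is metadata
        if not isinstance(other, SaltBridge):
            return NotImplemented
        return self.pair == other.pair

    def __hash__(self) -> int:
        return hash(self.pair)


@dataclass
class BridgeSet:
    """The salt bridges of one enzyme (model or declared list)."""

    enzyme_id: str
    bridges: set[SaltBridge] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.bridges)

    def __iter__(self):
        return iter(sorted(self.bridges, key=lambda b: (b.positions, b.pair)))

    def labels(self) -> set[tuple[str, str]]:
        return {b.pair for b in self.bridges}

    def to_tsv(self) -> str:
        lines = ["acidic\tbasic\tmin_distance"]
        for b in self:
            d = "" if b.min_distance is None else f"{b.min_distance:.3f}"
            lines.append(f"{b.acidic}\t{b.basic}\t{d}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, enzyme_id: str = "bridges") -> "BridgeSet":
        bridges = set()
        for i, line in enumerate(text.strip().splitlines()):
            if i == 0 and line.lower().startswith("acidic"):
                continue
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"bad bridge TSV line: {line!r}")
            dist = float(parts[2]) if len(parts) > 2 and parts[2] else None
            bridges.add(SaltBridge(parts[0], parts[1], dist))
        return cls(enzyme_id, bridges)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": 1,
                "enzyme_id": self.enzyme_id,
                "bridges": [
                    {"acidic": b.acidic, "basic": b.basic, "min_distance": b.min_distance}
                    for b in self
                ],
            },
            indent=2,
        )


@dataclass
class BridgeNetwork:
    """A connected component of ≥2 bridges sharing residues."""

    members: set[str]
    edges: set[SaltBridge]

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValidationError("a salt-bridge network needs at least 2 bridges")


@dataclass
class BridgeDiff:
    gained: set[SaltBridge]
    lost: set[SaltBridge]


def _charged_atoms(structure: Structure, table: dict[str, tuple[str, ...]]):
    """Collect (residue, coords array) for residues with charged-group atoms.

    Residues of a charged type that lack every expected side-chain atom are
    skipped with a warning count (truncated side chains in real models).
    """
    entries = []
    skipped = 0
    for res in structure:
        names = table.get(res.res_name)
        if not names:
            continue
        coords = [a.coords for a in res.atoms if a.name in names]
        if not coords:
            skipped += 1
            continue
        entries.append((res, np.vstack(coords)))
    return entries, skipped


def detect_bridges(
    structure: Structure,
    cutoff: float = 3.2,
    include_his: bool = True,
    interchain: bool = False,
) -> BridgeSet:
    """Geometric salt-bridge detection at ``cutoff`` Å (O···N minimum distance).

    One bridge per (acidic, basic) residue pair; the recorded distance is the
    minimum over qualifying atom pairs.  Histidine counts as basic by default;
    pairs across different chains are ignored unless ``interchain``.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    basic_table = dict(BASIC_ATOMS)
    if not include_his:
        basic_table.pop("HIS")
    acidic, n_skip_a = _charged_atoms(structure, ACIDIC_ATOMS)
    basic, n_skip_b = _charged_atoms(structure, basic_table)
    if n_skip_a or n_skip_b:
        logger.warning(
            "%s: %d charged residue(s) skipped for missing side-chain atoms",
            structure.id, n_skip_a + n_skip_b,
        )
    bridges = set()
    for ares, axyz in acidic:
        for bres, bxyz in basic:
            if not interchain and ares.chain_id != bres.chain_id:
                continue
            if (ares.chain_id, ares.seq_number, ares.insertion_code) == (
                bres.chain_id, bres.seq_number, bres.insertion_code
            ):
                continue
            d = cdist(axyz, bxyz).min()
            if d <= cutoff:
                bridges.add(SaltBridge(ares.label, bres.label, float(d)))
    return BridgeSet(structure.id, bridges)


_STRIP_RE = re.compile(r"\*+|\^[^\^\s]*\^")


def parse_bridge_list(text: str, enzyme_id: str = "parsed") -> BridgeSet:
    """Parse a printed bridge list such as ``"D59–R156, E61–R156"``.

    Markdown emphasis (``**``) and superscript markers (``^1^``) are stripped;
    en-dash, em-dash and hyphen all separate the partners.  Orientation is
    normalized acidic-first; an acidic–acidic or basic–basic token is a
    validation error.
    """
    cleaned = _STRIP_RE.sub("", text)
    bridges = set()
    for raw in cleaned.split(","):
        token = raw.strip()
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if not m:
            raise ParseError(f"malformed bridge token {token!r}")
        first = f"{m.group(1)}{m.group(2)}"
        second = f"{m.group(3)}{m.group(4)}"
        t1, t2 = m.group(1), m.group(3)
        if t1 in ACIDIC_TYPES and t2 in BASIC_TYPES:
            bridges.add(SaltBridge(first, second))
        elif t1 in BASIC_TYPES and t2 in ACIDIC_TYPES:
            bridges.add(SaltBridge(second, first))
        else:
            raise ValidationError(
                f"token {token!r} does not pair an acidic (D/E) with a basic (K/R/H) residue"
            )
    return BridgeSet(enzyme_id, bridges)


def build_networks(bridges: BridgeSet) -> list[BridgeNetwork]:
    """Connected components with ≥2 bridges, largest (by edge count) first."""
    g = nx.Graph()
    for b in bridges.bridges:
        g.add_edge(b.acidic, b.basic, bridge=b)
    networks = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() < 2:
            continue
        networks.append(
            BridgeNetwork(
                members=set(comp),
                edges={data["bridge"] for _, _, data in sub.edges(data=True)},
            )
        )
    networks.sort(key=lambda n: (-len(n.edges), -len(n.members), sorted(n.members)))
    return networks


MutationMap = dict[int, tuple[str, str]]


def _endpoints_match(wild_label: str, mut_label: str, mutations: MutationMap | None) -> bool:
    wt, wp = split_label(wild_label)
    mt, mp = split_label(mut_label)
    if wp != mp:
        return False
    if wt == mt:
        return True
    if mutations and mutations.get(wp) == (wt, mt):
        return True
    return False


def bridge_matches(wild: SaltBridge, mutant: SaltBridge, mutations: MutationMap | None = None) -> bool:
    """True if both endpoints sit at the same positions, allowing declared mutations."""
    return _endpoints_match(wild.acidic, mutant.acidic, mutations) and _endpoints_match(
        wild.basic, mutant.basic, mutations
    )


def diff_bridge_sets(
    wild: BridgeSet, mutant: BridgeSet, mutations: MutationMap | None = None
) -> BridgeDiff:
    """Bridges gained by / lost from the mutant, relative to the wild type.

    Matching is position-wise: a bridge is retained when both endpoints'
    positions are unchanged, even if a residue type changed at a position
    declared in ``mutations`` (position → (wild_res, mutant_res)).
    """
    gained = {
        m for m in mutant.bridges
        if not any(bridge_matches(w, m, mutations) for w in wild.bridges)
    }
    lost = {
        w for w in wild.bridges
        if not any(bridge_matches(w, m, mutations) for m in mutant.bridges)
    }
    return BridgeDiff(gained=gained, lost=lost)


def check_network_preserved(
    wild_networks: list[BridgeNetwork],
    mutant: BridgeSet,
    mutations: MutationMap | None = None,
) -> list[bool]:
    """For each wild-type network, is every edge present (position-wise) in the mutant?"""
    return [
        all(any(bridge_matches(e, m, mutations) for m in mutant.bridges) for e in net.edges)
        for net in wild_networks
    ]
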