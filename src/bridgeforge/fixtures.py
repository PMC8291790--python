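"""Deterministic synthetic inputs: planted-bridge structures, planted-RMSF
trajectories, Arrhenius rate tables, and the packaged worked example.

Everything here is generated from a seed, so the test suite and the
acceptance script need no external downloads.  The worked example bundles
the published salt-bridge tables of four GH32 exo-inulinases (one
cold-adapted target, three thermophilic homologs) and the engineered mutant,
together with a synthetic stand-in alignment that realizes the published
residue correspondences (the original alignment figure is not distributable
as data).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bridges import BridgeSet, parse_bridge_list, split_label
from .design import AlignmentColumnMap
from .errors import ValidationError
from .kinetics import GAS_CONSTANT, KELVIN_OFFSET
from .structure import ONE_TO_THREE, Atom, Residue, Structure, write_pdb
from .flex import Trajectory

# --------------------------------------------------------------------------
# planted-bridge structures

_CHARGED_SIDE_ATOMS = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "K": ("NZ",),
    "R": ("NE", "NH1", "NH2"),
    "H": ("ND1", "NE2"),
}
_BACKGROUND_RES = ("ALA", "GLY", "SER", "VAL", "THR")
_GRID_SPACING = 10.0  # Å between residue sites; keeps unplanted pairs far apart


@dataclass
class FixtureSpec:
    """Parameters for the synthetic generators; same seed → identical output."""

    seed: int = 0
    planted_bridges: list[tuple[str, str, float]] = field(default_factory=list)
    planted_rmsf: np.ndarray | None = None
    rate_params: tuple[float, float] = (1.0e7, 39.4)  # (A, Ea kJ/mol)


def _grid_site(i: int) -> np.ndarray:
    return np.array(
        [(i % 10) * _GRID_SPACING, ((i // 10) % 10) * _GRID_SPACING, (i // 100) * _GRID_SPACING]
    )


def _bridge_direction(k: int) -> np.ndarray:
    # distinct fixed unit vectors per planted bridge (golden-angle fan in xy)
    theta = 2.399963 * (k + 1)
    return np.array([np.cos(theta), np.sin(theta), 0.0])


def make_structure(
    planted_bridges: list[tuple[str, str, float]],
    n_residues: int | None = None,
    seed: int = 0,
    structure_id: str = "fixture",
) -> tuple[Structure, str]:
    """Build a synthetic structure in which exactly the planted bridges exist.

    Each planted triple ``(acidic_label, basic_label, distance)`` — e.g.
    ``("D10", "K20", 3.0)`` — places one basic charged nitrogen exactly
    ``distance`` Å from the acidic residue's first carboxylate oxygen.
    Residue sites sit on a 10 Å grid, so every unplanted charged pair is
    several Å beyond any sensible cutoff.  Returns the structure and its PDB
    text.
    """
    if not planted_bridges and n_residues is None:
        raise ValidationError("specify planted bridges or an explicit n_residues")
    rng = np.random.default_rng(seed)

    types: dict[int, str] = {}
    for acid, base, dist in planted_bridges:
        if dist <= 0:
            raise ValidationError(f"planted distance must be positive: {acid}–{base}")
        for label, allowed in ((acid, "DE"), (base, "KRH")):
            code, pos = split_label(label)
            if code not in allowed:
                raise ValidationError(f"{label!r}: expected a residue of class {allowed}")
            if types.get(pos, code) != code:
                raise ValidationError(
                    f"residue {pos} planted with conflicting types "
                    f"{types[pos]!r} and {code!r}: spec is unsatisfiable"
                )
            types[pos] = code
    max_pos = max(types) if types else 0
    n = n_residues if n_residues is not None else max_pos + 2
    if max_pos > n:
        raise ValidationError(f"planted position {max_pos} exceeds n_residues={n}")

    # base placement: CA + charged atoms at the residue's own grid site
    atom_coords: dict[int, dict[str, np.ndarray]] = {}
    for pos in range(1, n + 1):
        site = _grid_site(pos - 1)
        coords = {"CA": site.copy()}
        code = types.get(pos)
        if code:
            for j, name in enumerate(_CHARGED_SIDE_ATOMS[code]):
                coords[name] = site + np.array([0.0, 0.0, 1.0 + 0.8 * j])
        atom_coords[pos] = coords

    # move one free basic nitrogen next to each planted acid
    consumed: dict[int, int] = {}
    for k, (acid, base, dist) in enumerate(planted_bridges):
        a_code, a_pos = split_label(acid)
        b_code, b_pos = split_label(base)
        n_atoms = _CHARGED_SIDE_ATOMS[b_code]
        idx = consumed.get(b_pos, 0)
        if idx >= len(n_atoms):
            raise ValidationError(
                f"basic residue {base} has only {len(n_atoms)} charged nitrogen(s); "
                f"cannot satisfy another planted bridge"
            )
        consumed[b_pos] = idx + 1
        anchor = atom_coords[a_pos][_CHARGED_SIDE_ATOMS[a_code][0]]
        atom_coords[b_pos][n_atoms[idx]] = anchor + dist * _bridge_direction(k)

    residues = []
    for pos in range(1, n + 1):
        code = types.get(pos)
        res_name = ONE_TO_THREE[code] if code else _BACKGROUND_RES[
            rng.integers(0, len(_BACKGROUND_RES))
        ]
        atoms = [
            Atom(name=name, element=name[0], coords=xyz)
            for name, xyz in atom_coords[pos].items()
        ]
        residues.append(Residue(chain_id="A", seq_number=pos, res_name=res_name, atoms=atoms))
    structure = Structure(id=structure_id, residues=residues)
    return structure, write_pdb(structure)


# --------------------------------------------------------------------------
# planted-RMSF trajectories

def make_trajectory(
    amplitudes: np.ndarray | list[float],
    n_frames: int = 50,
    n_cycles: int = 3,
    seed: int = 0,
    spacing: float = 3.8,
) -> Trajectory:
    """Cα-only trajectory whose residue *i* oscillates sinusoidally with peak
    amplitude ``amplitudes[i]`` about a fixed chain, giving an exact expected
    RMSF of ``a/√2`` per residue (full oscillation periods are sampled).

    Fluctuation axes and phases are drawn from the seed, so identical seeds
    give identical trajectories.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(amp)) or np.any(amp < 0):
        raise ValidationError("amplitudes must be finite and non-negative")
    n_res = amp.size
    rng = np.random.default_rng(seed)
    base = np.zeros((n_res, 3))
    base[:, 0] = spacing * np.arange(n_res)
    axes = rng.normal(size=(n_res, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=n_res)
    t = np.arange(n_frames)
    wave = np.sin(2 * np.pi * n_cycles * t[:, None] / n_frames + phases[None, :])
    coords = base[None, :, :] + (amp[None, :, None] * wave[:, :, None]) * axes[None, :, :]
    return Trajectory(
        coords=coords,
        resids=np.arange(1, n_res + 1),
        names=["CA"] * n_res,
    )


def make_region_pattern(
    n_residues: int = 200,
    n_rigidified: int = 3,
    n_flexibilized: int = 5,
    base_amp: float = 0.5,
    delta_amp: float = 0.4,
    region_len: int = 12,
    seed: int = 0,
):
    """Two amplitude profiles plus regions emulating the published pattern:
    a mutant whose terminal regions rigidify while catalytic-pocket regions
    gain flexibility.

    Returns ``(amp_wild, amp_mutant, regions)`` where the first
    ``n_rigidified`` regions have lower mutant amplitude and the remaining
    ``n_flexibilized`` higher.
    """
    from .flex import Region

    total = n_rigidified + n_flexibilized
    gap = n_residues // total
    if gap < region_len + 2:
        raise ValidationError("n_residues too small for the requested regions")
    amp_wild = np.full(n_residues, base_amp)
    amp_mut = np.full(n_residues, base_amp)
    regions = []
    for k in range(total):
        start = k * gap + 1
        end = start + region_len - 1
        sl = slice(start - 1, end)
        if k < n_rigidified:
            amp_mut[sl] = base_amp - delta_amp
            label = f"terminus_{k + 1}"
        else:
            amp_mut[sl] = base_amp + delta_amp
            label = f"pocket_{k - n_rigidified + 1}"
        regions.append(Region(label, start, end))
    return amp_wild, amp_mut, regions


# --------------------------------------------------------------------------
# Arrhenius rate tables

def make_rates(
    a: float = 1.0e7,
    ea_kj_mol: float = 39.4,
    temps_c: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rate table v(T) = A·exp(−Ea/(R·T)) over 0–35 °C in 5° steps by default,
    with optional Gaussian noise on ln(v)."""
    if ea_kj_mol <= 0:
        raise ValidationError("Ea must be positive")
    temps = np.arange(0.0, 36.0, 5.0) if temps_c is None else np.asarray(temps_c, float)
    t_kelvin = temps + KELVIN_OFFSET
    ln_v = np.log(a) - ea_kj_mol * 1000.0 / (GAS_CONSTANT * t_kelvin)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ln_v = ln_v + rng.normal(0.0, noise_sd, size=ln_v.size)
    return pd.DataFrame({"temperature": temps, "velocity": np.exp(ln_v)})


# --------------------------------------------------------------------------
# packaged worked example (published bridge tables + stand-in alignment)

TARGET_ID = "InuAGN25"
MUTANT_ID = "Mut8S"
HOMOLOG_IDS = ("BfrA-Tm", "Inu-Aa", "InuA-Gs")

#: Published strong-salt-bridge lists (3.2 Å cutoff) for the four enzymes and
#: the designed mutant, in one-letter + report-number notation.
TABLE1_BRIDGES = {
    "BfrA-Tm": (
        "D52–K27, D53–H56, D67–K118, D68–H71, D201–R196, D234–R281, D318–R304, "
        "D386–H7, E69–R37, E103–R137, E130–K156, E190–R137, E219–K200, E286–K291, "
        "E297–R250, E308–K305, E325–R302, E325–R382, E329–R380, E344–R337, "
        "E367–R262, E367–R369, E391–R281, E391–H7"
    ),
    "Inu-Aa": (
        "D23–R486, D77–H80, D219–K200, D292–K257, D311–R450, D485–H31, E82–K84, "
        "E99–R91, E197–K247, E241–R188, E283–K257, E490–R354, E490–H31"
    ),
    "InuA-Gs": (
        "D149–R151, D199–R230, D253–K219, D267–R404, D394–K375, D437–H14, "
        "E34–R129, E203–R151, E209–K218, E364–R433, E442–R312, E442–H14"
    ),
    "InuAGN25": (
        "D87–H90, D176–R178, D289–R419, D383–R381, D453–H41, E217–K214, "
        "E230–R178, E458–R331, E458–H41"
    ),
    "Mut8S": (
        "D59–R156, D87–H90, D176–R178, D289–R419, D301–K243, D383–R381, "
        "D453–H41, E61–R156, E217–K214, E230–R178, E268–K244, E458–R331, E458–H41"
    ),
}

#: The eight designed substitutions, position → (wild residue, mutant residue).
MUTATIONS = {
    61: ("N", "E"),
    156: ("K", "R"),
    236: ("P", "E"),
    243: ("T", "K"),
    268: ("D", "E"),
    277: ("T", "D"),
    390: ("Q", "K"),
    409: ("R", "D"),
}

#: Mature-protein numbering of the target starts at 23 (22-residue signal
#: peptide removed); the homolog tables count from 1.
SEQUENCE_STARTS = {"InuAGN25": 23, "BfrA-Tm": 1, "Inu-Aa": 1, "InuA-Gs": 1}

_TARGET_RANGE = (23, 480)
_HOMOLOG_LENGTHS = {"BfrA-Tm": 400, "Inu-Aa": 500, "InuA-Gs": 450}

# Residue-correspondence anchors (homolog position → target position) encoding
# the published column relationships: the five hotspot columns (homolog bridge
# residues over target 61/236/268/277/409), the coordinating partner columns
# (156/243/390), and the partner columns where the target already carries the
# required charge.
_ANCHORS = {
    "BfrA-Tm": {27: 35, 52: 61, 196: 178, 200: 214, 201: 236, 219: 268, 329: 409, 380: 419},
    "Inu-Aa": {197: 236, 247: 250, 257: 255, 283: 268, 292: 277, 311: 409, 450: 419},
    "InuA-Gs": {34: 61, 129: 156, 209: 236, 218: 243, 219: 246, 253: 277, 375: 390, 394: 409},
}

# Target residues that carry meaning: its own bridge residues, the wild-type
# residues at the eight designed positions, the pre-existing partners of the
# mutant's gained bridges (D59, K244, D301), and lysines at partner columns
# that already satisfy the homolog bridges.
_TARGET_RESIDUES = {
    35: "K", 41: "H", 59: "D", 61: "N", 87: "D", 90: "H", 156: "K", 176: "D",
    178: "R", 214: "K", 217: "E", 230: "E", 236: "P", 243: "T", 244: "K",
    246: "K", 250: "K", 255: "K", 268: "D", 277: "T", 289: "D", 301: "D",
    331: "R", 381: "R", 383: "D", 390: "Q", 409: "R", 419: "R", 453: "D",
    458: "E",
}

_BACKGROUND_LETTERS = "AGSTVLIPFNQYWMC"
_ALIGNMENT_SEED = 74123  # fixed: the frozen data file is this builder's output
_DATA_FILE = "worked_example_alignment.fasta"


def _bridge_residue_letters(enzyme_id: str) -> dict[int, str]:
    letters: dict[int, str] = {}
    for bridge in parse_bridge_list(TABLE1_BRIDGES[enzyme_id], enzyme_id):
        for label in bridge.pair:
            code, pos = split_label(label)
            letters[pos] = code
    return letters


def build_worked_example_alignment() -> str:
    """Generate the synthetic stand-in alignment of the four enzymes.

    Layout: one backbone column per target position 23–480 carrying the
    anchored homolog residues; every unanchored homolog residue occupies its
    own single-sequence insertion column, placed to keep all position→column
    maps strictly monotonic.  Background residues are drawn deterministically
    from uncharged letters so that only the deliberately placed charges carry
    signal.
    """
    rng = np.random.default_rng(_ALIGNMENT_SEED)

    def background() -> str:
        return _BACKGROUND_LETTERS[rng.integers(0, len(_BACKGROUND_LETTERS))]

    t_lo, t_hi = _TARGET_RANGE
    target_seq = {p: _TARGET_RESIDUES.get(p) or background() for p in range(t_lo, t_hi + 1)}

    homolog_seq: dict[str, dict[int, str]] = {}
    for hid, length in _HOMOLOG_LENGTHS.items():
        letters = _bridge_residue_letters(hid)
        homolog_seq[hid] = {p: letters.get(p) or background() for p in range(1, length + 1)}

    placed: dict[str, dict[int, int]] = {}   # hid -> {target pos: homolog pos}
    insertions: dict[str, dict[int | None, list[int]]] = {}
    for hid, length in _HOMOLOG_LENGTHS.items():
        anchors = _ANCHORS[hid]
        placed[hid] = {t: p for p, t in anchors.items()}
        pend: dict[int | None, list[int]] = {}
        anchor_pos = sorted(anchors)
        for p in range(1, length + 1):
            if p in anchors:
                continue
            nxt = next((q for q in anchor_pos if q > p), None)
            key = anchors[nxt] if nxt is not None else None
            pend.setdefault(key, []).append(p)
        insertions[hid] = pend

    ids = [TARGET_ID, *_HOMOLOG_LENGTHS]
    rows: dict[str, list[str]] = {i: [] for i in ids}

    def emit_insertion(hid: str, p: int) -> None:
        for i in ids:
            rows[i].append(homolog_seq[hid][p] if i == hid else "-")

    for t in range(t_lo, t_hi + 1):
        for hid in _HOMOLOG_LENGTHS:
            for p in insertions[hid].get(t, []):
                emit_insertion(hid, p)
        rows[TARGET_ID].append(target_seq[t])
        for hid in _HOMOLOG_LENGTHS:
            p = placed[hid].get(t)
            rows[hid].append(homolog_seq[hid][p] if p is not None else "-")
    for hid in _HOMOLOG_LENGTHS:
        for p in insertions[hid].get(None, []):
            emit_insertion(hid, p)

    out = []
    for i in ids:
        out.append(f">{i} synthetic stand-in alignment row (worked example)")
        seq = "".join(rows[i])
        out.extend(seq[k : k + 60] for k in range(0, len(seq), 60))
    return "\n".join(out) + "\n"


@dataclass
class WorkedExample:
    """Published bridge tables, the packaged alignment, and expected outputs."""

    bridge_sets: dict[str, BridgeSet]
    alignment: AlignmentColumnMap
    target_id: str
    mutant_id: str
    mutations: dict[int, tuple[str, str]]
    expected: dict

    def design_inputs(self) -> dict[str, BridgeSet]:
        """Bridge sets of the four aligned enzymes (target + homologs)."""
        return {i: self.bridge_sets[i] for i in (self.target_id, *HOMOLOG_IDS)}


def packaged_worked_example() -> WorkedExample:
    """Load the frozen worked example shipped with the package."""
    data = importlib.resources.files("bridgeforge") / "data" / _DATA_FILE
    from .design import read_alignment

    with importlib.resources.as_file(data) as path:
        alignment = read_alignment(path, "aligned-fasta", starts=SEQUENCE_STARTS)
    bridge_sets = {
        eid: parse_bridge_list(text, eid) for eid, text in TABLE1_BRIDGES.items()
    }
    expected = {
        "counts": {"BfrA-Tm": 24, "Inu-Aa": 13, "InuA-Gs": 12, "InuAGN25": 9, "Mut8S": 13},
        "gained": {("D59", "R156"), ("E61", "R156"), ("D301", "K243"), ("E268", "K244")},
        "n_hotspots": 5,
        "proposal_positions": set(MUTATIONS),
        "proposals": {f"{w}{p}{m}" for p, (w, m) in MUTATIONS.items()},
        "n_networks_mut8s": 3,
        "nterm_network_members": {"D59", "E61", "R156"},
        "three_edge_network_members": {"D453", "H41", "E458", "R331"},
    }
    return WorkedExample(
        bridge_sets=bridge_sets,
        alignment=alignment,
        target_id=TARGET_ID,
        mutant_id=MUTANT_ID,
        mutations=dict(MUTATIONS),
        expected=expected,
    )
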