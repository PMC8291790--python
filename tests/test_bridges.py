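"""Salt-bridge detection, list parsing, networks, diffs — with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from bridgeforge.bridges import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    BridgeSet,
    SaltBridge,
    build_networks,
    check_network_preserved,
    detect_bridges,
    diff_bridge_sets,
    parse_bridge_list,
)
from bridgeforge.errors import ParseError, ValidationError
from bridgeforge.fixtures import TABLE1_BRIDGES, make_structure
from bridgeforge.structure import Atom, Residue, Structure


def _pair_structure(nz_x):
    """ASP OD1 at the origin, LYS NZ on the x-axis at ``nz_x`` Å."""
    return Structure(
        id="pair",
        residues=[
            Residue("A", 1, "ASP", [Atom("OD1", "O", [0.0, 0.0, 0.0])]),
            Residue("A", 2, "LYS", [Atom("NZ", "N", [nz_x, 0.0, 0.0])]),
        ],
    )


def test_detect_pair_inside_and_outside_cutoff():
    hit = detect_bridges(_pair_structure(3.0))
    assert len(hit) == 1
    (bridge,) = hit.bridges
    assert bridge.pair == ("D1", "K2") and bridge.min_distance == pytest.approx(3.0)
    assert len(detect_bridges(_pair_structure(3.3))) == 0


def test_his_flag_and_interchain_flag():
    st_ = Structure(
        id="s",
        residues=[
            Residue("A", 1, "GLU", [Atom("OE1", "O", [0, 0, 0])]),
            Residue("B", 2, "HIS", [Atom("NE2", "N", [2.8, 0, 0])]),
        ],
    )
    assert len(detect_bridges(st_)) == 0  # different chains
    assert len(detect_bridges(st_, interchain=True)) == 1
    assert len(detect_bridges(st_, interchain=True, include_his=False)) == 0


def _random_charged_structure(rng, n_res=30, box=14.0):
    """Residues with full charged groups thrown into a small box (many contacts)."""
    kinds = ["ASP", "GLU", "LYS", "ARG", "HIS", "ALA"]
    atoms_of = {**ACIDIC_ATOMS, **BASIC_ATOMS}
    residues = []
    for i in range(1, n_res + 1):
        kind = kinds[rng.integers(0, len(kinds))]
        center = rng.uniform(0, box, 3)
        names = atoms_of.get(kind, ())
        atom_list = [Atom("CA", "C", center)]
        for name in names:
            atom_list.append(Atom(name, name[0], center + rng.normal(0, 1.0, 3)))
        residues.append(Residue("A", i, kind, atom_list))
    return Structure(id="rand", residues=residues)


def _brute_force_detect(structure, cutoff=3.2, include_his=True):
    basic = dict(BASIC_ATOMS)
    if not include_his:
        basic.pop("HIS")
    found = {}
    for ra in structure:
        for rb in structure:
            if ra.chain_id != rb.chain_id or ra.seq_number == rb.seq_number:
                continue
            a_names = ACIDIC_ATOMS.get(ra.res_name, ())
            b_names = basic.get(rb.res_name, ())
            dists = [
                np.linalg.norm(x.coords - y.coords)
                for x in ra.atoms if x.name in a_names
                for y in rb.atoms if y.name in b_names
            ]
            if dists and min(dists) <= cutoff:
                found[(ra.label, rb.label)] = min(dists)
    return found


@pytest.mark.parametrize("seed", range(8))
def test_detection_equals_all_pairs_scan(seed):
    rng = np.random.default_rng(seed)
    st_ = _random_charged_structure(rng)
    got = {b.pair: b.min_distance for b in detect_bridges(st_).bridges}
    expected = _brute_force_detect(st_)
    assert got.keys() == expected.keys()
    for pair, d in expected.items():
        assert got[pair] == pytest.approx(d)


@given(st.integers(0, 10_000))
def test_detection_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    st_ = _random_charged_structure(rng, n_res=15)
    rot = Rotation.random(random_state=int(seed)).as_matrix()
    shift = rng.uniform(-50, 50, 3)
    moved = Structure(
        id="moved",
        residues=[
            Residue(r.chain_id, r.seq_number, r.res_name,
                    [Atom(a.name, a.element, rot @ a.coords + shift) for a in r.atoms])
            for r in st_
        ],
    )
    assert detect_bridges(st_).labels() == detect_bridges(moved).labels()


@given(st.integers(0, 10_000))
def test_detection_monotonic_in_cutoff(seed):
    rng = np.random.default_rng(seed)
    st_ = _random_charged_structure(rng, n_res=15)
    c1, c2 = sorted(rng.uniform(1.0, 6.0, 2))
    assert detect_bridges(st_, cutoff=c1).labels() <= detect_bridges(st_, cutoff=c2).labels()


def test_missing_sidechain_atoms_skipped_with_warning(caplog):
    st_ = Structure(
        id="trunc",
        residues=[
            Residue("A", 1, "ASP", [Atom("CA", "C", [0, 0, 0])]),  # no carboxylate
            Residue("A", 2, "LYS", [Atom("NZ", "N", [3.0, 0, 0])]),
        ],
    )
    with caplog.at_level("WARNING"):
        assert len(detect_bridges(st_)) == 0
    assert "skipped" in caplog.text


# -- printed-list parsing ---------------------------------------------------

def test_parse_simple_pair_and_empty():
    assert len(parse_bridge_list("D87–H90, D176–R178")) == 2
    assert len(parse_bridge_list("")) == 0


@pytest.mark.parametrize(
    "enzyme,count",
    [("BfrA-Tm", 24), ("Inu-Aa", 13), ("InuA-Gs", 12), ("InuAGN25", 9), ("Mut8S", 13)],
)
def test_parse_published_rows_reproduce_counts(enzyme, count):
    assert len(parse_bridge_list(TABLE1_BRIDGES[enzyme], enzyme)) == count


def test_parse_strips_markup_and_normalizes_orientation():
    bs = parse_bridge_list("**D52–K27**^1^, R156-D59")
    assert bs.labels() == {("D52", "K27"), ("D59", "R156")}


def test_parse_rejects_malformed_and_same_class_tokens():
    with pytest.raises(ParseError, match="D52=K27"):
        parse_bridge_list("D52=K27")
    with pytest.raises(ValidationError):
        parse_bridge_list("D52–E27")
    with pytest.raises(ValidationError):
        parse_bridge_list("K52–R27")


def test_bridge_set_tsv_round_trip():
    bs = parse_bridge_list(TABLE1_BRIDGES["InuAGN25"], "InuAGN25")
    again = BridgeSet.from_tsv(bs.to_tsv(), "InuAGN25")
    assert again.labels() == bs.labels()


# -- networks ---------------------------------------------------------------

def test_mut8s_networks(worked_example):
    nets = build_networks(worked_example.bridge_sets["Mut8S"])
    by_members = {frozenset(n.members): n for n in nets}
    nterm = by_members[frozenset({"D59", "E61", "R156"})]
    assert len(nterm.edges) == 2
    big = by_members[frozenset({"D453", "H41", "E458", "R331"})]
    assert {b.pair for b in big.edges} == {
        ("D453", "H41"), ("E458", "H41"), ("E458", "R331")
    }
    # largest (by edges) first
    assert nets[0] is big


def test_disjoint_single_bridges_form_no_network():
    bs = parse_bridge_list("D1–K2, D3–K4, E5–R6")
    assert build_networks(bs) == []


def _uf_components(bridges):
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in bridges:
        ra, rb = find(b.acidic), find(b.basic)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for b in bridges:
        comps.setdefault(find(b.acidic), set()).add(b)
    return {frozenset({e.acidic for e in es} | {e.basic for e in es}): es
            for es in comps.values()}


@given(st.integers(0, 10_000))
def test_networks_match_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    bridges = {
        SaltBridge(f"D{rng.integers(1, 12)}", f"K{rng.integers(20, 32)}")
        for _ in range(rng.integers(1, 15))
    }
    bs = BridgeSet("rand", bridges)
    expected = {
        members: es for members, es in _uf_components(bridges).items() if len(es) >= 2
    }
    got = {frozenset(n.members): n.edges for n in build_networks(bs)}
    assert got == expected
    # components partition the bridge-participating residues
    all_members = [m for n in build_networks(bs) for m in n.members]
    assert len(all_members) == len(set(all_members))


# -- diffs and preservation -------------------------------------------------

def test_published_diff_gained_four_lost_none(worked_example):
    d = diff_bridge_sets(
        worked_example.bridge_sets["InuAGN25"],
        worked_example.bridge_sets["Mut8S"],
        worked_example.mutations,
    )
    assert {b.pair for b in d.gained} == worked_example.expected["gained"]
    assert d.lost == set()


def test_identical_sets_diff_empty(worked_example):
    wt = worked_example.bridge_sets["InuAGN25"]
    d = diff_bridge_sets(wt, wt)
    assert d.gained == set() and d.lost == set()


def test_mutation_aware_matching_retains_renamed_endpoint():
    wild = parse_bridge_list("D10–K20")
    mut = parse_bridge_list("D10–R20")
    plain = diff_bridge_sets(wild, mut)
    assert len(plain.gained) == 1 and len(plain.lost) == 1
    aware = diff_bridge_sets(wild, mut, {20: ("K", "R")})
    assert aware.gained == set() and aware.lost == set()


@given(st.integers(0, 10_000))
def test_diff_matches_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)

    def random_set():
        return BridgeSet("x", {
            SaltBridge(f"E{rng.integers(1, 8)}", f"R{rng.integers(10, 18)}")
            for _ in range(rng.integers(0, 10))
        })

    a, b = random_set(), random_set()
    d = diff_bridge_sets(a, b)
    assert {x.pair for x in d.gained} == b.labels() - a.labels()
    assert {x.pair for x in d.lost} == a.labels() - b.labels()
    assert d.gained.isdisjoint(d.lost)


def test_network_preservation(worked_example):
    wt_nets = build_networks(worked_example.bridge_sets["InuAGN25"])
    flags = check_network_preserved(wt_nets, worked_example.bridge_sets["Mut8S"])
    assert flags == [True] * len(wt_nets)
    big = [n for n in wt_nets if "D453" in n.members]
    missing_one = parse_bridge_list("D453–H41, E458–H41")  # E458–R331 absent
    assert check_network_preserved(big, missing_one) == [False]
    assert check_network_preserved(big, BridgeSet("empty", set())) == [False]
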