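"""Contig-graph conformations, junction references and master selection."""

import itertools

import numpy as np
import pytest

from mitokit.conformation import (
    Contig,
    ContigGraph,
    GraphError,
    Link,
    build_junction_references,
    conformation_pairings,
    enumerate_conformations,
    score_junction_support,
    select_master,
)
from mitokit.genome_io import revcomp
from mitokit.synthetic import _base_probs, _scrubbed, demo_contig_graph, simulate_long_reads


def _seq(seed, n):
    return _scrubbed(np.random.default_rng(seed), n, _base_probs(0.45))


@pytest.fixture(scope="module")
def two_repeat():
    """Four unique contigs + two copy-2 inverted repeats (and the walks)."""
    return demo_contig_graph(seed=3)


def test_single_cycle_gives_one_conformation():
    graph = ContigGraph(
        {c.identifier: c for c in (Contig("a", _seq(1, 800)), Contig("b", _seq(2, 700)),
                                   Contig("c", _seq(3, 600)))},
        [Link("a", "T", "b", "H"), Link("b", "T", "c", "H"), Link("c", "T", "a", "H")],
    )
    confs = enumerate_conformations(graph)
    assert len(confs) == 1
    assert len(confs[0].sequence) == 800 + 700 + 600


def test_disconnected_graph_raises_structural_error():
    graph = ContigGraph(
        {c.identifier: c for c in (Contig("a", _seq(1, 500)), Contig("b", _seq(2, 500)))},
        [Link("a", "T", "a", "H")],  # b unreachable, no links at all
    )
    with pytest.raises(GraphError):
        enumerate_conformations(graph)


def brute_force_closed_walks(graph):
    """Oracle: try every arrangement of contig copies and orientations and
    keep circular walks consistent with the links."""
    slots = []
    for cid, contig in graph.contigs.items():
        slots.extend([cid] * contig.copy_number)
    links = set()
    for ln in graph.links:
        links.add((ln.a, ln.end_a, ln.b, ln.end_b))
        links.add((ln.b, ln.end_b, ln.a, ln.end_a))

    def connected(x, ox, y, oy):
        exit_end = "T" if ox == "+" else "H"
        entry_end = "H" if oy == "+" else "T"
        return (x, exit_end, y, entry_end) in links

    seen = set()
    n = len(slots)
    for perm in set(itertools.permutations(slots)):
        for orients in itertools.product("+-", repeat=n):
            path = list(zip(perm, orients))
            if all(
                connected(*path[i], *path[(i + 1) % n]) for i in range(n)
            ):
                canon = _canon(path)
                seen.add(canon)
    return seen


def _canon(path):
    flip = [(c, "-" if o == "+" else "+") for c, o in reversed(path)]
    variants = []
    for p in (path, flip):
        for i in range(len(p)):
            variants.append(tuple(p[i:] + p[:i]))
    return min(variants)


def test_enumeration_matches_brute_force_oracle():
    # small graph: 3 unique contigs + 1 copy-2 inverted repeat
    contigs = {
        "a": Contig("a", _seq(1, 400)),
        "b": Contig("b", _seq(2, 350)),
        "c": Contig("c", _seq(3, 300)),
        "r": Contig("r", _seq(4, 200), copy_number=2),
    }
    links = [
        Link("a", "T", "r", "H"), Link("r", "T", "b", "H"),
        Link("b", "T", "r", "T"), Link("r", "H", "c", "H"),
        Link("c", "T", "a", "H"),
    ]
    graph = ContigGraph(contigs, links)
    confs = enumerate_conformations(graph)
    assert {c.canonical() for c in confs} == brute_force_closed_walks(graph)


def test_two_repeat_graph_yields_master_plus_two_isomers(two_repeat):
    _, confs = two_repeat
    assert len(confs) == 3
    # flipping one repeat's pairing in any walk yields another listed walk
    graph, _ = two_repeat
    pairings = [
        {rid: conformation_pairings(c, rid) for rid in graph.repeat_contigs()}
        for c in confs
    ]
    for i, j in itertools.combinations(range(3), 2):
        diff = sum(pairings[i][r] != pairings[j][r] for r in pairings[i])
        assert diff >= 1


def test_conformation_contains_each_contig_copy_number_times(two_repeat):
    graph, confs = two_repeat
    for conf in confs:
        for cid, contig in graph.contigs.items():
            fwd = conf.sequence.count(contig.sequence)
            rev = conf.sequence.count(revcomp(contig.sequence))
            assert fwd + rev == contig.copy_number


def test_junction_references_structure(two_repeat):
    graph, _ = two_repeat
    refs = build_junction_references(graph, "r1", flank=200)
    assert len(refs) == 4
    ups = {r.variant[0] for r in refs}
    downs = {r.variant[1] for r in refs}
    assert len(ups) == 2 and len(downs) == 2
    rep_len = len(graph.contigs["r1"].sequence)
    for r in refs:
        assert len(r.sequence) == rep_len + r.up_flank_len + r.down_flank_len
        assert r.up_flank_len == r.down_flank_len == 200


def test_junction_reference_zero_and_truncated_flank():
    contigs = {
        "a": Contig("a", _seq(1, 50)),  # shorter than the requested flank
        "b": Contig("b", _seq(2, 400)),
        "r": Contig("r", _seq(3, 150), copy_number=2),
        "c": Contig("c", _seq(4, 300)),
    }
    links = [
        Link("a", "T", "r", "H"), Link("r", "T", "b", "H"),
        Link("b", "T", "r", "T"), Link("r", "H", "c", "H"),
        Link("c", "T", "a", "H"),
    ]
    graph = ContigGraph(contigs, links)
    bare = build_junction_references(graph, "r", flank=0)
    assert all(ref.sequence == contigs["r"].sequence for ref in bare)
    refs = build_junction_references(graph, "r", flank=120)
    by_up = {ref.variant[0][0]: ref for ref in refs}
    assert by_up["a"].up_flank_len == 50  # truncated to the contig
    assert by_up["a"].sequence[:50] == contigs["a"].sequence[-50:]


def test_error_free_reads_support_only_their_variant(two_repeat):
    graph, confs = two_repeat
    refs = build_junction_references(graph, "r1", flank=200)
    target = refs[0]
    reads = [target.sequence, target.sequence[5:], revcomp(target.sequence)]
    support = score_junction_support(refs, reads, min_identity=80.0, min_hit=500)
    assert support.counts[target.variant] >= 2
    assert sum(v for k, v in support.counts.items() if k != target.variant) == 0


def test_read_shorter_than_min_hit_uncounted(two_repeat):
    graph, _ = two_repeat
    refs = build_junction_references(graph, "r1", flank=200)
    short = refs[0].sequence[:400]
    support = score_junction_support(refs, [short], min_identity=80.0, min_hit=1000)
    assert sum(support.counts.values()) == 0


def test_tied_support_flags_ambiguous(two_repeat):
    graph, confs = two_repeat
    planted = confs[0]
    reads, _ = simulate_long_reads(planted.sequence, coverage=10, length_mean=3500,
                                   error_rate=0.0, seed=1)
    supports = []
    for rid in graph.repeat_contigs():
        refs = build_junction_references(graph, rid, flank=200)
        supports.append(score_junction_support(refs, reads, min_identity=80.0, min_hit=800))
    # zero out one repeat's counts -> tie between its two pairings
    for k in supports[0].counts:
        supports[0].counts[k] = 0
    sel = select_master(graph, supports)
    assert sel.master is None
    assert supports[0].repeat_contig in sel.ambiguous_repeats


def test_single_conformation_graph_master_no_isomers():
    graph = ContigGraph(
        {c.identifier: c for c in (Contig("a", _seq(5, 900)), Contig("b", _seq(6, 800)))},
        [Link("a", "T", "b", "H"), Link("b", "T", "a", "H")],
    )
    sel = select_master(graph, [])
    assert sel.master is not None
    assert sel.isomers == [] and sel.candidates == []


def test_master_recovery_from_simulated_reads(two_repeat):
    graph, confs = two_repeat
    planted = confs[1]
    recovered = 0
    for seed in range(3):
        reads, _ = simulate_long_reads(planted.sequence, coverage=20, length_mean=4000,
                                       error_rate=0.10, seed=seed)
        supports = []
        for rid in graph.repeat_contigs():
            refs = build_junction_references(graph, rid, flank=200)
            supports.append(score_junction_support(refs, reads, min_identity=80.0,
                                                   min_hit=1000))
        sel = select_master(graph, supports)
        if sel.master is not None and sel.master.canonical() == planted.canonical():
            recovered += 1
            assert len(sel.isomers) == 2
    assert recovered == 3
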