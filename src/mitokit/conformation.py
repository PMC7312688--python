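"""Master-circle versus isomer resolution of a contig multigraph.

Plant mitogenomes with large repeats at copy number 2 admit several
circular arrangements: recombination across a repeat flips the segment
between its two copies, so an assembly graph with two independent copy-2
repeat contigs realizes four circular walks — one master conformation,
two single-flip isomers and one double-flip candidate.  Long reads decide
among them: for each repeat contig, four junction references are built
(each upstream flanking context paired with each downstream context around
the repeat template, with a configurable flank length), reads are assigned
to their best-matching reference, and the conformation consistent with the
top-supported pairing at every repeat is selected as the master.

Contig orientation convention: traversing a contig in ``+`` orientation
enters at its head (H) and exits at its tail (T); links join specific ends
of two contigs.  Conformations are deduplicated up to rotation and
reflection (reverse complement of the whole circle).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .genome_io import CircularSequence, revcomp

logger = logging.getLogger(__name__)


class GraphError(ValueError):
    pass


class ConflictError(GraphError):
    """Junction supports cannot be realized by any enumerated conformation."""


@dataclass
class Contig:
    identifier: str
    sequence: str
    copy_number: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.copy_number < 1:
            raise GraphError(f"contig {self.identifier} copy_number < 1")


@dataclass(frozen=True)
class Link:
    a: str
    end_a: str  # 'H' | 'T'
    b: str
    end_b: str
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.end_a not in ("H", "T") or self.end_b not in ("H", "T"):
            raise GraphError(f"link ends must be H or T: {self}")


@dataclass
class ContigGraph:
    contigs: dict[str, Contig]
    links: list[Link]

    def __post_init__(self) -> None:
        for ln in self.links:
            for cid in (ln.a, ln.b):
                if cid not in self.contigs:
                    raise GraphError(f"link references unknown contig {cid}")

    def incident(self, contig_id: str, end: str) -> list[tuple[str, str, int]]:
        """(other contig, other end, overlap) for each link at (contig_id, end)."""
        out = []
        for ln in self.links:
            if ln.a == contig_id and ln.end_a == end:
                out.append((ln.b, ln.end_b, ln.overlap))
            if ln.b == contig_id and ln.end_b == end:
                out.append((ln.a, ln.end_a, ln.overlap))
        return out

    def repeat_contigs(self) -> list[str]:
        return sorted(c.identifier for c in self.contigs.values() if c.copy_number >= 2)


def read_contig_graph(contigs_tsv, links_tsv, fasta=None) -> ContigGraph:
    """Read the TSV graph format: contigs.tsv (id, copy_number, sequence) and
    links.tsv (idA, endA, idB, endB[, overlap]).  Sequences may instead be
    supplied in a FASTA keyed by contig id."""
    cdf = pd.read_csv(contigs_tsv, sep="\t", dtype=str)
    seqs = {}
    if fasta is not None:
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    contigs = {}
    for row in cdf.itertuples(index=False):
        cid = str(row.id)
        seq = seqs.get(cid) or (str(row.sequence) if hasattr(row, "sequence") else "")
        if not seq or seq == "nan":
            raise GraphError(f"no sequence for contig {cid}")
        contigs[cid] = Contig(cid, seq, int(row.copy_number))
    ldf = pd.read_csv(links_tsv, sep="\t", dtype=str)
    links = [
        Link(
            str(r.idA),
            str(r.endA),
            str(r.idB),
            str(r.endB),
            int(getattr(r, "overlap", 0) or 0),
        )
        for r in ldf.itertuples(index=False)
    ]
    return ContigGraph(contigs, links)


# ---------------------------------------------------------------------------
# conformation enumeration
# ---------------------------------------------------------------------------

@dataclass
class Conformation:
    path: list[tuple[str, str]]  # (contig id, orientation '+'/'-')
    label: str = "candidate"
    sequence: str = ""

    def canonical(self) -> tuple:
        return _canonical_path(self.path)


def _flip(path):
    return [(cid, "-" if o == "+" else "+") for cid, o in reversed(path)]


def _canonical_path(path) -> tuple:
    variants = []
    for p in (path, _flip(path)):
        for i in range(len(p)):
            variants.append(tuple(p[i:] + p[:i]))
    return min(variants)


def _entry_exit(orientation: str) -> tuple[str, str]:
    return ("H", "T") if orientation == "+" else ("T", "H")


def enumerate_conformations(graph: ContigGraph) -> list[Conformation]:
    """All distinct circular walks using every contig its copy_number times,
    deduplicated up to rotation and reflection."""
    ids = sorted(graph.contigs)
    remaining = {cid: graph.contigs[cid].copy_number for cid in ids}
    total = sum(remaining.values())
    start = ids[0]
    found: dict[tuple, Conformation] = {}

    def dfs(path: list[tuple[str, str]]):
        cur, orient = path[-1]
        _, exit_end = _entry_exit(orient)
        if len(path) == total:
            # closed if a link returns to the start contig's entry end
            s_id, s_orient = path[0]
            s_entry, _ = _entry_exit(s_orient)
            for other, other_end, _ov in graph.incident(cur, exit_end):
                if other == s_id and other_end == s_entry:
                    conf = Conformation(path=list(path))
                    found.setdefault(conf.canonical(), conf)
                    break
            return
        for other, other_end, _ov in graph.incident(cur, exit_end):
            if remaining[other] == 0:
                continue
            orient_next = "+" if other_end == "H" else "-"
            remaining[other] -= 1
            path.append((other, orient_next))
            dfs(path)
            path.pop()
            remaining[other] += 1

    remaining[start] -= 1
    dfs([(start, "+")])
    remaining[start] += 1
    if not found:
        degrees = {
            cid: {
                "H": len(graph.incident(cid, "H")),
                "T": len(graph.incident(cid, "T")),
                "copies": graph.contigs[cid].copy_number,
            }
            for cid in ids
        }
        bad = [cid for cid, d in degrees.items() if d["H"] == 0 or d["T"] == 0]
        raise GraphError(
            f"no closed walk uses every contig its copy_number times; "
            f"degree-deficient contigs: {bad or 'none'}; degrees: {degrees}"
        )
    confs = list(found.values())
    confs.sort(key=lambda c: c.canonical())
    for c in confs:
        c.sequence = realize_sequence(graph, c)
    return confs


def _link_overlap(graph: ContigGraph, a: str, end_a: str, b: str, end_b: str) -> int:
    for ln in graph.links:
        if (ln.a, ln.end_a, ln.b, ln.end_b) == (a, end_a, b, end_b):
            return ln.overlap
        if (ln.b, ln.end_b, ln.a, ln.end_a) == (a, end_a, b, end_b):
            return ln.overlap
    return 0


def realize_sequence(graph: ContigGraph, conf: Conformation) -> str:
    """Concatenate oriented contig sequences around the circle, trimming link
    overlaps (default 0, blunt joins)."""
    parts = []
    n = len(conf.path)
    for i, (cid, orient) in enumerate(conf.path):
        seq = graph.contigs[cid].sequence
        if orient == "-":
            seq = revcomp(seq)
        nxt_id, nxt_orient = conf.path[(i + 1) % n]
        _, exit_end = _entry_exit(orient)
        nxt_entry, _ = _entry_exit(nxt_orient)
        ov = _link_overlap(graph, cid, exit_end, nxt_id, nxt_entry)
        parts.append(seq[: len(seq) - ov] if ov else seq)
    return "".join(parts)


# ---------------------------------------------------------------------------
# junction references and read support
# ---------------------------------------------------------------------------

@dataclass
class JunctionReference:
    repeat_contig: str
    variant: tuple[tuple[str, str], tuple[str, str]]  # ((up id, up end), (down id, down end))
    sequence: str
    up_flank_len: int
    down_flank_len: int


@dataclass
class JunctionSupport:
    repeat_contig: str
    counts: dict[tuple, int] = field(default_factory=dict)


def _flank_into_head(graph: ContigGraph, partner: str, partner_end: str, flank: int) -> str:
    """Sequence of `partner` (last `flank` bp) oriented to flow into the repeat's head."""
    seq = graph.contigs[partner].sequence
    if partner_end == "T":  # partner traversed '+', its tail abuts the repeat head
        return seq[-flank:] if flank else ""
    return revcomp(seq[:flank]) if flank else ""


def _flank_from_tail(graph: ContigGraph, partner: str, partner_end: str, flank: int) -> str:
    """Sequence of `partner` (first `flank` bp) as it continues from the repeat's tail."""
    seq = graph.contigs[partner].sequence
    if partner_end == "H":  # partner traversed '+', entered at its head
        return seq[:flank] if flank else ""
    return revcomp(seq[-flank:]) if flank else ""


def build_junction_references(
    graph: ContigGraph, repeat_id: str, flank: int = 200
) -> list[JunctionReference]:
    """The four flank-pairing references around a copy-2 repeat contig.

    Each upstream context at the repeat's head is paired with each
    downstream context at its tail; flanks are truncated to the flanking
    contig's length when shorter than requested.
    """
    contig = graph.contigs.get(repeat_id)
    if contig is None:
        raise GraphError(f"unknown contig {repeat_id}")
    ups = sorted(set((p, e) for p, e, _ in graph.incident(repeat_id, "H")))
    downs = sorted(set((p, e) for p, e, _ in graph.incident(repeat_id, "T")))
    if len(ups) < 2 or len(downs) < 2:
        raise GraphError(
            f"repeat {repeat_id} needs two flanking contexts on each side "
            f"(found {len(ups)} upstream, {len(downs)} downstream)"
        )
    refs = []
    for up in ups:
        for down in downs:
            up_len = min(flank, len(graph.contigs[up[0]].sequence))
            down_len = min(flank, len(graph.contigs[down[0]].sequence))
            seq = (
                _flank_into_head(graph, up[0], up[1], up_len)
                + contig.sequence
                + _flank_from_tail(graph, down[0], down[1], down_len)
            )
            refs.append(
                JunctionReference(
                    repeat_contig=repeat_id,
                    variant=(up, down),
                    sequence=seq,
                    up_flank_len=up_len,
                    down_flank_len=down_len,
                )
            )
    return refs


def _best_hit(read: str, ref: JunctionReference, min_identity: float, min_hit: int):
    """Best (identity, hit_len) of read vs reference requiring the alignment
    to span into both flanks; None if no qualifying hit."""
    margin = 10  # bases the alignment must reach into each flank
    ref_seq = ref.sequence
    ref_len = len(ref_seq)
    best = None
    for q in (read, revcomp(read)):
        # whole reference contained in the read
        if len(q) >= ref_len:
            r = edlib.align(ref_seq, q, mode="HW", task="distance")
            if r["editDistance"] >= 0:
                ident = 1.0 - r["editDistance"] / ref_len
                if ident * 100 >= min_identity and ref_len >= min_hit:
                    cand = (ident, ref_len)
                    if best is None or cand > best:
                        best = cand
        # read contained in the reference, spanning both junctions
        r = edlib.align(q, ref_seq, mode="HW", task="locations")
        if r["editDistance"] >= 0 and r["locations"]:
            s, e = r["locations"][0]
            hit_len = e - s + 1
            spans = (
                s <= max(ref.up_flank_len - margin, 0)
                and e >= ref_len - max(ref.down_flank_len - margin, 0) - 1
            ) if (ref.up_flank_len and ref.down_flank_len) else True
            ident = 1.0 - r["editDistance"] / max(hit_len, 1)
            if spans and ident * 100 >= min_identity and hit_len >= min_hit:
                cand = (ident, hit_len)
                if best is None or cand > best:
                    best = cand
    return best


def score_junction_support(
    references: list[JunctionReference],
    reads: list[str],
    min_identity: float = 80.0,
    min_hit: int = 3000,
) -> JunctionSupport:
    """Assign each read to its best-matching junction reference.

    A read counts for a variant only if its best qualifying hit (identity
    and hit-length thresholds, spanning into both flanks) is strictly
    better than on any other variant; ambiguous reads are uncounted.
    """
    if not references:
        raise GraphError("no junction references given")
    repeat = references[0].repeat_contig
    counts = {ref.variant: 0 for ref in references}
    for read in reads:
        scored = []
        for ref in references:
            hit = _best_hit(read.upper(), ref, min_identity, min_hit)
            if hit is not None:
                scored.append((hit, ref.variant))
        if not scored:
            continue
        scored.sort(reverse=True)
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            continue  # ambiguous between variants
        counts[scored[0][1]] += 1
    return JunctionSupport(repeat_contig=repeat, counts=counts)


# ---------------------------------------------------------------------------
# master selection
# ---------------------------------------------------------------------------

@dataclass
class MasterSelection:
    master: Conformation | None
    isomers: list[Conformation]
    candidates: list[Conformation]
    ambiguous_repeats: list[str]
    chosen_pairings: dict[str, frozenset]


def conformation_pairings(conf: Conformation, repeat_id: str) -> frozenset:
    """The set of (upstream, downstream) context pairs a conformation uses
    for a given repeat contig."""
    pairs = set()
    n = len(conf.path)
    for i, (cid, orient) in enumerate(conf.path):
        if cid != repeat_id:
            continue
        prev_id, prev_or = conf.path[(i - 1) % n]
        nxt_id, nxt_or = conf.path[(i + 1) % n]
        _, prev_exit = _entry_exit(prev_or)
        nxt_entry, _ = _entry_exit(nxt_or)
        if orient == "+":
            up = (prev_id, prev_exit)
            down = (nxt_id, nxt_entry)
        else:
            # traversed in reverse: successor attaches at the head, predecessor at the tail
            up = (nxt_id, nxt_entry)
            down = (prev_id, prev_exit)
        pairs.add((up, down))
    return frozenset(pairs)


def select_master(
    graph: ContigGraph, supports: list[JunctionSupport]
) -> MasterSelection:
    """Pick the conformation realizing the top-supported pairing at every
    copy-2 repeat; conformations one flip away are isomers.

    With upstream contexts {A, B} and downstream {C, D}, a conformation
    pairs them either (A·C, B·D) or (A·D, B·C); the pairing with the larger
    total read support wins.  Ties are flagged ambiguous and no master is
    named.  If the winning pairings of different repeats are jointly
    unrealizable a ConflictError lists them.
    """
    confs = enumerate_conformations(graph)
    by_repeat = {s.repeat_contig: s for s in supports}
    repeats = graph.repeat_contigs()
    missing = [r for r in repeats if r not in by_repeat]
    if missing:
        raise GraphError(f"missing junction support for repeats: {missing}")

    chosen: dict[str, frozenset] = {}
    ambiguous: list[str] = []
    for rid in repeats:
        support = by_repeat[rid]
        pairings = sorted({conformation_pairings(c, rid) for c in confs})
        scored = [
            (sum(support.counts.get(pair, 0) for pair in pairing), pairing)
            for pairing in pairings
        ]
        scored.sort(key=lambda t: -t[0])
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            ambiguous.append(rid)
        else:
            chosen[rid] = scored[0][1]

    if ambiguous:
        return MasterSelection(None, [], confs, ambiguous, chosen)

    def matches(conf: Conformation) -> int:
        return sum(conformation_pairings(conf, rid) == chosen[rid] for rid in repeats)

    masters = [c for c in confs if matches(c) == len(repeats)]
    if not masters and repeats:
        raise ConflictError(
            f"no conformation realizes all top pairings {chosen}; "
            f"supports may be contradictory"
        )
    master = masters[0] if repeats else confs[0]
    master.label = "master"
    isomers, candidates = [], []
    for c in confs:
        if c is master:
            continue
        if repeats and matches(c) == len(repeats) - 1:
            c.label = "isomer"
            isomers.append(c)
        else:
            c.label = "candidate"
            candidates.append(c)
    return MasterSelection(master, isomers, candidates, [], chosen)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_conformations_fasta(selection: MasterSelection, path) -> None:
    ordered = ([selection.master] if selection.master else []) + selection.isomers + selection.candidates
    with open(path, "w") as fh:
        for i, conf in enumerate(ordered):
            name = f"{conf.label}_{i}" if conf.label != "master" else "master"
            fh.write(f">{name} path={';'.join(f'{c}{o}' for c, o in conf.path)}\n")
            for j in range(0, len(conf.sequence), 70):
                fh.write(conf.sequence[j : j + 70] + "\n")


def write_supports_tsv(supports: list[JunctionSupport], path) -> None:
    rows = []
    for s in supports:
        for variant, count in sorted(s.counts.items()):
            (u, ue), (d, de) = variant
            rows.append(
                {
                    "repeat": s.repeat_contig,
                    "variant": f"{u}.{ue}|{d}.{de}",
                    "read_count": count,
                }
            )
    pd.DataFrame(rows, columns=["repeat", "variant", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


def write_decision_json(selection: MasterSelection, path) -> None:
    payload = {
        "master_path": selection.master.path if selection.master else None,
        "n_isomers": len(selection.isomers),
        "n_candidates": len(selection.candidates),
        "ambiguous_repeats": selection.ambiguous_repeats,
        "chosen_pairings": {
            rid: sorted([list(map(list, pair)) for pair in pairing])
            for rid, pairing in selection.chosen_pairings.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
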