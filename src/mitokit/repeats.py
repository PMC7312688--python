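"""Repeat census of a circular genome: SSRs, tandem repeats, dispersed repeats.

Three repeat classes are detected the way organelle-genome surveys report
them:

* **SSRs** — perfect runs of a 1–6 bp motif above a per-motif-size count
  threshold (defaults 8, 4, 4, 3, 3, 3 for mono..hexa), reported at their
  minimal period so a dinucleotide array is never double-reported as two
  mononucleotide runs.
* **Tandem repeats** — adjacent repetition of a longer unit (>= 7 bp by
  default), at least two copies with a possibly fractional trailing copy,
  reported once at the smallest period of the array.
* **Dispersed repeats** — pairs of similar blocks (>= 30 bp, identity
  > 80%) at distant loci in direct or inverted orientation, found by a
  genome-vs-self ``blastn`` search under unit match/mismatch scoring
  (+1/−3, gap open/extend 3/3, word size 7, E < 1), with self-diagonal
  hits removed, symmetric duplicates collapsed, and overlapping hit pairs
  merged into single repeat units.

Circular genomes are scanned with a virtual overhang for SSR/tandem
detection so origin-spanning arrays are found once (with wrap-around
coordinates).  The dispersed scan runs on the linearised sequence.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import CircularSequence, FeatureInterval, MitogenomeRecord

SSR_THRESHOLDS = (8, 4, 4, 3, 3, 3)
MOTIF_CLASSES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
DISPERSED_BINS = ((30, 49), (50, 69), (70, 99), (100, 149), (150, 199), (200, 999), (1000, None))


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class SSRRecord:
    motif: str
    motif_class: str
    repeat_count: int
    interval: FeatureInterval


@dataclass(frozen=True)
class TandemRepeat:
    unit: str
    unit_length: int
    copy_number: float
    interval: FeatureInterval
    location: str = ""


@dataclass(frozen=True)
class DispersedRepeat:
    interval_a: FeatureInterval
    interval_b: FeatureInterval
    length: int  # aligned block length of the representative hit
    orientation: str  # direct | inverted
    identity: float  # percent
    footprint_bp: int = 0  # union of merged hit intervals; 0 = not merged


@dataclass
class RepeatSummary:
    ssr_crosstab: pd.DataFrame | None = None
    ssr_class_counts: dict[str, int] = field(default_factory=dict)
    ssr_class_proportions: dict[str, float] = field(default_factory=dict)
    tandem: list[TandemRepeat] = field(default_factory=list)
    dispersed_bin_counts: dict[str, int] = field(default_factory=dict)
    dispersed_total_length: int = 0
    dispersed_genome_fraction_pct: float = 0.0


# ---------------------------------------------------------------------------
# run finding shared by SSR and tandem scanners
# ---------------------------------------------------------------------------

def _match_runs(arr: np.ndarray, period: int):
    """Maximal runs where arr[i] == arr[i+period]; yields (start, run_len)."""
    eq = arr[:-period] == arr[period:]
    if not eq.any():
        return
    idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b - a)


def _minimal_period(s: str) -> int:
    """Smallest p such that s[i] == s[i+p] for all valid i (KMP failure)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def _wrap_interval(start0: int, span: int, n: int, strand: str = "+") -> FeatureInterval:
    """Build a 1-based interval from a 0-based start on the overhang-extended string."""
    start = start0 + 1
    end = start0 + span
    if end <= n:
        return FeatureInterval(start, end, strand)
    return FeatureInterval(start, end - n, strand, wraps_origin=True)


def _drop_wrap_duplicates(items, n):
    """Remove linear-scan artifacts fully covered by a wrapping record's tail."""
    wrapped_tails = [
        it.interval.end for it in items if it.interval.wraps_origin
    ]
    if not wrapped_tails:
        return items
    cover = max(wrapped_tails)
    return [
        it for it in items if it.interval.wraps_origin or it.interval.end > cover
    ]


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

def find_ssrs(
    seq: CircularSequence, thresholds: tuple[int, ...] = SSR_THRESHOLDS
) -> list[SSRRecord]:
    """Perfect SSRs (motif size 1–6) above per-class repeat-count thresholds.

    Only maximal runs are reported, trimmed to whole motif copies, and a run
    is attributed to its minimal period only (an AT array is a dinucleotide
    SSR, not two interleaved mononucleotide runs).
    """
    if len(thresholds) != 6:
        raise RepeatError("need six thresholds for motif sizes 1..6")
    n = len(seq)
    overhang = min(n, 1000) if seq.is_circular else 0
    s = seq.residues + seq.residues[:overhang]
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out: list[SSRRecord] = []
    for p in range(1, 7):
        thr = thresholds[p - 1]
        if len(arr) <= p:
            continue
        for a, run in _match_runs(arr, p):
            span = run + p
            count = span // p
            if count < thr:
                continue
            motif = s[a : a + p]
            if "N" in motif or _minimal_period(motif) != p:
                continue
            if a >= n:
                continue  # lives entirely in the overhang copy
            span_trim = count * p
            if span_trim > n:  # degenerate: repeat covers whole circle
                span_trim = (n // p) * p
                count = span_trim // p
            out.append(
                SSRRecord(
                    motif=motif,
                    motif_class=MOTIF_CLASSES[p],
                    repeat_count=count,
                    interval=_wrap_interval(a, span_trim, n),
                )
            )
    out = _drop_wrap_duplicates(out, n)
    out.sort(key=lambda r: (r.interval.start, len(r.motif)))
    return out


def summarize_ssrs(records: list[SSRRecord]) -> RepeatSummary:
    """Cross-tabulate motif class x repeat count and per-class proportions."""
    summary = RepeatSummary()
    classes = list(MOTIF_CLASSES.values())
    counts = {c: 0 for c in classes}
    for r in records:
        counts[r.motif_class] += 1
    total = sum(counts.values())
    summary.ssr_class_counts = counts
    summary.ssr_class_proportions = {
        c: (round(100.0 * v / total, 2) if total else 0.0) for c, v in counts.items()
    }
    if records:
        df = pd.DataFrame(
            [{"motif_class": r.motif_class, "repeat_count": r.repeat_count} for r in records]
        )
        summary.ssr_crosstab = pd.crosstab(df["motif_class"], df["repeat_count"]).reindex(
            classes, fill_value=0
        )
    else:
        summary.ssr_crosstab = pd.DataFrame(index=classes)
    return summary


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def find_tandem_repeats(
    seq: CircularSequence,
    min_unit: int = 7,
    max_unit: int = 200,
    min_copies: float = 2.0,
) -> list[TandemRepeat]:
    """Maximal perfect tandem arrays with unit length >= min_unit.

    An array is reported once, at the smallest period of the spanned
    sequence; a trailing partial copy makes the copy number fractional.
    Arrays whose minimal period is below ``min_unit`` belong to the SSR
    census and are not reported here.
    """
    n = len(seq)
    overhang = min(n, 2 * max_unit + 1000) if seq.is_circular else 0
    s = seq.residues + seq.residues[:overhang]
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    found: list[TandemRepeat] = []
    for p in range(min_unit, min(max_unit, len(arr) - 1) + 1):
        for a, run in _match_runs(arr, p):
            span = run + p
            if span < min_copies * p:
                continue
            if a >= n:
                continue
            array_seq = s[a : a + span]
            if "N" in array_seq:
                continue
            if _minimal_period(array_seq) != p:
                continue  # reported at its true (smaller) period instead
            if span > n:
                span = n
            found.append(
                TandemRepeat(
                    unit=s[a : a + p],
                    unit_length=p,
                    copy_number=round(span / p, 2),
                    interval=_wrap_interval(a, span, n),
                )
            )
    # suppress arrays nested inside a larger reported array
    found.sort(key=lambda t: (-t.interval.span(n), t.unit_length))
    kept: list[TandemRepeat] = []
    for t in found:
        nested = any(
            _contains(big.interval, t.interval, n) and big is not t for big in kept
        )
        if not nested:
            kept.append(t)
    kept = _drop_wrap_duplicates(kept, n)
    kept.sort(key=lambda t: t.interval.start)
    return kept


def _linear_segments(iv: FeatureInterval, n: int) -> list[tuple[int, int]]:
    if not iv.wraps_origin:
        return [(iv.start, iv.end)]
    return [(iv.start, n), (1, iv.end)]


def _contains(big: FeatureInterval, small: FeatureInterval, n: int) -> bool:
    big_segs = _linear_segments(big, n)
    for a, b in _linear_segments(small, n):
        if not any(ba <= a and b <= bb for ba, bb in big_segs):
            return False
    return True


def classify_location(interval: FeatureInterval, record: MitogenomeRecord) -> str:
    """Gene name if the interval overlaps an exon, else IGS(left, right).

    Flanking genes are the nearest annotated genes on the circle in each
    direction, so intervals near the origin resolve with wraparound.
    """
    if not record.genes:
        raise RepeatError("record has no gene annotations")
    n = len(record.sequence)
    segs = _linear_segments(interval, n)

    def overlap_bp(iv: FeatureInterval) -> int:
        total = 0
        for a1, b1 in segs:
            for a2, b2 in _linear_segments(iv, n):
                total += max(0, min(b1, b2) - max(a1, a2) + 1)
        return total

    best_gene, best_ov = None, 0
    for gene in record.genes:
        for exons in gene.all_exon_sets():
            ov = sum(overlap_bp(e) for e in exons)
            if ov > best_ov:
                best_gene, best_ov = gene.name, ov
    if best_gene is not None:
        return best_gene

    # nearest flanking genes on the circle
    start, end = interval.start, interval.end if not interval.wraps_origin else interval.end + n

    def circ_gap(a: int, b: int) -> int:
        return (b - a) % n

    left_name, left_gap = None, None
    right_name, right_gap = None, None
    for gene in record.genes:
        for exons in gene.all_exon_sets():
            g_start = min(e.start for e in exons)
            g_end = max(e.end for e in exons)
            lg = circ_gap(g_end, start)
            rg = circ_gap(end % n if end > n else end, g_start)
            if left_gap is None or lg < left_gap:
                left_name, left_gap = gene.name, lg
            if right_gap is None or rg < right_gap:
                right_name, right_gap = gene.name, rg
    return f"IGS({left_name}, {right_name})"


# ---------------------------------------------------------------------------
# dispersed repeats (genome-vs-self blastn)
# ---------------------------------------------------------------------------

_BLAST_FIELDS = "qstart qend sstart send length pident evalue"


def _run_self_blast(fasta: Path, word: int, evalue: float) -> pd.DataFrame:
    if shutil.which("blastn") is None:
        raise RepeatError("blastn executable not found on PATH")
    cmd = [
        "blastn",
        "-query", str(fasta),
        "-subject", str(fasta),
        "-word_size", str(word),
        "-reward", "1",
        "-penalty", "-3",
        "-gapopen", "3",
        "-gapextend", "3",
        "-evalue", str(evalue),
        "-dust", "no",
        "-outfmt", f"6 {_BLAST_FIELDS}",
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RepeatError(f"blastn failed: {proc.stderr.strip()}")
    cols = _BLAST_FIELDS.split()
    if not proc.stdout.strip():
        return pd.DataFrame(columns=cols)
    rows = [line.split("\t") for line in proc.stdout.strip().splitlines()]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("qstart", "qend", "sstart", "send", "length"):
        df[c] = df[c].astype(int)
    for c in ("pident", "evalue"):
        df[c] = df[c].astype(float)
    return df


def find_dispersed_repeats(
    seq: CircularSequence,
    min_len: int = 30,
    min_identity: float = 80.0,
    evalue: float = 1.0,
    word: int = 7,
) -> list[DispersedRepeat]:
    """Dispersed repeat pairs from a genome-vs-self blastn search.

    The trivial full-length self-diagonal is removed, each repeat pair is
    reported once (intervals ordered along the genome), and partly or
    wholly overlapping hit pairs are merged into a single repeat unit whose
    footprint is the union of the merged intervals.
    """
    if len(seq) < 2 * min_len:
        raise RepeatError("sequence too short for dispersed-repeat scan")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "genome.fa"
        with open(fasta, "w") as fh:
            fh.write(f">{seq.identifier}\n{seq.residues}\n")
        df = _run_self_blast(fasta, word, evalue)

    hits = []
    seen = set()
    for row in df.itertuples(index=False):
        inverted = row.send < row.sstart
        a = (row.qstart, row.qend)
        b = (min(row.sstart, row.send), max(row.sstart, row.send))
        if a == b and not inverted:
            continue  # self-diagonal
        if row.length < min_len or row.pident <= min_identity or row.evalue >= evalue:
            continue
        lo, hi = sorted([a, b])
        key = (lo, hi, inverted)
        if key in seen:
            continue  # symmetric duplicate of an earlier hit
        seen.add(key)
        hits.append((lo, hi, inverted, row.length, row.pident))

    if not hits:
        return []

    # union-find merge: components where either projection overlaps
    parent = list(range(len(hits)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def overlaps(x, y):
        return x[0] <= y[1] and y[0] <= x[1]

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            ai, bi = hits[i][0], hits[i][1]
            aj, bj = hits[j][0], hits[j][1]
            if any(overlaps(u, v) for u in (ai, bi) for v in (aj, bj)):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(hits)):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        rep = max(members, key=lambda i: hits[i][3])
        lo, hi, inverted, length, pident = hits[rep]
        intervals = []
        for i in members:
            intervals.extend([hits[i][0], hits[i][1]])
        footprint = _union_length(intervals)
        out.append(
            DispersedRepeat(
                interval_a=FeatureInterval(lo[0], lo[1]),
                interval_b=FeatureInterval(hi[0], hi[1]),
                length=length,
                orientation="inverted" if inverted else "direct",
                identity=pident,
                footprint_bp=footprint,
            )
        )
    out.sort(key=lambda r: (r.interval_a.start, r.interval_b.start))
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_a, cur_b = ivs[0]
    for a, b in ivs[1:]:
        if a <= cur_b + 1:
            cur_b = max(cur_b, b)
        else:
            total += cur_b - cur_a + 1
            cur_a, cur_b = a, b
    total += cur_b - cur_a + 1
    return total


def bin_dispersed(records: list[DispersedRepeat], genome_length: int) -> RepeatSummary:
    """Size-bin counts, total merged footprint and genome fraction."""
    summary = RepeatSummary()
    labels = [
        f"{lo}-{hi}" if hi is not None else f">={lo}" for lo, hi in DISPERSED_BINS
    ]
    counts = dict.fromkeys(labels, 0)
    for r in records:
        for (lo, hi), label in zip(DISPERSED_BINS, labels):
            if r.length >= lo and (hi is None or r.length <= hi):
                counts[label] += 1
                break
    summary.dispersed_bin_counts = counts
    total = sum(r.footprint_bp or (r.interval_a.span() + r.interval_b.span()) for r in records)
    summary.dispersed_total_length = total
    summary.dispersed_genome_fraction_pct = (
        round(100.0 * total / genome_length, 2) if genome_length else 0.0
    )
    return summary


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def ssr_frame(records: list[SSRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "class": r.motif_class,
                "count": r.repeat_count,
                "start": r.interval.start,
                "end": r.interval.end,
            }
            for r in records
        ],
        columns=["motif", "class", "count", "start", "end"],
    )


def tandem_frame(records: list[TandemRepeat], genome_length: int | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "no": i + 1,
                "size_bp": r.interval.span(genome_length),
                "start": r.interval.start,
                "end": r.interval.end,
                "unit": r.unit,
                "copies": r.copy_number,
                "location": r.location,
            }
            for i, r in enumerate(records)
        ],
        columns=["no", "size_bp", "start", "end", "unit", "copies", "location"],
    )


def dispersed_frame(records: list[DispersedRepeat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "startA": r.interval_a.start,
                "endA": r.interval_a.end,
                "startB": r.interval_b.start,
                "endB": r.interval_b.end,
                "length": r.length,
                "orientation": r.orientation,
                "identity_pct": round(r.identity, 2),
            }
            for r in records
        ],
        columns=["startA", "endA", "startB", "endB", "length", "orientation", "identity_pct"],
    )
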