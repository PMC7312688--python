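"""Synthetic circular mitogenome fixtures with exact ground-truth manifests.

The generator emulates the statistical shape of a papilionoid legume
mitochondrial genome at desk scale: a circular A/T-rich (GC ~0.45)
molecule carrying perfect SSRs with an A/T-biased motif spectrum, exact
tandem duplications, two large (>1 kb) inverted dispersed repeats at copy
number 2, and annotated genes including multi-exon, trans-spliced,
ACG-start and CGA-stop cases.  Long reads are sampled from a chosen
circular conformation with substitution errors.

Everything is deterministic under a fixed seed, and every planted feature
is recorded with coordinates so detectors can be graded with zero
ambiguity.  The background is i.i.d. (no higher-order composition
structure) and is actively scrubbed of accidental repeats so that, at
planted-identity thresholds, the manifest is the complete truth: detectors
should report the planted set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, STANDARD_STOPS, EditingSite
from .genome_io import (
    CircularSequence,
    FeatureInterval,
    GeneModel,
    MitogenomeRecord,
    revcomp,
)
from .repeats import MOTIF_CLASSES, SSR_THRESHOLDS, find_ssrs, find_tandem_repeats

_BASES = "ACGT"


class SyntheticError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# plant specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRPlant:
    motif: str
    count: int


@dataclass(frozen=True)
class TandemPlant:
    unit_length: int
    copies: float  # may be fractional (trailing partial copy)


@dataclass(frozen=True)
class DispersedPlant:
    length: int
    orientation: str  # direct | inverted


@dataclass(frozen=True)
class GenePlant:
    name: str
    gene_type: str = "protein"
    n_codons: int = 250
    length_bp: int = 0  # for tRNA/rRNA
    strand: str = "+"
    n_exons: int = 1
    trans_spliced: bool = False
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    copies: int = 1


# defaults emulate the study conditions: A/T-rich SSR spectrum, two >1 kb
# inverted repeats at copy number 2, trans-splicing and editing-restored codons
DEFAULT_SSRS: tuple[SSRPlant, ...] = (
    SSRPlant("A", 10),
    SSRPlant("T", 9),
    SSRPlant("A", 8),
    SSRPlant("G", 8),
    SSRPlant("AT", 6),
    SSRPlant("TA", 5),
    SSRPlant("TC", 4),
    SSRPlant("AT", 4),
    SSRPlant("TAA", 4),
    SSRPlant("ATT", 4),
    SSRPlant("AAAT", 3),
    SSRPlant("TTCA", 3),
    SSRPlant("AATAG", 3),
    SSRPlant("AATGCT", 3),
)

# tandem units kept below the 30 bp dispersed-repeat floor so the planted
# dispersed manifest stays the complete truth for the self-alignment scan
DEFAULT_TANDEMS: tuple[TandemPlant, ...] = (
    TandemPlant(27, 2.0),
    TandemPlant(22, 2.0),
    TandemPlant(15, 2.33),
)

DEFAULT_DISPERSED: tuple[DispersedPlant, ...] = (
    DispersedPlant(4866, "inverted"),
    DispersedPlant(3529, "inverted"),
    DispersedPlant(220, "direct"),
)

DEFAULT_GENES: tuple[GenePlant, ...] = (
    GenePlant("atp1", n_codons=300, strand="+"),
    GenePlant("cox1", n_codons=320, strand="-"),
    GenePlant("cob", n_codons=260, strand="+"),
    GenePlant("matR", n_codons=400, strand="+"),
    GenePlant("ccmFC", n_codons=260, strand="+", n_exons=2, stop_codon="CGA"),
    GenePlant("rps10", n_codons=121, strand="+", n_exons=2, start_codon="ACG"),
    GenePlant("nad4", n_codons=300, strand="-", n_exons=3),
    GenePlant("nad1", n_codons=200, strand="+", n_exons=2, trans_spliced=True,
              start_codon="ACG"),
    GenePlant("rps3", n_codons=280, strand="+"),
    GenePlant("nad9", n_codons=190, strand="+"),
    GenePlant("trnM-CAU", gene_type="tRNA", length_bp=73, copies=2),
    GenePlant("trnC-GCA", gene_type="tRNA", length_bp=72),
    GenePlant("rrnL", gene_type="rRNA", length_bp=900),
    GenePlant("rrn5", gene_type="rRNA", length_bp=119),
)


# ---------------------------------------------------------------------------
# scrubbed random sequence
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _break_runs(arr: np.ndarray, rng: np.random.Generator, probs: np.ndarray,
                max_unit: int = 200) -> np.ndarray:
    """Destroy any lag-p repeat run that a detector could report.

    SSR-range lags (1-6) are broken when the full-copy count reaches the
    detection threshold; longer lags (up to max_unit) when the array spans
    two copies.  Replacement bases are redrawn until no run remains.
    """
    n = len(arr)
    for _ in range(60):
        dirty = False
        for p in range(1, min(max_unit, n - 1) + 1):
            eq = arr[:-p] == arr[p:]
            if not eq.any():
                continue
            idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
            for a, b in zip(idx[::2], idx[1::2]):
                span = (b - a) + p
                bad = (
                    span // p >= SSR_THRESHOLDS[p - 1] if p <= 6 else span >= 2 * p
                )
                if bad:
                    dirty = True
                    mid = a + span // 2
                    old = arr[mid]
                    choices = [c for c in b"ACGT" if c != old]
                    arr[mid] = choices[rng.integers(len(choices))]
        if not dirty:
            return arr
    raise SyntheticError("could not scrub background of accidental repeats")


def _scrubbed(rng: np.random.Generator, n: int, probs: np.ndarray,
              max_unit: int = 200) -> str:
    arr = _random_bases(rng, n, probs)
    arr = _break_runs(arr, rng, probs, max_unit)
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# random CDS without accidental SSRs
# ---------------------------------------------------------------------------

def _tail_has_ssr(s: str) -> bool:
    tail = s[-40:]
    for p in range(1, 7):
        thr_span = SSR_THRESHOLDS[p - 1] * p
        if len(tail) <= p:
            continue
        run = 0
        best = 0
        for i in range(p, len(tail)):
            run = run + 1 if tail[i] == tail[i - p] else 0
            best = max(best, run)
        if best + p >= thr_span:
            return True
    return False


def _has_tandem(s: str) -> bool:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    for p in range(7, len(arr) // 2 + 1):
        eq = arr[:-p] == arr[p:]
        if not eq.any():
            continue
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        runs = idx[1::2] - idx[::2]
        if (runs >= p).any():
            return True
    return False


def random_cds(rng: np.random.Generator, n_codons: int,
               start: str = "ATG", stop: str = "TAA") -> str:
    """Random coding sequence of n_codons (start and stop included), free of
    SSR-threshold runs and tandem arrays so planted-repeat manifests stay
    exact."""
    if n_codons < 3:
        raise SyntheticError("need at least 3 codons")
    sense = [c for c in SENSE_CODONS if c not in ("ATG",)] + ["ATG"]
    for _attempt in range(20):
        codons = [start]
        ok = True
        for _ in range(n_codons - 2):
            for _try in range(200):
                c = sense[rng.integers(len(sense))]
                if not _tail_has_ssr("".join(codons) + c):
                    codons.append(c)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        cds = "".join(codons) + stop
        if not _has_tandem(cds):
            return cds
    raise SyntheticError("could not build a repeat-free CDS")


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _guard_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in _BASES if b not in avoid]
    return choices[rng.integers(len(choices))]


@dataclass
class _Item:
    """One plantable block: sequence to place plus truth metadata."""

    kind: str
    seq: str
    meta: dict = field(default_factory=dict)


def _build_gene_items(rng, gene: GenePlant, probs) -> tuple[list[_Item], dict]:
    """Sequence blocks for one gene plant; trans-spliced genes produce one
    block per cis segment."""
    info: dict = {"plant": gene, "editing_sites": []}
    if gene.gene_type != "protein":
        seq = _scrubbed(rng, gene.length_bp, probs)
        items = [_Item("gene_block", seq, {"gene": gene.name, "block": 0})]
        if gene.copies > 1:
            for k in range(1, gene.copies):
                items.append(_Item("gene_block", seq, {"gene": gene.name, "block": k,
                                                       "extra_copy": True}))
        info["cds"] = None
        return items, info

    cds = random_cds(rng, gene.n_codons, gene.start_codon, gene.stop_codon)
    info["cds"] = cds
    if gene.start_codon == "ACG":
        info["editing_sites"].append(EditingSite(gene.name, 1, 2))
    if gene.stop_codon == "CGA":
        info["editing_sites"].append(EditingSite(gene.name, gene.n_codons, 1))

    # split the CDS into exons
    n_ex = max(1, gene.n_exons)
    if n_ex == 1:
        pieces = [cds]
    else:
        cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_ex - 1,
                                 replace=False))
        pieces = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
    info["exon_pieces"] = pieces

    items = []
    if gene.trans_spliced:
        # one genomic block per exon, placed independently; second block on
        # the opposite strand to exercise cross-strand joining
        for k, piece in enumerate(pieces):
            strand = gene.strand if k == 0 else ("-" if gene.strand == "+" else "+")
            block = piece if strand == "+" else revcomp(piece)
            items.append(
                _Item("gene_block", block,
                      {"gene": gene.name, "block": k, "strand": strand,
                       "exon_len": len(piece)})
            )
    else:
        intron_lens = [int(rng.integers(120, 400)) for _ in range(n_ex - 1)]
        locus_parts = []
        exon_offsets = []
        off = 0
        for k, piece in enumerate(pieces):
            exon_offsets.append((off, off + len(piece) - 1))
            locus_parts.append(piece)
            off += len(piece)
            if k < n_ex - 1:
                intron = _scrubbed(rng, intron_lens[k], probs)
                locus_parts.append(intron)
                off += len(intron)
        locus = "".join(locus_parts)
        if gene.strand == "-":
            locus = revcomp(locus)
        items.append(
            _Item("gene_block", locus,
                  {"gene": gene.name, "block": 0, "strand": gene.strand,
                   "exon_offsets": exon_offsets, "locus_len": len(locus)})
        )
    return items, info


def generate_genome(
    seed: int = 0,
    length: int = 120_000,
    gc: float = 0.45,
    ssrs: tuple[SSRPlant, ...] = DEFAULT_SSRS,
    tandems: tuple[TandemPlant, ...] = DEFAULT_TANDEMS,
    dispersed: tuple[DispersedPlant, ...] = DEFAULT_DISPERSED,
    genes: tuple[GenePlant, ...] = DEFAULT_GENES,
    identifier: str = "synthetic_mitogenome",
    verify: bool = True,
) -> tuple[MitogenomeRecord, dict]:
    """Build a circular genome with planted features and return the record
    plus its ground-truth manifest.

    The truth dict holds DataFrames ``ssrs``, ``tandems``, ``dispersed``,
    ``genes`` (1-based inclusive coordinates), a list ``editing_sites`` and
    the ``manifest`` of generation parameters.  With ``verify=True`` the
    SSR/tandem detectors are run once and the genome is regenerated under a
    derived seed in the (rare) event that junction effects created an
    unplanned repeat, so the manifest is exact by construction.
    """
    for salt in range(10):
        rng = np.random.default_rng((seed, salt))
        try:
            record, truth = _generate_once(
                rng, length, gc, ssrs, tandems, dispersed, genes, identifier
            )
        except SyntheticError:
            continue
        if not verify or _verify_plants(record, truth):
            truth["manifest"] = {
                "seed": seed,
                "salt": salt,
                "length": length,
                "gc": gc,
                "n_ssrs": len(ssrs),
                "n_tandems": len(tandems),
                "n_dispersed": len(dispersed),
                "n_genes": len(genes),
            }
            return record, truth
    raise SyntheticError("could not generate a clean genome in 10 attempts")


def _generate_once(rng, length, gc, ssrs, tandems, dispersed, genes, identifier):
    probs = _base_probs(gc)

    items: list[_Item] = []
    gene_infos: dict[str, dict] = {}
    for gene in genes:
        gitems, info = _build_gene_items(rng, gene, probs)
        gene_infos[gene.name] = info
        items.extend(gitems)

    for i, plant in enumerate(ssrs):
        if len(plant.motif) > 6 or plant.count < SSR_THRESHOLDS[len(plant.motif) - 1]:
            raise SyntheticError(f"SSR plant below detection threshold: {plant}")
        items.append(_Item("ssr", plant.motif * plant.count,
                           {"idx": i, "motif": plant.motif, "count": plant.count}))

    for i, plant in enumerate(tandems):
        for _try in range(50):
            unit = _scrubbed(rng, plant.unit_length, probs, max_unit=plant.unit_length // 2 or 1)
            if len(set(unit)) >= 3:
                break
        span = int(round(plant.unit_length * plant.copies))
        full = unit * int(np.ceil(plant.copies))
        arr = full[:span]
        items.append(_Item("tandem", arr,
                           {"idx": i, "unit": unit, "copies": plant.copies,
                            "span": span}))

    disp_blocks = []
    for i, plant in enumerate(dispersed):
        block = _scrubbed(rng, plant.length, probs)
        copy = revcomp(block) if plant.orientation == "inverted" else block
        items.append(_Item("disp_a", block, {"idx": i, "orientation": plant.orientation,
                                             "length": plant.length}))
        items.append(_Item("disp_b", copy, {"idx": i, "orientation": plant.orientation,
                                            "length": plant.length}))
        disp_blocks.append((block, copy))

    total_items = sum(len(it.seq) for it in items)
    n_gaps = len(items)
    spare = length - total_items - 2 * n_gaps  # 2 guard bases per junction
    if spare < 200 * n_gaps:
        raise SyntheticError(
            f"genome length {length} too small for planted content ({total_items} bp)"
        )
    # random gap sizes (>=100 bp) between items, consuming the spare length
    weights = rng.dirichlet(np.ones(n_gaps))
    gaps = (weights * (spare - 100 * n_gaps)).astype(int) + 100
    gaps[-1] += spare - int(gaps.sum())  # absorb rounding
    order = rng.permutation(len(items))

    chunks: list[str] = []
    placements: list[tuple[_Item, int]] = []  # (item, 1-based start)
    pos = 0
    for gi, idx in enumerate(order):
        item = items[idx]
        gap_len = int(gaps[gi])
        gap_seq = _scrubbed(rng, gap_len, probs)
        # guard bases stop planted repeats from extending into the background
        left_guard = right_guard = None
        if item.kind == "ssr":
            motif = item.meta["motif"]
            left_guard = _guard_base(rng, motif[-1])
            right_guard = _guard_base(rng, motif[0])
        elif item.kind == "tandem":
            unit, span = item.meta["unit"], item.meta["span"]
            left_guard = _guard_base(rng, unit[-1])
            right_guard = _guard_base(rng, unit[span % len(unit)])
        if left_guard:
            gap_seq = gap_seq[:-1] + left_guard
        chunks.append(gap_seq)
        pos += gap_len
        placements.append((item, pos + 1))
        chunks.append(item.seq)
        pos += len(item.seq)
        if right_guard:
            chunks.append(right_guard)
            pos += 1

    genome = "".join(chunks)
    if len(genome) < length:
        genome += _scrubbed(rng, length - len(genome), probs)
    genome = genome[:length]
    seq = CircularSequence(genome, identifier)

    # assemble truth tables and gene models from placements
    ssr_rows, tandem_rows, disp_pos = [], [], {}
    gene_blocks: dict[str, list[tuple[int, dict]]] = {}
    for item, start in placements:
        end = start + len(item.seq) - 1
        if item.kind == "ssr":
            m = item.meta
            ssr_rows.append({"motif": m["motif"],
                             "motif_class": MOTIF_CLASSES[len(m["motif"])],
                             "count": m["count"], "start": start, "end": end})
        elif item.kind == "tandem":
            m = item.meta
            tandem_rows.append({"unit": m["unit"], "unit_length": len(m["unit"]),
                                "copies": m["copies"], "start": start, "end": end})
        elif item.kind in ("disp_a", "disp_b"):
            disp_pos.setdefault(item.meta["idx"], {})[item.kind] = (start, end, item.meta)
        elif item.kind == "gene_block":
            gene_blocks.setdefault(item.meta["gene"], []).append((start, item.meta))

    disp_rows = []
    # identical multi-copy gene loci are bona fide dispersed repeats: record them
    for gene in genes:
        if gene.copies > 1 and gene.gene_type != "protein":
            blocks = sorted(s for s, _m in gene_blocks[gene.name])
            for a, b in zip(blocks, blocks[1:]):
                disp_rows.append({"a_start": a, "a_end": a + gene.length_bp - 1,
                                  "b_start": b, "b_end": b + gene.length_bp - 1,
                                  "length": gene.length_bp, "orientation": "direct"})
    for idx in sorted(disp_pos):
        a = disp_pos[idx]["disp_a"]
        b = disp_pos[idx]["disp_b"]
        (a_start, a_end, meta) = a
        (b_start, b_end, _) = b
        if b_start < a_start:
            a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
        disp_rows.append({"a_start": a_start, "a_end": a_end,
                          "b_start": b_start, "b_end": b_end,
                          "length": meta["length"],
                          "orientation": meta["orientation"]})

    gene_models, gene_rows, editing_sites = [], [], []
    for gene in genes:
        info = gene_infos[gene.name]
        blocks = sorted(gene_blocks[gene.name], key=lambda t: t[1]["block"])
        if gene.gene_type != "protein":
            exon_sets = []
            for start, meta in blocks:
                end = start + gene.length_bp - 1
                exon_sets.append([FeatureInterval(start, end, "+")])
            model = GeneModel(gene.name, gene.gene_type, exon_sets[0],
                              copy_count=len(exon_sets),
                              extra_copies=[e for e in exon_sets[1:]])
        elif gene.trans_spliced:
            exons = []
            for start, meta in blocks:
                end = start + meta["exon_len"] - 1
                exons.append(FeatureInterval(start, end, meta["strand"]))
            model = GeneModel(gene.name, "protein", exons, trans_spliced=True)
        else:
            start, meta = blocks[0]
            locus_len = meta["locus_len"]
            exons = []
            for off_a, off_b in meta["exon_offsets"]:
                if meta["strand"] == "+":
                    exons.append(FeatureInterval(start + off_a, start + off_b, "+"))
                else:
                    exons.append(
                        FeatureInterval(start + locus_len - 1 - off_b,
                                        start + locus_len - 1 - off_a, "-")
                    )
            model = GeneModel(gene.name, "protein", exons, trans_spliced=False)
        gene_models.append(model)
        editing_sites.extend(info["editing_sites"])
        gene_rows.append({"gene": gene.name, "type": gene.gene_type,
                          "n_codons": gene.n_codons if gene.gene_type == "protein" else 0,
                          "start_codon": gene.start_codon if gene.gene_type == "protein" else "",
                          "stop_codon": gene.stop_codon if gene.gene_type == "protein" else "",
                          "strand": gene.strand, "trans_spliced": gene.trans_spliced,
                          "copies": gene.copies,
                          "cds": info["cds"] or ""})

    # polish: junctions between placed blocks can complete repeat runs the
    # scrubbed pieces did not contain; rewrite offending bases (codon-aware
    # inside genes) until the detectors report exactly the planted sets
    protected: list[tuple[int, int]] = []  # 0-based inclusive, untouchable
    for r in ssr_rows:
        protected.append((r["start"] - 1, r["end"] - 1))
    for r in tandem_rows:
        protected.append((r["start"] - 1, r["end"] - 1))
    for r in disp_rows:
        protected.append((r["a_start"] - 1, r["a_end"] - 1))
        protected.append((r["b_start"] - 1, r["b_end"] - 1))
    codon_map: dict[int, tuple[str, int]] = {}
    cds_store: dict[str, str] = {
        g.name: gene_infos[g.name]["cds"]
        for g in genes
        if gene_infos[g.name]["cds"] is not None
    }
    for model in gene_models:
        if not model.is_protein:
            continue
        off = 0
        for iv in model.exons:
            rng_pos = range(iv.start - 1, iv.end)
            if iv.strand == "+":
                for k, pos0 in enumerate(rng_pos):
                    codon_map[pos0] = (model.name, off + k)
            else:
                ln = iv.end - iv.start + 1
                for k, pos0 in enumerate(rng_pos):
                    codon_map[pos0] = (model.name, off + ln - 1 - k)
            off += iv.end - iv.start + 1

    chars = list(genome)
    _guard_dispersed(chars, disp_rows, protected, rng)
    _polish(chars, rng, protected, codon_map, cds_store, gene_models,
            ssr_rows, tandem_rows)
    genome = "".join(chars)
    seq = CircularSequence(genome, identifier)
    for row in gene_rows:  # polish may have resampled codons
        if row["type"] == "protein":
            row["cds"] = cds_store[row["gene"]]

    record = MitogenomeRecord(seq, gene_models, organism="synthetic organism")
    truth = {
        "ssrs": pd.DataFrame(ssr_rows, columns=["motif", "motif_class", "count", "start", "end"]),
        "tandems": pd.DataFrame(tandem_rows, columns=["unit", "unit_length", "copies", "start", "end"]),
        "dispersed": pd.DataFrame(disp_rows, columns=["a_start", "a_end", "b_start", "b_end", "length", "orientation"]),
        "genes": pd.DataFrame(gene_rows),
        "editing_sites": editing_sites,
    }
    return record, truth


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _guard_dispersed(
    chars: list[str],
    disp_rows: list[dict],
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Force mismatches just outside each planted dispersed copy so local
    alignment cannot extend beyond the planted coordinates."""
    n = len(chars)

    def in_protected(p0: int) -> bool:
        return any(a <= p0 <= b for a, b in protected)

    def force_differ(p_fix: int, p_ref: int, complement: bool) -> None:
        p_fix %= n
        p_ref %= n
        ref = chars[p_ref]
        bad = _COMP[ref] if complement else ref
        if chars[p_fix] != bad:
            return
        if in_protected(p_fix):
            p_fix, p_ref = p_ref, p_fix  # rewrite the other side instead
            bad = _COMP[chars[p_ref]] if complement else chars[p_ref]
            if in_protected(p_fix):
                return
        alt = [b for b in _BASES if b != bad]
        chars[p_fix] = alt[int(rng.integers(len(alt)))]

    for r in disp_rows:
        a0, a1 = r["a_start"] - 1, r["a_end"] - 1
        b0, b1 = r["b_start"] - 1, r["b_end"] - 1
        inverted = r["orientation"] == "inverted"
        for k in (1, 2):
            if inverted:
                force_differ(b0 - k, a1 + k, complement=True)
                force_differ(b1 + k, a0 - k, complement=True)
            else:
                force_differ(b0 - k, a0 - k, complement=False)
                force_differ(b1 + k, a1 + k, complement=False)


def _polish(
    chars: list[str],
    rng: np.random.Generator,
    protected: list[tuple[int, int]],
    codon_map: dict[int, tuple[str, int]],
    cds_store: dict[str, str],
    gene_models: list[GeneModel],
    ssr_rows: list[dict],
    tandem_rows: list[dict],
) -> None:
    """Rewrite bases until SSR/tandem detectors report exactly the planted
    sets; coding positions are fixed codon-wise to keep genes translatable."""
    want_ssr = {(r["start"], r["end"]) for r in ssr_rows}
    want_tan = {(r["start"], r["end"]) for r in tandem_rows}
    prot = sorted(protected)
    models = {m.name: m for m in gene_models}

    def in_protected(p0: int) -> bool:
        return any(a <= p0 <= b for a, b in prot)

    def rewrite_codon(gene_name: str, codon_idx: int) -> bool:
        cds = cds_store[gene_name]
        n_codons = len(cds) // 3
        if codon_idx in (0, n_codons - 1):
            return False  # keep start/stop (and their editing sites) intact
        old = cds[codon_idx * 3 : codon_idx * 3 + 3]
        choices = [c for c in SENSE_CODONS if c != old]
        new = choices[int(rng.integers(len(choices)))]
        cds = cds[: codon_idx * 3] + new + cds[codon_idx * 3 + 3 :]
        cds_store[gene_name] = cds
        off = 0
        for iv in models[gene_name].exons:
            ln = iv.end - iv.start + 1
            piece = cds[off : off + ln]
            off += ln
            if iv.strand == "-":
                piece = revcomp(piece)
            chars[iv.start - 1 : iv.end] = list(piece)
        return True

    n = len(chars)
    for _ in range(120):
        seq = CircularSequence("".join(chars), "polish")
        extras = []
        for r in find_ssrs(seq):
            if (r.interval.start, r.interval.end) not in want_ssr:
                extras.append(r.interval)
        for t in find_tandem_repeats(seq):
            if (t.interval.start, t.interval.end) not in want_tan:
                extras.append(t.interval)
        if not extras:
            return
        fixed_any = False
        for iv in extras:
            positions = list(iv.positions(n))
            mid = len(positions) // 2
            for pos in positions[mid:] + positions[:mid]:
                p0 = pos - 1
                if in_protected(p0):
                    continue
                if p0 in codon_map:
                    gname, cds_off = codon_map[p0]
                    if rewrite_codon(gname, cds_off // 3):
                        fixed_any = True
                        break
                    continue
                old = chars[p0]
                alt = [b for b in _BASES if b != old]
                chars[p0] = alt[int(rng.integers(len(alt)))]
                fixed_any = True
                break
        if not fixed_any:
            raise SyntheticError("polish: every offending position is protected")
    raise SyntheticError("polish did not converge")


def _verify_plants(record: MitogenomeRecord, truth: dict) -> bool:
    """Detectors must report exactly the planted SSR/tandem sets."""
    detected = find_ssrs(record.sequence)
    want = {
        (r.motif_class, int(r.start), int(r.end))
        for r in truth["ssrs"].itertuples(index=False)
    }
    got = {(r.motif_class, r.interval.start, r.interval.end) for r in detected}
    if want != got:
        return False
    det_t = find_tandem_repeats(record.sequence)
    want_t = {(int(r.start), int(r.end)) for r in truth["tandems"].itertuples(index=False)}
    got_t = {(t.interval.start, t.interval.end) for t in det_t}
    return want_t == got_t


# ---------------------------------------------------------------------------
# long-read simulation
# ---------------------------------------------------------------------------

def simulate_long_reads(
    sequence: str | CircularSequence,
    coverage: float = 20.0,
    length_mean: int = 4000,
    length_sigma: float = 0.25,
    error_rate: float = 0.10,
    seed: int = 0,
    circular: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Sample substitution-error long reads uniformly around a (circular)
    sequence; read lengths are log-normal with the given mean.

    Returns the reads and a truth table (start, strand, length, true
    substitutions per read).  Lengths are capped at the sequence length.
    """
    if error_rate >= 0.25:
        raise SyntheticError("error_rate must be < 0.25")
    seq = sequence.residues if isinstance(sequence, CircularSequence) else str(sequence)
    n = len(seq)
    rng = np.random.default_rng(seed)
    n_reads = int(np.ceil(coverage * n / length_mean))
    mu = np.log(length_mean) - length_sigma**2 / 2
    rows, reads = [], []
    doubled = seq + seq
    for i in range(n_reads):
        ln = int(min(max(200, rng.lognormal(mu, length_sigma)), n))
        start = int(rng.integers(n)) if circular else int(rng.integers(max(n - ln, 1)))
        raw = doubled[start : start + ln]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = revcomp(raw)
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8).copy()
        err_mask = rng.random(ln) < error_rate
        n_err = int(err_mask.sum())
        if n_err:
            offsets = rng.integers(1, 4, size=n_err)
            lut = np.frombuffer(b"ACGT", dtype=np.uint8)
            base_idx = np.searchsorted(lut, arr[err_mask])
            arr[err_mask] = lut[(base_idx + offsets) % 4]
        reads.append(arr.tobytes().decode("ascii"))
        rows.append({"read": f"read_{i}", "start": start + 1, "strand": strand,
                     "length": ln, "n_errors": n_err})
    return reads, pd.DataFrame(rows)


def demo_contig_graph(
    seed: int = 0,
    unique_sizes: tuple[int, ...] = (3600, 4200, 3000, 3900),
    repeat_sizes: tuple[int, ...] = (1500, 1200),
    gc: float = 0.45,
):
    """The canonical conformation fixture: four unique contigs and two
    copy-number-2 repeat contigs wired as inverted repeats, admitting one
    master circle and two single-flip isomers.

    Returns (graph, conformations) with conformations enumerated and
    realized; any of them can serve as the planted truth for read
    simulation.
    """
    from .conformation import Contig, ContigGraph, Link, enumerate_conformations

    rng = np.random.default_rng((seed, 7))
    probs = _base_probs(gc)
    contigs = {}
    for i, size in enumerate(unique_sizes, start=1):
        contigs[f"u{i}"] = Contig(f"u{i}", _scrubbed(rng, size, probs))
    for j, size in enumerate(repeat_sizes, start=1):
        contigs[f"r{j}"] = Contig(f"r{j}", _scrubbed(rng, size, probs), copy_number=2)
    links = [
        Link("u1", "T", "r1", "H"), Link("r1", "T", "u2", "H"),
        Link("u2", "T", "r2", "H"), Link("r2", "T", "u3", "H"),
        Link("u3", "T", "r1", "T"), Link("r1", "H", "u4", "H"),
        Link("u4", "T", "r2", "T"), Link("r2", "H", "u1", "H"),
    ]
    graph = ContigGraph(contigs, links)
    return graph, enumerate_conformations(graph)


# ---------------------------------------------------------------------------
# codon-level divergence simulation (ground truth for Ka/Ks recovery)
# ---------------------------------------------------------------------------

def mutate_cds(
    cds: str, omega: float, ks_target: float, rng: np.random.Generator
) -> str:
    """Evolve one CDS by repeated point substitutions.

    Proposals are uniform single-nucleotide changes; synonymous proposals
    are accepted with probability min(1, 1/omega) and nonsynonymous with
    min(1, omega), so the realized dN/dS tracks omega while the synonymous
    divergence is driven to about ks_target.  Stop codons are never
    created; start and stop codons are left untouched.
    """
    from .codons import CODON_TO_AA

    if omega < 0:
        raise SyntheticError("omega must be >= 0")
    chars = list(cds.upper())
    n = len(chars)
    # crude synonymous site count (uniform rates) to convert ks_target to a
    # number of accepted synonymous changes
    s_sites = 0.0
    for i in range(0, n - 3, 3):
        codon = cds[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        syn = tot = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt in STANDARD_STOPS:
                    continue
                tot += 1
                if CODON_TO_AA.get(alt) == aa:
                    syn += 1
        if tot:
            s_sites += 3.0 * syn / tot
    target_syn = ks_target * s_sites
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    accepted_syn = 0.0
    for _ in range(int(200 * max(target_syn, 1) / max(p_syn, 1e-9))):
        if accepted_syn >= target_syn:
            break
        pos = int(rng.integers(3, n - 3))  # spare start and stop codons
        codon_start = (pos // 3) * 3
        codon = "".join(chars[codon_start : codon_start + 3])
        b = "ACGT"[rng.integers(4)]
        if b == chars[pos]:
            continue
        alt = codon[: pos - codon_start] + b + codon[pos - codon_start + 1 :]
        if alt in STANDARD_STOPS:
            continue
        syn = CODON_TO_AA.get(alt) == CODON_TO_AA.get(codon)
        accept_p = p_syn if syn else p_non
        if rng.random() < accept_p:
            chars[pos] = b
            if syn:
                accepted_syn += 1
    return "".join(chars)


def mutate_pair(
    record: MitogenomeRecord,
    omega_per_gene: dict[str, float],
    ks_target: float = 0.1,
    seed: int = 0,
) -> MitogenomeRecord:
    """Return a diverged copy of the record: each named gene's CDS evolved
    under its omega to roughly ks_target synonymous divergence."""
    from .genome_io import extract_cds

    rng = np.random.default_rng((seed, 101))
    chars = list(record.sequence.residues)
    for name, omega in sorted(omega_per_gene.items()):
        gene = record.gene(name)
        cds = extract_cds(record, name)
        mutated = mutate_cds(cds, omega, ks_target, rng)
        off = 0
        for iv in gene.exons:
            ln = iv.span()
            piece = mutated[off : off + ln]
            off += ln
            if iv.strand == "-":
                piece = revcomp(piece)
            chars[iv.start - 1 : iv.end] = list(piece)
    seq = CircularSequence("".join(chars), record.sequence.identifier + "_diverged")
    return MitogenomeRecord(seq, record.genes, organism=record.organism + " (diverged)")
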