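"""Reading, writing and basic accounting of circular mitogenome records.

Plant mitochondrial genomes are conventionally deposited as a single
circular "master" molecule with CDS/tRNA/rRNA features, some of them
multi-exon and a few trans-spliced (exons transcribed from non-contiguous,
even opposite-strand, segments).  This module provides the in-memory
record every downstream stage consumes, GenBank/FASTA round-tripping via
Biopython, trans-splicing-aware CDS extraction, and the per-region base
composition accounting (whole genome, protein-coding exons, cis-spliced
introns, tRNA, rRNA, non-coding).

Coordinates are 1-based inclusive throughout, matching the convention of
published organelle tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed input file or inconsistent record."""


class GenBankParseError(GenomeIOError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureInterval:
    """1-based inclusive genomic interval on a (possibly circular) sequence.

    ``wraps_origin`` marks intervals running off the end of the linear
    representation and continuing at position 1; for those ``start > end``
    is permitted and the spanned length needs the genome length to resolve.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise GenomeIOError(f"interval positions must be >= 1: {self}")
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"strand must be + or -: {self.strand!r}")
        if not self.wraps_origin and self.start > self.end:
            raise GenomeIOError(f"non-wrapping interval with start > end: {self}")

    def span(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise GenomeIOError("wrapping interval needs genome_length to compute span")
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int | None = None):
        """Yield 1-based positions covered, in genomic (5'->3' plus-strand) order."""
        if not self.wraps_origin:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)


@dataclass
class CircularSequence:
    """Uppercase DNA sequence with circular indexing.

    ``fetch`` uses 1-based inclusive coordinates and wraps modulo length
    when the molecule is circular.
    """

    residues: str
    identifier: str = "seq"
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise GenomeIOError("empty sequence")
        extra = set(self.residues) - ALPHABET
        if extra:
            raise GenomeIOError(f"disallowed residues {sorted(extra)} in {self.identifier}")

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Plus-strand sequence of [start, end], 1-based inclusive, wrapping if end < start."""
        n = len(self.residues)
        if not (1 <= start <= n and 1 <= end <= n):
            raise GenomeIOError(f"coordinates ({start},{end}) out of bounds for length {n}")
        if start <= end:
            return self.residues[start - 1 : end]
        if not self.is_circular:
            raise GenomeIOError("wrapping fetch on a linear sequence")
        return self.residues[start - 1 :] + self.residues[:end]

    def slice(self, iv: FeatureInterval) -> str:
        raw = self.fetch(iv.start, iv.end)
        return revcomp(raw) if iv.strand == "-" else raw

    def rotate(self, offset: int) -> "CircularSequence":
        """Rotate the origin so old position offset+1 becomes position 1."""
        off = offset % len(self.residues)
        return CircularSequence(
            self.residues[off:] + self.residues[:off], self.identifier, self.is_circular
        )


#: gene-name prefix -> functional category (field nomenclature)
_CATEGORY_PREFIXES = (
    ("nad", "complexI"),
    ("sdh", "complexII"),
    ("cob", "complexIII"),
    ("cox", "complexIV"),
    ("atp", "complexV"),
    ("ccm", "cytc_biogenesis"),
    ("rps", "ribosomal_SSU"),
    ("rpl", "ribosomal_LSU"),
    ("matr", "maturase"),
    ("mttb", "transport"),
    ("rrn", "rRNA"),
    ("trn", "tRNA"),
)


def classify_gene(name: str) -> str:
    low = name.lower()
    for prefix, cat in _CATEGORY_PREFIXES:
        if low.startswith(prefix):
            return cat
    return "other"


@dataclass
class GeneModel:
    """A unique gene: ordered exons of its primary copy plus any duplicate loci.

    ``exons`` follow annotation (transcript) order, which for trans-spliced
    genes is not genomic order.  ``copy_count`` collapses multi-copy genes
    (duplicate loci stored in ``extra_copies``) so that unique-gene counts
    match the convention of organelle gene-content tables.
    """

    name: str
    gene_type: str  # 'protein' | 'tRNA' | 'rRNA'
    exons: list[FeatureInterval]
    trans_spliced: bool = False
    copy_count: int = 1
    extra_copies: list[list[FeatureInterval]] = field(default_factory=list)
    category: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise GenomeIOError(f"gene {self.name} has no exons")
        if not self.category:
            self.category = classify_gene(self.name)
        if self.gene_type not in ("protein", "tRNA", "rRNA"):
            raise GenomeIOError(f"unknown gene_type {self.gene_type!r} for {self.name}")

    @property
    def is_protein(self) -> bool:
        return self.gene_type == "protein"

    def all_exon_sets(self) -> list[list[FeatureInterval]]:
        return [self.exons, *self.extra_copies]


@dataclass
class MitogenomeRecord:
    """Circular genome sequence plus its (collapsed) gene annotations."""

    sequence: CircularSequence
    genes: list[GeneModel]
    organism: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[str] = set()
        for g in self.genes:
            if g.name in seen:
                raise GenomeIOError(f"duplicate gene name after collapsing: {g.name}")
            seen.add(g.name)
            for exons in g.all_exon_sets():
                for iv in exons:
                    if iv.start > n or iv.end > n:
                        raise GenomeIOError(
                            f"exon {iv} of {g.name} outside sequence of length {n}"
                        )

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"gene {name!r} not annotated")

    @property
    def protein_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_protein]

    def unique_gene_count(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# GenBank / FASTA IO
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _feature_exons(feat: SeqFeature, genome_length: int) -> list[FeatureInterval]:
    exons = []
    for part in feat.location.parts:
        strand = "-" if part.strand == -1 else "+"
        exons.append(FeatureInterval(int(part.start) + 1, int(part.end), strand))
    if feat.location.strand == -1 and len(feat.location.parts) > 1:
        # Biopython lists parts of a minus-strand join in genomic order of the
        # location string; transcript order for a plain minus-strand join is
        # descending genomic order.
        strands = {p.strand for p in feat.location.parts}
        if strands == {-1} and "trans_splicing" not in feat.qualifiers:
            exons = sorted(exons, key=lambda iv: -iv.start)
    for iv in exons:
        if iv.end > genome_length:
            raise GenomeIOError(f"feature exon {iv} beyond sequence end {genome_length}")
    return exons


def read_genbank(path) -> MitogenomeRecord:
    """Parse a GenBank flat file with CDS/tRNA/rRNA features into a record.

    Multi-copy genes (identical names at distinct loci) are collapsed into a
    single :class:`GeneModel` with ``copy_count`` set.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with location info
        raise GenBankParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    topology = rec.annotations.get("topology", "circular")
    seq = CircularSequence(str(rec.seq), rec.id or "genome", topology != "linear")
    genes: dict[str, GeneModel] = {}
    for feat in rec.features:
        gtype = _FEATURE_TYPES.get(feat.type)
        if gtype is None:
            continue
        name = _feature_name(feat)
        if name is None:
            raise GenBankParseError(f"{feat.type} feature at {feat.location} lacks a gene name")
        exons = _feature_exons(feat, len(seq))
        trans = "trans_splicing" in feat.qualifiers or len({e.strand for e in exons}) > 1
        if name in genes:
            g = genes[name]
            g.extra_copies.append(exons)
            g.copy_count += 1
        else:
            genes[name] = GeneModel(name, gtype, exons, trans_spliced=trans)
    organism = rec.annotations.get("organism", "")
    return MitogenomeRecord(seq, list(genes.values()), organism)


def _exons_to_location(exons: list[FeatureInterval]) -> SimpleLocation | CompoundLocation:
    parts = [
        SimpleLocation(iv.start - 1, iv.end, strand=-1 if iv.strand == "-" else 1)
        for iv in exons
    ]
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def write_genbank(record: MitogenomeRecord, path) -> None:
    """Write a record back to a GenBank flat file (round-trips with read_genbank)."""
    rec = SeqRecord(
        Seq(record.sequence.residues),
        id=record.sequence.identifier,
        name=record.sequence.identifier[:16].replace(".", "_"),
        description=record.organism or "synthetic mitogenome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.sequence.is_circular else "linear",
            "organism": record.organism,
        },
    )
    ftype = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for g in record.genes:
        for exons in g.all_exon_sets():
            quals = {"gene": [g.name]}
            if g.trans_spliced:
                quals["trans_splicing"] = [""]
            rec.features.append(
                SeqFeature(_exons_to_location(exons), type=ftype[g.gene_type], qualifiers=quals)
            )
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path) -> CircularSequence:
    rec = SeqIO.read(str(path), "fasta")
    return CircularSequence(str(rec.seq), rec.id)


def write_fasta(seqs, path) -> None:
    """Write (identifier, sequence) pairs or CircularSequence objects to FASTA."""
    with open(path, "w") as fh:
        for s in seqs if isinstance(seqs, (list, tuple)) else [seqs]:
            if isinstance(s, CircularSequence):
                ident, residues = s.identifier, s.residues
            else:
                ident, residues = s
            fh.write(f">{ident}\n")
            for i in range(0, len(residues), 70):
                fh.write(residues[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

def extract_cds(record: MitogenomeRecord, gene_name: str) -> str:
    """Concatenated coding sequence of a protein gene.

    Exons are joined in annotation (transcript) order, each reverse
    complemented according to its own strand, which handles trans-spliced
    genes whose segments lie on opposite strands.
    """
    gene = record.gene(gene_name)
    if not gene.is_protein:
        raise GenomeIOError(f"{gene_name} is not protein-coding")
    cds = "".join(record.sequence.slice(iv) for iv in gene.exons)
    if len(cds) % 3 != 0:
        raise GenomeIOError(
            f"CDS of {gene_name} has length {len(cds)}, not divisible by 3"
        )
    return cds


# ---------------------------------------------------------------------------
# composition accounting
# ---------------------------------------------------------------------------

# region precedence when features overlap: each base counted once, highest wins
_REGION_CODES = {
    "rRNA": 1,
    "tRNA": 2,
    "cis_introns": 3,
    "pcg_exons": 4,
}
_REGION_ORDER = ["whole_genome", "pcg_exons", "cis_introns", "tRNA", "rRNA", "non_coding"]

COMPOSITION_COLUMNS = ["region", "A_pct", "C_pct", "G_pct", "T_pct", "GC_pct", "size_bp", "genome_pct"]


def _cis_blocks(gene: GeneModel, exons: list[FeatureInterval]) -> list[list[FeatureInterval]]:
    """Group a gene's exons into cis-spliced blocks.

    For an ordinary gene all exons form one block.  For a trans-spliced gene
    a block is a maximal run of annotation-order-consecutive exons on one
    strand whose genomic coordinates advance in transcription direction;
    only gaps inside a block are cis introns.
    """
    if not gene.trans_spliced:
        return [exons]
    blocks: list[list[FeatureInterval]] = [[exons[0]]]
    for prev, cur in zip(exons, exons[1:]):
        colinear = (
            prev.strand == cur.strand
            and ((cur.start > prev.end) if cur.strand == "+" else (cur.end < prev.start))
        )
        if colinear:
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    return blocks


def _intron_intervals(record: MitogenomeRecord) -> list[FeatureInterval]:
    introns = []
    for gene in record.protein_genes:
        for exons in gene.all_exon_sets():
            for block in _cis_blocks(gene, exons):
                ordered = sorted(block, key=lambda iv: iv.start)
                for a, b in zip(ordered, ordered[1:]):
                    if b.start > a.end + 1:
                        introns.append(FeatureInterval(a.end + 1, b.start - 1, a.strand))
    return introns


def _paint(labels: np.ndarray, iv: FeatureInterval, code: int, n: int) -> None:
    for pos in iv.positions(n):
        labels[pos - 1] = code


def compute_composition(record: MitogenomeRecord) -> pd.DataFrame:
    """Per-region base composition table.

    Overlapping features are resolved by precedence (protein exon >
    cis intron > tRNA > rRNA > non-coding) so region sizes partition the
    genome.  Ns are excluded from the percentage numerators and
    denominators but counted in region sizes.
    """
    n = len(record.sequence)
    labels = np.zeros(n, dtype=np.uint8)
    region_exons = {"rRNA": [], "tRNA": [], "pcg_exons": []}
    for gene in record.genes:
        key = "pcg_exons" if gene.is_protein else gene.gene_type
        for exons in gene.all_exon_sets():
            region_exons[key].extend(exons)
    # paint in increasing precedence so higher-precedence regions overwrite
    for iv in region_exons["rRNA"]:
        _paint(labels, iv, _REGION_CODES["rRNA"], n)
    for iv in region_exons["tRNA"]:
        _paint(labels, iv, _REGION_CODES["tRNA"], n)
    for iv in _intron_intervals(record):
        _paint(labels, iv, _REGION_CODES["cis_introns"], n)
    for iv in region_exons["pcg_exons"]:
        _paint(labels, iv, _REGION_CODES["pcg_exons"], n)

    arr = np.frombuffer(record.sequence.residues.encode("ascii"), dtype=np.uint8)
    rows = []

    def row(region: str, mask: np.ndarray) -> None:
        size = int(mask.sum())
        counts = {b: int(((arr == ord(b)) & mask).sum()) for b in "ACGT"}
        acgt = sum(counts.values())
        if acgt:
            pct = {b: round(100.0 * counts[b] / acgt, 2) for b in "ACGT"}
            gc = round(100.0 * (counts["C"] + counts["G"]) / acgt, 2)
        else:
            pct = {b: 0.0 for b in "ACGT"}
            gc = 0.0
        rows.append(
            {
                "region": region,
                "A_pct": pct["A"],
                "C_pct": pct["C"],
                "G_pct": pct["G"],
                "T_pct": pct["T"],
                "GC_pct": gc,
                "size_bp": size,
                "genome_pct": round(100.0 * size / n, 2),
            }
        )

    row("whole_genome", np.ones(n, dtype=bool))
    row("pcg_exons", labels == _REGION_CODES["pcg_exons"])
    row("cis_introns", labels == _REGION_CODES["cis_introns"])
    row("tRNA", labels == _REGION_CODES["tRNA"])
    row("rRNA", labels == _REGION_CODES["rRNA"])
    row("non_coding", labels == 0)
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def write_composition_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.2f")
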