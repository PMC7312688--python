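"""Codon usage, RSCU, amino-acid profiles and C-to-U editing-aware codons.

Plant mitochondria translate with the standard genetic code, but
post-transcriptional C-to-U RNA editing can restore canonical codons:
an annotated ACG start is read as AUG and a CGA stop as UGA after editing.
Codon totals therefore exclude terminal *standard* stop codons (TAA, TAG,
TGA) while retaining a non-stop terminal codon such as a pre-editing CGA,
which is what makes whole-genome codon counts reconcile with summed gene
lengths.

RSCU (relative synonymous codon usage) of a codon is its observed count
divided by the count expected were usage uniform within its synonymous
family; the family mean is exactly 1 whenever the family is observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .genome_io import MitogenomeRecord, extract_cds

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STANDARD_STOPS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)  # sense codons only
SENSE_CODONS = sorted(CODON_TO_AA)
FAMILIES: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, []).append(_c)
for _aa in FAMILIES:
    FAMILIES[_aa].sort()

ALL_CODONS = sorted(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)


class CodonError(ValueError):
    pass


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise CodonError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


# ---------------------------------------------------------------------------
# codon usage and RSCU
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_codons: int
    rscu: dict[str, float] = field(default_factory=dict)
    unobserved_families: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "aa": CODON_TO_AA.get(c, "*"),
                "count": self.counts.get(c, 0),
                "rscu": round(self.rscu.get(c, 0.0), 4),
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def codon_counts(cds_set: list[str]) -> CodonUsageTable:
    """Pooled per-codon counts over a CDS set.

    A terminal codon that is a standard stop is excluded; any other terminal
    codon (e.g. a CGA awaiting editing to UGA) is counted as a sense codon.
    ``total_codons`` sums sense-codon counts, so internal in-frame standard
    stops (legitimate in pre-editing sequences) are tallied in ``counts``
    but never inflate the total.
    """
    counts: dict[str, int] = {c: 0 for c in ALL_CODONS}
    for cds in cds_set:
        codons = split_codons(cds.upper())
        if codons and codons[-1] in STANDARD_STOPS:
            codons = codons[:-1]
        for c in codons:
            if c not in counts:
                raise CodonError(f"ambiguous codon {c!r}")
            counts[c] += 1
    total = sum(n for c, n in counts.items() if c not in STANDARD_STOPS)
    return CodonUsageTable(counts=counts, total_codons=total)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill in RSCU values; unobserved families get 0 for all members."""
    values: dict[str, float] = {}
    unobserved = []
    for aa, codons in FAMILIES.items():
        fam_total = sum(table.counts.get(c, 0) for c in codons)
        if fam_total == 0:
            unobserved.append(aa)
            for c in codons:
                values[c] = 0.0
            continue
        expected = fam_total / len(codons)
        for c in codons:
            values[c] = table.counts.get(c, 0) / expected
    table.rscu = values
    table.unobserved_families = sorted(unobserved)
    return table


# ---------------------------------------------------------------------------
# amino-acid profile
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidProfile:
    proportions: dict[str, float]

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions).sort_index()


def aa_profile(cds_set: list[str]) -> AminoAcidProfile:
    """Amino-acid composition over all translated residues of a CDS set.

    Terminal stops are dropped; internal in-frame stops (possible before
    RNA editing) are skipped with a warning rather than failing.
    """
    counts: dict[str, int] = {}
    internal_stops = 0
    for cds in cds_set:
        codons = split_codons(cds.upper())
        if codons and codons[-1] in STANDARD_STOPS:
            codons = codons[:-1]
        for c in codons:
            aa = CODON_TO_AA.get(c)
            if aa is None:
                internal_stops += 1
                continue
            counts[aa] = counts.get(aa, 0) + 1
    if internal_stops:
        logger.warning("skipped %d internal stop codons in amino-acid profile", internal_stops)
    total = sum(counts.values())
    if total == 0:
        raise CodonError("no translatable codons in input")
    return AminoAcidProfile({aa: n / total for aa, n in sorted(counts.items())})


# ---------------------------------------------------------------------------
# per-gene codon table (start/stop/editing flags)
# ---------------------------------------------------------------------------

@dataclass
class CodonTableRow:
    gene: str
    length: int
    start_codon: str
    stop_codon: str
    editing_flag: str  # none | start_ACG_to_AUG | stop_CGA_to_UGA
    direction: str  # F | R | F/R


def _direction(strands: set[str]) -> str:
    if strands == {"+"}:
        return "F"
    if strands == {"-"}:
        return "R"
    return "F/R"


def codon_table(record: MitogenomeRecord) -> list[CodonTableRow]:
    """One row per unique protein-coding gene: length, start/stop codons,
    strand direction, and the editing flag for ACG starts / CGA stops."""
    rows = []
    for gene in record.protein_genes:
        cds = extract_cds(record, gene.name)
        start, stop = cds[:3], cds[-3:]
        if start == "ACG":
            flag = "start_ACG_to_AUG"
        elif stop == "CGA":
            flag = "stop_CGA_to_UGA"
        else:
            flag = "none"
        rows.append(
            CodonTableRow(
                gene=gene.name,
                length=len(cds),
                start_codon=start,
                stop_codon=stop,
                editing_flag=flag,
                direction=_direction({e.strand for e in gene.exons}),
            )
        )
    rows.sort(key=lambda r: r.gene)
    return rows


def codon_table_frame(rows: list[CodonTableRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "length_bp": r.length,
                "start_codon": r.start_codon,
                "stop_codon": r.stop_codon,
                "editing_flag": r.editing_flag,
                "direction": r.direction,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# C-to-U editing application
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditingSite:
    """A C-to-U editing site addressed by codon index (1-based) and
    position within the codon (1..3)."""

    gene: str
    codon_index: int
    position_in_codon: int

    def __post_init__(self) -> None:
        if self.codon_index < 1 or self.position_in_codon not in (1, 2, 3):
            raise CodonError(f"invalid editing site {self}")

    @property
    def nt_offset(self) -> int:
        """0-based nucleotide offset within the CDS."""
        return (self.codon_index - 1) * 3 + self.position_in_codon - 1


def apply_editing(cds: str, sites: list[EditingSite]) -> str:
    """Apply C-to-U edits (C->T in DNA representation) at the given sites.

    A site addressing a T is treated as already edited (no-op), which makes
    the operation idempotent; a site addressing A, G or N is a validation
    error because C-to-U machinery cannot act there.
    """
    seq = list(cds.upper())
    for site in sites:
        off = site.nt_offset
        if off >= len(seq):
            raise CodonError(f"editing site {site} beyond CDS of length {len(seq)}")
        if seq[off] == "T":
            continue
        if seq[off] != "C":
            raise CodonError(
                f"editing site {site} addresses {seq[off]!r}, expected C"
            )
        seq[off] = "T"
    return "".join(seq)


def read_editing_sites(path) -> dict[str, list[EditingSite]]:
    """Read a TSV with columns gene, codon_index, pos_in_codon."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "codon_index", "pos_in_codon"}
    if not required.issubset(df.columns):
        raise CodonError(f"editing sites file needs columns {sorted(required)}")
    out: dict[str, list[EditingSite]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene), []).append(
            EditingSite(str(row.gene), int(row.codon_index), int(row.pos_in_codon))
        )
    return out
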