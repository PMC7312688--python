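"""Cross-species gene content and amino-acid-profile comparison.

Organelle annotations use inconsistent gene nomenclature across GenBank
records (ccmFC vs ccmFc vs ccmF_C, rrn26 vs rrnL, ...), so presence/absence
is decided on synonym-normalized names; anything unmatched is logged,
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .codons import AminoAcidProfile, aa_profile
from .genome_io import MitogenomeRecord, extract_cds

logger = logging.getLogger(__name__)

#: editable synonym map: variant (lowercase, stripped) -> canonical name
GENE_SYNONYMS: dict[str, str] = {
    "ccmfc": "ccmFC",
    "ccmf_c": "ccmFC",
    "ccmfc_": "ccmFC",
    "ccmfn": "ccmFN",
    "ccmf_n": "ccmFN",
    "matr": "matR",
    "mttb": "mttB",
    "rrn26": "rrnL",
    "rrn18": "rrnS",
    "rrn5": "rrn5",
    "coxii": "cox2",
    "coxi": "cox1",
    "coxiii": "cox3",
    "nad4l": "nad4L",
}

#: the standard protein-coding catalog used for presence/absence matrices
PCG_CATALOG: list[str] = [
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "cob",
    "cox1", "cox2", "cox3",
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFC", "ccmFN",
    "rps1", "rps3", "rps4", "rps7", "rps10", "rps12", "rps14", "rps19",
    "rpl2", "rpl5", "rpl10", "rpl16",
    "matR", "mttB",
    "sdh3", "sdh4",
]


def normalize_gene_name(name: str) -> str:
    key = name.strip().replace("-", "").replace(" ", "").lower()
    if key in GENE_SYNONYMS:
        return GENE_SYNONYMS[key]
    # canonical names pass through with their field capitalization
    for canonical in PCG_CATALOG:
        if key == canonical.lower():
            return canonical
    return name.strip()


@dataclass
class GeneContentMatrix:
    species: list[str]
    genes: list[str]
    presence: pd.DataFrame  # species x genes, boolean

    def to_frame(self) -> pd.DataFrame:
        return self.presence


@dataclass
class ProfileComparison:
    profiles: dict[str, AminoAcidProfile]
    flagged: list[str]
    gaps: dict[str, float] = field(default_factory=dict)


def build_gene_content_matrix(
    records: list[MitogenomeRecord], catalog: list[str] | None = None
) -> GeneContentMatrix:
    """Presence/absence of catalog genes per record, on normalized names."""
    catalog = list(catalog) if catalog is not None else list(PCG_CATALOG)
    if not catalog:
        raise ValueError("empty gene catalog")
    species = []
    rows = []
    for rec in records:
        label = rec.organism or rec.sequence.identifier
        species.append(label)
        names = set()
        for g in rec.genes:
            norm = normalize_gene_name(g.name)
            if norm != g.name:
                logger.info("%s: normalized gene name %s -> %s", label, g.name, norm)
            names.add(norm)
        unmatched = names - set(catalog) - {normalize_gene_name(c) for c in catalog}
        if unmatched:
            logger.info("%s: genes outside catalog: %s", label, sorted(unmatched))
        rows.append({gene: gene in names for gene in catalog})
    presence = pd.DataFrame(rows, index=species, columns=catalog)
    return GeneContentMatrix(species=species, genes=catalog, presence=presence)


def record_aa_profile(record: MitogenomeRecord) -> AminoAcidProfile:
    """Amino-acid profile over all protein-coding genes of a record."""
    cds_set = [extract_cds(record, g.name) for g in record.protein_genes]
    return aa_profile(cds_set)


def compare_profiles(
    profiles: dict[str, AminoAcidProfile],
    groups: dict[str, str],
    threshold: float = 0.005,
) -> ProfileComparison:
    """Flag amino acids whose between-group mean proportion gap exceeds
    ``threshold`` (absolute).  Exactly two group labels are compared."""
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    unknown = sorted(set(groups) - set(profiles))
    if unknown:
        raise ValueError(f"groups name unknown species: {unknown}")
    all_aas = sorted({aa for p in profiles.values() for aa in p.proportions})
    means = {}
    for label in labels:
        members = [s for s, g in groups.items() if g == label]
        if not members:
            raise ValueError(f"group {label} has no members")
        means[label] = {
            aa: sum(profiles[s].proportions.get(aa, 0.0) for s in members) / len(members)
            for aa in all_aas
        }
    gaps = {aa: abs(means[labels[0]][aa] - means[labels[1]][aa]) for aa in all_aas}
    flagged = sorted([aa for aa, gap in gaps.items() if gap > threshold])
    return ProfileComparison(profiles=profiles, flagged=flagged, gaps=gaps)


def shared_single_copy_genes(records: list[MitogenomeRecord]) -> list[str]:
    """Protein-coding genes present in every record with copy_count 1 everywhere."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    shared: set[str] | None = None
    for rec in records:
        names = {
            normalize_gene_name(g.name)
            for g in rec.protein_genes
            if g.copy_count == 1
        }
        shared = names if shared is None else shared & names
    return sorted(shared or [])
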