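"""Published reference tables for the *Phaseolus vulgaris* mitogenome.

The common bean reference mitogenome (GenBank NC_045135.1) is the
canonical worked example for this package.  Two small published tables
ship with the package so that gene-level codon accounting and the SSR
census summary can be reproduced without network access: the per-gene
profile (length, start/stop codon, strand direction) of its 31 unique
protein-coding genes, and the per-motif-class totals of its 314 perfect
SSRs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codons import STANDARD_STOPS

ACCESSION = "NC_045135.1"


def _data(name: str) -> pd.DataFrame:
    with resources.files("mitokit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_pcg_profile() -> pd.DataFrame:
    """Gene profile of the 31 unique protein-coding genes of NC_045135.1:
    columns gene, length_bp, start_codon, stop_codon, direction."""
    return _data("pvulgaris_pcg_profile.tsv")


def load_ssr_census() -> pd.DataFrame:
    """Published SSR census of NC_045135.1 by motif class (MISA thresholds
    8,4,4,3,3,3): columns motif_class, count."""
    return _data("pvulgaris_ssr_census.tsv")


def coding_codon_total(profile: pd.DataFrame | None = None) -> int:
    """Total sense codons over all protein genes: summed coding length in
    codons minus one terminal codon per gene whose stop is a standard stop
    (a non-stop terminal codon, e.g. a pre-editing CGA, stays counted)."""
    df = profile if profile is not None else load_pcg_profile()
    total = int(df["length_bp"].sum()) // 3
    standard = int(df["stop_codon"].isin(sorted(STANDARD_STOPS)).sum())
    return total - standard
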