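"""Codon usage, RSCU, amino-acid profiles and C-to-U editing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitokit.codons import (
    CODON_TO_AA,
    FAMILIES,
    SENSE_CODONS,
    CodonError,
    EditingSite,
    aa_profile,
    apply_editing,
    codon_counts,
    codon_table,
    rscu,
)
from mitokit.reference import coding_codon_total, load_pcg_profile, load_ssr_census
from mitokit.synthetic import random_cds


def test_single_cds_stop_excluded():
    assert codon_counts(["ATGTAA"]).total_codons == 1


def test_terminal_non_stop_codon_counted():
    # a pre-editing CGA terminal codon is a sense codon and stays in the total
    assert codon_counts(["ATGCGA"]).total_codons == 2


def test_counts_match_brute_force_tally():
    rng = np.random.default_rng(5)
    cds_set = [random_cds(rng, int(rng.integers(10, 60))) for _ in range(50)]
    table = codon_counts(cds_set)
    tally: dict[str, int] = {}
    for cds in cds_set:
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] in ("TAA", "TAG", "TGA"):
            codons = codons[:-1]
        for c in codons:
            tally[c] = tally.get(c, 0) + 1
    assert {c: n for c, n in table.counts.items() if n} == tally
    assert table.total_codons == sum(
        n for c, n in tally.items() if c not in ("TAA", "TAG", "TGA")
    )


def test_non_triplet_input_rejected():
    with pytest.raises(CodonError):
        codon_counts(["ATGA"])


def test_rscu_uniform_usage_is_one():
    cds = "ATG" + "".join(SENSE_CODONS) + "TAA"
    table = rscu(codon_counts([cds]))
    # every codon seen once except ATG (twice): families with equal counts -> 1.0
    for aa, codons in FAMILIES.items():
        if aa == "M":
            continue
        for c in codons:
            assert table.rscu[c] == pytest.approx(1.0)


def test_rscu_phe_three_to_one_split_forced_by_definition():
    table = rscu(codon_counts(["TTT" * 3 + "TTC" + "TAA"]))
    assert table.rscu["TTT"] == pytest.approx(1.5)
    assert table.rscu["TTC"] == pytest.approx(0.5)


def test_rscu_family_mean_is_one_for_observed_families():
    rng = np.random.default_rng(8)
    cds_set = [random_cds(rng, 200) for _ in range(10)]
    table = rscu(codon_counts(cds_set))
    for aa, codons in FAMILIES.items():
        if sum(table.counts[c] for c in codons) == 0:
            assert aa in table.unobserved_families
            continue
        assert np.mean([table.rscu[c] for c in codons]) == pytest.approx(1.0)


def test_aa_profile_single_residue_type():
    prof = aa_profile(["ATGATGTAA"])
    assert prof.proportions == {"M": 1.0}


def test_aa_profile_matches_translation_oracle():
    rng = np.random.default_rng(3)
    cds_set = [random_cds(rng, 40) for _ in range(5)]
    prof = aa_profile(cds_set)
    tally: dict[str, int] = {}
    for cds in cds_set:
        for i in range(0, len(cds) - 3, 3):  # drop terminal stop
            aa = CODON_TO_AA[cds[i : i + 3]]
            tally[aa] = tally.get(aa, 0) + 1
    total = sum(tally.values())
    assert prof.proportions == pytest.approx({aa: n / total for aa, n in tally.items()})
    assert sum(prof.proportions.values()) == pytest.approx(1.0, abs=1e-9)


def test_aa_profile_skips_internal_stop_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="mitokit.codons"):
        prof = aa_profile(["ATGTAAATGTAA"])  # internal TAA
    assert prof.proportions == {"M": 1.0}
    assert "internal stop" in caplog.text


def test_codon_table_editing_flags(record):
    rows = {r.gene: r for r in codon_table(record)}
    assert rows["rps10"].editing_flag == "start_ACG_to_AUG"
    assert rows["nad1"].editing_flag == "start_ACG_to_AUG"
    assert rows["ccmFC"].editing_flag == "stop_CGA_to_UGA"
    assert rows["atp1"].editing_flag == "none"
    assert rows["nad1"].direction == "F/R"  # trans-spliced across strands
    assert rows["cox1"].direction == "R"


def test_apply_editing_restores_start_codon():
    assert apply_editing("ACGAAATAA", [EditingSite("g", 1, 2)]).startswith("ATG")


def test_apply_editing_noop_and_errors():
    cds = "ATGAAACCC"
    assert apply_editing(cds, []) == cds
    with pytest.raises(CodonError):
        apply_editing(cds, [EditingSite("g", 2, 1)])  # addresses an A


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_apply_editing_changes_exactly_sites_and_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    cds = random_cds(rng, 30)
    c_positions = [i for i, b in enumerate(cds) if b == "C"]
    if not c_positions:
        return
    chosen = sorted(
        set(rng.choice(c_positions, size=min(10, len(c_positions)), replace=False))
    )
    sites = [EditingSite("g", p // 3 + 1, p % 3 + 1) for p in chosen]
    edited = apply_editing(cds, sites)
    diffs = [i for i in range(len(cds)) if cds[i] != edited[i]]
    assert diffs == chosen
    assert all(edited[i] == "T" for i in chosen)
    assert apply_editing(edited, sites) == edited  # idempotent


# ---------------------------------------------------------------------------
# published reference-table accounting (common bean, NC_045135.1)
# ---------------------------------------------------------------------------

def test_reference_gene_profile_codon_accounting():
    profile = load_pcg_profile()
    assert len(profile) == 31
    assert int(profile.length_bp.sum()) == 28_725
    assert coding_codon_total(profile) == 9_545
    assert int((profile.stop_codon == "TAA").sum()) == 15
    assert int((profile.start_codon == "ACG").sum()) == 4


def test_reference_ssr_census_proportions():
    census = load_ssr_census()
    total = int(census["count"].sum())
    assert total == 314
    mono = int(census.loc[census.motif_class == "mono", "count"].iloc[0])
    assert round(100 * mono / total, 2) == 44.27
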