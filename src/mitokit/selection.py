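"""Pairwise Ka/Ks estimation per gene (Yang–Nielsen counting framework).

For each orthologous gene pair the coding sequences are aligned through
their protein translations (global Needleman–Wunsch, BLOSUM62, gap open 10
/ extend 0.5), the alignment is back-translated to codons and gapped
columns dropped.  Rates are then estimated in the YN00 style:

1. the transition/transversion ratio kappa is estimated from the
   four-fold degenerate and non-degenerate site classes (K80 applied to
   each class, combined by site-count weighting);
2. synonymous (S) and nonsynonymous (N) site counts are mutational-flux
   expectations per codon under kappa and position-specific F3x4 target
   frequencies estimated jointly from both sequences, with mutations to
   stop codons excluded;
3. observed synonymous/nonsynonymous differences are counted with equal
   weighting over the shortest substitution pathways between differing
   codons (pathways through stop codons excluded when avoidable), keeping
   transitions and transversions separate;
4. multiple hits are corrected with a two-parameter (K80) correction
   applied separately to the synonymous and nonsynonymous classes,
   yielding Ks and Ka.

A two-sided Fisher's exact test on the (synonymous, nonsynonymous) x
(differences, non-differing sites) table screens estimates for validity.
Ks = 0 leaves the ratio undefined (reported as NA downstream), and
saturated distances (log argument <= 0) flag the result unreliable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.stats import fisher_exact

from .codons import CODON_TO_AA, STANDARD_STOPS, split_codons
from .genome_io import MitogenomeRecord, extract_cds

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_BASES = "ACGT"


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


class AlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    gene: str
    pairs: list[tuple[str, str]]

    @property
    def n_codons(self) -> int:
        return len(self.pairs)


@dataclass
class KaKsResult:
    gene: str
    ka: float
    ks: float
    ratio: float | None
    kappa: float
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    p_value: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# protein-guided codon alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def trim_terminal_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:] in STANDARD_STOPS:
        return cds[:-3]
    return cds


def protein_guided_align(cds_a: str, cds_b: str, gene: str = "") -> CodonAlignment:
    """Align two CDSs via their protein translations, back-translate to
    codons, and drop gapped columns and columns containing stop codons."""
    a = trim_terminal_stop(cds_a)
    b = trim_terminal_stop(cds_b)
    cod_a, cod_b = split_codons(a), split_codons(b)
    prot_a = str(Seq(a).translate()).replace("*", "X")
    prot_b = str(Seq(b).translate()).replace("*", "X")
    aligner = _make_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    pairs: list[tuple[str, str]] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            ca, cb = cod_a[i], cod_b[j]
            if ca in STANDARD_STOPS or cb in STANDARD_STOPS:
                continue
            if "N" in ca or "N" in cb:
                continue
            pairs.append((ca, cb))
    if not pairs:
        raise AlignmentError(f"no aligned codons remain for gene {gene or '<unnamed>'}")
    return CodonAlignment(gene=gene, pairs=pairs)


# ---------------------------------------------------------------------------
# site classification and kappa
# ---------------------------------------------------------------------------

def _degeneracy(codon: str, pos: int) -> int:
    """Number of alternative bases at pos that keep the amino acid (0, 1 or 3)."""
    aa = CODON_TO_AA.get(codon)
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if CODON_TO_AA.get(alt) == aa and alt not in STANDARD_STOPS:
            syn += 1
    return syn


def _k80_kappa(p: float, q: float) -> float | None:
    """kappa = alpha/beta from K80 given transition/transversion proportions."""
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None
    alpha = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    beta = -0.25 * math.log(w2)
    if beta <= 0:
        # no transversions observed: kappa unbounded, cap it
        return 50.0 if alpha > 0 else None
    return max(alpha / beta, 1e-6)


def estimate_kappa(pairs: list[tuple[str, str]]) -> tuple[float, list[str]]:
    """kappa from four-fold degenerate and non-degenerate positions.

    Per-class K80 kappa estimates are combined by a site-count weighted
    average; if neither class yields an estimate (e.g. identical
    sequences) kappa falls back to 2 with a flag.
    """
    stats = {4: [0, 0.0, 0.0], 0: [0, 0.0, 0.0]}  # class -> [sites, ts, tv]
    for ca, cb in pairs:
        for pos in range(3):
            da, db = _degeneracy(ca, pos), _degeneracy(cb, pos)
            cls = 4 if (da == 3 and db == 3) else (0 if (da == 0 and db == 0) else None)
            if cls is None:
                continue
            stats[cls][0] += 1
            x, y = ca[pos], cb[pos]
            if x != y:
                stats[cls][1 if _is_transition(x, y) else 2] += 1.0
    flags: list[str] = []
    weighted, weight = 0.0, 0.0
    for cls, (n, ts, tv) in stats.items():
        if n == 0:
            continue
        k = _k80_kappa(ts / n, tv / n)
        if k is not None:
            weighted += k * n
            weight += n
    if weight == 0:
        flags.append("kappa_default")
        return 2.0, flags
    return weighted / weight, flags


# ---------------------------------------------------------------------------
# site counting (F3x4-weighted mutational flux)
# ---------------------------------------------------------------------------

def _f3x4(pairs: list[tuple[str, str]]) -> list[dict[str, float]]:
    """Position-specific base frequencies pooled over both sequences."""
    freqs = [dict.fromkeys(_BASES, 0.0) for _ in range(3)]
    for ca, cb in pairs:
        for pos in range(3):
            freqs[pos][ca[pos]] += 1
            freqs[pos][cb[pos]] += 1
    for pos in range(3):
        tot = sum(freqs[pos].values())
        for b in _BASES:
            freqs[pos][b] = freqs[pos][b] / tot if tot else 0.25
    return freqs


def _codon_site_fractions(codon: str, kappa: float, f3x4) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon (sum = 3)."""
    aa = CODON_TO_AA.get(codon)
    syn_flux = 0.0
    tot_flux = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STANDARD_STOPS:
                continue
            rate = (kappa if _is_transition(codon[pos], b) else 1.0) * f3x4[pos][b]
            tot_flux += rate
            if CODON_TO_AA.get(alt) == aa:
                syn_flux += rate
    if tot_flux == 0:
        return 0.0, 3.0
    s = 3.0 * syn_flux / tot_flux
    return s, 3.0 - s


def count_sites(pairs: list[tuple[str, str]], kappa: float) -> tuple[float, float]:
    """Average synonymous/nonsynonymous site counts over both sequences."""
    f3x4 = _f3x4(pairs)
    s_tot = n_tot = 0.0
    for ca, cb in pairs:
        for c in (ca, cb):
            s, n = _codon_site_fractions(c, kappa, f3x4)
            s_tot += s
            n_tot += n
    return s_tot / 2.0, n_tot / 2.0


# ---------------------------------------------------------------------------
# difference counting (equal pathway weighting)
# ---------------------------------------------------------------------------

def _pathway_steps(ca: str, cb: str):
    """Yield (weight, steps) over valid substitution pathways ca -> cb.

    Pathways passing through stop codons are excluded unless every pathway
    does, in which case all are used.  Each step is (from_base, to_base,
    synonymous: bool).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    orders = list(itertools.permutations(diff_pos))
    pathways = []
    for order in orders:
        cur = ca
        steps = []
        valid = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STANDARD_STOPS:
                valid = False
            # a step into a stop codon classifies as nonsynonymous
            steps.append((cur[pos], cb[pos], CODON_TO_AA.get(nxt) == CODON_TO_AA.get(cur)))
            cur = nxt
        pathways.append((valid, steps))
    valid_paths = [steps for ok, steps in pathways if ok]
    chosen = valid_paths if valid_paths else [steps for _, steps in pathways]
    w = 1.0 / len(chosen)
    for steps in chosen:
        yield w, steps


def count_differences(pairs: list[tuple[str, str]]):
    """Fractional synonymous/nonsynonymous differences split by ts/tv.

    Returns (s_diffs, n_diffs, s_ts, s_tv, n_ts, n_tv).
    """
    sd = nd = s_ts = s_tv = n_ts = n_tv = 0.0
    for ca, cb in pairs:
        if ca == cb:
            continue
        for w, steps in _pathway_steps(ca, cb):
            for frm, to, syn in steps:
                ts = _is_transition(frm, to)
                if syn:
                    sd += w
                    s_ts, s_tv = (s_ts + w, s_tv) if ts else (s_ts, s_tv + w)
                else:
                    nd += w
                    n_ts, n_tv = (n_ts + w, n_tv) if ts else (n_ts, n_tv + w)
    return sd, nd, s_ts, s_tv, n_ts, n_tv


def _k80_distance(p: float, q: float) -> float | None:
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d if d != 0 else 0.0


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

def yn_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Ka, Ks and their ratio for a codon alignment (see module docstring)."""
    pairs = alignment.pairs
    if not pairs:
        raise AlignmentError("empty codon alignment")
    kappa, flags = estimate_kappa(pairs)
    s_sites, n_sites = count_sites(pairs, kappa)
    sd, nd, s_ts, s_tv, n_ts, n_tv = count_differences(pairs)

    if s_sites > 0:
        ks = _k80_distance(s_ts / s_sites, s_tv / s_sites)
    else:
        ks = 0.0 if sd == 0 else None
    if n_sites > 0:
        ka = _k80_distance(n_ts / n_sites, n_tv / n_sites)
    else:
        ka = 0.0 if nd == 0 else None

    if ks is None or ka is None:
        flags.append("saturated")
        ks = float("nan") if ks is None else ks
        ka = float("nan") if ka is None else ka
        ratio = None
    elif ks == 0.0:
        ratio = None
        if nd or sd:
            flags.append("ks_zero")
    else:
        ratio = ka / ks
    return KaKsResult(
        gene=alignment.gene,
        ka=ka,
        ks=ks,
        ratio=ratio,
        kappa=kappa,
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=nd,
        s_diffs=sd,
        flags=flags,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_exact_2x2(table: list[list[int]]) -> float:
    """Two-sided Fisher's exact test probability for a 2x2 count table."""
    return float(fisher_exact(table, alternative="two-sided").pvalue)


def fisher_validity(result: KaKsResult) -> float:
    """Two-sided Fisher's exact test on (syn, nonsyn) x (diffs, non-diffs).

    Fractional site and difference counts are rounded half-up.  A table
    with a zero margin is degenerate and scored p = 1 with a flag.
    """
    s = _round_half_up(result.s_sites)
    n = _round_half_up(result.n_sites)
    sd = min(_round_half_up(result.s_diffs), s)
    nd = min(_round_half_up(result.n_diffs), n)
    table = [[sd, s - sd], [nd, n - nd]]
    if min(sum(table[0]), sum(table[1]), table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
        result.flags.append("fisher_degenerate")
        result.p_value = 1.0
        return 1.0
    p = fisher_exact_2x2(table)
    result.p_value = p
    return p


def genome_pair_scan(
    record_a: MitogenomeRecord, record_b: MitogenomeRecord
) -> list[KaKsResult]:
    """Ka/Ks for every protein-coding gene shared by name between two records."""
    names_a = {g.name for g in record_a.protein_genes}
    names_b = {g.name for g in record_b.protein_genes}
    results = []
    for name in sorted(names_a & names_b):
        try:
            aln = protein_guided_align(
                extract_cds(record_a, name), extract_cds(record_b, name), gene=name
            )
        except (AlignmentError, ValueError) as exc:
            logger.warning("skipping gene %s: %s", name, exc)
            continue
        res = yn_kaks(aln)
        fisher_validity(res)
        results.append(res)
    skipped = sorted(names_a.symmetric_difference(names_b))
    if skipped:
        logger.info("genes absent from one genome, skipped: %s", ", ".join(skipped))
    return results


def kaks_frame(results: list[KaKsResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "Ka": round(r.ka, 4),
                "Ks": round(r.ks, 4),
                "ratio": "NA" if r.ratio is None else round(r.ratio, 4),
                "p_value": "NA" if r.p_value is None else round(r.p_value, 6),
                "N_sites": round(r.n_sites, 1),
                "S_sites": round(r.s_sites, 1),
                "flags": ";".join(r.flags),
            }
            for r in results
        ],
        columns=["gene", "Ka", "Ks", "ratio", "p_value", "N_sites", "S_sites", "flags"],
    )
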