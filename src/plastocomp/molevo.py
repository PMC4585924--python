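"""Protein-guided codon alignment, Nei–Gojobori (NG86) Ks/Ka estimation and
the generation-time molecular clock.

The NG86 counting method classifies each codon position fractionally as
synonymous or non-synonymous by enumerating its three single-nucleotide
neighbours under translation table 11 (neighbours that are stop codons are
excluded from the denominator), counts synonymous/non-synonymous differences
between aligned codons by averaging over all minimal substitution pathways
(pathways through stop codons excluded), and corrects the proportions with
the Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p).

Divergence times follow the generation-time clock: the number of elapsed
generations is mean Ks divided by the per-generation substitution rate, and
each assumed generation time (years per generation) converts generations to
years.  By convention the generation count is Ks/mu; set ``per_lineage=True``
to halve it (two diverging lineages each accumulating half the distance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .genome_io import (AnnotatedGenome, TRANSLATION_TABLE,
                        extract_cds_and_upstream)

logger = logging.getLogger("plastocomp")

BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE]
STOP_CODONS = frozenset(_TABLE.stop_codons)
#: codon -> amino acid for the 61 sense codons of table 11
CODON_AA = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_AA))

#: Default per-generation substitution rate (unicellular green algae,
#: nuclear; plastid and nuclear rates are taken as similar).
DEFAULT_MU = 3.23e-10
#: Default generation times in years: 24 h for a heterotroph, 72 h for an
#: autotroph.
DEFAULT_GENERATION_TIMES = {"heterotroph": 0.00274, "autotroph": 0.008219}


def translate(cds: str) -> str:
    return "".join(CODON_AA.get(cds[i: i + 3], "X")
                   for i in range(0, len(cds) - 2, 3))


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one sense codon.

    Each of the three positions contributes the fraction of its non-stop
    single-nucleotide neighbours that are synonymous; the two fractions at a
    position sum to 1, so s + n == 3 exactly.
    """
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1:]
            if neighbour in STOP_CODONS:
                continue
            valid += 1
            if CODON_AA[neighbour] == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


def _step_class(c_from: str, c_to: str) -> int:
    """1 if the single-nucleotide step is synonymous, else 0."""
    return 1 if CODON_AA.get(c_from) == CODON_AA.get(c_to) else 0


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two aligned
    sense codons, averaged over all minimal substitution pathways.

    Pathways passing through a stop codon are excluded; in the (rare) case
    that every pathway is blocked, all pathways are used with steps into or
    out of a stop counted as non-synonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[int, int, bool]:
        syn = non = 0
        cur = c1
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            syn_step = _step_class(cur, nxt)
            syn += syn_step
            non += 1 - syn_step
            cur = nxt
        return syn, non, through_stop

    paths = [walk(order) for order in permutations(diff_pos)]
    valid = [(s, n) for s, n, blocked in paths if not blocked]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance for a proportion of differences; None when saturated
    (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    gene: str
    codons_a: list[str]  # aligned codon columns; '---' marks a gap
    codons_b: list[str]
    n_codons_compared: int  # columns where both sequences have a codon


class CodonAlignmentError(ValueError):
    """Raised when a gene cannot be codon-aligned (e.g. internal stop)."""


def _prepare_cds(cds: str, gene: str, label: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        logger.warning("%s (%s): length %d not divisible by 3; trailing %d nt "
                       "trimmed", gene, label, len(cds), len(cds) % 3)
        cds = cds[: len(cds) - len(cds) % 3]
    codons = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise CodonAlignmentError(
                f"{gene} ({label}): internal stop codon {c} at codon {i + 1}")
        if any(b not in BASES for b in c):
            raise CodonAlignmentError(
                f"{gene} ({label}): ambiguous codon {c} at codon {i + 1}")
    if not codons:
        raise CodonAlignmentError(f"{gene} ({label}): empty coding sequence")
    return codons


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_PROT_ALIGNER = _protein_aligner()


def align_codons(cds_a: str, cds_b: str, gene: str = "") -> CodonAlignment:
    """Protein-guided pairwise codon alignment.

    Both coding sequences are translated (table 11), the proteins are
    globally aligned (BLOSUM62, gap open -11 / extend -1), and the protein
    alignment is back-translated so that gaps occur only in whole-codon
    units.  Terminal stop codons are trimmed; internal stops reject the gene.
    """
    codons_a = _prepare_cds(cds_a, gene, "A")
    codons_b = _prepare_cds(cds_b, gene, "B")
    prot_a = "".join(CODON_AA[c] for c in codons_a)
    prot_b = "".join(CODON_AA[c] for c in codons_b)
    if prot_a == prot_b:
        rows = (prot_a, prot_b)
    else:
        aln = _PROT_ALIGNER.align(prot_a, prot_b)[0]
        rows = (str(aln[0]), str(aln[1]))

    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = compared = 0
    for ca, cb in zip(*rows):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(codons_a[ia])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(codons_b[ib])
            ib += 1
        if ca != "-" and cb != "-":
            compared += 1
    return CodonAlignment(gene, out_a, out_b, compared)


# ---------------------------------------------------------------------------
# Ks/Ka estimation
# ---------------------------------------------------------------------------


@dataclass
class KsKaResult:
    gene: str
    n_codons: int
    S: float  # synonymous sites (averaged over the two sequences)
    N: float
    Sd: float  # pathway-averaged synonymous differences
    Nd: float
    pS: float | None
    pN: float | None
    ks: float | None
    ka: float | None
    omega: float | None
    saturated: bool


def ng86(alignment: CodonAlignment) -> KsKaResult:
    """NG86 counting estimate of Ks and Ka from a codon alignment."""
    if alignment.n_codons_compared < 1:
        raise ValueError(f"{alignment.gene}: no comparable codons")
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if "-" in ca or "-" in cb:
            continue
        n_codons += 1
        s_a += codon_sites(ca)[0]
        s_b += codon_sites(cb)[0]
        d = codon_differences(ca, cb)
        sd += d[0]
        nd += d[1]
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else None
    pN = nd / N if N > 0 else None
    ks = jukes_cantor(pS) if pS is not None else None
    ka = jukes_cantor(pN) if pN is not None else None
    saturated = (pS is not None and pS >= 0.75) or (ks is not None and ks >= 1.0)
    omega = ka / ks if (ks is not None and ka is not None and ks > 0) else None
    return KsKaResult(alignment.gene, n_codons, S, N, sd, nd, pS, pN,
                      ks, ka, omega, saturated)


def mean_ks(results: list[KsKaResult], policy: str = "unweighted") -> float:
    """Average Ks over genes with a defined Ks.

    Genes whose correction is undefined (pS >= 3/4) have no Ks and are
    excluded; a gene flagged saturated merely because Ks >= 1 still carries a
    defined distance and is averaged.  ``policy='unweighted'`` is the plain
    per-gene mean; ``'site_weighted'`` weights each gene by its synonymous
    site count.
    """
    usable = [r for r in results if r.ks is not None]
    if not usable:
        raise ValueError("no gene with a defined Ks")
    if policy == "unweighted":
        return sum(r.ks for r in usable) / len(usable)
    if policy == "site_weighted":
        wsum = sum(r.S for r in usable)
        return sum(r.ks * r.S for r in usable) / wsum
    raise ValueError(f"unknown averaging policy {policy!r}")


def kska_table(
    A: AnnotatedGenome, B: AnnotatedGenome
) -> tuple[pd.DataFrame, list[KsKaResult]]:
    """Per-gene Ks/Ka for every protein-coding gene shared by name between
    two genomes.  Genes that fail codon alignment are skipped with a warning.
    """
    names_a = {f.name for f in A.features if f.gene_type == "protein"}
    names_b = {f.name for f in B.features if f.gene_type == "protein"}
    results: list[KsKaResult] = []
    for name in sorted(names_a & names_b):
        cds_a = extract_cds_and_upstream(A, name, 0).cds
        cds_b = extract_cds_and_upstream(B, name, 0).cds
        try:
            aln = align_codons(cds_a, cds_b, gene=name)
            results.append(ng86(aln))
        except (CodonAlignmentError, ValueError) as exc:
            logger.warning("skipping %s: %s", name, exc)
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_codons": [r.n_codons for r in results],
            "S": [r.S for r in results],
            "N": [r.N for r in results],
            "Sd": [r.Sd for r in results],
            "Nd": [r.Nd for r in results],
            "Ks": [r.ks for r in results],
            "Ka": [r.ka for r in results],
            "omega": [r.omega for r in results],
            "saturated": [r.saturated for r in results],
        }
    )
    return df, results


# ---------------------------------------------------------------------------
# Generation-time clock
# ---------------------------------------------------------------------------


@dataclass
class DivergenceEstimate:
    mean_ks: float
    mu: float
    n_generations: float
    per_lineage: bool
    times_years: dict[str, float]
    t_low_years: float
    t_high_years: float


def divergence_time(
    mean_ks_value: float,
    mu: float = DEFAULT_MU,
    generation_times: dict[str, float] | None = None,
    per_lineage: bool = False,
) -> DivergenceEstimate:
    """Convert a mean synonymous distance into generations and years.

    n_generations = mean Ks / mu (halved when ``per_lineage`` is set), and
    each lifestyle's generation time (years per generation) converts
    generations to years; the low/high window spans the provided lifestyles.
    """
    if mu <= 0:
        raise ValueError("substitution rate mu must be > 0")
    if mean_ks_value < 0:
        raise ValueError("mean Ks must be >= 0")
    gens = generation_times or DEFAULT_GENERATION_TIMES
    if not gens or any(g <= 0 for g in gens.values()):
        raise ValueError("generation times must be positive")
    n_generations = mean_ks_value / mu
    if per_lineage:
        n_generations /= 2.0
    times = {k: n_generations * v for k, v in gens.items()}
    return DivergenceEstimate(
        mean_ks=mean_ks_value,
        mu=mu,
        n_generations=n_generations,
        per_lineage=per_lineage,
        times_years=times,
        t_low_years=min(times.values()),
        t_high_years=max(times.values()),
    )
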