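"""Name-based gene-content comparison and pairwise identity profiles.

Cross-genome orthology here is by normalized gene name (tRNAs keep their
anticodon, so trnL(GAG) != trnL(UAG)).  Gene counts for the shared/lost
accounting use distinct names: duplicate copies inside inverted repeats
collapse to one name for the set algebra but are reported separately.

Identity is computed from an implemented global pairwise alignment with
match +1, mismatch -1, gap open -2, gap extend -1; identity = matching
columns / total alignment columns (gap columns count in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .genome_io import AnnotatedGenome, extract_cds_and_upstream

NUC_MATCH = 1
NUC_MISMATCH = -1
NUC_GAP_OPEN = -2
NUC_GAP_EXTEND = -1


@dataclass
class ContentComparison:
    id_a: str
    id_b: str
    shared: set[str]
    only_in_a: set[str]
    only_in_b: set[str]
    n_a: int
    n_b: int
    n_shared: int
    lost_from_b_by_category: dict[str, int] = field(default_factory=dict)
    duplicated_in_a: dict[str, int] = field(default_factory=dict)
    duplicated_in_b: dict[str, int] = field(default_factory=dict)


def _duplicates(genome: AnnotatedGenome) -> dict[str, int]:
    counts: dict[str, int] = {}
    for name in genome.gene_names:
        counts[name] = counts.get(name, 0) + 1
    return {k: v for k, v in counts.items() if v > 1}


def compare_content(A: AnnotatedGenome, B: AnnotatedGenome) -> ContentComparison:
    """Set algebra on distinct normalized gene names, with a per-category
    breakdown of the genes present in A but lost from B."""
    names_a = A.distinct_names()
    names_b = B.distinct_names()
    shared = names_a & names_b
    only_a = names_a - names_b
    only_b = names_b - names_a

    cat_of = {f.name: f.category for f in A.features}
    lost_by_cat: dict[str, int] = {}
    for name in only_a:
        cat = cat_of[name]
        lost_by_cat[cat] = lost_by_cat.get(cat, 0) + 1

    return ContentComparison(
        id_a=A.id,
        id_b=B.id,
        shared=shared,
        only_in_a=only_a,
        only_in_b=only_b,
        n_a=len(names_a),
        n_b=len(names_b),
        n_shared=len(shared),
        lost_from_b_by_category=dict(sorted(lost_by_cat.items())),
        duplicated_in_a=_duplicates(A),
        duplicated_in_b=_duplicates(B),
    )


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------


def make_nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NUC_MATCH
    aligner.mismatch_score = NUC_MISMATCH
    aligner.open_gap_score = NUC_GAP_OPEN
    aligner.extend_gap_score = NUC_GAP_EXTEND
    return aligner


_ALIGNER = make_nucleotide_aligner()


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two nucleotide sequences; returns the two gapped
    rows of the (deterministic, first-optimal) alignment."""
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def alignment_identity(row_a: str, row_b: str) -> float:
    """Matching columns over total alignment columns."""
    if not row_a:
        return 1.0
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return matches / len(row_a)


def pairwise_identity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    return alignment_identity(*align_pair(a, b))


def window_identities(row_a: str, row_b: str, window: int = 100) -> list[float]:
    """Identity in consecutive ``window``-column slices of an alignment."""
    out = []
    for i in range(0, len(row_a), window):
        out.append(alignment_identity(row_a[i: i + window], row_b[i: i + window]))
    return out


def gene_identity_profile(
    A: AnnotatedGenome,
    B: AnnotatedGenome,
    window: int = 100,
    upstream_bp: int = 50,
) -> pd.DataFrame:
    """Per-shared-gene identity table: coding-sequence identity, mean identity
    over ``window``-bp alignment windows, and 5'UTR (upstream) identity.

    Columns: gene, type, category, cds_identity, mean_window_identity,
    upstream_identity, n_windows.
    """
    comp = compare_content(A, B)
    type_of = {f.name: f.gene_type for f in A.features}
    cat_of = {f.name: f.category for f in A.features}
    rows = []
    for name in sorted(comp.shared):
        ext_a = extract_cds_and_upstream(A, name, upstream_bp)
        ext_b = extract_cds_and_upstream(B, name, upstream_bp)
        row_a, row_b = align_pair(ext_a.cds, ext_b.cds)
        wins = window_identities(row_a, row_b, window)
        up_identity = pairwise_identity(ext_a.upstream, ext_b.upstream) \
            if upstream_bp else float("nan")
        rows.append(
            {
                "gene": name,
                "type": type_of[name],
                "category": cat_of[name],
                "cds_identity": alignment_identity(row_a, row_b),
                "mean_window_identity": sum(wins) / len(wins),
                "upstream_identity": up_identity,
                "n_windows": len(wins),
            }
        )
    return pd.DataFrame(rows)
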