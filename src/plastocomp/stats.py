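"""Per-genome compactness metrics: size, GC/AT, non-coding fraction,
mean intergenic distance, gene counts, inverted-repeat detection.

Coding coverage is the union of all annotated gene features on the circle
(overlaps counted once); "non-coding" is everything not covered.  The mean
intergenic distance is total uncovered length divided by the number of
maximal uncovered gaps between consecutive genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import AnnotatedGenome, revcomp


@dataclass
class IRReport:
    present: bool
    length: int = 0
    # half-open coordinates of the two arms on the forward strand
    first_arm: tuple[int, int] | None = None
    second_arm: tuple[int, int] | None = None


@dataclass
class GenomeStats:
    genome_id: str
    size_bp: int
    gc_percent: float
    at_percent: float
    noncoding_percent: float
    mean_intergenic_bp: float
    n_gaps: int
    n_protein: int
    n_rRNA: int
    n_tRNA: int
    has_inverted_repeat: bool
    ir_length_bp: int
    no_features: bool = False


def _merged_coverage(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    """Union of feature intervals on the circle, as sorted linear intervals
    in [0, L) (a wrap interval contributes two pieces)."""
    L = len(genome)
    pieces = []
    for f in genome.features:
        if f.wraps:
            pieces.append((f.start, L))
            if f.end > 0:
                pieces.append((0, f.end))
        else:
            pieces.append((f.start, f.end))
    if not pieces:
        return []
    pieces.sort()
    merged = [list(pieces[0])]
    for a, b in pieces[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def coverage_gaps(genome: AnnotatedGenome) -> list[tuple[int, int]]:
    """Maximal uncovered arcs of the circle, half-open; a gap spanning the
    origin is reported as (start, end) with end <= start."""
    L = len(genome)
    merged = _merged_coverage(genome)
    if not merged:
        return [(0, 0)]  # single gap covering the whole circle
    gaps = []
    for (a0, b0), (a1, _b1) in zip(merged, merged[1:]):
        if a1 > b0:
            gaps.append((b0, a1))
    # arc from the last covered piece back around to the first
    first_a, _ = merged[0]
    _, last_b = merged[-1]
    if last_b < L or first_a > 0:
        if not (last_b == L and first_a == 0):
            gaps.append((last_b % L, first_a))
    return gaps


def _gap_length(gap: tuple[int, int], L: int) -> int:
    a, b = gap
    if a == b == 0 and L > 0:
        return L  # degenerate "whole circle" gap
    return (b - a) % L if (b - a) % L != 0 else (L if a == b else 0)


def genome_stats(genome: AnnotatedGenome) -> GenomeStats:
    """Compute the compactness summary for one annotated genome."""
    L = len(genome)
    seq = genome.sequence
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at if gc + at else 1
    counts = genome.counts_by_type()

    no_features = not genome.features
    if no_features:
        noncoding = 100.0
        mean_gap = float(L)
        n_gaps = 1
    else:
        covered = sum(b - a for a, b in _merged_coverage(genome))
        uncovered = L - covered
        noncoding = 100.0 * uncovered / L
        gaps = [g for g in coverage_gaps(genome) if _gap_length(g, L) > 0]
        n_gaps = len(gaps)
        mean_gap = uncovered / n_gaps if n_gaps else 0.0

    ir = detect_inverted_repeat(genome)
    return GenomeStats(
        genome_id=genome.id,
        size_bp=L,
        gc_percent=100.0 * gc / denom,
        at_percent=100.0 * at / denom,
        noncoding_percent=noncoding,
        mean_intergenic_bp=mean_gap,
        n_gaps=n_gaps,
        n_protein=counts["protein"],
        n_rRNA=counts["rRNA"],
        n_tRNA=counts["tRNA"],
        has_inverted_repeat=ir.present,
        ir_length_bp=ir.length,
        no_features=no_features,
    )


def detect_inverted_repeat(
    genome: AnnotatedGenome, min_len: int = 1000, seed_k: int = 25
) -> IRReport:
    """Longest pair of reverse-complement repeats >= ``min_len`` at distinct,
    non-overlapping loci (the canonical plastid IR), by exact k-mer seeding
    and ungapped extension."""
    if min_len < 100:
        raise ValueError("min_len must be >= 100")
    seq = genome.sequence
    L = len(seq)
    if L < 2 * min_len:
        return IRReport(False)
    rc = revcomp(seq)

    seeds: dict[str, list[int]] = {}
    for i in range(0, L - seed_k + 1):
        seeds.setdefault(seq[i: i + seed_k], []).append(i)

    best = IRReport(False)
    seen: set[tuple[int, int]] = set()
    step = max(1, seed_k // 2)
    for j in range(0, L - seed_k + 1, step):
        kmer = rc[j: j + seed_k]
        for i in seeds.get(kmer, ()):
            # rc[j:j+k] equals revcomp of seq[L-j-k : L-j]
            a, b = i, i + seed_k           # arm 1 (forward)
            c, d = L - j - seed_k, L - j   # arm 2 (its revcomp elsewhere)
            if (a, c) in seen:
                continue
            # extend while seq[a..b) == revcomp(seq[c..d))
            while a > 0 and d < L and seq[a - 1] == _COMP[seq[d]]:
                a -= 1
                d += 1
            while b < L and c > 0 and seq[b] == _COMP[seq[c - 1]]:
                b += 1
                c -= 1
            seen.add((a, c))
            length = b - a
            if length >= min_len and length > best.length:
                lo, hi = sorted([(a, b), (c, d)])
                if lo[1] <= hi[0]:  # distinct, non-overlapping arms
                    best = IRReport(True, length, lo, hi)
    return best


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def stats_table(genomes: list[AnnotatedGenome]):
    """Compactness metrics for several genomes as a DataFrame (one row per
    genome, columns mirroring the standard ptDNA feature tables)."""
    import pandas as pd

    rows = []
    for g in genomes:
        s = genome_stats(g)
        rows.append(
            {
                "genome": s.genome_id,
                "size_bp": s.size_bp,
                "ncDNA_percent": round(s.noncoding_percent, 2),
                "mean_intergenic_bp": round(s.mean_intergenic_bp, 1),
                "n_protein": s.n_protein,
                "n_rRNA": s.n_rRNA,
                "n_tRNA": s.n_tRNA,
                "gc_percent": round(s.gc_percent, 2),
                "at_percent": round(s.at_percent, 2),
                "inverted_repeat_bp": s.ir_length_bp if s.has_inverted_repeat else 0,
            }
        )
    return pd.DataFrame(rows)
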