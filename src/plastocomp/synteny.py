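"""Circular gene-order comparison via signed permutations.

A genome's gene order (restricted to the genes shared with a partner) is a
signed circular permutation: gene names ordered by position, signed by
strand.  A conserved adjacency is an unordered gene pair that is adjacent on
both circles; the breakpoint distance is the number of shared genes minus
the number of conserved adjacencies, and collinear blocks are the maximal
chains of conserved adjacencies.  Orientation-compatible adjacencies (the
pair also preserves relative strand under one reading direction of the
partner) are reported separately.  All statistics are invariant under
rotation and reflection of either genome.

Following the field convention for plastid gene-order comparison, tRNAs are
excluded by default (protein-coding and rRNA genes only) but can be included
by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import AnnotatedGenome

logger = logging.getLogger("plastocomp")


@dataclass
class SignedPermutation:
    genome_id: str
    order: list[tuple[str, int]]  # (gene name, +1/-1) clockwise around circle

    def __len__(self) -> int:
        return len(self.order)

    def names(self) -> list[str]:
        return [n for n, _ in self.order]


@dataclass
class SyntenyResult:
    id_a: str
    id_b: str
    n_shared: int
    conserved_adjacencies: int
    oriented_adjacencies: int
    adjacency_fraction: float
    n_blocks: int
    breakpoint_distance: int
    defined: bool = True


def shared_gene_set(
    A: AnnotatedGenome, B: AnnotatedGenome, include_trna: bool = False
) -> set[str]:
    def names(g: AnnotatedGenome) -> set[str]:
        return {
            f.name for f in g.features
            if include_trna or f.gene_type != "tRNA"
        }

    return names(A) & names(B)


def to_signed_permutation(
    genome: AnnotatedGenome, shared: set[str]
) -> SignedPermutation:
    """Genes in ``shared``, ordered by start position around the circle,
    signed by strand.  A duplicated shared name (inverted-repeat copy) keeps
    its first occurrence only."""
    seen: set[str] = set()
    order: list[tuple[str, int]] = []
    for f in genome.features:
        if f.name not in shared:
            continue
        if f.name in seen:
            logger.warning("%s: duplicated shared gene %s; keeping first copy",
                           genome.id, f.name)
            continue
        seen.add(f.name)
        order.append((f.name, f.strand))
    return SignedPermutation(genome.id, order)


def canonicalize(
    P: SignedPermutation, anchor: str, reflect: bool = False
) -> SignedPermutation:
    """Rotate so ``anchor`` comes first; if ``reflect``, reverse the reading
    direction (reverse order, flip signs) before rotating."""
    order = P.order
    if reflect:
        order = [(n, -s) for n, s in reversed(order)]
    names = [n for n, _ in order]
    try:
        i = names.index(anchor)
    except ValueError:
        raise KeyError(f"anchor gene {anchor!r} not in permutation of "
                       f"{P.genome_id!r}") from None
    return SignedPermutation(P.genome_id, order[i:] + order[:i])


def _adjacencies(P: SignedPermutation) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    n = len(P)
    return [(P.order[i], P.order[(i + 1) % n]) for i in range(n)]


def _conservation_flags(
    PA: SignedPermutation, PB: SignedPermutation
) -> tuple[list[bool], int]:
    """For each circular adjacency of A, whether the gene pair is adjacent in
    B; also counts how many of those additionally preserve relative
    orientation (as read, or under reflection of B)."""
    succ: dict[str, tuple[str, int, int]] = {}  # name -> (next name, sign, next sign)
    n = len(PB)
    for i in range(n):
        a, sa = PB.order[i]
        b, sb = PB.order[(i + 1) % n]
        succ[a] = (b, sa, sb)

    flags: list[bool] = []
    oriented = 0
    for (a, sa), (b, sb) in _adjacencies(PA):
        fwd = succ.get(a)
        rev = succ.get(b)
        adjacent = (fwd is not None and fwd[0] == b) or \
                   (rev is not None and rev[0] == a)
        flags.append(adjacent)
        # orientation preserved when B (as read, or reflected) contains the
        # adjacency with the same signs: (a,sa)(b,sb) or (b,-sb)(a,-sa)
        if fwd is not None and fwd[0] == b and (fwd[1], fwd[2]) == (sa, sb):
            oriented += 1
        elif rev is not None and rev[0] == a and (rev[1], rev[2]) == (-sb, -sa):
            oriented += 1
    return flags, oriented


def compare_order(
    A: AnnotatedGenome, B: AnnotatedGenome, include_trna: bool = False
) -> SyntenyResult:
    """Conserved adjacencies, collinear blocks and breakpoint distance for
    one genome pair.  With fewer than two shared genes the distance is
    undefined and the result is flagged."""
    shared = shared_gene_set(A, B, include_trna)
    PA = to_signed_permutation(A, shared)
    PB = to_signed_permutation(B, shared)
    return compare_permutations(PA, PB)


def compare_permutations(
    PA: SignedPermutation, PB: SignedPermutation
) -> SyntenyResult:
    n = len(PA)
    if n != len(PB) or set(PA.names()) != set(PB.names()):
        raise ValueError("permutations must contain the same gene set")
    if n < 2:
        return SyntenyResult(PA.genome_id, PB.genome_id, n, 0, 0,
                             float("nan"), n, 0, defined=False)
    flags, oriented = _conservation_flags(PA, PB)
    conserved = sum(flags)
    breakpoints = n - conserved
    n_blocks = breakpoints if breakpoints else 1
    return SyntenyResult(
        id_a=PA.genome_id,
        id_b=PB.genome_id,
        n_shared=n,
        conserved_adjacencies=conserved,
        oriented_adjacencies=oriented,
        adjacency_fraction=conserved / n,
        n_blocks=n_blocks,
        breakpoint_distance=breakpoints,
    )


def collinear_blocks(PA: SignedPermutation, PB: SignedPermutation) -> list[list[str]]:
    """Maximal runs of genes in A chained by conserved adjacencies with B."""
    n = len(PA)
    if n == 0:
        return []
    flags, _ = _conservation_flags(PA, PB)
    if all(flags):
        return [PA.names()]
    # start each block just after a breakpoint
    start = next(i for i, ok in enumerate(flags) if not ok) + 1
    blocks: list[list[str]] = []
    block = [PA.order[start % n][0]]
    for k in range(n):
        i = (start + k) % n
        if flags[i] and k < n - 1:
            block.append(PA.order[(i + 1) % n][0])
        else:
            blocks.append(block)
            if k < n - 1:
                block = [PA.order[(i + 1) % n][0]]
    return blocks


def pairwise_matrix(
    genomes: list[AnnotatedGenome], include_trna: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric all-pairs matrices of adjacency fraction and breakpoint
    distance (diagonal: 1.0 and 0).  Pairs with fewer than two shared genes
    are reported as NaN."""
    ids = [g.id for g in genomes]
    k = len(genomes)
    adj = np.full((k, k), np.nan)
    bpd = np.full((k, k), np.nan)
    np.fill_diagonal(adj, 1.0)
    np.fill_diagonal(bpd, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            res = compare_order(genomes[i], genomes[j], include_trna)
            if res.defined:
                adj[i, j] = adj[j, i] = res.adjacency_fraction
                bpd[i, j] = bpd[j, i] = res.breakpoint_distance
    return (
        pd.DataFrame(adj, index=ids, columns=ids),
        pd.DataFrame(bpd, index=ids, columns=ids),
    )


def random_signed_permutation(
    n: int, rng: np.random.Generator, genome_id: str = "random"
) -> SignedPermutation:
    """Uniform random signed circular permutation of genes g0..g{n-1} (used
    as the null model for adjacency conservation)."""
    names = [f"g{i}" for i in rng.permutation(n)]
    signs = rng.choice([-1, 1], size=n)
    return SignedPermutation(genome_id, list(zip(names, (int(s) for s in signs))))
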