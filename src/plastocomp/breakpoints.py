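"""Deletion-breakpoint calling and junction characterization.

Walking the reference circle (all gene types, tRNAs included, since lost
tRNAs participate in deletion runs), maximal runs of genes absent from the
reduced genome become breakpoint regions.  Each region's junction is the
intergenic sequence between the two retained flanking genes in the reduced
genome, extended symmetrically into the flanks when shorter than a minimum
window; the junction's AT content and tRNA adjacency are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .content import align_pair, alignment_identity
from .genome_io import AnnotatedGenome, circular_slice

DEFAULT_JUNCTION_WINDOW = 100


@dataclass
class BreakpointRegion:
    bp_id: str  # BP1, BP2, ... in reference order
    missing_genes: list[str]
    left_flank: str
    right_flank: str
    left_flank_type: str
    right_flank_type: str
    deleted_span_bp: int  # reference distance between the flanks
    junction_start: int  # coordinates of the junction window in the reduced genome
    junction_end: int
    junction_seq: str
    junction_at_percent: float
    trna_adjacent: bool
    clean: bool  # flanks directly adjacent in the reduced genome


def at_percent(seq: str) -> float:
    if not seq:
        return 0.0
    at = seq.count("A") + seq.count("T")
    denom = at + seq.count("G") + seq.count("C")
    return 100.0 * at / denom if denom else 0.0


def _feature_end_linear(f, L: int) -> int:
    return f.end + L if f.wraps else f.end


def find_breakpoints(
    reference: AnnotatedGenome,
    reduced: AnnotatedGenome,
    window: int = DEFAULT_JUNCTION_WINDOW,
) -> list[BreakpointRegion]:
    """Maximal runs of reference genes missing from the reduced genome, with
    their junctions located in the reduced genome.

    Regions are labelled BP1.. in reference order starting at position 0 of
    the reference circle.  Runs separated only by other missing genes merge
    automatically (a flank is always a retained gene).
    """
    ref_feats = reference.features
    present = reduced.distinct_names()
    missing = [f.name not in present for f in ref_feats]
    if not any(missing):
        return []
    if all(missing):
        raise ValueError("no reference gene is retained in the reduced genome")

    n = len(ref_feats)
    L_ref = len(reference)
    L_red = len(reduced)
    red_feats = reduced.features
    red_index = {f.name: i for i, f in reversed(list(enumerate(red_feats)))}

    # collect maximal circular runs of missing reference genes
    regions: list[BreakpointRegion] = []
    retained_idx = [i for i in range(n) if not missing[i]]
    for k, i in enumerate(retained_idx):
        j = retained_idx[(k + 1) % len(retained_idx)]
        run = []
        p = (i + 1) % n
        while p != j:
            run.append(ref_feats[p])
            p = (p + 1) % n
        if not run:
            continue
        lf, rf = ref_feats[i], ref_feats[j]
        span = (rf.start - _feature_end_linear(lf, L_ref)) % L_ref

        # locate the junction between the flanks in the reduced genome
        li = red_index[lf.name]
        ri = red_index[rf.name]
        m = len(red_feats)
        if (li + 1) % m == ri:
            gap = (_feature_end_linear(red_feats[li], L_red) % L_red,
                   red_feats[ri].start)
            clean = True
        elif (ri + 1) % m == li:
            gap = (_feature_end_linear(red_feats[ri], L_red) % L_red,
                   red_feats[li].start)
            clean = True
        else:
            # flanks separated in the reduced genome (rearranged); report the
            # intergenic region downstream of the left flank
            nxt = red_feats[(li + 1) % m]
            gap = (_feature_end_linear(red_feats[li], L_red) % L_red, nxt.start)
            clean = False

        gs, ge = gap
        gap_len = (ge - gs) % L_red
        if gap_len < window:
            extra = window - gap_len
            gs = (gs - extra // 2) % L_red
            ge = (ge + (extra - extra // 2)) % L_red
        seq = circular_slice(reduced.sequence, gs, ge)
        regions.append(
            BreakpointRegion(
                bp_id="",
                missing_genes=[f.name for f in run],
                left_flank=lf.name,
                right_flank=rf.name,
                left_flank_type=lf.gene_type,
                right_flank_type=rf.gene_type,
                deleted_span_bp=span,
                junction_start=gs,
                junction_end=ge,
                junction_seq=seq,
                junction_at_percent=at_percent(seq),
                trna_adjacent=(lf.gene_type == "tRNA" or rf.gene_type == "tRNA"),
                clean=clean,
            )
        )

    # stable labels: order by reference position of the first missing gene
    first_pos = {id(r): reference.features_by_name(r.missing_genes[0])[0].start
                 for r in regions}
    regions.sort(key=lambda r: first_pos[id(r)])
    for i, r in enumerate(regions, start=1):
        r.bp_id = f"BP{i}"
    return regions


def junction_report(
    regions: list[BreakpointRegion],
) -> tuple[pd.DataFrame, dict]:
    """Per-region table plus aggregate statistics (mean junction AT%, number
    of tRNA-adjacent regions)."""
    df = pd.DataFrame(
        {
            "bp_id": [r.bp_id for r in regions],
            "n_missing": [len(r.missing_genes) for r in regions],
            "missing_genes": [",".join(r.missing_genes) for r in regions],
            "left_flank": [r.left_flank for r in regions],
            "right_flank": [r.right_flank for r in regions],
            "deleted_span_bp": [r.deleted_span_bp for r in regions],
            "junction_at_percent": [round(r.junction_at_percent, 2)
                                    for r in regions],
            "trna_adjacent": [r.trna_adjacent for r in regions],
            "clean": [r.clean for r in regions],
        }
    )
    summary = {
        "n_regions": len(regions),
        "mean_junction_at_percent": (
            sum(r.junction_at_percent for r in regions) / len(regions)
            if regions else float("nan")
        ),
        "n_trna_adjacent": sum(r.trna_adjacent for r in regions),
        "total_missing_genes": sum(len(r.missing_genes) for r in regions),
    }
    return df, summary


def junction_similarity(
    regions: list[BreakpointRegion],
    identity_threshold: float = 0.70,
    min_len: int = 30,
) -> list[tuple[str, str, float]]:
    """All-vs-all identity of junction windows; pairs whose global-alignment
    identity exceeds the threshold (over alignments of at least ``min_len``
    columns) are flagged as similar."""
    flagged = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            a, b = regions[i].junction_seq, regions[j].junction_seq
            if not a or not b:
                continue
            row_a, row_b = align_pair(a, b)
            if len(row_a) < min_len:
                continue
            ident = alignment_identity(row_a, row_b)
            if ident >= identity_threshold:
                flagged.append((regions[i].bp_id, regions[j].bp_id, ident))
    return flagged
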