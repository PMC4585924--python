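#!/usr/bin/env python
"""Optional networked check: reproduce the published comparison from the
deposited GenBank records.

This script needs the two annotated plastid genome records — KC843975
(Auxenochlorella protothecoides, photosynthetic reference) and KJ001761
(Prototheca wickerhamii, reduced) — either as local GenBank flat files or
fetched from NCBI (requires network access, which the regular test suite
deliberately does not assume).  It then reruns the pipeline and prints the
published quantities next to the recomputed ones: genome sizes 84,580 /
55,636 bp, GC 30.8 / 31.2%, gene counts 76+3+30 and 40+3+27, the 109/70/39
shared-gene accounting, the lost-gene classes, ~17 breakpoint regions with
13 tRNA-adjacent junctions averaging >85% AT, and a mean NG86 Ks near 0.816.

Usage:
    python scripts/accession_report.py --reference KC843975.gb --reduced KJ001761.gb
    python scripts/accession_report.py --fetch --out-dir data/
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from plastocomp.breakpoints import find_breakpoints, junction_report
from plastocomp.content import compare_content
from plastocomp.genome_io import read_genbank
from plastocomp.molevo import divergence_time, kska_table, mean_ks
from plastocomp.stats import genome_stats
from plastocomp.synteny import compare_order

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")
REFERENCE_ACC = "KC843975"
REDUCED_ACC = "KJ001761"


def fetch(acc: str, out_dir: Path) -> Path:
    out = out_dir / f"{acc}.gb"
    if not out.exists():
        print(f"fetching {acc} ...", file=sys.stderr)
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=120) as r:
            out.write_bytes(r.read())
    return out


def line(label: str, published, computed) -> None:
    print(f"{label:<42} published {published!s:>12}   computed {computed}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reference", type=Path, help="KC843975 GenBank file")
    parser.add_argument("--reduced", type=Path, help="KJ001761 GenBank file")
    parser.add_argument("--fetch", action="store_true",
                        help="download the records from NCBI")
    parser.add_argument("--out-dir", type=Path, default=Path("data"))
    args = parser.parse_args()

    if args.fetch:
        args.out_dir.mkdir(parents=True, exist_ok=True)
        args.reference = fetch(REFERENCE_ACC, args.out_dir)
        args.reduced = fetch(REDUCED_ACC, args.out_dir)
    if not (args.reference and args.reduced):
        parser.error("provide --reference/--reduced paths or --fetch")

    ref = read_genbank(args.reference)
    red = read_genbank(args.reduced)

    s_ref, s_red = genome_stats(ref), genome_stats(red)
    line("reference size (bp)", 84580, s_ref.size_bp)
    line("reduced size (bp)", 55636, s_red.size_bp)
    line("reference GC (%)", 30.8, round(s_ref.gc_percent, 1))
    line("reduced GC (%)", 31.2, round(s_red.gc_percent, 1))
    line("reference genes (protein/rRNA/tRNA)", "76/3/30",
         f"{s_ref.n_protein}/{s_ref.n_rRNA}/{s_ref.n_tRNA}")
    line("reduced genes (protein/rRNA/tRNA)", "40/3/27",
         f"{s_red.n_protein}/{s_red.n_rRNA}/{s_red.n_tRNA}")
    line("reference inverted repeat", "absent",
         "present" if s_ref.has_inverted_repeat else "absent")

    comp = compare_content(ref, red)
    line("distinct reference genes", 109, comp.n_a)
    line("shared genes", 70, comp.n_shared)
    line("genes lost from reduced", 39, len(comp.only_in_a))
    line("lost photosynthesis genes", 31,
         comp.lost_from_b_by_category.get("photosynthesis", 0))
    for expected in ("ycf3", "ycf4", "ycf12", "cemA", "ccsA",
                     "trnL(GAG)", "trnS(GGA)", "trnT(GGU)"):
        line(f"  lost set contains {expected}", True,
             expected in comp.only_in_a)

    syn = compare_order(ref, red)
    line("adjacency fraction (shared circle)", "high",
         round(syn.adjacency_fraction, 3))

    regions = find_breakpoints(ref, red)
    _, summary = junction_report(regions)
    line("breakpoint regions (BP1..)", "17 (+/-2)", summary["n_regions"])
    line("tRNA-adjacent regions", 13, summary["n_trna_adjacent"])
    line("mean junction AT (%)", ">85",
         round(summary["mean_junction_at_percent"], 1))

    _, results = kska_table(ref, red)
    mks = mean_ks(results)
    line("mean Ks over shared genes", 0.816, round(mks, 3))
    est = divergence_time(mks)
    line("generations since divergence (1e9)", 2.52,
         round(est.n_generations / 1e9, 2))
    line("divergence window (Myr)", "6-20",
         f"{est.t_low_years / 1e6:.1f}-{est.t_high_years / 1e6:.1f}")


if __name__ == "__main__":
    main()
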