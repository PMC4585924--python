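"""Synthetic plastome pairs with known divergence, planted deletions and
optional inversions.

The generator builds an AT-rich circular genome as a gene–spacer alternation
(protein, rRNA and tRNA genes across the nine functional categories), then
evolves a descendant: protein genes accumulate single-nucleotide codon
changes accepted so that the realized NG86-counted per-gene divergence is
driven to the configured Ks/Ka targets (changes creating stop codons are
rejected); RNA genes and spacers evolve by per-site substitution at scaled
rates; planted deletions remove gene runs plus their internal spacers and
fuse the flanks with a new AT-rich junction spacer; inversions
reverse-complement whole gene spans.  The returned truth object records the
realized per-gene divergence (recomputed exactly from the true codon
correspondence, not the target) and the planted junction coordinates, so
estimators and the breakpoint caller can be tested against ground truth.

All randomness flows from integer-seeded numpy generators; the same seed
reproduces the same genomes bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (AnnotatedGenome, GeneFeature, revcomp, write_genbank)
from .molevo import (BASES, CODON_AA, SENSE_CODONS, STOP_CODONS,
                     CodonAlignment, KsKaResult, ng86)

# Curated plastid gene-name pools per functional category.
GENE_POOLS = {
    "photosynthesis": [
        "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
        "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ", "psaA",
        "psaB", "psaC", "psaI", "psaJ", "psaM", "rbcL", "chlB", "chlL",
        "chlN",
    ],
    "atp_synthase": ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"],
    "cytochrome": ["petA", "petB", "petD", "petG", "petL", "ccsA"],
    "ribosomal_protein": [
        "rps2", "rps3", "rps4", "rps7", "rps8", "rps9", "rps11", "rps12",
        "rps14", "rps18", "rps19", "rpl2", "rpl5", "rpl12", "rpl14",
        "rpl16", "rpl19", "rpl20", "rpl23", "rpl36",
    ],
    "rna_polymerase": ["rpoA", "rpoB", "rpoC1", "rpoC2"],
    "other_conserved": ["tufA", "infA", "clpP", "cemA", "minD", "ftsH", "accD"],
}

TRNA_POOL = [
    "trnA(UGC)", "trnC(GCA)", "trnD(GUC)", "trnE(UUC)", "trnF(GAA)",
    "trnG(GCC)", "trnH(GUG)", "trnI(GAU)", "trnK(UUU)", "trnL(UAA)",
    "trnL(GAG)", "trnM(CAU)", "trnN(GUU)", "trnP(UGG)", "trnQ(UUG)",
    "trnR(ACG)", "trnS(GCU)", "trnS(GGA)", "trnT(GGU)", "trnV(UAC)",
    "trnW(CCA)", "trnY(GUA)",
]

RRNA_NAMES = ("rrs", "rrl", "rrf")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome pair.

    Defaults emulate a compact AT-rich plastome at the divergence of the
    study system: intergenic AT fraction 0.85, pairwise synonymous target
    Ks 0.8 with Ka an order of magnitude lower, RNA genes more conserved
    than proteins and spacers less conserved.
    """

    seed: int = 0
    label: str = "sim"
    n_genes: dict[str, int] = field(default_factory=lambda: {
        "photosynthesis": 12,
        "atp_synthase": 4,
        "cytochrome": 3,
        "ribosomal_protein": 10,
        "rna_polymerase": 3,
        "rRNA": 3,
        "tRNA": 8,
        "other_conserved": 2,
        "orf_unknown": 1,
    })
    protein_codon_range: tuple[int, int] = (100, 500)
    trna_len_range: tuple[int, int] = (72, 90)
    rrna_lengths: tuple[int, int, int] = (1490, 2890, 120)  # rrs, rrl, rrf
    intergenic_len_range: tuple[int, int] = (20, 400)
    intergenic_at: float = 0.85
    coding_at: float = 0.65
    target_ks: float = 0.8
    target_ka: float = 0.05
    rna_rate_multiplier: float = 0.1  # RNA genes: fraction of target_ks
    noncoding_multiplier: float = 1.5  # spacers: multiple of target_ks
    photosynthesis_clusters: int | None = None
    deletions: list[list[str]] = field(default_factory=list)
    inversions: list[tuple[str, str]] = field(default_factory=list)
    junction_len_range: tuple[int, int] = (100, 200)
    junction_at: float = 0.90

    def validate(self) -> None:
        if any(v < 0 for v in self.n_genes.values()):
            raise ValueError("gene counts must be >= 0")
        if sum(self.n_genes.values()) == 0:
            raise ValueError("config generates an empty genome")
        for lo, hi in (self.protein_codon_range, self.trna_len_range,
                       self.intergenic_len_range, self.junction_len_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        for frac in (self.intergenic_at, self.coding_at, self.junction_at):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("AT fractions must be in [0, 1]")
        if not 0.0 <= self.target_ks < 3.0:
            raise ValueError("target_ks outside the correctable range [0, 3)")
        if self.target_ka < 0:
            raise ValueError("target_ka must be >= 0")


@dataclass
class PlantedDeletion:
    missing_genes: list[str]
    left_flank: str
    right_flank: str
    junction_start: int  # junction spacer coordinates in the descendant
    junction_end: int
    junction_seq: str


@dataclass
class SimulationTruth:
    seed: int
    ancestor_id: str
    descendant_id: str
    gene_truths: dict[str, KsKaResult]  # realized NG86 divergence per protein gene
    deletions: list[PlantedDeletion]
    inversions: list[tuple[str, str]]
    # per-gene codon correspondence is the identity (no indels are simulated
    # within genes); recorded as the codon count per retained protein gene
    codon_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ancestor generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, at: float) -> str:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _sense_codon_weights(at: float) -> np.ndarray:
    base_p = {"A": at / 2, "T": at / 2, "C": (1 - at) / 2, "G": (1 - at) / 2}
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]]
                  for c in SENSE_CODONS])
    return w / w.sum()


def _random_cds(rng: np.random.Generator, n_codons: int, at: float) -> str:
    """Random stop-free CDS: ATG + sampled sense codons + TAA."""
    weights = _sense_codon_weights(at)
    idx = rng.choice(len(SENSE_CODONS), size=max(n_codons - 2, 1), p=weights)
    body = "".join(SENSE_CODONS[i] for i in idx)
    return "ATG" + body + "TAA"


@dataclass
class _Segment:
    kind: str  # "gene" | "spacer"
    seq: str  # forward-strand genomic sequence
    name: str = ""
    gene_type: str = ""
    category: str = ""
    strand: int = 1


def _gene_specs(config: SimulationConfig, rng: np.random.Generator):
    specs = []
    for category, count in config.n_genes.items():
        if category == "tRNA":
            for i in range(count):
                name = TRNA_POOL[i] if i < len(TRNA_POOL) else f"trnX(N{i:02d})"
                length = int(rng.integers(*config.trna_len_range,
                                          endpoint=True))
                specs.append((name, "tRNA", category, length))
        elif category == "rRNA":
            for i in range(count):
                name = RRNA_NAMES[i % 3]
                length = config.rrna_lengths[i % 3]
                specs.append((name, "rRNA", category, length))
        elif category == "orf_unknown":
            for i in range(count):
                codons = int(rng.integers(*config.protein_codon_range,
                                          endpoint=True))
                specs.append((f"orf{101 + i}", "protein", category, codons))
        else:
            pool = GENE_POOLS.get(category, [])
            for i in range(count):
                name = pool[i] if i < len(pool) else f"{category[:3]}{i:02d}"
                codons = int(rng.integers(*config.protein_codon_range,
                                          endpoint=True))
                specs.append((name, "protein", category, codons))
    return specs


def _order_specs(specs, config: SimulationConfig, rng: np.random.Generator):
    """Shuffle gene order; optionally keep photosynthesis genes in a fixed
    number of well-separated contiguous clusters (plastid operon style)."""
    photo = [s for s in specs if s[2] == "photosynthesis"]
    others = [s for s in specs if s[2] != "photosynthesis"]
    others = [others[i] for i in rng.permutation(len(others))]
    k = config.photosynthesis_clusters
    if not photo or not k:
        mixed = photo + others
        return [mixed[i] for i in rng.permutation(len(mixed))]
    k = min(k, len(photo))
    photo = [photo[i] for i in rng.permutation(len(photo))]
    clusters = [list(c) for c in np.array_split(np.arange(len(photo)), k)]
    # insertion slots spaced so no two clusters abut
    base = max(len(others) // k, 2)
    ordered = []
    ci = 0
    for i, spec in enumerate(others):
        if ci < k and i == ci * base + 1:
            ordered.extend(photo[j] for j in clusters[ci])
            ci += 1
        ordered.append(spec)
    while ci < k:  # ran out of others (tiny configs)
        ordered.extend(photo[j] for j in clusters[ci])
        ci += 1
    return ordered


def generate_ancestor(config: SimulationConfig) -> AnnotatedGenome:
    """Assemble the ancestral circular genome as gene–spacer alternation."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    ordered = _order_specs(_gene_specs(config, rng), config, rng)

    segments: list[_Segment] = []
    for name, gtype, category, size in ordered:
        spacer_len = int(rng.integers(*config.intergenic_len_range,
                                      endpoint=True))
        segments.append(_Segment("spacer",
                                 _random_seq(rng, spacer_len,
                                             config.intergenic_at)))
        if gtype == "protein":
            gene_seq = _random_cds(rng, size, config.coding_at)
        else:
            gene_seq = _random_seq(rng, size, config.coding_at)
        strand = 1 if rng.random() < 0.7 else -1
        genomic = revcomp(gene_seq) if strand == -1 else gene_seq
        segments.append(_Segment("gene", genomic, name, gtype, category,
                                 strand))
    return _assemble(f"{config.label}-ancestor-{config.seed}", segments)


def _assemble(genome_id: str, segments: list[_Segment]) -> AnnotatedGenome:
    seq_parts = []
    features = []
    pos = 0
    for seg in segments:
        if seg.kind == "gene":
            features.append(GeneFeature(seg.name, seg.gene_type, seg.category,
                                        seg.strand, pos, pos + len(seg.seq)))
        seq_parts.append(seg.seq)
        pos += len(seg.seq)
    return AnnotatedGenome(genome_id, "".join(seq_parts), features)


def _decompose(genome: AnnotatedGenome) -> list[_Segment]:
    """Split a (non-overlapping, non-wrapping) annotated genome back into
    alternating gene/spacer segments."""
    segments: list[_Segment] = []
    pos = 0
    for f in genome.features:
        if f.wraps or f.start < pos:
            raise ValueError("simulator requires non-overlapping, "
                             "non-origin-spanning features")
        if f.start > pos:
            segments.append(_Segment("spacer", genome.sequence[pos: f.start]))
        segments.append(_Segment("gene", genome.sequence[f.start: f.end],
                                 f.name, f.gene_type, f.category, f.strand))
        pos = f.end
    if pos < len(genome):
        segments.append(_Segment("spacer", genome.sequence[pos:]))
    return segments


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------


def _jc_p(distance: float) -> float:
    """Expected proportion of differing sites at a given JC69 distance."""
    return 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))


def _mutate_sites(seq: str, p: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution with probability ``p`` to a
    uniformly chosen different base."""
    if p <= 0 or not seq:
        return seq
    chars = np.array(list(seq))
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hits:
        old = chars[i]
        choices = [b for b in BASES if b != old]
        chars[i] = choices[rng.integers(3)]
    return "".join(chars)


def _pair_tables():
    """Lazily built lookup tables used by the codon proposal loop."""
    global _SITES_S, _PAIR
    if _SITES_S is None:
        from .molevo import codon_sites
        _SITES_S = {c: codon_sites(c)[0] for c in SENSE_CODONS}
        _PAIR = {}
    return _SITES_S, _PAIR


_SITES_S = None
_PAIR: dict[tuple[str, str], tuple[float, float]] | None = None


def _pair_diff(c1: str, c2: str) -> tuple[float, float]:
    sites, pair = _pair_tables()
    key = (c1, c2)
    hit = pair.get(key)
    if hit is None:
        from .molevo import codon_differences
        hit = codon_differences(c1, c2)
        pair[key] = hit
    return hit


def _evolve_cds(
    codons: list[str],
    target_ks: float,
    target_ka: float,
    rng: np.random.Generator,
    max_stall: int = 400,
) -> list[str]:
    """Accept single-nucleotide codon changes until the realized NG86
    divergence from the ancestor is as close as possible to the targets.

    The start codon and any terminal stop stay fixed.  A proposal is accepted
    only if it moves the currently targeted statistic (Ka first, then Ks)
    strictly closer to its target; the loop stops after ``max_stall``
    consecutive rejections.
    """
    sites, _ = _pair_tables()
    mutable = list(range(1, len(codons)))  # codon 0 = ATG stays fixed
    if not mutable:
        return list(codons)
    cur = list(codons)
    s_anc = sum(sites[c] for c in codons)
    s_cur = s_anc
    sd = nd = 0.0
    n3 = 3.0 * len(codons)

    def distances(s_c, sd_v, nd_v):
        S = (s_anc + s_c) / 2.0
        N = n3 - S
        pS = sd_v / S if S > 0 else 0.0
        pN = nd_v / N if N > 0 else 0.0
        ks = -0.75 * math.log1p(-4 * pS / 3) if pS < 0.75 else math.inf
        ka = -0.75 * math.log1p(-4 * pN / 3) if pN < 0.75 else math.inf
        return ks, ka

    for phase, target in (("ka", target_ka), ("ks", target_ks)):
        stall = 0
        while stall < max_stall:
            ks, ka = distances(s_cur, sd, nd)
            cur_val = ka if phase == "ka" else ks
            if cur_val == target:
                break
            i = mutable[int(rng.integers(len(mutable)))]
            pos = int(rng.integers(3))
            base = BASES[int(rng.integers(4))]
            old = cur[i]
            if base == old[pos]:
                stall += 1
                continue
            new = old[:pos] + base + old[pos + 1:]
            if new in STOP_CODONS:
                stall += 1
                continue
            syn = CODON_AA[new] == CODON_AA[old]
            if (phase == "ka") == syn:  # wrong class for this phase
                stall += 1
                continue
            d_old = _pair_diff(codons[i], old)
            d_new = _pair_diff(codons[i], new)
            s_new = s_cur - sites[old] + sites[new]
            sd_new = sd - d_old[0] + d_new[0]
            nd_new = nd - d_old[1] + d_new[1]
            ks_n, ka_n = distances(s_new, sd_new, nd_new)
            new_val = ka_n if phase == "ka" else ks_n
            if abs(new_val - target) < abs(cur_val - target):
                cur[i] = new
                s_cur, sd, nd = s_new, sd_new, nd_new
                stall = 0
            else:
                stall += 1
    return cur


def evolve(
    ancestor: AnnotatedGenome, config: SimulationConfig
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Evolve a descendant from an ancestor under the configured targets,
    apply planted deletions/inversions, and record the realized truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    segments = _decompose(ancestor)

    p_rna = _jc_p(config.target_ks * config.rna_rate_multiplier)
    p_nc = _jc_p(min(config.target_ks * config.noncoding_multiplier, 2.0))

    gene_truths: dict[str, KsKaResult] = {}
    codon_counts: dict[str, int] = {}
    evolved: list[_Segment] = []
    for seg in segments:
        if seg.kind == "spacer":
            evolved.append(_Segment("spacer",
                                    _mutate_sites(seg.seq, p_nc, rng)))
            continue
        if seg.gene_type == "protein":
            cds = revcomp(seg.seq) if seg.strand == -1 else seg.seq
            codons = [cds[i: i + 3] for i in range(0, len(cds) - 2, 3)]
            body, stop = codons[:-1], codons[-1]
            new_body = _evolve_cds(body, config.target_ks, config.target_ka,
                                   rng)
            truth_aln = CodonAlignment(seg.name, body, new_body, len(body))
            gene_truths[seg.name] = ng86(truth_aln)
            codon_counts[seg.name] = len(body)
            new_cds = "".join(new_body) + stop
            new_seq = revcomp(new_cds) if seg.strand == -1 else new_cds
        else:
            new_seq = _mutate_sites(seg.seq, p_rna, rng)
        evolved.append(_Segment(seg.kind, new_seq, seg.name, seg.gene_type,
                                seg.category, seg.strand))

    evolved, deletion_markers = _apply_deletions(evolved, config, rng)
    evolved = _apply_inversions(evolved, config)
    for seg in evolved:
        if seg.kind == "gene" and seg.name in gene_truths and \
                seg.name in {g for run in config.deletions for g in run}:
            raise AssertionError("deleted gene survived")  # defensive

    descendant = _assemble(f"{config.label}-descendant-{config.seed}", evolved)

    # resolve junction coordinates in the assembled descendant
    deletions: list[PlantedDeletion] = []
    pos = 0
    marker_coords = {}
    for seg in evolved:
        if seg.kind == "spacer" and seg.name.startswith("__junction"):
            marker_coords[seg.name] = (pos, pos + len(seg.seq), seg.seq)
        pos += len(seg.seq)
    for marker, (run, lf, rf) in deletion_markers.items():
        js, je, jseq = marker_coords[marker]
        deletions.append(PlantedDeletion(run, lf, rf, js, je, jseq))

    # drop gene truths for deleted genes (they are absent from the pair)
    deleted = {g for run in config.deletions for g in run}
    gene_truths = {k: v for k, v in gene_truths.items() if k not in deleted}
    codon_counts = {k: v for k, v in codon_counts.items() if k not in deleted}

    truth = SimulationTruth(
        seed=config.seed,
        ancestor_id=ancestor.id,
        descendant_id=descendant.id,
        gene_truths=gene_truths,
        deletions=deletions,
        inversions=list(config.inversions),
        codon_counts=codon_counts,
    )
    return descendant, truth


def _apply_deletions(segments, config: SimulationConfig,
                     rng: np.random.Generator):
    """Remove each configured gene run (plus internal and flanking spacers)
    and replace it with a fresh AT-rich junction spacer."""
    markers: dict[str, tuple[list[str], str, str]] = {}
    gene_names = [s.name for s in segments if s.kind == "gene"]
    for run_no, run in enumerate(config.deletions):
        for g in run:
            if g not in gene_names:
                raise ValueError(f"deletion references absent gene {g!r}")
        idx = [i for i, s in enumerate(segments) if s.kind == "gene"
               and s.name in run]
        lo, hi = min(idx), max(idx)
        interior = [s.name for s in segments[lo: hi + 1] if s.kind == "gene"]
        if set(interior) != set(run):
            raise ValueError(f"deletion run {run} is not contiguous in the "
                             "ancestor gene order")
        # widen to swallow the flanking spacers
        a = lo - 1 if lo > 0 and segments[lo - 1].kind == "spacer" else lo
        b = hi + 1 if hi + 1 < len(segments) and \
            segments[hi + 1].kind == "spacer" else hi
        left = next((s.name for s in reversed(segments[:a]) if s.kind == "gene"),
                    None)
        right = next((s.name for s in segments[b + 1:] if s.kind == "gene"),
                     None)
        jlen = int(rng.integers(*config.junction_len_range, endpoint=True))
        junction = _Segment("spacer", _random_seq(rng, jlen, config.junction_at),
                            name=f"__junction{run_no}")
        marker = junction.name
        segments = segments[:a] + [junction] + segments[b + 1:]
        markers[marker] = (list(run), left or "", right or "")
    return segments, markers


def _apply_inversions(segments, config: SimulationConfig):
    for first, last in config.inversions:
        gene_idx = {s.name: i for i, s in enumerate(segments)
                    if s.kind == "gene"}
        if first not in gene_idx or last not in gene_idx:
            missing = first if first not in gene_idx else last
            raise ValueError(f"inversion references absent gene {missing!r}")
        lo, hi = gene_idx[first], gene_idx[last]
        if lo > hi:
            lo, hi = hi, lo
        span = segments[lo: hi + 1]
        flipped = [
            _Segment(s.kind, revcomp(s.seq), s.name, s.gene_type, s.category,
                     -s.strand if s.kind == "gene" else 1)
            for s in reversed(span)
        ]
        segments = segments[:lo] + flipped + segments[hi + 1:]
    return segments


# ---------------------------------------------------------------------------
# Study fixture
# ---------------------------------------------------------------------------


@dataclass
class StudyFixture:
    reference: AnnotatedGenome  # photosynthetic analogue (the ancestor)
    reduced: AnnotatedGenome  # heterotrophic analogue, photosynthesis lost
    truth: SimulationTruth
    config: SimulationConfig


def make_study_fixture(seed: int, out_dir: str | Path | None = None,
                       n_deletion_runs: int = 6,
                       target_ks: float = 0.8,
                       config: SimulationConfig | None = None) -> StudyFixture:
    """Miniature analogue of the study pair: a photosynthetic reference of
    ~40 genes whose photosynthesis genes sit in a handful of clusters, and a
    reduced descendant that lost every photosynthesis cluster through planted
    deletions at pairwise synonymous divergence ``target_ks``.

    A custom ``config`` (gene counts, rates) may be supplied; its
    photosynthesis clusters become the planted deletion runs."""
    if config is None:
        config = SimulationConfig(seed=seed, label="study",
                                  photosynthesis_clusters=n_deletion_runs,
                                  target_ks=target_ks)
    else:
        config.seed = seed
        config.photosynthesis_clusters = n_deletion_runs
    reference = generate_ancestor(config)

    # read the photosynthesis clusters off the generated gene order
    runs: list[list[str]] = []
    current: list[str] = []
    for f in reference.features:
        if f.category == "photosynthesis":
            current.append(f.name)
        elif current:
            runs.append(current)
            current = []
    if current:  # cluster touching the end of the linear listing
        if runs and reference.features[0].category == "photosynthesis":
            runs[0] = current + runs[0]
        else:
            runs.append(current)
    config.deletions = runs

    reduced, truth = evolve(reference, config)
    fixture = StudyFixture(reference, reduced, truth, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genbank(reference, out / "reference.gb")
        write_genbank(reduced, out / "reduced.gb")
        (out / "truth.json").write_text(json.dumps(truth_to_dict(truth),
                                                   indent=2))
    return fixture


def truth_to_dict(truth: SimulationTruth) -> dict:
    return {
        "seed": truth.seed,
        "ancestor_id": truth.ancestor_id,
        "descendant_id": truth.descendant_id,
        "genes": {
            name: {
                "n_codons": r.n_codons, "S": r.S, "N": r.N,
                "Sd": r.Sd, "Nd": r.Nd, "ks": r.ks, "ka": r.ka,
                "saturated": r.saturated,
            }
            for name, r in truth.gene_truths.items()
        },
        "deletions": [
            {
                "missing_genes": d.missing_genes,
                "left_flank": d.left_flank,
                "right_flank": d.right_flank,
                "junction_start": d.junction_start,
                "junction_end": d.junction_end,
            }
            for d in truth.deletions
        ],
        "inversions": [list(iv) for iv in truth.inversions],
    }
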