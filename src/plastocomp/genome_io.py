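"""Annotated circular genomes: parsing, gene-name normalization, coordinates.

Everything downstream (compactness statistics, gene-content comparison,
synteny, breakpoint calling, Ks/Ka estimation) operates on the
:class:`AnnotatedGenome` produced here.  Coordinates are 0-based half-open
internally; GenBank's 1-based inclusive coordinates are converted at the
boundary.  A feature that spans the origin of the circle is stored with
``wraps=True`` and ``end < start``; :func:`feature_length` and
:func:`feature_sequence` are the single place the wrap rule is resolved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastocomp")

# Translation table 11 (bacterial/plastid) is used for all protein work.
TRANSLATION_TABLE = 11

#: The nine functional categories used to colour plastid gene maps.
CATEGORIES = (
    "photosynthesis",
    "atp_synthase",
    "cytochrome",
    "ribosomal_protein",
    "rna_polymerase",
    "rRNA",
    "tRNA",
    "other_conserved",
    "orf_unknown",
)

GENE_TYPES = ("protein", "rRNA", "tRNA")


# ---------------------------------------------------------------------------
# Gene-name normalization
# ---------------------------------------------------------------------------

_AA3TO1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "fmet": "M", "phe": "F",
    "pro": "P", "ser": "S", "thr": "T", "trp": "W", "tyr": "Y",
    "val": "V", "sec": "U",
}

#: Curated synonym table (case-insensitive keys).  rRNA genes follow the
#: bacterial rrs/rrl/rrf convention for 16S/23S/5S.
DEFAULT_SYNONYMS = {
    "16s ribosomal rna": "rrs",
    "23s ribosomal rna": "rrl",
    "5s ribosomal rna": "rrf",
    "16s rrna": "rrs",
    "23s rrna": "rrl",
    "5s rrna": "rrf",
    "rrna-16s": "rrs",
    "rrna-23s": "rrl",
    "rrna-5s": "rrf",
    "rrn16": "rrs",
    "rrn23": "rrl",
    "rrn5": "rrf",
    "rrn16s": "rrs",
    "rrn23s": "rrl",
    "rrn5s": "rrf",
    "rns": "rrs",
    "rnl": "rrl",
    "16s": "rrs",
    "23s": "rrl",
    "5s": "rrf",
}

_TRN_SHORT = re.compile(r"^trn([A-Za-z])[\s(_-]*([ACGTUacgtu]{3})?\)?$")
_TRN_LONG = re.compile(r"^t?RNA[\s_-]*([A-Za-z]{3,4})[\s(_-]*([ACGTUacgtu]{3})?\)?$",
                       re.IGNORECASE)
_SYMBOL = re.compile(r"^[A-Za-z]{2,4}\d{0,3}[A-Za-z]?\d{0,3}$")
_SUFFIX = re.compile(r"^([a-z]{3})([a-z])(\d{0,3})$")


def _format_trna(aa1: str, anticodon: str | None) -> str:
    """Render a tRNA name as one-letter amino acid plus anticodon, RNA
    alphabet, e.g. ``trnL(GAG)`` / ``trnT(GGU)``."""
    if not anticodon:
        return f"trn{aa1.upper()}"
    return f"trn{aa1.upper()}({anticodon.upper().replace('T', 'U')})"


def normalize_gene_name(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Normalize a raw gene/product label to the community symbol.

    Plain symbols are case-folded (``ATPI`` -> ``atpI``); tRNAs are rendered
    ``trnX(NNN)`` with the anticodon in the RNA alphabet; a configurable
    synonym table maps verbose labels (``16S ribosomal RNA`` -> ``rrs``).
    Unrecognized labels pass through unchanged (a debug message is logged).
    """
    if not raw:
        raise ValueError("empty gene name")
    name = raw.strip()
    table = DEFAULT_SYNONYMS if synonyms is None else {**DEFAULT_SYNONYMS, **synonyms}
    hit = table.get(name.lower())
    if hit is not None:
        return hit

    m = _TRN_SHORT.match(name)
    if m:
        return _format_trna(m.group(1), m.group(2))
    m = _TRN_LONG.match(name)
    if m:
        aa = _AA3TO1.get(m.group(1).lower())
        if aa is not None:
            return _format_trna(aa, m.group(2))

    if _SYMBOL.match(name):
        low = name.lower()
        m = _SUFFIX.match(low)
        if m:
            # rpoc1 -> rpoC1, atpi -> atpI, psba -> psbA
            return m.group(1) + m.group(2).upper() + m.group(3)
        return low

    logger.debug("gene name %r not recognized; passed through unchanged", raw)
    return name


def categorize_gene(name: str, gene_type: str) -> str:
    """Assign one of the nine functional categories from the normalized name."""
    if gene_type == "tRNA" or name.startswith("trn"):
        return "tRNA"
    if gene_type == "rRNA" or name in ("rrs", "rrl", "rrf") or name.startswith("rrn"):
        return "rRNA"
    low = name.lower()
    if low.startswith(("psa", "psb", "rbc", "chl")):
        return "photosynthesis"
    if low.startswith("atp"):
        return "atp_synthase"
    if low.startswith("pet") or low in ("ccsa", "ccs1", "petn"):
        return "cytochrome"
    if low.startswith(("rps", "rpl")):
        return "ribosomal_protein"
    if low.startswith("rpo"):
        return "rna_polymerase"
    if low.startswith(("orf", "ycf")):
        return "orf_unknown"
    return "other_conserved"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One named gene on the circle.

    ``start``/``end`` are 0-based half-open; an origin-spanning feature has
    ``wraps=True`` and covers ``[start, L) + [0, end)``.
    """

    name: str
    gene_type: str  # protein | rRNA | tRNA
    category: str
    strand: int  # +1 / -1
    start: int
    end: int
    wraps: bool = False

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Circular nucleotide sequence plus ordered gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gene_names(self) -> list[str]:
        return [f.name for f in self.features]

    def distinct_names(self) -> set[str]:
        return set(self.gene_names)

    def features_by_name(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]

    def counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in GENE_TYPES}
        for f in self.features:
            out[f.gene_type] += 1
        return out


# ---------------------------------------------------------------------------
# Circular-coordinate primitives
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest distance between two positions on a circle of ``length`` bp."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    d = (b - a) % length
    return min(d, length - d)


def circular_slice(sequence: str, start: int, end: int) -> str:
    """Sequence of the half-open arc ``[start, end)``; wraps when end <= start."""
    L = len(sequence)
    start %= L
    end %= L
    if end > start:
        return sequence[start:end]
    return sequence[start:] + sequence[:end]


def feature_length(feature: GeneFeature, genome: AnnotatedGenome) -> int:
    return feature.length(len(genome))


def feature_sequence(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Nucleotide sequence of a feature read 5'->3' on its own strand."""
    if feature.wraps:
        raw = genome.sequence[feature.start:] + genome.sequence[: feature.end]
    else:
        raw = genome.sequence[feature.start: feature.end]
    return revcomp(raw) if feature.strand == -1 else raw


def _intervals(feature: GeneFeature, length: int) -> list[tuple[int, int]]:
    if feature.wraps:
        return [(feature.start, length), (0, feature.end)]
    return [(feature.start, feature.end)]


class CdsExtraction(NamedTuple):
    cds: str
    upstream: str
    upstream_overlaps_gene: bool


def extract_cds_and_upstream(
    genome: AnnotatedGenome, gene: str, upstream_bp: int = 50
) -> CdsExtraction:
    """Coding sequence of ``gene`` plus the ``upstream_bp`` nucleotides 5' of
    its start codon (the 5'UTR window), both read on the gene's strand.

    The upstream window wraps through the origin when needed and is returned
    even when it overlaps a neighbouring gene; the overlap is flagged.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    feats = genome.features_by_name(gene)
    if not feats:
        raise KeyError(f"gene {gene!r} not found in genome {genome.id!r}")
    f = feats[0]
    L = len(genome)
    cds = feature_sequence(genome, f)
    if f.strand == -1:
        up_start, up_end = f.end % L, (f.end + upstream_bp) % L
        upstream = revcomp(circular_slice(genome.sequence, up_start, up_end)) \
            if upstream_bp else ""
    else:
        up_start, up_end = (f.start - upstream_bp) % L, f.start
        upstream = circular_slice(genome.sequence, up_start, up_end) \
            if upstream_bp else ""

    overlap = False
    if upstream_bp:
        win = [(up_start, up_end)] if up_end > up_start else \
            [(up_start, L), (0, up_end)]
        for other in genome.features:
            if other is f:
                continue
            for (a, b) in _intervals(other, L):
                for (c, d) in win:
                    if a < d and c < b:
                        overlap = True
    return CdsExtraction(cds, upstream, overlap)


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate the circle so that old position ``offset`` becomes position 0."""
    L = len(genome)
    offset %= L
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        length = f.length(L)
        start = (f.start - offset) % L
        end = start + length
        wraps = end > L
        feats.append(replace(f, start=start, end=end - L if wraps else end,
                             wraps=wraps))
    return AnnotatedGenome(genome.id, seq, feats, genome.circular)


def reflect_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Reverse-complement the whole circle, flipping every feature's strand."""
    L = len(genome)
    seq = revcomp(genome.sequence)
    feats = []
    for f in genome.features:
        length = f.length(L)
        end_lin = f.end + L if f.wraps else f.end
        start = (L - end_lin) % L
        end = start + length
        wraps = end > L
        feats.append(replace(f, start=start, end=end - L if wraps else end,
                             wraps=wraps, strand=-f.strand))
    return AnnotatedGenome(genome.id, seq, feats, genome.circular)


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_TYPED = {"CDS": "protein", "rRNA": "rRNA", "tRNA": "tRNA"}
_CATEGORY_NOTE = re.compile(r"category=(\w+)")


def _location_to_coords(loc, length: int) -> tuple[int, int, bool]:
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) > 1 and int(parts[-1].end) == length and int(parts[0].start) == 0:
        # origin-spanning join(a..L, 1..b)
        return int(parts[-1].start), int(parts[0].end), True
    return int(loc.start), int(loc.end), False


def _feature_name(feat, start: int) -> tuple[str, bool]:
    for key in ("gene", "standard_name", "product", "locus_tag"):
        vals = feat.qualifiers.get(key)
        if vals:
            return vals[0], False
    return f"orf{start + 1}", True


def _type_from_name(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name in ("rrs", "rrl", "rrf") or name.startswith("rrn"):
        return "rRNA"
    return "protein"


def read_genbank(path, synonyms: dict[str, str] | None = None) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    CDS/rRNA/tRNA features are taken as the typed gene set; bare ``gene``
    features are kept only when no typed feature overlaps them (types are then
    inferred from the normalized name).  Names are run through
    :func:`normalize_gene_name`.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq:
        raise ValueError(f"{path}: record has no sequence")
    L = len(seq)
    circular = rec.annotations.get("topology", "circular") == "circular"

    typed: list[GeneFeature] = []
    gene_only = []
    for feat in rec.features:
        if feat.type not in _TYPED and feat.type != "gene":
            continue
        start, end, wraps = _location_to_coords(feat.location, L)
        strand = -1 if feat.location.strand == -1 else 1
        raw, synthesized = _feature_name(feat, start)
        name = normalize_gene_name(raw, synonyms)
        if synthesized:
            logger.warning("%s: feature at %d..%d has no name; recorded as %s",
                           rec.id, start, end, name)
        note = " ".join(feat.qualifiers.get("note", []))
        m = _CATEGORY_NOTE.search(note)
        if feat.type == "gene":
            gene_only.append((name, strand, start, end, wraps, m))
            continue
        gtype = _TYPED[feat.type]
        category = m.group(1) if m and m.group(1) in CATEGORIES \
            else categorize_gene(name, gtype)
        typed.append(GeneFeature(name, gtype, category, strand, start, end, wraps))

    covered = {(f.name, f.start) for f in typed}
    spans = [(f.start, f.end if not f.wraps else f.end + L) for f in typed]
    for name, strand, start, end, wraps, m in gene_only:
        end_lin = end + L if wraps else end
        if (name, start) in covered or any(
            a <= start and end_lin <= b for a, b in spans
        ):
            continue  # CDS/rRNA/tRNA inside this gene already recorded
        gtype = _type_from_name(name)
        category = m.group(1) if m and m.group(1) in CATEGORIES \
            else categorize_gene(name, gtype)
        typed.append(GeneFeature(name, gtype, category, strand, start, end, wraps))

    genome = AnnotatedGenome(rec.id or rec.name, seq, typed, circular)
    for f in genome.features:
        if f.gene_type == "protein" and f.length(L) % 3 != 0:
            logger.warning("%s: protein gene %s length %d not divisible by 3",
                           genome.id, f.name, f.length(L))
    return genome


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write a genome back to a GenBank flat file (round-trip safe)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.id[:16] or "genome",
        name=re.sub(r"\W", "_", genome.id)[:16] or "genome",
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    L = len(genome)
    ftype = {v: k for k, v in _TYPED.items()}
    for f in genome.features:
        if f.wraps:
            loc = CompoundLocation([
                SimpleLocation(f.start, L, strand=f.strand),
                SimpleLocation(0, f.end, strand=f.strand),
            ])
        else:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        qualifiers = {"gene": [f.name], "note": [f"category={f.category}"]}
        if f.gene_type == "protein":
            qualifiers["transl_table"] = [str(TRANSLATION_TABLE)]
        rec.features.append(SeqFeature(loc, type=ftype[f.gene_type],
                                       qualifiers=qualifiers))
    SeqIO.write(rec, str(path), "genbank")


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs to FASTA."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def features_table(genome: AnnotatedGenome):
    """Feature table as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    L = len(genome)
    return pd.DataFrame(
        {
            "name": [f.name for f in genome.features],
            "type": [f.gene_type for f in genome.features],
            "category": [f.category for f in genome.features],
            "strand": [f.strand for f in genome.features],
            "start": [f.start for f in genome.features],
            "end": [f.end for f in genome.features],
            "wraps": [f.wraps for f in genome.features],
            "length_bp": [f.length(L) for f in genome.features],
        }
    )
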