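import pytest

from plastocomp.genome_io import AnnotatedGenome, GeneFeature, revcomp
from plastocomp.simulate import make_study_fixture


@pytest.fixture(scope="session")
def study():
    """Synthetic study pair: photosynthetic reference, reduced descendant
    lacking the photosynthesis genes, pairwise Ks ~ 0.8, with truth."""
    return make_study_fixture(7)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """The same fixture written out as GenBank files plus truth JSON."""
    d = tmp_path_factory.mktemp("study")
    make_study_fixture(7, out_dir=d)
    return d


@pytest.fixture
def build_genome():
    """Hand-build a circular annotated genome from (name, type, category,
    strand, gene 5'->3' sequence) tuples separated by fixed spacers."""

    def _build(genes, spacer="TTATATAATTTA", genome_id="toy"):
        parts, feats, pos = [], [], 0
        for name, gtype, cat, strand, gene_seq in genes:
            parts.append(spacer)
            pos += len(spacer)
            genomic = revcomp(gene_seq) if strand == -1 else gene_seq
            feats.append(GeneFeature(name, gtype, cat, strand,
                                     pos, pos + len(genomic)))
            parts.append(genomic)
            pos += len(genomic)
        parts.append(spacer)
        return AnnotatedGenome(genome_id, "".join(parts), feats)

    return _build
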