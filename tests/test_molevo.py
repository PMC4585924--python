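"""Codon alignment, NG86 counting vs the brute-force oracle, and the clock."""

import math

import numpy as np
import pytest

from plastocomp.molevo import (CodonAlignment, CodonAlignmentError,
                               align_codons, codon_differences, codon_sites,
                               divergence_time, jukes_cantor, mean_ks, ng86)

from ng86_oracle import SENSE, oracle_differences, oracle_kska, oracle_sites


def _aln(codons_a, codons_b, gene="g"):
    return CodonAlignment(gene, list(codons_a), list(codons_b),
                          sum(1 for a, b in zip(codons_a, codons_b)
                              if "-" not in a and "-" not in b))


def test_identical_sequences_have_zero_distance():
    r = ng86(_aln(["ATG", "GCT", "AAA"], ["ATG", "GCT", "AAA"]))
    assert r.Sd == r.Nd == 0
    assert r.ks == r.ka == 0.0
    assert not r.saturated


def test_single_synonymous_codon_saturates():
    """TTT vs TTC: one synonymous difference against a third of a synonymous
    site; the proportion exceeds the correction range."""
    r = ng86(_aln(["TTT"], ["TTC"]))
    assert r.Sd == 1 and r.Nd == 0
    assert r.S == pytest.approx(1 / 3)
    assert r.N == pytest.approx(8 / 3)
    assert r.pS == pytest.approx(3.0)
    assert r.ks is None and r.saturated


def test_two_codon_example_matches_oracle():
    a, b = ["GGG", "AAA"], ["GGA", "AAA"]
    r = ng86(_aln(a, b))
    expected = oracle_kska(a, b)
    assert r.Sd == pytest.approx(expected["Sd"]) == 1.0
    assert r.Nd == pytest.approx(expected["Nd"]) == 0.0
    assert r.S == pytest.approx(expected["S"])
    assert r.ks == pytest.approx(expected["ks"])


def test_site_counts_sum_to_three_per_codon():
    for codon in SENSE:
        s, n = codon_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert (s, n) == pytest.approx(oracle_sites(codon))


@pytest.mark.parametrize("seed", range(3))
def test_differences_match_oracle_on_random_pairs(seed):
    rng = np.random.default_rng(seed)
    for _ in range(200):
        c1, c2 = (SENSE[i] for i in rng.integers(0, len(SENSE), 2))
        assert codon_differences(c1, c2) == \
            pytest.approx(oracle_differences(c1, c2))


def test_ng86_is_symmetric():
    rng = np.random.default_rng(42)
    codons_a = [SENSE[i] for i in rng.integers(0, len(SENSE), 60)]
    codons_b = [SENSE[i] for i in rng.integers(0, len(SENSE), 60)]
    fwd = ng86(_aln(codons_a, codons_b))
    rev = ng86(_aln(codons_b, codons_a))
    for field in ("S", "N", "Sd", "Nd", "ks", "ka"):
        assert getattr(fwd, field) == pytest.approx(getattr(rev, field))


def test_sites_plus_nonsites_equals_three_per_compared_codon(study):
    for r in study.truth.gene_truths.values():
        assert r.S + r.N == pytest.approx(3 * r.n_codons)
        assert r.Sd + r.Nd <= 3 * r.n_codons


CDS = "ATG" + "GATTCAAGAGGT" * 12 + "TAA"


def test_align_identical_cds_has_no_gaps():
    aln = align_codons(CDS, CDS)
    assert aln.n_codons_compared == len(CDS) // 3 - 1  # stop trimmed
    assert "---" not in aln.codons_a + aln.codons_b


def test_align_detects_single_codon_deletion():
    deleted = CDS[:30] + CDS[33:]
    aln = align_codons(CDS, deleted)
    assert aln.codons_b.count("---") == 1
    assert aln.codons_a.count("---") == 0
    assert aln.n_codons_compared == len(deleted) // 3 - 1


def test_align_rejects_internal_stop():
    bad = CDS[:30] + "TGA" + CDS[33:]
    with pytest.raises(CodonAlignmentError):
        align_codons(CDS, bad)


def test_alignment_recovers_true_columns_on_simulated_genes(study):
    """With divergence below saturation the protein-guided alignment must
    reproduce the simulator's true (identity) codon correspondence."""
    from plastocomp.genome_io import extract_cds_and_upstream
    for gene, truth in list(study.truth.gene_truths.items())[:8]:
        cds_a = extract_cds_and_upstream(study.reference, gene, 0).cds
        cds_b = extract_cds_and_upstream(study.reduced, gene, 0).cds
        aln = align_codons(cds_a, cds_b, gene)
        assert "---" not in aln.codons_a + aln.codons_b
        est = ng86(aln)
        assert est.ks == pytest.approx(truth.ks)
        assert est.ka == pytest.approx(truth.ka)


def test_jukes_cantor_correction():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(1 - 0.4))
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None


def _result(ks, S=100.0):
    from plastocomp.molevo import KsKaResult
    return KsKaResult("g", 100, S, 200.0, 10.0, 5.0, 0.1, 0.025,
                      ks, 0.02, None, ks is not None and ks >= 1)


def test_mean_ks_unweighted():
    assert mean_ks([_result(0.5), _result(1.1)]) == pytest.approx(0.8)
    assert mean_ks([_result(0.7)]) == pytest.approx(0.7)


def test_mean_ks_excludes_undefined_and_weights_sites():
    results = [_result(0.5, S=100.0), _result(None), _result(1.1, S=300.0)]
    assert mean_ks(results) == pytest.approx(0.8)
    weighted = (0.5 * 100 + 1.1 * 300) / 400
    assert mean_ks(results, "site_weighted") == pytest.approx(weighted)
    with pytest.raises(ValueError):
        mean_ks([_result(None)])


def test_divergence_time_reproduces_study_numbers():
    est = divergence_time(0.816, 3.23e-10,
                          {"heterotroph": 0.00274, "autotroph": 0.008219})
    assert est.n_generations == pytest.approx(2.526e9, rel=1e-3)
    assert est.t_low_years == pytest.approx(6.92e6, rel=1e-2)
    assert est.t_high_years == pytest.approx(2.076e7, rel=1e-2)


def test_divergence_time_trivial_cases():
    assert divergence_time(0.0).n_generations == 0.0
    est = divergence_time(3.23e-4, 3.23e-10)
    assert est.n_generations == pytest.approx(1e6)
    half = divergence_time(0.816, per_lineage=True)
    assert half.n_generations == pytest.approx(
        divergence_time(0.816).n_generations / 2)


def test_divergence_time_is_linear():
    a = divergence_time(0.4, 1e-10, {"x": 2.0})
    b = divergence_time(0.8, 1e-10, {"x": 2.0})
    c = divergence_time(0.4, 1e-10, {"x": 4.0})
    assert b.n_generations == pytest.approx(2 * a.n_generations)
    assert c.times_years["x"] == pytest.approx(2 * a.times_years["x"])


def test_divergence_time_validation():
    with pytest.raises(ValueError):
        divergence_time(0.5, mu=0.0)
    with pytest.raises(ValueError):
        divergence_time(-0.1)
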