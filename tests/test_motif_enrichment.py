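import logging
from collections import Counter

import numpy as np
import pytest

from comparekit import (
    PWM, ValidationError,
    dinucleotide_shuffle, enrich_motifs, extract_promoters, gen_promoters,
    scan_best_score,
)
from comparekit.motif_enrichment import reverse_complement
from conftest import make_pwm, promoter_set_from_records, random_pwm
from _oracles import best_scan_oracle


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
    return {"chr1": seq}


@pytest.fixture
def toy_annotation():
    import pandas as pd
    return pd.DataFrame({
        "gene": ["GPLUS", "GMINUS", "GEDGE"],
        "chrom": ["chr1", "chr1", "chr1"],
        "tss": [1000, 1000, 100],
        "strand": ["+", "-", "+"],
    })


class TestExtractPromoters:
    def test_plus_strand_window(self, toy_genome, toy_annotation):
        proms = extract_promoters(["GPLUS"], toy_annotation, toy_genome,
                                  window_bp=200)
        gene, iv, seq = proms.records[0]
        assert (iv.start, iv.end) == (800, 1000)
        assert seq == toy_genome["chr1"][800:1000]
        assert len(seq) == 200

    def test_minus_strand_is_reverse_complemented(self, toy_genome,
                                                  toy_annotation):
        proms = extract_promoters(["GMINUS"], toy_annotation, toy_genome,
                                  window_bp=200)
        _, iv, seq = proms.records[0]
        assert (iv.start, iv.end) == (1000, 1200)
        assert seq == reverse_complement(toy_genome["chr1"][1000:1200])

    def test_truncation_at_contig_start_warns(self, toy_genome,
                                              toy_annotation, caplog):
        with caplog.at_level(logging.WARNING, logger="comparekit"):
            proms = extract_promoters(["GEDGE"], toy_annotation, toy_genome,
                                      window_bp=500)
        _, iv, seq = proms.records[0]
        assert (iv.start, iv.end) == (0, 100)
        assert len(seq) == 100
        assert any("truncated" in r.message for r in caplog.records)

    def test_unknown_gene_rejected(self, toy_genome, toy_annotation):
        with pytest.raises(ValidationError, match="NOPE"):
            extract_promoters(["NOPE"], toy_annotation, toy_genome, 100)

    def test_unknown_contig_rejected(self, toy_genome, toy_annotation):
        ann = toy_annotation.copy()
        ann.loc[0, "chrom"] = "chrMissing"
        with pytest.raises(ValidationError, match="chrMissing"):
            extract_promoters(["GPLUS"], ann, toy_genome, 100)

    def test_bed_export(self, toy_genome, toy_annotation, tmp_path):
        from comparekit import read_bed
        bed = tmp_path / "p.bed"
        extract_promoters(["GPLUS", "GMINUS"], toy_annotation, toy_genome,
                          window_bp=150, bed_out=bed)
        intervals = read_bed(bed)
        assert [iv.name for iv in intervals] == ["GPLUS", "GMINUS"]

    def test_fasta_genome_path(self, toy_genome, toy_annotation, tmp_path):
        from comparekit import write_fasta
        fa = tmp_path / "g.fa"
        write_fasta(toy_genome, fa)
        proms = extract_promoters(["GPLUS"], toy_annotation, fa, window_bp=50)
        assert proms.records[0][2] == toy_genome["chr1"][950:1000]


class TestScan:
    def test_consensus_scores_sum_of_max_log_odds(self):
        pwm = make_pwm(consensus="ACGTACG", strength=0.9)
        expected = np.sum(np.log2(np.max(pwm.matrix, axis=0)
                                  / pwm.background[0]))
        hit = scan_best_score("ACGTACG", pwm)
        assert hit.score == pytest.approx(expected)
        assert hit.position == 0

    def test_background_pwm_scores_zero_everywhere(self):
        uniform = PWM("BG", np.full((4, 5), 0.25))
        hit = scan_best_score("ACGTACGTACGT", uniform)
        assert hit.score == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            pwm = random_pwm(rng, "R", length=4)
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 12)])
            expected = best_scan_oracle(
                seq, pwm.matrix.tolist(), pwm.background.tolist()
            )
            assert scan_best_score(seq, pwm).score == \
                pytest.approx(expected, abs=1e-10)

    def test_ambiguous_bases_score_background(self):
        pwm = make_pwm(consensus="ACGT", strength=0.9)
        hit = scan_best_score("NNNN", pwm)
        assert hit.score == pytest.approx(0.0, abs=1e-12)

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValidationError):
            scan_best_score("ACG", make_pwm(consensus="ACGTACG"))

    def test_strand_symmetry(self, rng):
        pwm = random_pwm(rng, "R", length=5)
        for _ in range(5):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
            fwd = scan_best_score(seq, pwm).score
            rev = scan_best_score(reverse_complement(seq), pwm).score
            assert fwd == pytest.approx(rev, abs=1e-10)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        for _ in range(10):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
            shuffled = dinucleotide_shuffle(seq, rng)
            assert len(shuffled) == len(seq)
            assert Counter(zip(seq, seq[1:])) == \
                Counter(zip(shuffled, shuffled[1:]))

    def test_endpoints_preserved(self, rng):
        seq = "ACGTTGCATGCAGTACCGTA"
        shuffled = dinucleotide_shuffle(seq, rng)
        assert shuffled[0] == seq[0]
        assert shuffled[-1] == seq[-1]

    def test_shuffles_actually_vary(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        outcomes = {dinucleotide_shuffle(seq, rng) for _ in range(5)}
        assert len(outcomes) > 1


class TestEnrichMotifs:
    def test_planted_motif_ranks_first_among_decoys(self, rng):
        planted = make_pwm("PLANTED", consensus="ACGTACG", strength=0.95)
        decoys = [random_pwm(rng, f"DECOY{i:02d}") for i in range(10)]
        records, _ = gen_promoters(120, 250, planted, plant_rate=0.8, seed=17)
        proms = promoter_set_from_records(records, 250)
        results = enrich_motifs(proms, [planted] + decoys,
                                n_shuffles=40, seed=23)
        assert results[0].motif_id == "PLANTED"
        assert results[0].rank == 1
        assert results[0].z < 0  # negative z = enriched

    def test_results_sorted_and_ranks_unique(self, rng):
        pwms = [random_pwm(rng, f"M{i}") for i in range(5)]
        records, _ = gen_promoters(30, 120, pwms[0], plant_rate=0.0, seed=3)
        proms = promoter_set_from_records(records, 120)
        results = enrich_motifs(proms, pwms, n_shuffles=25, seed=4)
        nlp = [r.neg_log10_p for r in results]
        assert nlp == sorted(nlp, reverse=True)
        assert [r.rank for r in results] == list(range(1, 6))

    def test_deterministic_under_seed(self, rng):
        pwms = [random_pwm(rng, f"M{i}") for i in range(3)]
        records, _ = gen_promoters(20, 100, pwms[0], plant_rate=0.2, seed=5)
        proms = promoter_set_from_records(records, 100)
        a = enrich_motifs(proms, pwms, n_shuffles=25, seed=6)
        b = enrich_motifs(proms, pwms, n_shuffles=25, seed=6)
        assert [(r.motif_id, r.z, r.p) for r in a] == \
            [(r.motif_id, r.z, r.p) for r in b]

    def test_too_few_shuffles_rejected(self):
        pwm = make_pwm()
        records, _ = gen_promoters(5, 50, pwm, plant_rate=0.0, seed=1)
        proms = promoter_set_from_records(records, 50)
        with pytest.raises(ValidationError, match="unstable null"):
            enrich_motifs(proms, [pwm], n_shuffles=19, seed=0)

    def test_x10_scale_column(self, rng):
        pwms = [random_pwm(rng, "M0")]
        records, _ = gen_promoters(20, 100, pwms[0], plant_rate=0.0, seed=8)
        proms = promoter_set_from_records(records, 100)
        (result,) = enrich_motifs(proms, pwms, n_shuffles=25, seed=9)
        assert result.neg_log10_p_x10 == pytest.approx(10 * result.neg_log10_p)
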