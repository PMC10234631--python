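"""Window extraction, frequency matrices, logo math, and site scoring."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from scipy import stats

from foxsplice import synthetic
from foxsplice.config import SimulationConfig
from foxsplice.splice import (IntronRecord, classify_py_tract, extract_splice_sites,
                              gene_average_pfm, information_content, make_windows,
                              position_frequency, score_site, train_wmm)

# hand-built toy intron: 3 exon nt | gt ... 18C py tract ... ag | 3 exon nt
EXON_L = "CCAAA"
INTRON = "GT" + "ACGT" + "T" * 10 + "C" * 18 + "AG"
EXON_R = "TTTGG"
TOY_FIVE = "AAA" + "gtacgt"
TOY_THREE = ("c" * 18).lower() + "ag" + "TTT"
TOY_PY = "c" * 18


def toy_genome(strand="+"):
    """Place the toy intron on a small chromosome; returns (genome, bed_row)."""
    pad = "A" * 10
    locus = EXON_L + INTRON + EXON_R
    if strand == "-":
        locus = reverse_complement(locus)
    seq = pad + locus + pad
    start = len(pad) + len(EXON_L)
    return {"chrT": seq}, ("chrT", start, start + len(INTRON), "FOX|0", 0, strand)


class TestExtraction:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_toy_intron_windows(self, strand):
        genome, bed = toy_genome(strand)
        (rec,) = extract_splice_sites(genome, [bed])
        assert rec.five_ss == TOY_FIVE
        assert rec.three_ss == TOY_THREE
        assert rec.py_tract == TOY_PY
        assert rec.canonical

    def test_py_tract_is_three_ss_prefix(self, intron_set):
        records = extract_splice_sites(intron_set.genome, intron_set.bed_rows())
        assert all(r.py_tract == r.three_ss[:18] for r in records)

    def test_generator_roundtrip_exact(self, intron_set):
        records = extract_splice_sites(intron_set.genome, intron_set.bed_rows())
        assert len(records) == len(intron_set.records)
        for generated, extracted in zip(intron_set.records, records):
            assert generated.five_ss == extracted.five_ss
            assert generated.three_ss == extracted.three_ss
            assert generated.py_tract == extracted.py_tract

    def test_strand_involution(self, intron_set):
        """Extracting from the reverse-complemented genome with flipped
        coordinates and strand yields identical transcript-orientation windows."""
        chrom = next(iter(intron_set.genome))
        seq = intron_set.genome[chrom]
        flipped_genome = {chrom: reverse_complement(seq)}
        L = len(seq)
        flipped_bed = [(r.chrom, L - r.end, L - r.start, r.name, 0,
                        "-" if r.strand == "+" else "+")
                       for r in intron_set.records]
        records = extract_splice_sites(flipped_genome, flipped_bed)
        for generated, extracted in zip(intron_set.records, records):
            assert generated.five_ss == extracted.five_ss
            assert generated.three_ss == extracted.three_ss

    def test_out_of_bounds_interval_skipped(self):
        genome, bed = toy_genome()
        bad = ("chrT", 0, 2, "BAD|0", 0, "+")
        records = extract_splice_sites(genome, [bad, bed])
        assert [r.gene_id for r in records] == ["FOX"]

    def test_noncanonical_flagged_not_dropped(self):
        genome = {"chrT": "A" * 10 + "CCAAA" + "CC" + "T" * 24 + "CC" + "TTTGG" + "A" * 10}
        bed = ("chrT", 15, 15 + 28, "NC|0", 0, "+")
        (rec,) = extract_splice_sites(genome, [bed])
        assert not rec.canonical


class TestPositionFrequency:
    def test_half_half_columns(self):
        pfm = position_frequency(["C" * 18, "T" * 18])
        frame = pfm.to_frame()
        assert np.allclose(frame["C"], 0.5) and np.allclose(frame["U"], 0.5)

    def test_single_sequence_indicator(self):
        pfm = position_frequency(["ACGT"])
        assert np.allclose(pfm.probs.max(axis=1), 1.0)
        assert pfm.probs.sum() == pytest.approx(4.0)

    def test_columns_sum_to_one(self, intron_set):
        pfm = position_frequency([r.py_tract for r in intron_set.records])
        assert np.allclose(pfm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_n_excluded_from_denominator(self):
        pfm = position_frequency(["AC", "NC"])
        assert pfm.probs[0, 0] == 1.0  # A column: 1 of 1 informative
        assert pfm.probs[1, 1] == 1.0

    def test_sampling_matches_known_profile(self, config):
        iset = synthetic.gen_intron_set(config, "crich", n=1000)
        pfm = position_frequency([r.py_tract for r in iset.records])
        expected = config.pytract_profile_crich
        sigma = np.sqrt(expected * (1 - expected) / pfm.n_sequences)
        assert (np.abs(pfm.probs - expected) <= 3 * np.maximum(sigma, 1e-12)).mean() > 0.98

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_frequency([])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            position_frequency(["AAA", "AAAA"])


class TestGeneAveragePfm:
    def test_single_intron_indicator(self, intron_set):
        pfm = gene_average_pfm(intron_set.records[:1])
        assert np.allclose(np.sort(pfm.probs, axis=1)[:, -1], 1.0)

    def test_two_opposite_introns_half_half(self):
        recs = [IntronRecord("g", i, "c", 0, 30, "+",
                             "AAAgtacgt", seq * 18 + "ag" + "AAA", seq * 18)
                for i, seq in enumerate(["c", "t"])]
        pfm = gene_average_pfm(recs)
        frame = pfm.to_frame()
        assert np.allclose(frame["C"], 0.5) and np.allclose(frame["U"], 0.5)

    def test_matches_per_position_tally(self, intron_set):
        gene = intron_set.records[0].gene_id
        introns = [r for r in intron_set.records if r.gene_id == gene]
        pfm = gene_average_pfm(introns)
        for pos_idx in range(18):
            col = [r.py_tract[pos_idx].upper() for r in introns]
            for base_idx, base in enumerate("ACGT"):
                assert pfm.probs[pos_idx, base_idx] == pytest.approx(
                    col.count(base) / len(col))


class TestInformationContent:
    @pytest.mark.parametrize("column,bits", [
        ([0.25, 0.25, 0.25, 0.25], 0.0),
        ([1.0, 0.0, 0.0, 0.0], 2.0),
        ([0.5, 0.5, 0.0, 0.0], 1.0),
    ])
    def test_analytic_columns(self, column, bits):
        from foxsplice.splice import PositionFrequencyMatrix
        pfm = PositionFrequencyMatrix([0], np.array([column]), 1)
        ic, logo = information_content(pfm)
        assert ic[0] == pytest.approx(bits)
        assert logo[0] == pytest.approx(np.array(column) * bits)

    def test_bounds(self, intron_set):
        pfm = position_frequency([r.py_tract for r in intron_set.records])
        ic, _ = information_content(pfm)
        assert ((ic >= 0) & (ic <= 2)).all()


class TestClassifyPyTract:
    def test_c_rich_by_mean_rule(self):
        label, freqs = classify_py_tract(["C" * 9 + "T" * 5 + "A" * 4])
        assert label == "C-rich" and freqs["C"] > freqs["U"]

    def test_exact_tie_is_neither(self):
        label, _ = classify_py_tract(["C" * 9 + "T" * 9])
        assert label == "neither"

    def test_crich_profile_per_intron_rate_matches_exact(self):
        """At P(C)=0.5, P(U)=0.2 per position the exact trinomial probability
        that a single 18-nt tract has more C than U is 0.9271; the observed
        per-intron C-rich rate matches it within 3 binomial sigma."""
        import math
        p_crich = sum(
            math.factorial(18) / (math.factorial(c) * math.factorial(u)
                                  * math.factorial(18 - c - u))
            * 0.5 ** c * 0.2 ** u * 0.3 ** (18 - c - u)
            for c in range(19) for u in range(19 - c) if c > u)
        n = 1000
        cfg = SimulationConfig(seed=0)
        iset = synthetic.gen_intron_set(cfg, "crich", n=n)
        rate = np.mean([classify_py_tract(r.py_tract)[0] == "C-rich"
                        for r in iset.records])
        assert abs(rate - p_crich) <= 3 * np.sqrt(p_crich * (1 - p_crich) / n)

    def test_crich_profile_gene_level_classification(self):
        """Averaged over a gene's introns, the C-rich call is near-certain:
        >= 95% of 3-intron genes classify C-rich in every seeded run."""
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            iset = synthetic.gen_intron_set(cfg, "crich", n=200)
            by_gene = {}
            for r in iset.records:
                by_gene.setdefault(r.gene_id, []).append(r)
            labels = [classify_py_tract(gene_average_pfm(rs))[0]
                      for rs in by_gene.values()]
            assert np.mean([lab == "C-rich" for lab in labels]) >= 0.95


class TestWeightMatrix:
    def test_consensus_training_scores_two_bits_per_position(self):
        sites = ["AAAGTAAGT"] * 10
        model = train_wmm(sites, "5ss", pseudocount=0.0)
        assert score_site(model, "AAAGTAAGT") == pytest.approx(2.0 * 9)

    def test_background_identical_to_training_scores_zero(self):
        sites = ["ACGTACGTA", "CGTACGTAC", "GTACGTACG", "TACGTACGT"]
        model = train_wmm(sites, "5ss", pseudocount=0.0)
        # every column of this training set is uniform over ACGT
        assert np.allclose(model.score_table, 0.0)
        assert score_site(model, "AAAAAAAAA") == pytest.approx(0.0)

    def test_score_additivity(self):
        rng = np.random.default_rng(1)
        sites = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(50)]
        model = train_wmm(sites, "5ss")
        window = "ACGTACGTA"
        brute = sum(model.score_table[i, "ACGT".index(ch)]
                    for i, ch in enumerate(window))
        assert score_site(model, window) == pytest.approx(brute)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_wmm(["AAA"], "5ss")
        model = train_wmm(["AAAGTAAGT"], "5ss")
        with pytest.raises(ValueError):
            score_site(model, "AAAA")

    def test_strict_mode_rejects_ambiguity(self):
        model = train_wmm(["AAAGTAAGT"], "5ss")
        with pytest.raises(ValueError):
            score_site(model, "AAAGTAANT", strict=True)
        with pytest.warns(UserWarning):
            score_site(model, "AAAGTAANT")

    def test_heldout_sites_outscore_random(self):
        """Windows from the training profile score above background-random
        windows (one-sided rank test)."""
        rng = np.random.default_rng(2)
        profile = np.array([[0.7, 0.1, 0.1, 0.1]] * 9)

        def draw(n):
            return ["".join(np.array(list("ACGT"))[
                [rng.choice(4, p=profile[i]) for i in range(9)]]) for _ in range(n)]

        model = train_wmm(draw(300), "5ss")
        heldout = [score_site(model, w) for w in draw(500)]
        random_windows = [score_site(model, "".join(rng.choice(list("ACGT"), 9)))
                          for _ in range(500)]
        stat = stats.mannwhitneyu(heldout, random_windows, alternative="greater")
        assert stat.pvalue < 0.01
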