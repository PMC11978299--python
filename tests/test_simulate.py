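"""Synthetic-data generator: region arithmetic, determinism, editing statistics."""

import numpy as np
import pysam
import pytest
from scipy import stats

from dramseq.genemodel import Transcriptome, revcomp
from dramseq.pileup import build_pileup, extract_candidates
from dramseq.simulate import (
    ConditionSpec,
    SyntheticTruth,
    generate_transcriptome,
    plant_m5c_sites,
    simulate_bisulfite_amplicon,
    simulate_reads,
    simulate_sanger_trace,
    write_fasta,
)


class TestGenerateTranscriptome:
    def test_region_lengths_follow_fractions(self):
        tx = generate_transcriptome(1, (300, 300), (0.2, 0.5, 0.3), seed=1)
        g = tx.genes[0]
        assert (g.utr5_len, g.cds_len, g.utr3_len) == (60, 150, 90)
        assert g.cds_len % 3 == 0

    def test_fraction_sum_validation(self):
        with pytest.raises(ValueError):
            generate_transcriptome(1, (300, 300), (0.5, 0.5, 0.3), seed=1)

    def test_deterministic_fasta(self, tmp_path):
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(generate_transcriptome(5, seed=7).references, str(a))
        write_fasta(generate_transcriptome(5, seed=7).references, str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_both_strands_and_cds_multiple_of_three(self):
        tx = generate_transcriptome(10, seed=2)
        assert {g.strand for g in tx.genes} == {"+", "-"}
        assert all(g.cds_len % 3 == 0 for g in tx.genes)


class TestPlantSites:
    def test_degenerate_weights_put_all_sites_in_cds(self, toy_transcriptome):
        sites = plant_m5c_sites(
            toy_transcriptome, 10, region_weights={"CDS": 1.0}, seed=4
        )
        tx = toy_transcriptome
        assert len(sites) == 10
        for s in sites:
            g = tx.gene_by_id(s.transcript_id)
            assert g.region_of(s.position) == "CDS"

    def test_fixed_rate_range(self, toy_transcriptome):
        sites = plant_m5c_sites(
            toy_transcriptome, 5, rate_range=(0.147, 0.147), seed=4
        )
        assert all(s.edit_rate == pytest.approx(0.147) for s in sites)

    def test_sites_are_sense_strand_cytosines_and_unique(self, toy_transcriptome, toy_truth):
        seen = set()
        for s in toy_truth:
            g = toy_transcriptome.gene_by_id(s.transcript_id)
            assert toy_transcriptome.transcript_seq(g)[s.position] == "C"
            assert (s.transcript_id, s.position) not in seen
            seen.add((s.transcript_id, s.position))

    def test_region_counts_within_binomial_bounds(self):
        tx = generate_transcriptome(30, (600, 1200), seed=5)
        weights = {"CDS": 0.6, "UTR3": 0.3, "UTR5": 0.1}
        sites = plant_m5c_sites(tx, 200, region_weights=weights, seed=5)
        counts = {"CDS": 0, "UTR3": 0, "UTR5": 0}
        for s in sites:
            g = tx.gene_by_id(s.transcript_id)
            counts[g.region_of(s.position)] += 1
        for region, w in weights.items():
            lo = stats.binom.ppf(0.005, 200, w)
            hi = stats.binom.ppf(0.995, 200, w)
            assert lo <= counts[region] <= hi


class TestSimulateReads:
    def test_null_condition_gives_zero_mismatches(self, toy_transcriptome, toy_truth, tmp_path):
        spec = ConditionSpec(
            "DRAM_MUT", coverage_mean=20, rate_multiplier=0.0, seed=9
        )
        (path,) = simulate_reads(
            toy_transcriptome, toy_truth, spec, out_dir=str(tmp_path)
        )
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            assert all(read.get_tag("NM") == 0 for read in fh)

    def test_determinism_byte_identical_sam(self, toy_transcriptome, toy_truth, tmp_path):
        spec = ConditionSpec("DRAM", coverage_mean=15, error_rate=0.001, seed=21)
        (a,) = simulate_reads(
            toy_transcriptome, toy_truth, spec, out_dir=str(tmp_path / "a")
        )
        (b,) = simulate_reads(
            toy_transcriptome, toy_truth, spec, out_dir=str(tmp_path / "b")
        )
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_read_count_conservation(self, toy_transcriptome, tmp_path):
        spec = ConditionSpec("DRAM", coverage_mean=30, rate_multiplier=0.0, seed=3)
        (path,) = simulate_reads(toy_transcriptome, [], spec, editor="CBE", out_dir=str(tmp_path))
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            n = sum(1 for _ in fh)
        expected = sum(
            round(30 * g.length / 100) for g in toy_transcriptome.genes
        )
        assert n == expected

    def test_edited_fraction_matches_binomial_oracle(self, tmp_path):
        """One site at rate 0.5, deep coverage: pooled in-window edited fraction ~ Binomial."""
        tx = generate_transcriptome(1, (400, 400), seed=13)
        g = tx.genes[0]
        tseq = tx.transcript_seq(g)
        pos = next(
            t for t in range(150, 250) if tseq[t] == "C"
        )
        site = SyntheticTruth("s", g.transcript_id, pos, "CBE", 0.5)
        spec = ConditionSpec("DRAM", coverage_mean=2000, seed=17)
        (path,) = simulate_reads(tx, [site], spec, out_dir=str(tmp_path))
        pile = build_pileup(path, tx.references)
        cands = extract_candidates(pile, tx, "C2U")
        window_pos = {
            g.to_genomic(t)
            for t in range(pos - 20, pos + 21)
            if 0 <= t < g.length and tseq[t] == "C"
        }
        sub = cands[cands["pos"].isin(window_pos)]
        edited, cov = sub["edited_reads"].sum(), sub["coverage"].sum()
        frac = edited / cov
        sd = np.sqrt(0.5 * 0.5 / cov)
        assert abs(frac - 0.5) <= 3 * sd

    def test_knockout_attenuation_fold(self, tmp_path):
        """DRAM vs 0.1x-attenuated knockout differ >=1.5-fold at planted sites."""
        tx = generate_transcriptome(3, (500, 700), seed=23)
        truth = plant_m5c_sites(tx, 6, rate_range=(0.3, 0.3), seed=24)
        ratios = {}
        for name, mult in (("DRAM", 1.0), ("KNOCKOUT", 0.1)):
            spec = ConditionSpec(name, coverage_mean=300, rate_multiplier=mult, seed=25)
            (path,) = simulate_reads(tx, truth, spec, out_dir=str(tmp_path / name))
            pile = build_pileup(path, tx.references)
            cands = extract_candidates(pile, tx, "C2U")
            # pooled edited fraction over all planted-site windows
            win = set()
            for s in truth:
                g = tx.gene_by_id(s.transcript_id)
                tseq = tx.transcript_seq(g)
                win |= {
                    (g.chrom, g.to_genomic(t))
                    for t in range(s.position - 20, s.position + 21)
                    if 0 <= t < g.length and tseq[t] == "C"
                }
            sub = cands[[(r.ref, r.pos) in win for r in cands.itertuples()]]
            ratios[name] = sub["edited_reads"].sum() / sub["coverage"].sum()
        assert ratios["DRAM"] / ratios["KNOCKOUT"] >= 1.5

    def test_strand_involution(self, tmp_path):
        """Reverse-complementing the reference and flipping gene strand leaves
        transcript-space edit counts unchanged."""
        tx = generate_transcriptome(1, (400, 400), seed=31)
        g = tx.genes[0]
        assert g.strand == "+"
        flipped_ref = {g.chrom: revcomp(tx.references[g.chrom])}
        L = len(tx.references[g.chrom])
        from dramseq.genemodel import GeneModel

        g_flip = GeneModel(
            g.transcript_id,
            g.chrom,
            L - g.end,
            L - g.start,
            "-",
            g.utr5_len,
            g.cds_len,
            g.utr3_len,
        )
        tx_flip = Transcriptome(flipped_ref, [g_flip])
        assert tx.transcript_seq(g) == tx_flip.transcript_seq(g_flip)
        truth = plant_m5c_sites(tx, 4, rate_range=(0.4, 0.4), seed=32)
        spec = ConditionSpec("DRAM", coverage_mean=50, seed=33)
        counts = {}
        for label, t, gene in (("fwd", tx, g), ("rev", tx_flip, g_flip)):
            (path,) = simulate_reads(t, truth, spec, out_dir=str(tmp_path / label))
            cands = extract_candidates(build_pileup(path, t.references), t, "C2U")
            counts[label] = {
                gene.to_transcript(r.pos): (r.edited_reads, r.coverage)
                for r in cands.itertuples()
            }
        assert counts["fwd"] == counts["rev"]

    def test_read_length_longer_than_transcript_skips(self, toy_transcriptome, tmp_path):
        spec = ConditionSpec("DRAM", coverage_mean=5, rate_multiplier=0.0, seed=1)
        (path,) = simulate_reads(
            toy_transcriptome, [], spec, read_length=10_000, editor="CBE", out_dir=str(tmp_path)
        )
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            assert sum(1 for _ in fh) == 0


class TestBisulfiteAmplicon:
    AMPLICON = "ATTCGGACCATCGATCAAGCTTCGGA"

    def _site(self, frac):
        return SyntheticTruth(
            "s", "amp", self.AMPLICON.index("C"), "CBE", 0.0, m5c_fraction=frac
        )

    def test_unmethylated_fully_converts(self):
        reads = simulate_bisulfite_amplicon(self._site(0.0), self.AMPLICON, 200, 1.0, seed=1)
        pos = self.AMPLICON.index("C")
        assert all(seq[pos] == "T" for _, seq in reads)

    def test_fully_methylated_always_retains(self):
        reads = simulate_bisulfite_amplicon(self._site(1.0), self.AMPLICON, 200, 0.7, seed=1)
        pos = self.AMPLICON.index("C")
        assert all(seq[pos] == "C" for _, seq in reads)

    def test_retained_fraction_within_three_sd(self):
        reads = simulate_bisulfite_amplicon(self._site(0.755), self.AMPLICON, 10_000, 1.0, seed=2)
        pos = self.AMPLICON.index("C")
        frac = sum(seq[pos] == "C" for _, seq in reads) / len(reads)
        sd = np.sqrt(0.755 * 0.245 / 10_000)
        assert abs(frac - 0.755) <= 3 * sd

    def test_read_count_exact_and_deterministic(self):
        a = simulate_bisulfite_amplicon(self._site(0.5), self.AMPLICON, 50, 1.0, seed=3)
        b = simulate_bisulfite_amplicon(self._site(0.5), self.AMPLICON, 50, 1.0, seed=3)
        assert len(a) == 50 and a == b


class TestSangerTrace:
    def test_zero_rate_gives_pure_columns(self):
        trace = simulate_sanger_trace(0.0, "ACGTC", 4)
        assert (trace.max(axis=1) == 1.0).all()

    def test_secondary_peak_proportion(self):
        trace = simulate_sanger_trace(0.136, "GCAGT", 1)
        assert trace.loc[1, "C"] == pytest.approx(0.864)
        assert trace.loc[1, "T"] == pytest.approx(0.136)

    def test_columns_sum_to_one(self):
        trace = simulate_sanger_trace(0.42, "AACGT", 0)
        assert np.allclose(trace.sum(axis=1), 1.0)

    def test_rejects_uneditable_base(self):
        with pytest.raises(ValueError):
            simulate_sanger_trace(0.1, "GGGG", 0)
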