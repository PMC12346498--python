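"""Pileup construction, variant calling, SNP subtraction, and codon effects."""

import numpy as np
import pytest

from mitokit.editing import (
    PileupColumn,
    VariantSite,
    build_pileup,
    build_pileup_from_sam,
    call_sites,
    classify_effect,
    column_frequency,
    load_editing_table,
    percent,
    subtract_snps,
    summarize_editing,
)
from mitokit.seqcore import FrameError, round_half_up, translate
from mitokit.synthetic import simulate_amplicon_reads


def random_cds(seed: int, n_codons: int) -> str:
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def column(ref, pos, cov, a, c, g, t, gene="g"):
    return PileupColumn(ref_id=gene, pos=pos, ref_base=ref, coverage=cov, counts=(a, c, g, t))


def site(gene, pos, ref="C", alt="T", freq=0.5, cov=100):
    counts = [0, 0, 0, 0]
    counts["ACGT".index(ref)] = int(cov * (1 - freq))
    counts["ACGT".index(alt)] = cov - counts["ACGT".index(ref)]
    return VariantSite(gene=gene, cds_position=pos, ref_base=ref, alt_base=alt,
                       frequency=freq, coverage=cov, counts=tuple(counts),
                       alts=((alt, counts["ACGT".index(alt)], freq),))


class TestBuildPileup:
    def test_error_free_tiling(self):
        ref = random_cds(1, 80)
        reads = simulate_amplicon_reads(ref, [], depth=10, read_len=60, seed=2)
        pileup = build_pileup(ref, reads)
        mid = [col for col in pileup if 60 <= col.pos <= len(ref) - 60]
        for col in mid:
            assert col.counts["ACGT".index(col.ref_base)] == col.coverage
            assert col.coverage >= 9

    def test_planted_alt_within_binomial_noise(self):
        ref = random_cds(3, 120)
        pos = 181
        reads = simulate_amplicon_reads(ref, [(pos, "T", 0.5)], depth=200, read_len=100, seed=4)
        (col,) = [c for c in build_pileup(ref, reads) if c.pos == pos]
        frac = col.counts[3] / col.coverage
        se = np.sqrt(0.25 / col.coverage)
        assert abs(frac - 0.5) <= 3 * se

    def test_empty_reads_empty_pileup(self):
        assert build_pileup("ACGTACGT" * 20, []) == []

    def test_sam_input_round_trip(self, tmp_path):
        ref = random_cds(5, 60)
        reads = simulate_amplicon_reads(ref, [(40, "T", 1.0)], depth=6, read_len=80, seed=6)
        sam = tmp_path / "r.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:geneX\tLN:%d\n" % len(ref))
            for r in reads:
                start = int(r.name.split("|start=")[1].split("|")[0])
                fh.write(f"{r.name.split('|')[0]}\t0\tgeneX\t{start}\t60\t{len(r.seq)}M\t*\t0\t0\t{r.seq}\t*\n")
        direct = {c.pos: c.counts for c in build_pileup(ref, reads, ref_id="geneX")}
        via_sam = {c.pos: c.counts for c in build_pileup_from_sam(str(sam), ref, "geneX")}
        assert via_sam == direct

    def test_sam_wrong_reference_rejected(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:other\tLN:100\n")
        with pytest.raises(ValueError, match="other"):
            build_pileup_from_sam(str(sam), "ACGT" * 25, "geneX")


class TestCallSites:
    def test_published_row_cox2_721(self, params):
        col = column("C", 721 + 100, 205, 0, 141, 0, 64, gene="cox2")
        (s,) = call_sites([col], params, flank=100)
        assert (s.gene, s.cds_position, s.alt_base) == ("cox2", 721, "T")
        assert s.frequency_2dp == 0.31
        assert s.all_subs == "CT"
        assert s.focus

    def test_published_multi_alt_row_nad5_1510(self, params):
        col = column("G", 1510 + 100, 278, 40, 3, 235, 0, gene="nad5")
        (s,) = call_sites([col], params, flank=100)
        assert s.alt_base == "A"
        assert s.all_subs == "GA GC"
        assert s.frequency_2dp == 0.15

    def test_low_coverage_not_called(self, params):
        col = column("C", 150, 4, 0, 2, 0, 2)
        assert call_sites([col], params, flank=100) == []

    def test_low_frequency_not_called(self, params):
        col = column("C", 150, 450, 0, 407, 43, 0)  # 43/450 = 0.096 < 0.10
        assert call_sites([col], params, flank=100) == []

    def test_flank_positions_get_negative_indices(self, params):
        col = column("C", 40, 100, 0, 50, 0, 50)
        (s,) = call_sites([col], params, flank=100, cds_len=300)
        assert s.cds_position == -61 and not s.in_cds

    def test_calling_is_monotone_in_thresholds(self, params):
        rng = np.random.default_rng(9)
        cols = []
        for pos in range(101, 401):
            cov = int(rng.integers(3, 60))
            alt = int(rng.integers(0, cov + 1))
            cols.append(column("C", pos, cov, 0, cov - alt, 0, alt))
        base = call_sites(cols, params, flank=100)
        stricter_freq = call_sites(cols, params.with_overrides(edit_min_freq=0.3), flank=100)
        stricter_cov = call_sites(cols, params.with_overrides(edit_min_cov=20), flank=100)
        keys = lambda sites: {(s.cds_position) for s in sites}
        assert keys(stricter_freq) <= keys(base)
        assert keys(stricter_cov) <= keys(base)

    def test_frequency_rederivable_from_counts(self, params):
        rng = np.random.default_rng(10)
        cols = []
        for pos in range(101, 131):
            g = int(rng.integers(0, 10))
            cols.append(column("C", pos, 50 + g, 0, 30, g, 20))
        for s in call_sites(cols, params, flank=100):
            col = [c for c in cols if c.pos == s.cds_position + 100][0]
            non_ref = sum(n for b, n in zip("ACGT", col.counts) if b != col.ref_base)
            assert s.frequency == pytest.approx(non_ref / col.coverage)

    def test_all_published_rows_frequency_recomputed(self, params):
        table = load_editing_table()
        for _, row in table.iterrows():
            col = column(row["Reference"], int(row["Position"]) + 100, int(row["Coverage"]),
                         int(row["A"]), int(row["C"]), int(row["G"]), int(row["T"]),
                         gene=row["Region"])
            assert round_half_up(column_frequency(col), 2) == pytest.approx(row["Frequency"])


class TestSubtractSnps:
    def test_published_three_overlaps(self):
        rna = [site("cox2", 698), site("cox2", 721), site("nad6", 26), site("atp1", 69, ref="G", alt="A")]
        dna = [site("cox2", 698), site("cox2", 721), site("nad6", 26)]
        kept, removed = subtract_snps(rna, dna)
        assert len(removed) == 3 and len(kept) == 1
        assert kept[0].gene == "atp1"

    def test_disjoint_lists_untouched(self):
        rna = [site("cox2", 10)]
        dna = [site("nad4", 10), site("cox2", 11)]
        kept, removed = subtract_snps(rna, dna)
        assert kept == rna and removed == []

    def test_603_candidates_minus_3_overlaps(self):
        rng = np.random.default_rng(12)
        positions = rng.choice(np.arange(1, 5000), size=603, replace=False)
        rna = [site("g", int(p)) for p in positions]
        dna = [site("g", int(p)) for p in positions[:3]]
        kept, removed = subtract_snps(rna, dna)
        assert (len(kept), len(removed)) == (600, 3)

    def test_match_on_position_not_alt(self):
        kept, removed = subtract_snps([site("g", 5, alt="T")], [site("g", 5, alt="A")])
        assert kept == [] and len(removed) == 1


class TestClassifyEffect:
    def test_stop_gain_caa_to_taa(self):
        cds = random_cds(20, 250)
        pos = 718
        cds = cds[: pos - 1] + "CAA" + cds[pos + 2 :]
        e = classify_effect(site("atp6", pos), cds)
        assert (e.codon_pos, e.ref_codon, e.edited_codon, e.effect) == (1, "CAA", "TAA", "stop_gain")

    def test_stop_gain_cga_to_tga_at_codon_3(self):
        cds = random_cds(21, 80)
        cds = cds[:6] + "CGA" + cds[9:]
        e = classify_effect(site("rps19", 7), cds)
        assert (e.codon_index, e.codon_pos, e.edited_codon, e.effect) == (3, 1, "TGA", "stop_gain")

    def test_synonymous_ctc_to_ctt(self):
        cds = "ATG" + "CTC" + "TAA"
        e = classify_effect(site("g", 6), cds)
        assert (e.ref_aa, e.edited_aa, e.effect) == ("L", "L", "synonymous")

    def test_ser_to_leu(self):
        cds = "ATG" + "TCA" + "TAA"
        e = classify_effect(site("g", 5), cds)
        assert (e.ref_aa, e.edited_aa, e.effect) == ("S", "L", "nonsynonymous")
        assert e.is_c_to_u

    def test_start_gain(self):
        cds = "ACG" + "CTC" + "TAA"
        e = classify_effect(site("g", 2, ref="C", alt="T"), cds)
        assert e.effect == "start_gain" and e.edited_codon == "ATG"

    def test_frame_error(self):
        with pytest.raises(FrameError):
            classify_effect(site("g", 2), "ATGC")

    def test_agrees_with_mutate_translate_oracle(self):
        # brute-force oracle: substitute, translate the whole CDS, compare proteins
        rng = np.random.default_rng(33)
        cds = random_cds(34, 400)
        protein = translate(cds)
        n_checked = 0
        while n_checked < 1000:
            pos = int(rng.integers(1, len(cds) + 1))
            alt = "ACGT"[int(rng.integers(0, 4))]
            if cds[pos - 1] == alt:
                continue
            e = classify_effect(site("g", pos, ref=cds[pos - 1], alt=alt), cds)
            mutated = cds[: pos - 1] + alt + cds[pos:]
            mutated_protein = translate(mutated)
            aa_idx = (pos - 1) // 3
            assert e.ref_aa == protein[aa_idx]
            assert e.edited_aa == mutated_protein[aa_idx]
            if e.effect == "synonymous":
                assert mutated_protein == protein
            elif e.effect == "stop_gain":
                assert protein[aa_idx] != "*" and mutated_protein[aa_idx] == "*"
            elif e.effect == "nonsynonymous":
                assert mutated_protein[aa_idx] != protein[aa_idx]
            n_checked += 1


class TestSummarize:
    def test_empty_summary_all_zero(self):
        s = summarize_editing([])
        assert s["n_sites"] == 0 and s["synonymous"] == 0 and s["per_gene"] == {}

    def test_counts_and_percentages(self):
        cds = "ATG" + "TCA" + "CTC" + "CAA" + "TAA"  # M S L Q *
        sites = [
            classify_effect(site("a", 5), cds),           # TCA->TTA Ser->Leu, pos2
            classify_effect(site("a", 9), cds),           # CTC->CTT syn, pos3
            classify_effect(site("b", 10), cds),          # CAA->TAA stop, pos1
        ]
        s = summarize_editing(sites)
        assert s["n_sites"] == 3
        assert s["codon_position_counts"] == {1: 1, 2: 1, 3: 1}
        assert s["synonymous"] == 1 and s["nonsynonymous"] == 2
        assert s["stop_gain"] == 1
        assert s["per_gene"] == {"a": 2, "b": 1}
        assert s["aa_changes"]["S>L"] == 1
        assert s["c_to_u"] == 3

    def test_published_codon_position_percentages(self):
        assert percent(185, 600) == 30.83
        assert percent(316, 600) == 52.67
        assert percent(99, 600) == 16.50

    def test_position_counts_partition_total(self, toy):
        mito, _, feats, truth = toy
        from mitokit.seqcore import extract_cds

        sites = []
        for feat in feats:
            cds = extract_cds(mito, feat, flank=0)
            for gene, pos, freq in truth.planted_edits:
                if gene == feat.gene:
                    sites.append(classify_effect(site(gene, pos), cds))
        s = summarize_editing(sites)
        assert sum(s["codon_position_counts"].values()) == s["n_sites"]
        assert s["synonymous"] + s["nonsynonymous"] == s["n_sites"]


class TestRecovery:
    def test_planted_edits_recovered_error_free_over_10_seeds(self, params):
        """Sensitivity >= 0.99 for planted frequency >= 0.15 at depth >= 50,
        and zero calls at unedited positions, aggregated over 10 seeds."""
        planted_total = recovered = false_calls = 0
        for seed in range(10):
            ref_cds = random_cds(seed + 70, 150)
            flank_seq = random_cds(seed + 71, 40)[:100]
            ref = flank_seq + ref_cds + flank_seq
            rng = np.random.default_rng(seed)
            c_positions = [i + 1 for i in range(3, len(ref_cds) - 3) if ref_cds[i] == "C"]
            chosen = sorted(rng.choice(c_positions, size=10, replace=False).tolist())
            sites_in = [(p + 100, "T", float(rng.uniform(0.15, 0.9))) for p in chosen]
            reads = simulate_amplicon_reads(ref, sites_in, depth=60, read_len=100, seed=seed + 500)
            pileup = build_pileup(ref, reads, ref_id="g")
            called = call_sites(pileup, params, flank=100, cds_len=len(ref_cds))
            called_pos = {s.cds_position for s in called if s.in_cds}
            planted_total += len(chosen)
            recovered += len(called_pos & set(chosen))
            false_calls += len(called_pos - set(chosen))
        assert recovered / planted_total >= 0.99
        assert false_calls == 0
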