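"""Dispersed repeat detection vs a quadratic brute-force oracle, plus the
published repeat-table loader and its consistency audit."""

import numpy as np
import pytest

from mitokit.dispersed import (
    RepeatPair,
    audit_drs_table,
    effective_repeat_types,
    find_dispersed_repeats,
    load_drs_table,
    pairs_to_table,
    verify_pair,
)
from mitokit.seqcore import CoordinateError, GenomeRecord, revcomp


def brute_force_pairs(seq: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact pairs >= min_len as 1-based (start1, start2, length, type),
    by direct quadratic extension from every position pair. Excludes
    overlapping/abutting copies; applies no containment suppression."""
    n = len(seq)
    found = set()
    for i in range(n):
        for j in range(i + 1, n):
            if seq[i] != seq[j]:
                continue
            if i > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal
            length = 0
            while j + length < n and seq[i + length] == seq[j + length]:
                length += 1
            if length >= min_len and j > i + length:
                found.add((i + 1, j + 1, length, "F"))
    r = revcomp(seq)
    for i in range(n):
        for jr in range(n):
            if seq[i] != r[jr]:
                continue
            if i > 0 and jr > 0 and seq[i - 1] == r[jr - 1]:
                continue
            length = 0
            while i + length < n and jr + length < n and seq[i + length] == r[jr + length]:
                length += 1
            if length < min_len:
                continue
            j = n - jr - length
            a, b = sorted((i, j))
            if b > a + length:
                found.add((a + 1, b + 1, length, "P"))
    return found


def plant(bg: str, inserts: list[tuple[int, str]]) -> str:
    s = list(bg)
    for pos0, frag in inserts:
        s[pos0 : pos0 + len(frag)] = list(frag)
    return "".join(s)


def random_seq(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindDispersedRepeats:
    def test_random_genome_empty_at_50(self):
        genome = GenomeRecord(id="r", seq=random_seq(13, 20_000))
        assert find_dispersed_repeats(genome, min_len=50) == []

    def test_planted_direct_pair_exact(self):
        frag = random_seq(1, 300)
        seq = plant(random_seq(2, 10_000), [(1000, frag), (5000, frag)])
        pairs = find_dispersed_repeats(GenomeRecord(id="g", seq=seq), min_len=50)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.rtype, p.length) == ("F", 300)
        assert (p.start1, p.end1, p.start2, p.end2) == (1001, 1300, 5001, 5300)

    def test_planted_palindromic_pair_exact(self):
        frag = random_seq(3, 120)
        seq = plant(random_seq(4, 10_000), [(2000, frag), (8000, revcomp(frag))])
        pairs = find_dispersed_repeats(GenomeRecord(id="g", seq=seq), min_len=50)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.rtype, p.length, p.start1, p.start2) == ("P", 120, 2001, 8001)
        assert verify_pair(GenomeRecord(id="g", seq=seq), p)

    def test_three_copy_repeat_reported_as_pair_closure(self):
        frag = random_seq(5, 80)
        seq = plant(random_seq(6, 12_000), [(1000, frag), (5000, frag), (9000, frag)])
        pairs = find_dispersed_repeats(GenomeRecord(id="g", seq=seq), min_len=50)
        assert len(pairs) == 3  # all pairwise combinations of the 3 copies
        assert {(p.start1, p.start2) for p in pairs} == {(1001, 5001), (1001, 9001), (5001, 9001)}

    def test_containment_suppression(self):
        # a long duplication whose interior also repeats: only the container reported
        inner = random_seq(7, 60)
        block = random_seq(8, 200) + inner + random_seq(9, 200)
        seq = plant(random_seq(10, 15_000), [(1000, block), (8000, block),
                                             (999, "A"), (7999, "C"),
                                             (1000 + len(block), "G"),
                                             (8000 + len(block), "T")])
        pairs = find_dispersed_repeats(GenomeRecord(id="g", seq=seq), min_len=50)
        assert len(pairs) == 1
        assert pairs[0].length == len(block)

    def test_ids_descend_by_length(self, toy_mito):
        pairs = find_dispersed_repeats(toy_mito)
        lengths = [p.length for p in pairs]
        assert lengths == sorted(lengths, reverse=True)
        assert [p.id for p in pairs] == [f"DRS{i}" for i in range(1, len(pairs) + 1)]

    def test_planted_truth_recovered_exactly(self, toy_mito, toy_truth):
        found = {(p.rtype, p.start1, p.end1, p.start2, p.end2)
                 for p in find_dispersed_repeats(toy_mito)}
        planted = {(p.rtype, p.start1, p.end1, p.start2, p.end2)
                   for p, _ in toy_truth.planted_repeat_pairs}
        assert found == planted

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivalence_with_brute_force(self, seed):
        frag = random_seq(seed + 50, 25)
        pal = random_seq(seed + 60, 18)
        seq = plant(random_seq(seed, 3000),
                    [(300, frag), (1500, frag), (700, pal), (2500, revcomp(pal))])
        oracle = brute_force_pairs(seq, min_len=10)
        # compare against the detector with containment suppression disabled by
        # reconstructing the raw maximal set: every detector pair must be in the
        # oracle, and every oracle pair must be contained in some detector pair.
        pairs = find_dispersed_repeats(GenomeRecord(id="g", seq=seq), min_len=10)
        det = {(p.start1, p.start2, p.length, p.rtype) for p in pairs}
        assert det <= oracle
        for s1, s2, length, rtype in oracle:
            covered = any(
                p.rtype == rtype
                and p.start1 <= s1 and s1 + length - 1 <= p.end1
                and p.start2 <= s2 and s2 + length - 1 <= p.end2
                for p in pairs
            )
            assert covered, (s1, s2, length, rtype)

    def test_maximality(self, toy_mito):
        s = toy_mito.seq
        for p in find_dispersed_repeats(toy_mito):
            i, j, L = p.start1 - 1, p.start2 - 1, p.length
            if p.rtype == "F":
                assert i == 0 or s[i - 1] != s[j - 1]
                assert j + L == len(s) or s[i + L] != s[j + L]
            else:
                comp = dict(zip("ACGT", "TGCA"))
                assert i == 0 or j + L == len(s) or s[i - 1] != comp[s[j + L]]
                assert j == 0 or s[i + L] != comp[s[j - 1]]

    def test_symmetry_under_revcomp(self, toy_mito):
        fwd = find_dispersed_repeats(toy_mito)
        rev = find_dispersed_repeats(GenomeRecord(id="rc", seq=revcomp(toy_mito.seq)))
        assert sorted((p.length, p.rtype) for p in fwd) == sorted((p.length, p.rtype) for p in rev)

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            find_dispersed_repeats(GenomeRecord(id="s", seq="ACGT" * 10), min_len=50)


class TestVerifyPair:
    GENOME = GenomeRecord(id="g", seq=plant(random_seq(30, 2000),
                                            [(100, random_seq(31, 60)),
                                             (900, random_seq(31, 60))]))

    def test_emitted_pairs_verify(self, toy_mito):
        for p in find_dispersed_repeats(toy_mito):
            assert verify_pair(toy_mito, p)

    def test_shifted_pair_fails(self):
        p = RepeatPair(id="x", length=60, rtype="F", start1=101, end1=160,
                       start2=902, end2=961)
        assert not verify_pair(self.GENOME, p)

    def test_palindrome_checked_as_direct_fails(self):
        frag = random_seq(32, 60)
        seq = plant(random_seq(33, 2000), [(100, frag), (900, revcomp(frag))])
        genome = GenomeRecord(id="g", seq=seq)
        p_ok = RepeatPair(id="p", length=60, rtype="P", start1=101, end1=160,
                          start2=901, end2=960)
        p_bad = RepeatPair(id="f", length=60, rtype="F", start1=101, end1=160,
                           start2=901, end2=960)
        assert verify_pair(genome, p_ok)
        assert not verify_pair(genome, p_bad)

    def test_out_of_bounds(self):
        p = RepeatPair(id="x", length=60, rtype="F", start1=1990, end1=2049,
                       start2=1, end2=60)
        with pytest.raises(CoordinateError):
            verify_pair(self.GENOME, p)


class TestPublishedTable:
    def test_row_and_type_counts(self):
        table = load_drs_table()
        assert len(table) == 47
        types = effective_repeat_types(table)
        assert (types == "P").sum() == 18
        assert (types == "F").sum() == 29

    def test_first_copy_length_of_longest_row(self):
        table = load_drs_table()
        row = table.iloc[0]
        assert row["End1"] - row["Start1"] + 1 == 9875

    def test_audit_flags_inconsistent_rows_without_correcting(self):
        table = load_drs_table()
        audited = audit_drs_table(table)
        flagged = set(audited.loc[audited["audit"] != "", "ID"])
        assert {"DRS16", "DRS21"} <= flagged  # arithmetically inconsistent rows
        assert "DRS1" not in flagged and "DRS4" not in flagged
        # the audit does not alter any coordinate
        assert (audited[table.columns] == table).all().all()


def test_palindromic_output_convention():
    frag = random_seq(40, 80)
    seq = plant(random_seq(41, 5000), [(500, frag), (3000, revcomp(frag))])
    pairs = find_dispersed_repeats(GenomeRecord(id="g", seq=seq), min_len=50)
    table = pairs_to_table(pairs)
    row = table[table["Repeat Type"] == "P"].iloc[0]
    assert row["Start2"] > row["End2"]  # orientation signalled by descending copy 2
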