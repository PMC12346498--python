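"""Perfect SSR scanning and long-tandem-repeat (period >= 7) detection.

Microsatellites (SSRs) are maximal perfect tandem runs of a primitive 1-6 bp
unit whose copy number meets a per-unit-size minimum (MISA convention:
mono >= 10, di >= 5, tri >= 4, tetra/penta/hexa >= 3). Long tandem repeats are
arrays with period 7-500, located on the self-match profile at lag = period
and scored +2 per match / -7 per substitution against the array's majority
consensus, reported when the score reaches the minimum (50 by default; a
perfect array of total length L scores 2L).

The long-tandem detector is a deterministic period scan over the self-match
profile; substitutions interrupt and penalise an array, indels are not chased
(an indel shifts the register and truncates the array at that point). This
differs from Tandem Repeats Finder's stochastic k-tuple heuristic on purpose:
the detector is exact and reproducible for the perfect and
substitution-degraded arrays that dominate organelle genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import GenomeRecord, Parameters

__all__ = ["SsrRecord", "TandemRepeatRecord", "find_ssrs", "find_tandem_repeats", "ssr_class_counts"]

SSR_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SsrRecord:
    """One perfect simple sequence repeat; coordinates 1-based inclusive."""

    motif: str
    unit_len: int
    copies: int
    start: int
    end: int

    def __post_init__(self) -> None:
        assert self.end - self.start + 1 == self.unit_len * self.copies
        assert len(self.motif) == self.unit_len


@dataclass(frozen=True)
class TandemRepeatRecord:
    """One long tandem repeat array; coordinates 1-based inclusive."""

    unit: str
    period: int
    copy_number: float
    start: int
    end: int
    score: int


def is_primitive(motif: str) -> bool:
    """True unless the motif is itself a repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def _match_runs(arr: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array as (start, length), 0-based."""
    if arr.size == 0:
        return []
    padded = np.concatenate(([False], arr, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def find_ssrs(genome: GenomeRecord, params: Parameters | None = None) -> list[SsrRecord]:
    """All maximal perfect SSRs meeting the per-unit-size copy thresholds.

    Runs are reported once, under their primitive unit (a poly-A run is mono,
    never di); only full copies count, so a 9.5-copy run of a dinucleotide is
    reported with 9 copies. Within one unit size, overlapping phase-shifted
    reports are resolved left to right so reported records never overlap.
    """
    params = params or Parameters()
    s = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    n = s.size
    out: list[SsrRecord] = []
    for p, min_units in sorted(params.ssr_min_units.items()):
        if n < p * min_units:
            continue
        runs = []
        for m_start, m_len in _match_runs(s[:-p] == s[p:]):
            run_len = m_len + p  # self-match run of length m covers m + p bases
            copies = run_len // p
            if copies < min_units:
                continue
            runs.append((m_start, run_len))
        prev_end = -1  # 0-based inclusive end of the previous accepted run
        for start0, run_len in runs:
            if start0 <= prev_end:  # trim a rare < p-base overlap with the previous run
                run_len -= prev_end + 1 - start0
                start0 = prev_end + 1
            copies = run_len // p
            if copies < min_units:
                continue
            motif = genome.seq[start0 : start0 + p]
            if not is_primitive(motif):
                continue
            end0 = start0 + copies * p - 1
            out.append(SsrRecord(motif=motif, unit_len=p, copies=copies,
                                 start=start0 + 1, end=end0 + 1))
            prev_end = end0
    out.sort(key=lambda r: (r.start, r.unit_len))
    return out


def ssr_class_counts(ssrs: list[SsrRecord]) -> dict[str, int]:
    """Tally SSRs per unit-size class (mono ... hexa)."""
    counts = {name: 0 for name in SSR_CLASS_NAMES.values()}
    for r in ssrs:
        counts[SSR_CLASS_NAMES[r.unit_len]] += 1
    counts["total"] = len(ssrs)
    return counts


def _arrays_for_period(s: np.ndarray, seq: str, p: int, params: Parameters) -> list[TandemRepeatRecord]:
    """Maximal-scoring tandem arrays at one period from the lag-p self-match profile."""
    match = s[:-p] == s[p:]
    runs = _match_runs(match)
    if not runs:
        return []
    out = []
    i = 0
    while i < len(runs):
        # Chain match-runs across substitution gaps while each extension pays for
        # itself, then trim weak boundary runs so the chain is max-scoring.
        chain = [runs[i]]
        j = i + 1
        while j < len(runs):
            gs, gl = runs[j]
            gap = gs - (chain[-1][0] + chain[-1][1])
            if params.ltr_mismatch * gap + params.ltr_match * gl <= 0:
                break
            chain.append(runs[j])
            j += 1
        while len(chain) > 1:
            gap = chain[1][0] - (chain[0][0] + chain[0][1])
            if params.ltr_match * chain[0][1] + params.ltr_mismatch * gap <= 0:
                chain.pop(0)
            else:
                break
        while len(chain) > 1:
            gap = chain[-1][0] - (chain[-2][0] + chain[-2][1])
            if params.ltr_match * chain[-1][1] + params.ltr_mismatch * gap <= 0:
                chain.pop()
            else:
                break
        start = chain[0][0]
        end = chain[-1][0] + chain[-1][1]  # exclusive, on the match profile
        arr_start, arr_end = start, end + p  # array spans the profile plus one unit
        copy_number = (arr_end - arr_start) / p
        if copy_number < 1.9 or 2 * (arr_end - arr_start) < params.ltr_min_score:
            i = j
            continue
        # Score the array against its per-offset majority consensus: +2 per
        # consensus match, -7 per substitution. This is exact for the
        # substitution-only arrays the detector models, and scores an array
        # identically at every period that describes it, so the multi-period
        # collapse resolves to the smallest period.
        region = seq[arr_start:arr_end]
        unit_chars, matches, mismatches = [], 0, 0
        for o in range(p):
            column = region[o::p]
            best_base = max(sorted(set(column)), key=column.count)
            unit_chars.append(best_base)
            hit = column.count(best_base)
            matches += hit
            mismatches += len(column) - hit
        total = params.ltr_match * matches + params.ltr_mismatch * mismatches
        if total >= params.ltr_min_score:
            out.append(TandemRepeatRecord(
                unit="".join(unit_chars), period=p,
                copy_number=round(copy_number, 2),
                start=arr_start + 1, end=arr_end, score=total,
            ))
        i = j
    return out


def find_tandem_repeats(genome: GenomeRecord, params: Parameters | None = None) -> list[TandemRepeatRecord]:
    """Long tandem repeats with period in [ltr_min_unit, ltr_max_period].

    Overlapping reports of the same array at several periods (a period-10
    array also matches itself at lag 20, 30, ...) are collapsed to the
    highest-scoring record; ties keep the smallest period. Records are
    returned sorted by start.
    """
    params = params or Parameters()
    s = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    n = s.size
    candidates: list[TandemRepeatRecord] = []
    for p in range(params.ltr_min_unit, min(params.ltr_max_period, n // 2) + 1):
        candidates.extend(_arrays_for_period(s, genome.seq, p, params))
    # collapse overlapping multi-period reports
    candidates.sort(key=lambda r: (-r.score, r.period, r.start))
    kept: list[TandemRepeatRecord] = []
    for cand in candidates:
        if any(cand.start <= k.end and k.start <= cand.end for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept
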