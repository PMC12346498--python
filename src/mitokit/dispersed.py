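"""Dispersed (non-tandem) repeat detection: direct (F) and palindromic (P) pairs.

A dispersed repeat is a pair of non-adjacent, non-overlapping exact copies of
a sequence of at least ``min_len`` bases, either on the same strand (direct,
F) or on opposite strands (palindromic, P). Detection is exact-match
seed-and-extend: every shared k-mer (k = min(21, min_len)) that cannot be
extended one base to the left seeds a maximal match, which is then extended
to the right. Pairs wholly contained in a longer reported pair are
suppressed, so a long duplication is reported once rather than as a cloud of
sub-repeats; repeats with more than two copies appear as all pairwise
combinations. Ids DRS1, DRS2, ... are assigned in descending length order,
ties broken by the first copy's start.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .seqcore import CoordinateError, GenomeRecord, revcomp

__all__ = [
    "RepeatPair",
    "find_dispersed_repeats",
    "verify_pair",
    "pairs_to_table",
    "load_drs_table",
    "audit_drs_table",
]


@dataclass(frozen=True)
class RepeatPair:
    """One dispersed repeat pair, 1-based inclusive forward-strand coordinates.

    Both copies are stored as forward-strand intervals with start <= end;
    for P pairs the second copy's *content* is the reverse complement of the
    first. Report writers may flip copy-2 coordinates to signal orientation.
    """

    id: str
    length: int
    rtype: str  # "F" | "P"
    start1: int
    end1: int
    start2: int
    end2: int

    def __post_init__(self) -> None:
        if self.rtype not in ("F", "P"):
            raise ValueError(f"rtype must be 'F' or 'P', got {self.rtype!r}")

    @property
    def interval1(self) -> tuple[int, int]:
        return (self.start1, self.end1)

    @property
    def interval2(self) -> tuple[int, int]:
        return (self.start2, self.end2)


def verify_pair(genome: GenomeRecord, pair: RepeatPair) -> bool:
    """True iff the pair's type-specific exact-identity invariant holds."""
    n = genome.length
    for s, e in (pair.interval1, pair.interval2):
        if not 1 <= s <= e <= n:
            raise CoordinateError(f"{pair.id}: interval ({s}, {e}) outside genome")
    a = genome.seq[pair.start1 - 1 : pair.end1]
    b = genome.seq[pair.start2 - 1 : pair.end2]
    if pair.end1 - pair.start1 != pair.end2 - pair.start2:
        return False
    return a == b if pair.rtype == "F" else b == revcomp(a)


def _primitive_period(s: str) -> int:
    """Smallest p with s[i] == s[i+p] for all valid i (KMP failure function)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1]


def _tandem_derived(s: str, i: int, j: int, length: int) -> bool:
    """True when a pair is an echo of one tandem array rather than dispersed copies.

    If the copy itself is a tandem array (primitive period p <= length/2) and
    the whole span from copy 1 through copy 2 continues that periodicity, the
    'pair' is two windows of a single array.
    """
    p = _primitive_period(s[i : i + length])
    if p > length // 2:
        return False
    span = s[i : j + length]
    return all(span[x] == span[x + p] for x in range(len(span) - p))


def _maximal_forward_pairs(s: str, min_len: int, k: int) -> set[tuple[int, int, int]]:
    """Left-maximal exact same-strand matches as 0-based (i, j, length), i < j."""
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    n = len(s)
    found: set[tuple[int, int, int]] = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai, i in enumerate(positions):
            for j in positions[ai + 1 :]:
                if i > 0 and s[i - 1] == s[j - 1]:
                    continue  # not left-maximal; seeded one base earlier
                length = k
                while j + length < n and s[i + length] == s[j + length]:
                    length += 1
                if length >= min_len:
                    found.add((i, j, length))
    return found


def _maximal_palindromic_pairs(s: str, min_len: int, k: int) -> set[tuple[int, int, int]]:
    """Palindromic matches as 0-based (i, j, length) on the forward strand, i <= j.

    A match of S against R = revcomp(S) at (i, jr) maps to forward intervals
    [i, i+L) and [n-jr-L, n-jr).
    """
    n = len(s)
    r = revcomp(s)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()
    for jr in range(n - k + 1):
        for i in index.get(r[jr : jr + k], ()):
            if i > 0 and jr > 0 and s[i - 1] == r[jr - 1]:
                continue
            length = k
            while i + length < n and jr + length < n and s[i + length] == r[jr + length]:
                length += 1
            if length < min_len:
                continue
            j = n - jr - length  # forward-strand start of the second copy
            a, b = sorted(((i, length), (j, length)))
            found.add((a[0], b[0], length))
    return found


def find_dispersed_repeats(genome: GenomeRecord, min_len: int = 50) -> list[RepeatPair]:
    """All maximal exact dispersed repeat pairs of length >= min_len.

    Tandem-adjacent duplicates (copies that abut or overlap) are excluded, and
    pairs contained within a longer reported pair are suppressed.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    if genome.length < 2 * min_len:
        raise ValueError("genome shorter than two copies of min_len")
    k = min(21, min_len)
    s = genome.seq
    raw: list[tuple[int, int, int, str]] = []
    for i, j, length in _maximal_forward_pairs(s, min_len, k):
        if j <= i + length:  # overlapping or abutting: tandem, not dispersed
            continue
        if _tandem_derived(s, i, j, length):
            continue
        raw.append((i, j, length, "F"))
    for i, j, length in _maximal_palindromic_pairs(s, min_len, k):
        if j <= i + length:
            continue
        raw.append((i, j, length, "P"))
    # longest first so containment suppression sees the container before the contained
    raw.sort(key=lambda t: (-t[2], t[0], t[1], t[3]))
    kept: list[tuple[int, int, int, str]] = []
    for i, j, length, rtype in raw:
        iv1 = (i, i + length - 1)
        iv2 = (j, j + length - 1)
        contained = False
        for ki, kj, klen, _ in kept:
            kv1 = (ki, ki + klen - 1)
            kv2 = (kj, kj + klen - 1)
            for a, b in ((kv1, kv2), (kv2, kv1)):
                if a[0] <= iv1[0] and iv1[1] <= a[1] and b[0] <= iv2[0] and iv2[1] <= b[1]:
                    contained = True
                    break
            if contained:
                break
        if not contained:
            kept.append((i, j, length, rtype))
    pairs = [
        RepeatPair(
            id=f"DRS{idx}", length=length, rtype=rtype,
            start1=i + 1, end1=i + length, start2=j + 1, end2=j + length,
        )
        for idx, (i, j, length, rtype) in enumerate(kept, start=1)
    ]
    return pairs


def pairs_to_table(pairs: list[RepeatPair], flip_palindromic: bool = True) -> pd.DataFrame:
    """Report table; P pairs show copy 2 with start > end to signal orientation."""
    rows = []
    for p in pairs:
        s2, e2 = p.start2, p.end2
        if flip_palindromic and p.rtype == "P":
            s2, e2 = e2, s2
        rows.append((p.id, p.length, p.rtype, p.start1, p.end1, s2, e2))
    return pd.DataFrame(
        rows, columns=["ID", "Repeat Length", "Repeat Type", "Start1", "End1", "Start2", "End2"]
    )


# ----------------------------------------------------------------------------
# Published dispersed-repeat statistics for the T. wilfordii mitogenome
# (accession OR538545.1), shipped as package data.


def load_drs_table() -> pd.DataFrame:
    """Published 47-row dispersed-repeat table (OR538545.1), coordinates 1-based."""
    with resources.files("mitokit.data").joinpath("tw_mito_drs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def effective_repeat_types(table: pd.DataFrame) -> pd.Series:
    """Repeat type per row, honouring the coordinate-orientation convention.

    Palindromic copies are conventionally written with start > end; a row is
    treated as palindromic when it is labeled P *or* either copy is written
    descending (which catches rows mislabeled F but written in palindromic
    orientation).
    """
    desc = (table["End1"] < table["Start1"]) | (table["End2"] < table["Start2"])
    return pd.Series(
        ["P" if p or d else "F" for p, d in zip(table["Repeat Type"] == "P", desc)],
        index=table.index,
        name="effective_type",
    )


def audit_drs_table(table: pd.DataFrame) -> pd.DataFrame:
    """Flag internally inconsistent rows of a published-style repeat table.

    Under 1-based inclusive coordinates each copy should span exactly
    ``Repeat Length`` bases, with palindromic second copies allowed to be
    written start > end. Rows violating this are flagged, never corrected.
    """
    flags = []
    for _, row in table.iterrows():
        problems = []
        len1 = row["End1"] - row["Start1"] + 1
        len2 = abs(row["End2"] - row["Start2"]) + 1
        if len1 != row["Repeat Length"]:
            problems.append(f"copy1 spans {len1} bases, not {row['Repeat Length']}")
        if len2 != row["Repeat Length"]:
            problems.append(f"copy2 spans {len2} bases, not {row['Repeat Length']}")
        if row["Repeat Type"] == "F" and (row["End1"] < row["Start1"] or row["End2"] < row["Start2"]):
            problems.append("direct repeat written with start > end")
        if row["Repeat Type"] == "P" and row["End1"] < row["Start1"]:
            problems.append("first copy written with start > end")
        flags.append("; ".join(problems))
    out = table.copy()
    out["audit"] = flags
    return out
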