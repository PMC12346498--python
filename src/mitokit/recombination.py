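"""Repeat-mediated recombination testing with long reads.

A dispersed repeat pair defines four genome conformations: the two reference
arrangements (each copy with its own flanks) and the two recombinant products
in which the flanks are exchanged across the repeat. Intramolecular
recombination between the copies is detectable as long reads that join one
copy's upstream flank to the other copy's downstream flank.

For each pair the four conformations are built from the repeat plus flanking
sequence (500 bp by default); for palindromic pairs the second copy's context
is reverse complemented into the first copy's frame before the exchange, so
all four conformations read the repeat in the same orientation. A read
supports a conformation when its best alignment covers the informative
window — the entire repeat plus at least ``recomb_min_anchor`` bases of both
flanks — at identity >= ``recomb_min_identity``; best-hit assignment with
score ties counted as ambiguous keeps a read from inflating several
categories at once. The recombination frequency is
(rec1 + rec2) / (ref1 + ref2 + rec1 + rec2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .dispersed import RepeatPair, verify_pair
from .seqcore import GenomeRecord, Parameters, revcomp
from .synthetic import ReadRecord

__all__ = ["ConformationSet", "ConformationSupport", "build_conformations", "count_support", "screen_all"]

CONFORMATIONS = ("ref1", "ref2", "rec1", "rec2")

# A read is assigned to its best-matching conformation only when the best
# window identity beats the runner-up by this much; anything closer is counted
# ambiguous. Distinct flanks differ by ~0.15 identity over an informative
# window, so genuine assignments clear the margin easily, while reads that
# only partially cover one anchor (whose scores are alignment noise) do not.
AMBIGUITY_MARGIN = 0.05


@dataclass(frozen=True)
class ConformationSet:
    """The four flank-repeat-flank arrangements for one repeat pair."""

    pair_id: str
    ref1: str
    ref2: str
    rec1: str
    rec2: str
    repeat_len: int
    flank_lens: dict = field(default_factory=dict)  # {"upA": int, "downA": int, "upB": int, "downB": int}
    provenance: dict = field(default_factory=dict)
    truncated: bool = False

    def seq(self, name: str) -> str:
        return getattr(self, name)


@dataclass
class ConformationSupport:
    """Read support per conformation and the derived recombination frequency."""

    pair_id: str
    counts: dict
    ambiguous: int = 0
    untestable: bool = False

    @property
    def n_informative(self) -> int:
        return sum(self.counts.values())

    @property
    def recombination_frequency(self) -> float | None:
        total = self.n_informative
        if total == 0:
            return None
        return (self.counts["rec1"] + self.counts["rec2"]) / total


def build_conformations(genome: GenomeRecord, pair: RepeatPair, flank: int = 500) -> ConformationSet:
    """Construct ref1/ref2/rec1/rec2 for one pair; flanks truncate at genome ends."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not verify_pair(genome, pair):
        raise ValueError(f"{pair.id}: repeat-pair identity invariant does not hold")
    if pair.start2 <= pair.end1:
        raise ValueError(f"{pair.id}: copies overlap; not a dispersed pair")
    s = genome.seq
    a1, a2 = pair.start1 - 1, pair.end1  # 0-based half-open copy A
    b1, b2 = pair.start2 - 1, pair.end2
    repeat = s[a1:a2]
    up_a = s[max(0, a1 - flank) : a1]
    down_a = s[a2 : a2 + flank]
    if pair.rtype == "F":
        up_b = s[max(0, b1 - flank) : b1]
        down_b = s[b2 : b2 + flank]
    else:
        # copy B reads as revcomp(repeat); rotate its context into copy A's frame
        up_b = revcomp(s[b2 : b2 + flank])
        down_b = revcomp(s[max(0, b1 - flank) : b1])
    truncated = min(len(up_a), len(down_a), len(up_b), len(down_b)) < flank
    return ConformationSet(
        pair_id=pair.id,
        ref1=up_a + repeat + down_a,
        ref2=up_b + repeat + down_b,
        rec1=up_a + repeat + down_b,
        rec2=up_b + repeat + down_a,
        repeat_len=len(repeat),
        flank_lens={"upA": len(up_a), "downA": len(down_a), "upB": len(up_b), "downB": len(down_b)},
        provenance={
            "copyA": (pair.start1, pair.end1, "+"),
            "copyB": (pair.start2, pair.end2, "+" if pair.rtype == "F" else "-"),
            "flank": flank,
        },
        truncated=truncated,
    )


def _informative_window(conf: ConformationSet, name: str, anchor: int) -> str | None:
    """Repeat plus up to ``anchor`` bases of both flanks; None if a flank is absent."""
    seq = conf.seq(name)
    up_len = conf.flank_lens["upA"] if name in ("ref1", "rec1") else conf.flank_lens["upB"]
    down_len = conf.flank_lens["downA"] if name in ("ref1", "rec2") else conf.flank_lens["downB"]
    a = min(anchor, up_len)
    d = min(anchor, down_len)
    if a == 0 or d == 0:
        return None  # no flank to anchor in: window cannot discriminate
    start = up_len - a
    end = up_len + conf.repeat_len + d
    return seq[start:end]


def count_support(
    conf: ConformationSet,
    reads: list[ReadRecord],
    params: Parameters | None = None,
) -> ConformationSupport:
    """Assign each read to its best-matching conformation, ties to ambiguous.

    A read is informative for a conformation when the conformation's
    informative window aligns within the read (either strand) at identity
    >= ``recomb_min_identity``; identity is 1 - edit_distance / window_length.
    If no read is long enough to span the smallest window the pair is
    reported untestable.
    """
    params = params or Parameters()
    windows = {}
    for name in CONFORMATIONS:
        w = _informative_window(conf, name, params.recomb_min_anchor)
        if w is not None:
            windows[name] = w
    support = ConformationSupport(pair_id=conf.pair_id, counts={n: 0 for n in CONFORMATIONS})
    if not windows:
        support.untestable = True
        return support
    min_window = min(len(w) for w in windows.values())
    max_read = max((len(r.seq) for r in reads), default=0)
    if max_read < min_window:
        support.untestable = True
        return support
    max_dist = {n: int((1.0 - params.recomb_min_identity) * len(w)) for n, w in windows.items()}
    for read in reads:
        best_name, best_ident, second_ident = None, -1.0, -1.0
        rc = revcomp(read.seq)
        for name, w in windows.items():
            if len(read.seq) < len(w):
                continue
            dists = [
                d for d in (
                    edlib.align(w, read.seq, mode="HW", task="distance", k=max_dist[name])["editDistance"],
                    edlib.align(w, rc, mode="HW", task="distance", k=max_dist[name])["editDistance"],
                )
                if d >= 0  # -1 means no alignment within the identity budget
            ]
            if not dists:
                continue
            ident = 1.0 - min(dists) / len(w)
            if ident > best_ident:
                best_name, best_ident, second_ident = name, ident, best_ident
            elif ident > second_ident:
                second_ident = ident
        if best_name is None:
            continue
        if best_ident - second_ident <= AMBIGUITY_MARGIN:
            support.ambiguous += 1
        else:
            support.counts[best_name] += 1
    return support


def screen_all(
    genome: GenomeRecord,
    pairs: list[RepeatPair],
    reads: list[ReadRecord],
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Recombination screen over all pairs: one row per pair plus a summary.

    The returned frame carries ``n_supported_pairs`` (pairs with any
    recombinant support) and ``n_untestable`` in ``frame.attrs``.
    """
    params = params or Parameters()
    rows = []
    for pair in pairs:
        conf = build_conformations(genome, pair, flank=params.recomb_flank)
        sup = count_support(conf, reads, params)
        freq = sup.recombination_frequency
        rows.append({
            "pair_id": pair.id,
            "length": pair.length,
            "rtype": pair.rtype,
            "n_ref1": sup.counts["ref1"],
            "n_ref2": sup.counts["ref2"],
            "n_rec1": sup.counts["rec1"],
            "n_rec2": sup.counts["rec2"],
            "n_ambiguous": sup.ambiguous,
            "untestable": sup.untestable,
            "recomb_freq": float("nan") if freq is None else freq,
        })
    frame = pd.DataFrame(
        rows,
        columns=["pair_id", "length", "rtype", "n_ref1", "n_ref2", "n_rec1",
                 "n_rec2", "n_ambiguous", "untestable", "recomb_freq"],
    )
    frame.attrs["n_supported_pairs"] = int(((frame["n_rec1"] + frame["n_rec2"]) > 0).sum()) if len(frame) else 0
    frame.attrs["n_untestable"] = int(frame["untestable"].sum()) if len(frame) else 0
    return frame
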