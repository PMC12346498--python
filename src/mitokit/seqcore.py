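"""Sequence and annotation data model for organelle genome analysis.

Plant mitochondrial genomes are large (hundreds of kb), repeat-rich molecules
whose analysis rests on a small set of primitives: named nucleotide sequences
with linear or circular topology, multi-exon CDS features in 1-based inclusive
coordinates, reverse complementation, flank-aware CDS extraction, and
translation under the standard genetic code (plant mitochondria use the
universal table; the canonical editing-derived stops CAA→UAA and CGA→UGA are
consistent with it).

All externally visible coordinates are 1-based inclusive. Sequences are held
uppercase over the alphabet {A, C, G, T, N}; U is normalised to T on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "CdsFeature",
    "Parameters",
    "AlphabetError",
    "FastaFormatError",
    "CoordinateError",
    "FrameError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "revcomp",
    "gc_content",
    "extract_cds",
    "translate",
    "round_half_up",
]

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty, duplicate ids, illegal characters)."""


class CoordinateError(ValueError):
    """Interval outside the genome, or invalid for its topology."""


class FrameError(ValueError):
    """CDS length not divisible by three."""


def _check_alphabet(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise AlphabetError(f"illegal characters {sorted(bad)} in {context}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention; Python's round is half-even)."""
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence with topology."""

    id: str
    seq: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        _check_alphabet(self.seq, f"record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps around the origin iff circular."""
        n = self.length
        if start < 1 or end < start:
            raise CoordinateError(f"bad interval ({start}, {end})")
        if end <= n:
            return self.seq[start - 1 : end]
        if self.topology != "circular":
            raise CoordinateError(
                f"interval ({start}, {end}) outside linear genome of length {n}"
            )
        if end - start + 1 > n:
            raise CoordinateError("interval longer than circular genome")
        return (self.seq * 2)[start - 1 : end]


@dataclass(frozen=True)
class CdsFeature:
    """A (possibly spliced) protein-coding feature in 1-based inclusive coordinates.

    ``intervals`` are genomic exon intervals sorted ascending regardless of
    strand; for minus-strand features the spliced mRNA is the reverse
    complement of their concatenation.
    """

    gene: str
    genome_id: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    notes: str = ""
    coding_complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivals = tuple((int(s), int(e)) for s, e in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        if not ivals:
            raise ValueError(f"{self.gene}: no intervals")
        for s, e in ivals:
            if s > e:
                raise ValueError(f"{self.gene}: interval start {s} > end {e}")
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.gene}: intervals overlap or are unsorted")
        if self.coding_complete and self.spliced_length % 3 != 0:
            raise ValueError(
                f"{self.gene}: spliced length {self.spliced_length} not divisible by 3"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


@dataclass(frozen=True)
class Parameters:
    """Tunable thresholds for every analysis stage.

    Defaults follow standard organelle practice: MISA-style SSR unit-count
    minima, Tandem Repeats Finder score/period limits with (+2, -7, -7)
    weights, 50 bp dispersed-repeat floor, 500 bp recombination flanks,
    1000 bp MTPT validation flanks, 100 bp CDS flanks for gene-centric
    editing references, and REDItools-style frequency/coverage cutoffs.
    """

    ssr_min_units: dict = field(
        default_factory=lambda: {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    ltr_min_unit: int = 7
    ltr_max_period: int = 500
    ltr_min_score: int = 50
    ltr_match: int = 2
    ltr_mismatch: int = -7
    ltr_indel: int = -7
    drs_min_len: int = 50
    recomb_flank: int = 500
    mtpt_flank: int = 1000
    cds_flank: int = 100
    edit_min_freq: float = 0.10
    edit_min_cov: int = 5
    edit_focus_freq: float = 0.20
    recomb_min_anchor: int = 100
    recomb_min_identity: float = 0.80

    def __post_init__(self) -> None:
        for name in (
            "ltr_min_unit", "ltr_max_period", "ltr_min_score", "drs_min_len",
            "recomb_flank", "mtpt_flank", "cds_flank", "edit_min_cov",
            "recomb_min_anchor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.edit_min_freq <= 1:
            raise ValueError("edit_min_freq must be in (0, 1]")
        if any(v <= 0 for v in self.ssr_min_units.values()):
            raise ValueError("SSR unit thresholds must be strictly positive")

    def with_overrides(self, **kwargs) -> "Parameters":
        return replace(self, **kwargs)


# ----------------------------------------------------------------------------
# I/O


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a multi-FASTA file into GenomeRecords (uppercased, U→T)."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalise(str(rec.seq))
        bad = set(seq) - ALPHABET
        if bad:
            raise FastaFormatError(
                f"illegal characters {sorted(bad)} in record {rec.id!r}"
            )
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[GenomeRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff3(path: str | os.PathLike, feature_types: tuple[str, ...] = ("CDS",)) -> list[CdsFeature]:
    """Read CDS (or tRNA/rRNA) features from GFF3, grouped by their ``gene`` attribute.

    Multi-line CDS features (spliced genes) are merged into one CdsFeature with
    sorted intervals. The ``gene`` attribute is required on every row.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[tuple[str, str], dict] = {}
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            genes = feat.attributes.get("gene")
            if not genes:
                raise ValueError(
                    f"GFF3 row {feat.seqid}:{feat.start}-{feat.end} lacks a 'gene' attribute"
                )
            key = (genes[0], feat.seqid)
            entry = grouped.setdefault(
                key, {"strand": feat.strand, "intervals": [], "type": ftype}
            )
            entry["intervals"].append((feat.start, feat.end))
    feats = []
    for (gene, seqid), entry in grouped.items():
        intervals = tuple(sorted(entry["intervals"]))
        length = sum(e - s + 1 for s, e in intervals)
        feats.append(
            CdsFeature(
                gene=gene,
                genome_id=seqid,
                strand=entry["strand"],
                intervals=intervals,
                notes=entry["type"],
                coding_complete=(entry["type"] == "CDS" and length % 3 == 0),
            )
        )
    feats.sort(key=lambda f: (f.genome_id, f.start))
    return feats


def write_gff3(feats: list[CdsFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            ftype = f.notes if f.notes in ("CDS", "tRNA", "rRNA") else "CDS"
            for s, e in f.intervals:
                fh.write(
                    f"{f.genome_id}\tmitokit\t{ftype}\t{s}\t{e}\t.\t{f.strand}\t0\t"
                    f"ID=cds-{f.gene};gene={f.gene}\n"
                )


# ----------------------------------------------------------------------------
# Core sequence operations


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; an involution."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(rec: GenomeRecord | str) -> float:
    """GC percentage: 100·(G+C)/(A+C+G+T); N excluded from the denominator.

    Full precision is returned; round with :func:`round_half_up` for reports.
    """
    seq = rec.seq if isinstance(rec, GenomeRecord) else rec
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined for an all-N sequence")
    return 100.0 * gc / denom


def extract_cds(genome: GenomeRecord, feat: CdsFeature, flank: int = 0) -> str:
    """Spliced sense-strand CDS with ``flank`` genomic bases on either side.

    The result reads 5'→3' of the mRNA: minus-strand features are reverse
    complemented after splicing, so their 5' flank comes from the genomic
    downstream side. Flanks are truncated at the ends of a linear genome and
    wrap around on a circular one.
    """
    n = genome.length
    for s, e in feat.intervals:
        if genome.topology == "linear" and not (1 <= s <= e <= n):
            raise CoordinateError(
                f"{feat.gene}: interval ({s}, {e}) outside linear genome of length {n}"
            )
    spliced = "".join(genome.slice(s, e) for s, e in feat.intervals)
    up_start = feat.start - flank
    if genome.topology == "circular":
        up = genome.slice(((up_start - 1) % n) + 1, ((up_start - 1) % n) + flank) if flank else ""
        down = genome.slice(feat.end + 1, feat.end + flank) if flank else ""
    else:
        up = genome.seq[max(0, up_start - 1) : feat.start - 1]
        down = genome.seq[feat.end : feat.end + flank]
    seq = up + spliced + down
    return revcomp(seq) if feat.strand == "-" else seq


def translate(cds: str) -> str:
    """Translate under the standard genetic code; stops as '*', N-codons as 'X'."""
    _check_alphabet(cds)
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate(table=1))
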