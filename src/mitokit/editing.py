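"""C-to-U RNA-editing site calling from read pileups, with SNP subtraction.

Editing is called gene-centrically, REDItools-style: RNA reads are aligned to
each protein-coding gene's spliced CDS plus 100 bp flanks, per-position base
counts are tallied, and a site is called where an alternative base reaches
frequency >= 0.10 at coverage >= 5 (both configurable; sites with frequency
above 0.20 carry a ``focus`` flag). DNA reads from the same sample are
processed identically and candidate editing sites that coincide with a DNA
variant, matched on (gene, CDS position), are subtracted — a genomic
polymorphism shows the same substitution in RNA and would otherwise
masquerade as editing. Remaining in-CDS sites are classified by codon
position and effect (synonymous / nonsynonymous / stop gain / start gain);
C→T substitutions in CDS orientation are the C-to-U events that dominate
plant organellar editing.

Multi-alt columns are reported as one site carrying every observed
substitution and a combined non-reference frequency, the convention of
published pileup tables. Reported frequencies are rounded half away from
zero to 2 decimals; internal comparisons keep full precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .seqcore import (
    CdsFeature,
    FrameError,
    GenomeRecord,
    Parameters,
    extract_cds,
    revcomp,
    round_half_up,
    translate,
)
from .synthetic import ReadRecord

__all__ = [
    "PileupColumn",
    "VariantSite",
    "EditingSite",
    "build_pileup",
    "build_pileup_from_sam",
    "column_frequency",
    "call_sites",
    "subtract_snps",
    "classify_effect",
    "summarize_editing",
    "run_editing_pipeline",
    "load_editing_table",
    "percent",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def percent(part: float, whole: float) -> float:
    """100·part/whole rounded half away from zero to 2 decimals."""
    if whole == 0:
        raise ValueError("percentage undefined for a zero denominator")
    return round_half_up(100.0 * part / whole, 2)


@dataclass
class PileupColumn:
    """Per-position base tally over a gene-centric reference (1-based)."""

    ref_id: str
    pos: int
    ref_base: str
    coverage: int
    counts: tuple  # (A, C, G, T)

    def __post_init__(self) -> None:
        assert sum(self.counts) <= self.coverage
        assert all(c >= 0 for c in self.counts)


@dataclass(frozen=True)
class VariantSite:
    """One called site; flank positions carry negative / over-length CDS indices."""

    gene: str
    cds_position: int
    ref_base: str
    alt_base: str  # primary (highest-count) alternative
    frequency: float  # combined non-reference frequency, full precision
    coverage: int
    counts: tuple  # (A, C, G, T)
    alts: tuple = ()  # ((base, count, freq), ...) for every observed alternative
    focus: bool = False
    in_cds: bool = True

    @property
    def all_subs(self) -> str:
        return " ".join(f"{self.ref_base}{b}" for b, _, _ in self.alts)

    @property
    def frequency_2dp(self) -> float:
        return round_half_up(self.frequency, 2)


@dataclass(frozen=True)
class EditingSite:
    """A classified in-CDS site with its codon context and effect."""

    site: VariantSite
    codon_index: int
    codon_pos: int
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    effect: str  # synonymous | nonsynonymous | stop_gain | start_gain
    is_c_to_u: bool

    @property
    def gene(self) -> str:
        return self.site.gene

    @property
    def cds_position(self) -> int:
        return self.site.cds_position


# ----------------------------------------------------------------------------
# Pileup construction


def _map_read(ref: str, seq: str, max_mismatch_frac: float = 0.15) -> tuple[int, str] | None:
    """Ungapped placement of a short read on ref; returns (0-based start, oriented seq).

    Seeds exact k-mers at several read offsets on both strands, scores each
    candidate placement by mismatches, and accepts the best placement when its
    mismatch fraction stays below the cap. Suited to the error-free or
    substitution-only short reads this package simulates and maps.
    """
    n, m = len(ref), len(seq)
    if m == 0 or m > n:
        return None
    k = min(20, m)
    best: tuple[int, int, str] | None = None  # (mismatches, start, oriented)
    for oriented in (seq, revcomp(seq)):
        for off in range(0, m - k + 1, k):
            seed = oriented[off : off + k]
            hit = ref.find(seed)
            while hit != -1:
                start = hit - off
                if 0 <= start <= n - m:
                    mm = sum(1 for a, b in zip(oriented, ref[start : start + m]) if a != b)
                    if best is None or mm < best[0]:
                        best = (mm, start, oriented)
                hit = ref.find(seed, hit + 1)
        if best is not None and best[0] == 0:
            break
    if best is None or best[0] > max_mismatch_frac * m:
        return None
    return best[1], best[2]


def build_pileup(ref: str, reads: list[ReadRecord], ref_id: str = "ref") -> list[PileupColumn]:
    """Per-position base counts from reads placed on ``ref`` by the built-in mapper."""
    n = len(ref)
    counts = [[0, 0, 0, 0] for _ in range(n)]
    coverage = [0] * n
    for read in reads:
        placed = _map_read(ref, read.seq)
        if placed is None:
            continue
        start, oriented = placed
        for i, base in enumerate(oriented):
            coverage[start + i] += 1
            if base in _BASE_IDX:
                counts[start + i][_BASE_IDX[base]] += 1
    return [
        PileupColumn(ref_id=ref_id, pos=i + 1, ref_base=ref[i],
                     coverage=coverage[i], counts=tuple(counts[i]))
        for i in range(n)
        if coverage[i] > 0
    ]


def build_pileup_from_sam(path: str, ref: str, ref_id: str) -> list[PileupColumn]:
    """Pileup from a SAM file of reads aligned to this gene-centric reference.

    Soft-clipped and off-reference bases are excluded (only aligned pairs
    count). The SAM's reference name must match ``ref_id``.
    """
    import pysam

    n = len(ref)
    counts = [[0, 0, 0, 0] for _ in range(n)]
    coverage = [0] * n
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        names = set(sam.references or ())
        if names and ref_id not in names:
            raise ValueError(f"SAM references {sorted(names)} do not include {ref_id!r}")
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name != ref_id:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if rpos is None or not 0 <= rpos < n:
                    continue
                coverage[rpos] += 1
                base = seq[qpos]
                if base in _BASE_IDX:
                    counts[rpos][_BASE_IDX[base]] += 1
    return [
        PileupColumn(ref_id=ref_id, pos=i + 1, ref_base=ref[i],
                     coverage=coverage[i], counts=tuple(counts[i]))
        for i in range(n)
        if coverage[i] > 0
    ]


# ----------------------------------------------------------------------------
# Site calling


def column_frequency(column: PileupColumn) -> float:
    """Combined non-reference frequency of a column, full precision."""
    if column.coverage == 0:
        return 0.0
    non_ref = sum(c for b, c in zip(BASES, column.counts) if b != column.ref_base)
    return non_ref / column.coverage


def call_sites(
    pileup: list[PileupColumn],
    params: Parameters | None = None,
    flank: int | None = None,
    cds_len: int | None = None,
) -> list[VariantSite]:
    """Variant sites where some alternative base passes frequency and coverage cuts.

    ``flank`` converts reference positions to CDS positions (flank columns get
    negative or over-length indices); when omitted, ``params.cds_flank`` is
    used. A site qualifies when coverage >= edit_min_cov and at least one
    alternative base alone reaches edit_min_freq; the reported frequency is
    the combined non-reference frequency of the column.
    """
    params = params or Parameters()
    flank = params.cds_flank if flank is None else flank
    out: list[VariantSite] = []
    for col in pileup:
        if col.coverage < params.edit_min_cov or col.ref_base not in _BASE_IDX:
            continue
        alts = [
            (b, c, c / col.coverage)
            for b, c in zip(BASES, col.counts)
            if b != col.ref_base and c > 0
        ]
        if not alts or max(f for _, _, f in alts) < params.edit_min_freq:
            continue
        primary = max(alts, key=lambda t: t[1])[0]
        freq = column_frequency(col)
        if col.pos <= flank:
            cds_position = col.pos - flank - 1  # negative: 5' flank
        else:
            cds_position = col.pos - flank
        in_cds = cds_len is None or 1 <= cds_position <= cds_len
        if cds_len is not None and cds_position > cds_len:
            in_cds = False
        out.append(VariantSite(
            gene=col.ref_id, cds_position=cds_position, ref_base=col.ref_base,
            alt_base=primary, frequency=freq, coverage=col.coverage,
            counts=col.counts, alts=tuple(alts),
            focus=freq > params.edit_focus_freq, in_cds=in_cds,
        ))
    return out


def subtract_snps(
    rna_sites: list[VariantSite], dna_sites: list[VariantSite]
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Drop RNA sites coinciding with a DNA variant, matched on (gene, CDS position)."""
    snp_keys = {(s.gene, s.cds_position) for s in dna_sites}
    kept, removed = [], []
    for site in rna_sites:
        (removed if (site.gene, site.cds_position) in snp_keys else kept).append(site)
    return kept, removed


def classify_effect(site: VariantSite, cds: str) -> EditingSite:
    """Codon context and effect of substituting the site's primary alternative."""
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3")
    pos = site.cds_position
    if not 1 <= pos <= len(cds):
        raise ValueError(f"CDS position {pos} outside CDS of length {len(cds)}")
    codon_index = (pos - 1) // 3 + 1
    codon_pos = (pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start : start + 3]
    edited = list(ref_codon)
    edited[codon_pos - 1] = site.alt_base
    edited_codon = "".join(edited)
    ref_aa = translate(ref_codon)
    edited_aa = translate(edited_codon)
    if ref_aa != "*" and edited_aa == "*":
        effect = "stop_gain"
    elif codon_index == 1 and edited_codon == "ATG" and ref_codon != "ATG":
        effect = "start_gain"
    elif ref_aa == edited_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return EditingSite(
        site=site, codon_index=codon_index, codon_pos=codon_pos,
        ref_codon=ref_codon, edited_codon=edited_codon,
        ref_aa=ref_aa, edited_aa=edited_aa, effect=effect,
        is_c_to_u=(site.ref_base == "C" and site.alt_base == "T"),
    )


def summarize_editing(sites: list[EditingSite]) -> dict:
    """Per-gene counts, amino-acid change tallies, codon-position distribution,
    synonymous/nonsynonymous splits, stop/start gains, and the C-to-U share."""
    n = len(sites)
    per_gene = Counter(s.gene for s in sites)
    changes = Counter(f"{s.ref_aa}>{s.edited_aa}" for s in sites)
    pos_counts = {p: sum(1 for s in sites if s.codon_pos == p) for p in (1, 2, 3)}
    syn = sum(1 for s in sites if s.effect == "synonymous")
    stop_gain = sum(1 for s in sites if s.effect == "stop_gain")
    start_gain = sum(1 for s in sites if s.effect == "start_gain")
    c2u = sum(1 for s in sites if s.is_c_to_u)
    return {
        "n_sites": n,
        "per_gene": dict(sorted(per_gene.items(), key=lambda kv: (-kv[1], kv[0]))),
        "aa_changes": dict(changes.most_common()),
        "codon_position_counts": pos_counts,
        "codon_position_percent": {p: percent(c, n) if n else 0.0 for p, c in pos_counts.items()},
        "synonymous": syn,
        "nonsynonymous": n - syn,
        "synonymous_percent": percent(syn, n) if n else 0.0,
        "nonsynonymous_percent": percent(n - syn, n) if n else 0.0,
        "stop_gain": stop_gain,
        "start_gain": start_gain,
        "c_to_u": c2u,
        "c_to_u_percent": percent(c2u, n) if n else 0.0,
    }


# ----------------------------------------------------------------------------
# Gene-centric pipeline


def run_editing_pipeline(
    genome: GenomeRecord,
    feats: list[CdsFeature],
    rna_reads_by_gene: dict[str, list[ReadRecord]],
    dna_reads_by_gene: dict[str, list[ReadRecord]] | None = None,
    params: Parameters | None = None,
    c2u_only: bool = False,
) -> dict:
    """Call, subtract, and classify editing over every gene's CDS±flank reference.

    Returns a dict with candidate RNA sites, DNA SNP sites, the SNP-subtracted
    site list, classified in-CDS editing sites, and the summary. Flank sites
    are retained in the candidate list but excluded from classification.
    """
    params = params or Parameters()
    dna_reads_by_gene = dna_reads_by_gene or {}
    rna_sites: list[VariantSite] = []
    dna_sites: list[VariantSite] = []
    cds_by_gene: dict[str, str] = {}
    for feat in feats:
        cds = extract_cds(genome, feat, flank=0)
        cds_by_gene[feat.gene] = cds
        ref = extract_cds(genome, feat, flank=params.cds_flank)
        up_flank = min(params.cds_flank, _left_flank_len(genome, feat))
        for pool, acc in ((rna_reads_by_gene, rna_sites), (dna_reads_by_gene, dna_sites)):
            reads = pool.get(feat.gene, [])
            if not reads:
                continue
            pileup = build_pileup(ref, reads, ref_id=feat.gene)
            acc.extend(call_sites(pileup, params, flank=up_flank, cds_len=len(cds)))
    kept, removed = subtract_snps(rna_sites, dna_sites)
    classified = []
    for site in kept:
        if not site.in_cds:
            continue
        if c2u_only and not (site.ref_base == "C" and site.alt_base == "T"):
            continue
        classified.append(classify_effect(site, cds_by_gene[site.gene]))
    return {
        "rna_candidates": rna_sites,
        "dna_snps": dna_sites,
        "kept": kept,
        "removed": removed,
        "classified": classified,
        "summary": summarize_editing(classified),
    }


def _left_flank_len(genome: GenomeRecord, feat: CdsFeature) -> int:
    # length of 5'-flank actually present in the extracted mRNA-oriented reference
    if feat.strand == "+":
        return feat.start - 1
    return genome.length - feat.end


def sites_to_table(sites: list[VariantSite]) -> pd.DataFrame:
    """Report table shaped like published pileup listings."""
    rows = [
        {
            "Region": s.gene, "Position": s.cds_position, "Reference": s.ref_base,
            "Coverage": s.coverage, "Base Count [A, C, G, T]": list(s.counts),
            "AllSubs": s.all_subs, "Frequency": s.frequency_2dp, "Focus": s.focus,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=[
        "Region", "Position", "Reference", "Coverage",
        "Base Count [A, C, G, T]", "AllSubs", "Frequency", "Focus",
    ])


def load_editing_table() -> pd.DataFrame:
    """Published 35-row pileup table (mitogenome OR538545.1 PCGs) as shipped data."""
    with resources.files("mitokit.data").joinpath("tw_mito_editing_pileup.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
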