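"""Mitochondrial plastid DNA (MTPT) detection, annotation, and validation.

Chloroplast-genome fragments integrate into plant mitochondrial genomes at a
low but persistent rate; the resulting MTPTs confound barcoding and assembly
and often carry complete tRNA genes or fragments of photosynthesis genes.
Detection here is a local homology search between the two genomes (NCBI
blastn, both strands) with explicit post-filters — minimum hit length 30 bp
and minimum identity 0.70 by default — followed by a merge of overlapping
hits on the mitochondrial axis so each discrete insertion is reported once.
Each hit can then be annotated with the plastid genes it carries (complete
when fully contained, partial when properly overlapping) and validated by
long reads that span the full insertion plus anchors in both mitochondrial
flanks.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass, replace

import edlib
import pandas as pd

from .seqcore import CdsFeature, GenomeRecord, Parameters, revcomp, round_half_up, write_fasta
from .synthetic import ReadRecord

__all__ = ["MtptHit", "find_mtpts", "mtpt_fraction", "annotate_mtpts", "validate_mtpts", "mtpt_summary"]

_BLAST_COLS = ["qstart", "qend", "sstart", "send", "pident", "length", "bitscore"]


@dataclass(frozen=True)
class MtptHit:
    """One homologous mitogenome/plastome fragment; coordinates 1-based inclusive."""

    id: str
    mito_start: int
    mito_end: int
    plastid_start: int
    plastid_end: int
    strand: str  # "+": same orientation; "-": plastid fragment reverse complemented
    length: int
    identity: float
    in_IR: bool = False
    genes_complete: tuple = ()
    genes_partial: tuple = ()
    validated: str = "untested"  # "supported" | "unsupported" | "untested"

    def __post_init__(self) -> None:
        assert self.length == self.mito_end - self.mito_start + 1
        assert 0.0 < self.identity <= 1.0


def _run_blastn(query: GenomeRecord, subject: GenomeRecord) -> pd.DataFrame:
    """blastn query-vs-subject; query coordinates are the mitochondrial axis."""
    with tempfile.TemporaryDirectory() as tmp:
        qpath = os.path.join(tmp, "query.fa")
        spath = os.path.join(tmp, "subject.fa")
        write_fasta([query], qpath)
        write_fasta([subject], spath)
        proc = subprocess.run(
            ["blastn", "-task", "blastn", "-query", qpath, "-subject", spath,
             "-outfmt", "6 " + " ".join(_BLAST_COLS)],
            capture_output=True, text=True, check=True,
        )
    rows = [line.split("\t") for line in proc.stdout.splitlines() if line.strip()]
    frame = pd.DataFrame(rows, columns=_BLAST_COLS)
    if len(frame):
        frame = frame.astype({c: float for c in _BLAST_COLS}).astype(
            {c: int for c in ("qstart", "qend", "sstart", "send", "length")})
    return frame


def find_mtpts(
    mito: GenomeRecord,
    plastid: GenomeRecord,
    min_len: int = 30,
    min_identity: float = 0.70,
) -> list[MtptHit]:
    """Plastid-derived fragments in the mitogenome, merged on the mito axis.

    Hits are filtered by length and identity, then overlapping/abutting hits
    on the mitochondrial axis are merged into one fragment (plastid
    coordinates and strand from the highest-scoring constituent, identity
    length-weighted). Ids MTPT1... are assigned in descending length order.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    if not mito.seq or not plastid.seq:
        raise ValueError("both genomes must be non-empty")
    hits = _run_blastn(mito, plastid)
    if not len(hits):
        return []
    hits = hits[(hits["length"] >= min_len) & (hits["pident"] >= 100.0 * min_identity)]
    if not len(hits):
        return []
    hits = hits.sort_values(["qstart", "qend"]).reset_index(drop=True)
    clusters: list[list[int]] = []
    cur_end = -1
    for idx, row in hits.iterrows():
        if clusters and row["qstart"] <= cur_end + 1:
            clusters[-1].append(idx)
            cur_end = max(cur_end, row["qend"])
        else:
            clusters.append([idx])
            cur_end = row["qend"]
    merged = []
    for members in clusters:
        sub = hits.loc[members]
        best = sub.loc[sub["bitscore"].idxmax()]
        m_start, m_end = int(sub["qstart"].min()), int(sub["qend"].max())
        identity = float((sub["pident"] * sub["length"]).sum() / sub["length"].sum()) / 100.0
        strand = "+" if best["sstart"] <= best["send"] else "-"
        ps, pe = sorted((int(best["sstart"]), int(best["send"])))
        merged.append(dict(
            mito_start=m_start, mito_end=m_end, plastid_start=ps, plastid_end=pe,
            strand=strand, length=m_end - m_start + 1, identity=min(identity, 1.0),
        ))
    merged.sort(key=lambda h: (-h["length"], h["mito_start"]))
    return [MtptHit(id=f"MTPT{i}", **h) for i, h in enumerate(merged, start=1)]


def mtpt_fraction(total_mtpt: int, genome_len: int) -> float:
    """Percentage of the mitogenome covered by MTPT sequence, 2 decimals."""
    if total_mtpt < 0 or genome_len <= 0:
        raise ValueError("lengths must be non-negative and genome_len positive")
    if total_mtpt > genome_len:
        raise ValueError("total MTPT length exceeds genome length")
    return round_half_up(100.0 * total_mtpt / genome_len, 2)


def annotate_mtpts(
    hits: list[MtptHit],
    plastid_feats: list[CdsFeature],
    ir_intervals: list[tuple[int, int]] = (),
) -> list[MtptHit]:
    """Attach gene content (complete/partial) and IR membership to each hit.

    A plastid gene is complete when its full span lies inside the hit's
    plastid interval, partial when it properly overlaps it; ``in_IR`` is set
    when the plastid interval intersects any inverted-repeat interval.
    """
    out = []
    for hit in hits:
        hs, he = hit.plastid_start, hit.plastid_end
        complete, partial = [], []
        for feat in plastid_feats:
            fs, fe = feat.start, feat.end
            if fs >= hs and fe <= he:
                complete.append(feat.gene)
            elif fs <= he and fe >= hs:
                partial.append(feat.gene)
        in_ir = any(hs <= e and s <= he for s, e in ir_intervals)
        out.append(replace(hit, genes_complete=tuple(complete),
                           genes_partial=tuple(partial), in_IR=in_ir))
    return out


def validate_mtpts(
    mito: GenomeRecord,
    hits: list[MtptHit],
    reads: list[ReadRecord],
    flank: int = 1000,
    params: Parameters | None = None,
) -> list[MtptHit]:
    """Flank-anchored long-read validation of each MTPT.

    A hit is ``supported`` when at least one read aligns across the full
    insertion plus ``recomb_min_anchor`` bases of both mitochondrial flanks at
    identity >= ``recomb_min_identity``; ``untested`` when no read is long
    enough to span that window.
    """
    params = params or Parameters()
    out = []
    for hit in hits:
        anchor = min(params.recomb_min_anchor, flank)
        core_start = hit.mito_start - 1
        core_end = hit.mito_end
        core = mito.seq[core_start:core_end]
        left = mito.seq[max(0, core_start - anchor) : core_start]
        right = mito.seq[core_end : core_end + anchor]
        window_len = len(left) + len(core) + len(right)
        core_budget = int((1.0 - params.recomb_min_identity) * len(core))
        spanning_possible = any(len(r.seq) >= window_len for r in reads)
        if not spanning_possible:
            out.append(replace(hit, validated="untested"))
            continue
        supported = False
        for read in reads:
            if len(read.seq) < window_len:
                continue
            for target in (read.seq, revcomp(read.seq)):
                if _anchored_match(core, left, right, target, core_budget, params):
                    supported = True
                    break
            if supported:
                break
        out.append(replace(hit, validated="supported" if supported else "unsupported"))
    return out


def _anchored_match(core: str, left: str, right: str, target: str,
                    core_budget: int, params: Parameters) -> bool:
    """True when core aligns inside target AND both flank anchors align at their
    own identity threshold immediately around the core's location.

    Checking the anchors separately keeps a read that matches only the core
    (e.g. a plastid read over an MTPT's source locus) from counting as
    spanning support.
    """
    res = edlib.align(core, target, mode="HW", task="locations", k=core_budget)
    if res["editDistance"] < 0 or not res["locations"]:
        return False
    slack = max(10, core_budget)
    for loc_start, loc_end in res["locations"][:4]:
        ok = True
        for anchor_seq, seg in (
            (left, target[max(0, loc_start - len(left) - slack) : loc_start + slack]),
            (right, target[loc_end + 1 - slack : loc_end + 1 + len(right) + slack]),
        ):
            if not anchor_seq:
                continue
            budget = int((1.0 - params.recomb_min_identity) * len(anchor_seq))
            d = edlib.align(anchor_seq, seg, mode="HW", task="distance", k=budget)["editDistance"]
            if d < 0:
                ok = False
                break
        if ok:
            return True
    return False


def mtpt_summary(hits: list[MtptHit], mito_len: int) -> dict:
    total = sum(h.length for h in hits)
    return {
        "n_hits": len(hits),
        "total_bp": total,
        "percent_of_mitogenome": mtpt_fraction(total, mito_len) if mito_len else 0.0,
    }


def hits_to_table(hits: list[MtptHit]) -> pd.DataFrame:
    rows = [
        {
            "id": h.id, "mito_start": h.mito_start, "mito_end": h.mito_end,
            "plastid_start": h.plastid_start, "plastid_end": h.plastid_end,
            "strand": h.strand, "length": h.length, "identity": round(h.identity, 4),
            "in_IR": h.in_IR,
            "genes_complete": ",".join(h.genes_complete),
            "genes_partial": ",".join(h.genes_partial),
            "validated": h.validated,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=[
        "id", "mito_start", "mito_end", "plastid_start", "plastid_end", "strand",
        "length", "identity", "in_IR", "genes_complete", "genes_partial", "validated",
    ])
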