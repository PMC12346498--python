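"""Synthetic organelle genomes, reads, and truth tables.

Every downstream stage of the package is testable without any download: this
module builds a toy mitogenome/plastome pair with planted SSRs, tandem
arrays, dispersed repeat pairs (optionally recombinationally active at a set
mixture fraction), plastid-derived insertions (MTPTs), protein-coding genes,
and planted C→U editing and DNA SNP frequencies — and emits the truth table
alongside, so detectors can be scored against known answers.

Planting is done by overwriting windows of an i.i.d. background (default GC
45% for the mitogenome, 37% for the plastome, mirroring typical organelle
base composition), with single-base guards at feature boundaries so planted
repeats are maximal exactly at their recorded coordinates, and a scrubbing
pass that disrupts chance background SSRs so the planted truth is the whole
truth. Read simulators encode provenance (source record, interval, strand) in
read names, which lets support-counting tests compare assignments against
labels with no external aligner. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .seqcore import CdsFeature, GenomeRecord, Parameters, revcomp
from .tandem import SsrRecord, TandemRepeatRecord, find_ssrs, is_primitive

__all__ = [
    "ReadRecord",
    "PlantedGene",
    "PlantingSpec",
    "TruthTables",
    "PlantingError",
    "make_toy_organelles",
    "simulate_long_reads",
    "simulate_amplicon_reads",
    "write_fastq",
    "read_fastq",
    "write_truth_tables",
]

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


class PlantingError(ValueError):
    """The planting spec does not fit the requested genome."""


@dataclass(frozen=True)
class ReadRecord:
    """A simulated read; provenance lives in the name."""

    name: str
    seq: str
    qual: str | None = None

    def fastq_qual(self) -> str:
        return self.qual if self.qual is not None else "I" * len(self.seq)


@dataclass(frozen=True)
class PlantedGene:
    name: str
    length: int  # nucleotides including start and stop codons; divisible by 3
    strand: str = "+"


@dataclass(frozen=True)
class PlantingSpec:
    """What to plant. Defaults give a small but complete exercise of every stage."""

    genes: tuple = (
        PlantedGene("cox2", 660, "+"),
        PlantedGene("nad4", 720, "-"),
        PlantedGene("ccmB", 600, "+"),
    )
    ssrs: tuple = (
        ("A", 12), ("AG", 6), ("CAT", 5), ("ACTG", 4), ("AACGT", 3), ("AACGTC", 3),
    )
    tandems: tuple = (("ACGTACGGTTACG", 4), ("ACGGATCGTT", 25))
    repeat_pairs: tuple = ((300, "F", 0.0), (120, "P", 0.0))
    mtpts: tuple = ((500, 1.0), (300, 0.95))
    edits_per_gene: int = 8
    edit_freq_range: tuple = (0.2, 0.9)
    n_snp_overlaps: int = 3
    n_snp_extra: int = 2
    snp_freq_range: tuple = (0.3, 0.7)
    mito_gc: float = 0.45
    plastid_gc: float = 0.37


@dataclass(frozen=True)
class PlantedMtpt:
    mito_start: int  # 1-based inclusive
    mito_end: int
    plastid_start: int
    plastid_end: int
    identity: float


@dataclass
class TruthTables:
    """Planted ground truth emitted alongside every generated dataset."""

    planted_ssrs: list
    planted_tandems: list
    planted_repeat_pairs: list  # (RepeatPair, recombinant_fraction)
    planted_mtpts: list  # PlantedMtpt
    planted_edits: list  # (gene, cds_position, true_frequency)
    planted_snps: list  # (gene, cds_position, alt, true_frequency)
    seed: int


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _random_cds(rng: np.random.Generator, length: int) -> str:
    if length % 3 != 0 or length < 9:
        raise PlantingError(f"gene length {length} must be >= 9 and divisible by 3")
    codons = ["ATG"]
    n_mid = length // 3 - 2
    while len(codons) < n_mid + 1:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _guard(arr: np.ndarray, idx: int, forbidden: set[str]) -> None:
    """Force arr[idx] to a base outside ``forbidden`` (no-op if already so)."""
    if idx < 0 or idx >= arr.size:
        return
    if chr(arr[idx]) not in forbidden:
        return
    for b in BASES:
        if b not in forbidden:
            arr[idx] = ord(b)
            return


class _Allocator:
    """Sequential window allocator with randomised inter-feature gaps."""

    def __init__(self, rng: np.random.Generator, genome_len: int, margin: int = 800):
        self.rng = rng
        self.cursor = margin  # 0-based
        self.limit = genome_len - margin

    def take(self, length: int, what: str) -> int:
        gap = int(self.rng.integers(600, 1500))
        start = self.cursor + gap
        if start + length > self.limit:
            raise PlantingError(f"planting spec infeasible: no room for {what} ({length} bp)")
        self.cursor = start + length
        return start


def make_toy_organelles(
    seed: int,
    mito_len: int = 60_000,
    plastid_len: int = 30_000,
    spec: PlantingSpec | None = None,
) -> tuple[GenomeRecord, GenomeRecord, list[CdsFeature], TruthTables]:
    """Build a toy mitogenome + plastome with planted, recorded features."""
    if mito_len < 10_000 or plastid_len < 10_000:
        raise PlantingError("genome lengths must be >= 10 kb")
    spec = spec or PlantingSpec()
    rng = np.random.default_rng(seed)
    plastid = _random_seq(rng, plastid_len, spec.plastid_gc)
    mito = _random_seq(rng, mito_len, spec.mito_gc)
    alloc = _Allocator(rng, mito_len)

    # --- genes -------------------------------------------------------------
    feats: list[CdsFeature] = []
    gene_seqs: dict[str, str] = {}
    for gene in spec.genes:
        cds = _random_cds(rng, gene.length)
        start0 = alloc.take(gene.length, f"gene {gene.name}")
        genomic = cds if gene.strand == "+" else revcomp(cds)
        mito[start0 : start0 + gene.length] = np.frombuffer(genomic.encode(), dtype=np.uint8)
        feats.append(CdsFeature(
            gene=gene.name, genome_id="toy_mito", strand=gene.strand,
            intervals=((start0 + 1, start0 + gene.length),),
        ))
        gene_seqs[gene.name] = cds

    # --- SSRs --------------------------------------------------------------
    planted_ssrs: list[SsrRecord] = []
    for motif, copies in spec.ssrs:
        if not is_primitive(motif):
            raise PlantingError(f"SSR motif {motif!r} is not primitive")
        p, run = len(motif), motif * copies
        start0 = alloc.take(len(run), f"SSR {motif}x{copies}")
        mito[start0 : start0 + len(run)] = np.frombuffer(run.encode(), dtype=np.uint8)
        _guard(mito, start0 - 1, {chr(mito[start0 - 1 + p])})
        end0 = start0 + len(run) - 1
        _guard(mito, end0 + 1, {chr(mito[end0 + 1 - p])})
        planted_ssrs.append(SsrRecord(motif=motif, unit_len=p, copies=copies,
                                      start=start0 + 1, end=end0 + 1))

    # --- tandem arrays -----------------------------------------------------
    planted_tandems: list[TandemRepeatRecord] = []
    for unit, copies in spec.tandems:
        p, run = len(unit), unit * copies
        start0 = alloc.take(len(run), f"tandem {unit}x{copies}")
        mito[start0 : start0 + len(run)] = np.frombuffer(run.encode(), dtype=np.uint8)
        _guard(mito, start0 - 1, {chr(mito[start0 - 1 + p])})
        end0 = start0 + len(run) - 1
        _guard(mito, end0 + 1, {chr(mito[end0 + 1 - p])})
        planted_tandems.append(TandemRepeatRecord(
            unit=unit, period=p, copy_number=float(copies),
            start=start0 + 1, end=end0 + 1, score=2 * len(run),
        ))

    # --- dispersed repeat pairs: first copies now, second copies after MTPTs
    from .dispersed import RepeatPair  # local import to avoid a cycle at import time

    pair_payload = []
    for length, rtype, fraction in spec.repeat_pairs:
        if rtype not in ("F", "P"):
            raise PlantingError(f"repeat type must be F or P, got {rtype!r}")
        if not 0.0 <= fraction <= 1.0:
            raise PlantingError("recombinant fraction must be in [0, 1]")
        content = _to_str(_random_seq(rng, length, spec.mito_gc))
        c1 = alloc.take(length, f"repeat copy1 ({length} bp {rtype})")
        mito[c1 : c1 + length] = np.frombuffer(content.encode(), dtype=np.uint8)
        pair_payload.append((length, rtype, fraction, content, c1))

    # --- MTPT insertions ---------------------------------------------------
    planted_mtpts: list[PlantedMtpt] = []
    p_cursor = 500
    for length, identity in spec.mtpts:
        if not 0.0 < identity <= 1.0:
            raise PlantingError("MTPT identity must be in (0, 1]")
        ps = p_cursor + int(rng.integers(200, 800))
        if ps + length > plastid_len - 500:
            raise PlantingError(f"planting spec infeasible: no room in plastid for {length} bp MTPT")
        p_cursor = ps + length
        fragment = plastid[ps : ps + length].copy()
        n_sub = int(round((1.0 - identity) * length))
        if n_sub:
            pos = rng.choice(length, size=n_sub, replace=False)
            for q in pos:
                choices = [ord(b) for b in BASES if ord(b) != fragment[q]]
                fragment[q] = choices[int(rng.integers(0, 3))]
        m0 = alloc.take(length, f"MTPT ({length} bp)")
        mito[m0 : m0 + length] = fragment
        _guard(mito, m0 - 1, {chr(plastid[ps - 1])})
        _guard(mito, m0 + length, {chr(plastid[ps + length])})
        planted_mtpts.append(PlantedMtpt(
            mito_start=m0 + 1, mito_end=m0 + length,
            plastid_start=ps + 1, plastid_end=ps + length, identity=identity,
        ))

    # --- second repeat copies ----------------------------------------------
    planted_pairs = []
    for length, rtype, fraction, content, c1 in pair_payload:
        copy2 = content if rtype == "F" else revcomp(content)
        c2 = alloc.take(length, f"repeat copy2 ({length} bp {rtype})")
        mito[c2 : c2 + length] = np.frombuffer(copy2.encode(), dtype=np.uint8)
        if rtype == "F":
            _guard(mito, c2 - 1, {chr(mito[c1 - 1])})
            _guard(mito, c2 + length, {chr(mito[c1 + length])})
        else:
            comp = dict(zip("ACGT", "TGCA"))
            _guard(mito, c2 + length, {comp[chr(mito[c1 - 1])]})
            _guard(mito, c2 - 1, {comp[chr(mito[c1 + length])]})
        planted_pairs.append((
            RepeatPair(id=f"planted{len(planted_pairs) + 1}", length=length, rtype=rtype,
                       start1=c1 + 1, end1=c1 + length, start2=c2 + 1, end2=c2 + length),
            fraction,
        ))

    # --- scrub chance background SSRs so planted truth is the whole truth ---
    truth_intervals = {(r.start, r.end) for r in planted_ssrs}
    mito_rec = _scrub_chance_ssrs(mito, truth_intervals, feats, planted_pairs, planted_mtpts, plastid, rng)

    # --- planted edits and SNPs on the final CDS sequences ------------------
    mito_genome = GenomeRecord(id="toy_mito", seq=_to_str(mito_rec))
    from .seqcore import extract_cds

    planted_edits = []
    lo, hi = spec.edit_freq_range
    for feat in feats:
        cds = extract_cds(mito_genome, feat, flank=0)
        c_positions = [i + 1 for i in range(3, len(cds) - 3) if cds[i] == "C"]
        k = min(spec.edits_per_gene, len(c_positions))
        chosen = sorted(rng.choice(c_positions, size=k, replace=False).tolist())
        for pos in chosen:
            planted_edits.append((feat.gene, int(pos), float(rng.uniform(lo, hi))))

    planted_snps = []
    slo, shi = spec.snp_freq_range
    by_gene: dict[str, list] = {}
    for gene, pos, _ in planted_edits:
        by_gene.setdefault(gene, []).append(pos)
    overlap_pool = [(g, ps[0]) for g, ps in by_gene.items()]
    for gene, pos in overlap_pool[: spec.n_snp_overlaps]:
        planted_snps.append((gene, pos, "T", float(rng.uniform(slo, shi))))
    for _ in range(spec.n_snp_extra):
        feat = feats[int(rng.integers(0, len(feats)))]
        cds = extract_cds(mito_genome, feat, flank=0)
        edited = set(by_gene.get(feat.gene, []))
        pos = int(rng.integers(4, len(cds) - 3))
        while pos in edited:
            pos = int(rng.integers(4, len(cds) - 3))
        ref = cds[pos - 1]
        alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        planted_snps.append((feat.gene, pos, alt, float(rng.uniform(slo, shi))))

    plastid_genome = GenomeRecord(id="toy_plastid", seq=_to_str(plastid))
    truth = TruthTables(
        planted_ssrs=planted_ssrs,
        planted_tandems=planted_tandems,
        planted_repeat_pairs=planted_pairs,
        planted_mtpts=planted_mtpts,
        planted_edits=planted_edits,
        planted_snps=planted_snps,
        seed=seed,
    )
    return mito_genome, plastid_genome, feats, truth


def _scrub_chance_ssrs(mito, truth_intervals, feats, planted_pairs, planted_mtpts, plastid, rng):
    """Disrupt background SSRs that were not planted, co-mutating duplicated loci.

    A mutation inside a planted repeat copy is mirrored into the partner copy
    (complemented for palindromic pairs) and a mutation inside an MTPT is
    mirrored into its plastid source, so duplication truth stays exact. Inside
    a CDS the replacement base is chosen so no stop codon appears in frame.
    """
    params = Parameters()
    for _round in range(6):
        genome = GenomeRecord(id="toy_mito", seq=_to_str(mito))
        extras = [r for r in find_ssrs(genome, params) if (r.start, r.end) not in truth_intervals]
        if not extras:
            return mito
        for r in extras:
            g0 = (r.start + r.end) // 2 - 1  # 0-based position to disrupt
            current = chr(mito[g0])
            candidates = [b for b in BASES if b != current]
            choice = None
            for feat in feats:
                s0, e0 = feat.start - 1, feat.end - 1
                if s0 <= g0 <= e0:
                    frame_start = s0 + ((g0 - s0) // 3) * 3
                    codon = [chr(mito[frame_start + k]) for k in range(3)]
                    off = g0 - frame_start
                    for b in candidates:
                        trial = codon.copy()
                        trial[off] = b
                        fwd = "".join(trial)
                        if fwd not in _STOPS and revcomp(fwd) not in _STOPS:
                            choice = b
                            break
                    break
            if choice is None:
                choice = candidates[int(rng.integers(0, len(candidates)))]
            mito[g0] = ord(choice)
            for pair, _f in planted_pairs:
                for (sa, ea), (sb, eb) in (((pair.start1, pair.end1), (pair.start2, pair.end2)),
                                           ((pair.start2, pair.end2), (pair.start1, pair.end1))):
                    if sa - 1 <= g0 <= ea - 1:
                        off = g0 - (sa - 1)
                        if pair.rtype == "F":
                            mito[sb - 1 + off] = ord(choice)
                        else:
                            mito[eb - 1 - off] = ord(revcomp(choice))
            for m in planted_mtpts:
                if m.mito_start - 1 <= g0 <= m.mito_end - 1:
                    plastid[m.plastid_start - 1 + (g0 - (m.mito_start - 1))] = ord(choice)
    return mito


# ----------------------------------------------------------------------------
# Read simulators


def simulate_long_reads(
    genomes: list[tuple[GenomeRecord, float]],
    n: int,
    mean_len: int = 8000,
    error_rate: float = 0.0,
    seed: int = 0,
    sigma: float = 0.25,
) -> list[ReadRecord]:
    """Long reads from a weighted genome mixture with indel-dominated errors.

    Lengths are log-normal around ``mean_len`` (truncated to the source
    genome); errors split 50% substitutions, 25% insertions, 25% deletions.
    Read names record source record, 1-based interval, and strand.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= error_rate <= 0.3:
        raise ValueError("error_rate must be in [0, 0.3]")
    weights = np.array([w for _, w in genomes], dtype=float)
    if weights.size == 0 or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("genome weights must sum to 1")
    rng = np.random.default_rng(seed)
    mu = np.log(mean_len) - sigma**2 / 2
    sources = rng.choice(len(genomes), size=n, p=weights)
    reads: list[ReadRecord] = []
    for i, src in enumerate(sources):
        genome = genomes[src][0]
        length = int(min(max(200, rng.lognormal(mu, sigma)), genome.length))
        start0 = int(rng.integers(0, genome.length - length + 1))
        seq = genome.seq[start0 : start0 + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        if error_rate > 0:
            seq = _apply_errors(seq, error_rate, rng)
        reads.append(ReadRecord(
            name=f"read{i}|src={genome.id}|start={start0 + 1}|end={start0 + length}|strand={strand}",
            seq=seq,
        ))
    return reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() >= rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.5:  # substitution
            out.append(BASES[(BASES.index(ch) + 1 + int(rng.integers(0, 3))) % 4])
        elif kind < 0.75:  # insertion (keep the base, add a random one)
            out.append(ch)
            out.append(BASES[int(rng.integers(0, 4))])
        # else deletion: drop the base
    return "".join(out)


def simulate_amplicon_reads(
    ref: str,
    sites: list[tuple[int, str, float]],
    depth: int,
    read_len: int = 100,
    seed: int = 0,
) -> list[ReadRecord]:
    """Uniform-coverage error-free short reads with planted per-site alt frequencies.

    At each listed (1-based position, alt, frequency) site, every covering
    read independently carries the alt with the given probability; everywhere
    else reads are exact substrings of ``ref``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    L = len(ref)
    if read_len > L:
        read_len = L
    for pos, alt, freq in sites:
        if not 1 <= pos <= L:
            raise ValueError(f"site position {pos} outside reference of length {L}")
        if alt not in BASES:
            raise ValueError(f"alt must be one of {BASES}, got {alt!r}")
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"site frequency {freq} outside [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    i = 0
    for _pass in range(depth):
        offset = int(rng.integers(0, read_len))
        starts = list(range(offset, L - read_len + 1, read_len))
        if offset > 0:
            starts.insert(0, 0)
        if not starts or starts[-1] < L - read_len:
            starts.append(L - read_len)
        for s0 in starts:
            seq = ref[s0 : s0 + read_len]
            carried = []
            for pos, alt, freq in sites:
                p0 = pos - 1
                if s0 <= p0 < s0 + read_len and rng.random() < freq:
                    carried.append((p0 - s0, alt))
            if carried:
                chars = list(seq)
                for off, alt in carried:
                    chars[off] = alt
                seq = "".join(chars)
            reads.append(ReadRecord(name=f"amp{i}|src=ref|start={s0 + 1}|end={s0 + read_len}|strand=+", seq=seq))
            i += 1
    return reads


# ----------------------------------------------------------------------------
# FASTQ and truth-table I/O


def write_fastq(reads: list[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.fastq_qual()}\n")


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            reads.append(ReadRecord(name=header[1:].strip(), seq=seq, qual=qual))
    return reads


def write_truth_tables(truth: TruthTables, outdir: str | os.PathLike, spec: PlantingSpec | None = None) -> None:
    """Truth as TSVs plus a JSON manifest with the seed (and spec, if given)."""
    import pandas as pd

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame([asdict(r) for r in truth.planted_ssrs]).to_csv(
        os.path.join(outdir, "truth_ssrs.tsv"), sep="\t", index=False)
    pd.DataFrame([asdict(r) for r in truth.planted_tandems]).to_csv(
        os.path.join(outdir, "truth_tandems.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{**asdict(p), "recombinant_fraction": f} for p, f in truth.planted_repeat_pairs]
    ).to_csv(os.path.join(outdir, "truth_repeat_pairs.tsv"), sep="\t", index=False)
    pd.DataFrame([asdict(m) for m in truth.planted_mtpts]).to_csv(
        os.path.join(outdir, "truth_mtpts.tsv"), sep="\t", index=False)
    pd.DataFrame(truth.planted_edits, columns=["gene", "cds_position", "true_frequency"]).to_csv(
        os.path.join(outdir, "truth_edits.tsv"), sep="\t", index=False)
    pd.DataFrame(truth.planted_snps, columns=["gene", "cds_position", "alt", "true_frequency"]).to_csv(
        os.path.join(outdir, "truth_snps.tsv"), sep="\t", index=False)
    manifest = {"seed": truth.seed}
    if spec is not None:
        manifest["spec"] = json.loads(json.dumps(asdict(spec), default=list))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
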