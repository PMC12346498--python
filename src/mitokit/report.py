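"""End-to-end pipeline on synthetic data and the aggregated genome report.

``run_pipeline`` generates (or is pointed at) a dataset, runs every stage in
dependency order — SSR and tandem scans, dispersed repeats, the
four-conformation recombination screen, MTPT detection/validation, and
gene-centric RNA-editing calling with SNP subtraction — writes one TSV per
stage plus a JSON report aggregating the headline numbers, and records a run
manifest (version, seed, parameters, input digests) for provenance. Two runs
with the same seed and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import pandas as pd

from . import __version__
from .dispersed import find_dispersed_repeats, pairs_to_table
from .editing import run_editing_pipeline, sites_to_table
from .mtpt import annotate_mtpts, find_mtpts, hits_to_table, mtpt_summary, validate_mtpts
from .recombination import build_conformations, screen_all
from .seqcore import GenomeRecord, Parameters, gc_content, round_half_up, write_fasta, write_gff3
from .synthetic import (
    PlantingSpec,
    make_toy_organelles,
    simulate_amplicon_reads,
    simulate_long_reads,
    write_fastq,
    write_truth_tables,
)
from .tandem import find_ssrs, find_tandem_repeats, ssr_class_counts

__all__ = ["simulate_dataset", "run_pipeline"]


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_dataset(
    outdir: str,
    seed: int = 1,
    mito_len: int = 60_000,
    plastid_len: int = 30_000,
    spec: PlantingSpec | None = None,
    params: Parameters | None = None,
    n_long_reads: int = 300,
    long_read_mean: int = 8000,
    long_read_error: float = 0.0,
    n_recomb_reads: int = 200,
    recomb_read_mean: int = 3000,
    rna_depth: int = 60,
    dna_depth: int = 60,
    read_len: int = 100,
) -> dict:
    """Generate the toy dataset, reads, and truth tables; return them in memory too.

    Long reads come from the whole mitogenome; for each recombinationally
    active planted pair an extra pool of locus reads is drawn from the four
    conformations at the planted mixture fraction. RNA short reads carry the
    planted editing frequencies *and* the planted SNPs (a genomic polymorphism
    is transcribed too); DNA short reads carry only the SNPs.
    """
    os.makedirs(outdir, exist_ok=True)
    params = params or Parameters()
    spec = spec or PlantingSpec()
    mito, plastid, feats, truth = make_toy_organelles(seed, mito_len, plastid_len, spec)
    write_fasta([mito], os.path.join(outdir, "mito.fasta"))
    write_fasta([plastid], os.path.join(outdir, "plastid.fasta"))
    write_gff3(feats, os.path.join(outdir, "features.gff3"))
    write_truth_tables(truth, outdir, spec)

    long_reads = simulate_long_reads(
        [(mito, 1.0)], n=n_long_reads, mean_len=long_read_mean,
        error_rate=long_read_error, seed=seed + 1,
    )
    for k, (pair, fraction) in enumerate(truth.planted_repeat_pairs):
        if fraction <= 0:
            continue
        conf = build_conformations(mito, pair, flank=params.recomb_flank)
        mix = [
            (GenomeRecord(id=f"{pair.id}_ref1", seq=conf.ref1), (1 - fraction) / 2),
            (GenomeRecord(id=f"{pair.id}_ref2", seq=conf.ref2), (1 - fraction) / 2),
            (GenomeRecord(id=f"{pair.id}_rec1", seq=conf.rec1), fraction / 2),
            (GenomeRecord(id=f"{pair.id}_rec2", seq=conf.rec2), fraction / 2),
        ]
        long_reads.extend(simulate_long_reads(
            mix, n=n_recomb_reads, mean_len=recomb_read_mean,
            error_rate=long_read_error, seed=seed + 100 + k,
        ))
    write_fastq(long_reads, os.path.join(outdir, "long_reads.fastq"))

    edits_by_gene: dict[str, list] = {}
    for gene, pos, freq in truth.planted_edits:
        edits_by_gene.setdefault(gene, []).append((gene, pos, "T", freq))
    snps_by_gene: dict[str, list] = {}
    for gene, pos, alt, freq in truth.planted_snps:
        snps_by_gene.setdefault(gene, []).append((gene, pos, alt, freq))

    from .seqcore import extract_cds

    rna_reads: dict[str, list] = {}
    dna_reads: dict[str, list] = {}
    for gi, feat in enumerate(feats):
        ref = extract_cds(mito, feat, flank=params.cds_flank)
        up = min(params.cds_flank, feat.start - 1 if feat.strand == "+" else mito.length - feat.end)
        rna_sites = [
            (pos + up, alt, freq)
            for _, pos, alt, freq in edits_by_gene.get(feat.gene, []) + snps_by_gene.get(feat.gene, [])
        ]
        dna_sites = [(pos + up, alt, freq) for _, pos, alt, freq in snps_by_gene.get(feat.gene, [])]
        rna_reads[feat.gene] = simulate_amplicon_reads(
            ref, rna_sites, depth=rna_depth, read_len=read_len, seed=seed + 1000 + gi)
        dna_reads[feat.gene] = simulate_amplicon_reads(
            ref, dna_sites, depth=dna_depth, read_len=read_len, seed=seed + 2000 + gi)
    for pool, name in ((rna_reads, "rna_reads.fastq"), (dna_reads, "dna_reads.fastq")):
        write_fastq([r for reads in pool.values() for r in reads], os.path.join(outdir, name))

    return {
        "mito": mito, "plastid": plastid, "feats": feats, "truth": truth,
        "long_reads": long_reads, "rna_reads": rna_reads, "dna_reads": dna_reads,
        "params": params, "spec": spec, "seed": seed,
    }


def run_pipeline(
    outdir: str,
    seed: int = 1,
    params: Parameters | None = None,
    dataset: dict | None = None,
    c2u_only: bool = False,
    **simulate_kwargs,
) -> dict:
    """Run every stage on a (by default freshly simulated) dataset; return the report."""
    os.makedirs(outdir, exist_ok=True)
    params = params or Parameters()
    if dataset is None:
        dataset = simulate_dataset(os.path.join(outdir, "data"), seed=seed,
                                   params=params, **simulate_kwargs)
    mito, plastid, feats = dataset["mito"], dataset["plastid"], dataset["feats"]

    ssrs = find_ssrs(mito, params)
    pd.DataFrame([dataclasses.asdict(r) for r in ssrs]).to_csv(
        os.path.join(outdir, "ssrs.tsv"), sep="\t", index=False)
    tandems = find_tandem_repeats(mito, params)
    pd.DataFrame([dataclasses.asdict(r) for r in tandems]).to_csv(
        os.path.join(outdir, "tandems.tsv"), sep="\t", index=False)
    pairs = find_dispersed_repeats(mito, min_len=params.drs_min_len)
    pairs_to_table(pairs).to_csv(os.path.join(outdir, "dispersed.tsv"), sep="\t", index=False)

    recomb = screen_all(mito, pairs, dataset["long_reads"], params)
    recomb.to_csv(os.path.join(outdir, "recombination.tsv"), sep="\t", index=False)

    hits = find_mtpts(mito, plastid)
    hits = annotate_mtpts(hits, [])
    hits = validate_mtpts(mito, hits, dataset["long_reads"], flank=params.mtpt_flank, params=params)
    hits_to_table(hits).to_csv(os.path.join(outdir, "mtpt.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "mtpt_summary.json"), "w") as fh:
        json.dump(mtpt_summary(hits, mito.length), fh, indent=2, sort_keys=True)

    editing = run_editing_pipeline(
        mito, feats, dataset["rna_reads"], dataset["dna_reads"], params, c2u_only=c2u_only)
    sites_to_table(editing["kept"]).to_csv(os.path.join(outdir, "editing_sites.tsv"), sep="\t", index=False)
    sites_to_table(editing["removed"]).to_csv(
        os.path.join(outdir, "editing_removed_snp_overlaps.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "editing_summary.json"), "w") as fh:
        json.dump(editing["summary"], fh, indent=2, sort_keys=True)

    by_type = {"F": 0, "P": 0}
    for p in pairs:
        by_type[p.rtype] += 1
    report = {
        "genome": {"id": mito.id, "length": mito.length,
                   "gc_percent": round_half_up(gc_content(mito), 2)},
        "ssr": ssr_class_counts(ssrs),
        "tandem_repeats": len(tandems),
        "dispersed_repeats": {"total": len(pairs), **by_type},
        "recombination": {
            "pairs_tested": int(len(recomb)),
            "pairs_with_recombinant_support": recomb.attrs["n_supported_pairs"],
            "pairs_untestable": recomb.attrs["n_untestable"],
        },
        "mtpt": mtpt_summary(hits, mito.length),
        "editing": editing["summary"],
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    inputs = {}
    data_dir = os.path.join(outdir, "data")
    if os.path.isdir(data_dir):
        for name in sorted(os.listdir(data_dir)):
            path = os.path.join(data_dir, name)
            if os.path.isfile(path):
                inputs[name] = _digest(path)
    manifest = {
        "tool": "mitokit", "version": __version__, "seed": seed,
        "parameters": {k: v for k, v in dataclasses.asdict(params).items()},
        "input_digests": inputs,
    }
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
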