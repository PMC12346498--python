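"""Generate a toy mitogenome/plastome pair with planted, recorded features.

The generator overwrites windows of a random background (GC 45% / 37%) with
SSRs, tandem arrays, dispersed repeat pairs, plastid-derived insertions, and
protein-coding genes, and returns the truth tables every detector can be
scored against.
"""

from mitokit import gc_content, make_toy_organelles

mito, plastid, feats, truth = make_toy_organelles(seed=1)

print(f"mitogenome : {mito.id}, {mito.length:,} bp, GC {gc_content(mito):.2f}%")
print(f"plastome   : {plastid.id}, {plastid.length:,} bp, GC {gc_content(plastid):.2f}%")
print(f"genes      : {[f.gene for f in feats]}")
print(f"planted    : {len(truth.planted_ssrs)} SSRs, {len(truth.planted_tandems)} tandem arrays,"
      f" {len(truth.planted_repeat_pairs)} dispersed pairs, {len(truth.planted_mtpts)} MTPTs,"
      f" {len(truth.planted_edits)} editing sites, {len(truth.planted_snps)} SNPs")
print("\nEvery coordinate below is 1-based inclusive on the toy mitogenome;")
print("these are the answers the detection examples should recover.")
for r in truth.planted_ssrs[:3]:
    print(f"  SSR  {r.motif!r} x{r.copies} at {r.start}-{r.end}")
for pair, fraction in truth.planted_repeat_pairs:
    print(f"  pair {pair.rtype} {pair.length} bp at {pair.start1}-{pair.end1} / "
          f"{pair.start2}-{pair.end2} (recombinant fraction {fraction})")
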