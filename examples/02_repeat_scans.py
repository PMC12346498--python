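"""Scan a genome for SSRs, long tandem repeats, and dispersed repeat pairs.

SSRs are perfect 1-6 bp-unit runs above MISA-style copy minima; long tandem
repeats have units of 7+ bp scored +2/-7 against their consensus; dispersed
repeats are exact non-adjacent copies >= 50 bp, direct (F) or palindromic (P).
"""

from mitokit import find_dispersed_repeats, find_ssrs, find_tandem_repeats, make_toy_organelles
from mitokit.tandem import ssr_class_counts

mito, _, _, truth = make_toy_organelles(seed=1)

ssrs = find_ssrs(mito)
print("SSR class counts:", ssr_class_counts(ssrs))
print("e.g.", ssrs[0])

tandems = find_tandem_repeats(mito)
for t in tandems:
    print(f"tandem: unit {t.unit!r} period {t.period} x{t.copy_number} "
          f"at {t.start}-{t.end}, score {t.score} (2x length for a perfect array)")

pairs = find_dispersed_repeats(mito)
for p in pairs:
    print(f"dispersed {p.id}: {p.rtype} {p.length} bp at "
          f"{p.start1}-{p.end1} / {p.start2}-{p.end2}")

planted = {(p.start1, p.start2) for p, _ in truth.planted_repeat_pairs}
found = {(p.start1, p.start2) for p in pairs}
print("planted dispersed pairs recovered exactly:", planted == found)
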