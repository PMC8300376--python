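"""TaqMan allelic discrimination of NR6A1 g.748C>T on the full cohort.

Generates the default 96-sample cohort (24 wild boars, 67 pigs from five
breeds, 5 deliberate hybrids), amplifies the NR6A1 target and calls the
genotype by competitive probe matching.
"""

from collections import Counter

import boarmark as bm

panel = bm.default_panel()
cohort = bm.generate_cohort(seed=0)

calls = Counter()
for s in cohort.samples:
    amplicon = bm.extract_amplicon(s.nr6a1_template,
                                   panel.assays["NR6A1"].primers, "NR6A1")
    calls[(s.role, bm.taqman_call(amplicon, panel.probes))] += 1

print("NR6A1 g.748C>T calls by sample role:")
for (role, call), n in sorted(calls.items()):
    print(f"  {role:10s} {call}: {n}")

print("\nThe C allele marks the wild-boar lineage and the T allele the "
      "domestic lineage; every first-generation hybrid carries one of "
      "each (CT), so this single SNP separates the three groups cleanly.")
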