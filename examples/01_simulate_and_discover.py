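"""Simulate a diploid sample against a pangenome panel and discover
candidate variants.

Builds the "tiny" scenario (one 30 kb contig, an 8-haplotype panel, a
near-identical 5 kb duplication with mismapped reads), then scans the
read pileup for positions where at least two reads assert the same
mismatch or indel.
"""

from pancall import simulate_biased_scenario
from pancall.pipeline import discover_bundle_candidates

bundle = simulate_biased_scenario(seed=1, preset="tiny")
print(f"reference contigs : {bundle.reference.lengths}")
print(f"panel haplotypes  : {bundle.panel.haplotype_count}")
print(f"simulated reads   : {len(bundle.reads)}")
print(f"truth variants    : {len(bundle.truth.records)}")
print(f"donor haplotypes  : {bundle.manifest['donors']}")

candidates = discover_bundle_candidates(bundle)
truth_keys = {k for k, _ in bundle.truth.records}
real = sum(1 for c in candidates if c.key in truth_keys)
print(f"\ncandidates        : {len(candidates)} "
      f"({real} match a truth variant, {len(candidates) - real} are noise)")
print("first five:")
for c in candidates[:5]:
    tag = "true" if c.key in truth_keys else "false"
    print(f"  {c.contig}:{c.pos + 1} {c.ref_allele}>{c.alt_allele} "
          f"support {c.alt_support}/{c.total_depth} ({c.kind}, {tag})")

# The excess of false candidates over truth sites comes from the
# duplication: reads mismapped between the two near-identical copies
# pile up mismatches at the wrong locus. The genotyper's job is to
# classify these as homozygous-reference.
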