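"""Encode a pangenome-augmented pileup tensor and read off its channels.

Each candidate becomes a (200, 221, 6) tensor: 100 haplotype rows stacked
on 100 read rows, 221 reference columns centered on the candidate, six
channels. The haplotype-block supports-alt fraction at the center column
equals the candidate's panel allele frequency.
"""

import numpy as np

from pancall import PileupConfig, panel_allele_frequency, simulate_biased_scenario
from pancall.pileup import CHANNELS
from pancall.pipeline import build_labelled_examples, discover_bundle_candidates

bundle = simulate_biased_scenario(seed=1, preset="tiny")
candidates = discover_bundle_candidates(bundle)
truth = bundle.truth.alt_counts()
het = next(c for c in candidates if truth.get(c.key) == 1)
ex = build_labelled_examples(bundle, [het])[0]
cfg = PileupConfig()
ch = {name: i for i, name in enumerate(CHANNELS)}

print(f"candidate  : {het.contig}:{het.pos + 1} {het.ref_allele}>{het.alt_allele}")
print(f"tensor     : shape {ex.tensor.shape}, values in "
      f"[{ex.tensor.min():.2f}, {ex.tensor.max():.2f}], label {ex.label} (1 = het)")

hap_rows = ex.tensor[: bundle.panel.haplotype_count]
center = cfg.center
hap_support = hap_rows[:, center, ch["SUPPORTS_ALT"]]
carriers = int((hap_support == 1.0).sum())
paf = panel_allele_frequency(bundle.panel, het.key, bundle.reference)
print(f"\nhaplotype block: {carriers}/{bundle.panel.haplotype_count} rows "
      f"support the alt at the center column")
print(f"panel allele frequency of this alt: {paf.frequency:.3f} "
      "(the two numbers agree by construction)")

read_rows = ex.tensor[100:]
covered = read_rows[:, center, ch["BASE"]] != 0
alt_frac = float(
    (read_rows[covered, center, ch["SUPPORTS_ALT"]] == 1.0).mean()
)
print(f"read block: {int(covered.sum())} reads cover the site, "
      f"alt fraction {alt_frac:.2f} (a het should sit near 0.5)")

blank = [ch["BASE_QUAL"], ch["MAP_QUAL"], ch["STRAND"]]
print("haplotype quality/strand channels are blank:",
      bool(not ex.tensor[:100][:, :, blank].any()))
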