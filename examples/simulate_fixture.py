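"""Generate a synthetic ChIP-seq regulon and write it as flat files.

The simulator plants motif instances in a random genome, lays out CDS
annotations so some promoters contain a planted site, and produces an IP
coverage track with sharp, near-triangular pileups over the sites plus a
featureless control track.
"""

import numpy as np

import sigmascan as sg

cfg = sg.SyntheticRegulonConfig(seed=0)  # 100 kb, 12 sites, 8 genes
genome, truth, ip, control = sg.simulate_regulon(cfg)
paths = sg.write_fixture_bundle(genome, truth, ip, control, "sigmascan_out/fixture")

print(f"genome: {len(genome):,} bp, GC {100 * (genome.count('G') + genome.count('C')) / len(genome):.1f}%")
print(f"planted sites: {truth.n_sites} (consensus {cfg.motif.consensus()})")
flagged = truth.gene_records.has_planted_site_in_promoter.sum()
print(f"genes: {len(truth.gene_records)}, with a site in the promoter: {flagged}")
print(f"IP coverage: median {np.median(ip.values):.0f}, max {ip.values.max():.0f}; "
      f"control max {control.values.max():.0f}")
print("files:", ", ".join(paths))
# The IP maximum sits ~50x above the median background: that contrast is
# what the dual-threshold peak rule exploits.
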