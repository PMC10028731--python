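"""The whole pipeline in one call: simulate -> peaks -> motif -> scan.

run_all chains the stages, writes every intermediate as a flat file under
the output directory, and records counts and checksums in manifest.json.
"""

import json

import sigmascan as sg

cfg = sg.PipelineConfig(output_dir="sigmascan_out/end_to_end", seed=0)
cfg.simulate = sg.SyntheticRegulonConfig(seed=0)

manifest = sg.run_all(cfg)

for stage, info in manifest["stages"].items():
    counts = info.get("counts")
    if counts:
        print(f"{stage}: {json.dumps(counts)}")
print("\noutputs in sigmascan_out/end_to_end/ "
      "(peaks.bed, site_windows.fa, motif.meme, hits_*.tsv, manifest.json)")
# peaks_passing_shape counts the planted sites the peak caller recovered;
# hits_below_q_threshold counts promoters the motif scan flags at q <= 0.6.
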