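"""Run the full synthetic demo pipeline and print the report.

Equivalent to `sagpop run --outdir demo_run --seed 1` with a reduced
replicate count; re-running with the same seed reproduces every output file
bit for bit (the manifest records sha256 digests).
"""

import json

from sagpop.pipeline import PipelineConfig, make_report, run_pipeline

cfg = PipelineConfig(seed=1, rm_seeds=3, error_genome_len=1_000_000)
outdir = run_pipeline(cfg, "demo_run")
report = make_report(outdir)
print(json.dumps(report, indent=2, sort_keys=True))
# rm_separation_orders_of_magnitude >= 2 is the headline contrast between
# the clonal and recombinogenic regimes.
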