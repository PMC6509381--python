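"""Run the whole workflow end to end with one seed.

Equivalent to `coastniche run-all` on the command line: synthesize ->
thin -> screen -> tune -> fit -> evaluate -> GSA -> project -> binarize ->
decompose -> report, with every stage's artifacts written to the output
directory and a manifest that makes the run reproducible.
"""

from pathlib import Path

from coastniche import RunConfig, run_pipeline

config = RunConfig(seed=7, output_dir="scratch/example_run")
manifest, results = run_pipeline(config)

print(f"stages: {', '.join(f'{k} ({v:.1f}s)' for k, v in manifest.stages.items())}")
print()
print(Path(config.output_dir, "summary.txt").read_text())
print(f"artifacts and manifest under {config.output_dir}/")
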