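"""One-call end-to-end run with the stage accounting and written outputs.

Equivalent to the CLI `pathnet run-all`; all results land in
./scratch/example_results as TSV/GMT files.
"""

from pathlib import Path

from pathnet import pipeline, synthetic

paths = synthetic.generate_all(Path("scratch/example_data"), synthetic.STD_V1)
res = pipeline.run_all(
    pipeline.PipelineConfig(
        obo=paths["obo"], gaf=paths["gaf"], gmt=paths["gmt"],
        diseases=paths["diseases"], seed=17,
    ),
    outdir=Path("scratch/example_results"),
)

print("stage accounting (pathways removed at each step):")
for stage, count, detail in res.stage_log:
    print(f"  {stage:30s} {count:4d}  {detail}")
print(f"\nthreshold {res.threshold:.3f}; "
      f"{res.net.graph.number_of_nodes()} nodes / {res.net.n_edges} edges; "
      f"clustering {res.clustering:.3f}")
print("outputs:", sorted(p.name for p in Path("scratch/example_results").iterdir()))
# Re-running with the same seed reproduces every output byte for byte.
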