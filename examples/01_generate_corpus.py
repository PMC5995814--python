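"""Generate the standard synthetic corpus and peek at its shape.

Writes an OBO ontology, GAF annotations, a GMT pathway collection and a
disease gene table (plus ground-truth TSVs) into ./scratch/example_data.
"""

from pathlib import Path

from pathnet import synthetic
from pathnet.curation import load_gmt

out = Path("scratch/example_data")
paths = synthetic.generate_all(out, synthetic.STD_V1)
ps = load_gmt(paths["gmt"])
sizes = sorted(len(p.genes) for p in ps)

print(f"wrote {len(paths)} files to {out}")
print(f"pathways: {len(ps)}, gene universe: {len(ps.gene_universe)}")
print(f"pathway sizes: min {sizes[0]}, median {sizes[len(sizes) // 2]}, max {sizes[-1]}")
# The collection is deliberately redundant and long-tailed, with planted
# duplicates and disease-named pathways for the curation stages to remove.
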