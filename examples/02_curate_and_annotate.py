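"""Curate the pathway collection and build the annotation table.

Shows the three curation stages (duplicate removal, disease-name
filtering, annotation-coverage filtering) with their removal counts, and
the effect of evidence filtering plus ancestor propagation on the
gene -> GO-term table.
"""

from pathlib import Path

from pathnet import annotations as ann
from pathnet import curation, synthetic
from pathnet.ontology import load_obo

paths = synthetic.generate_all(Path("scratch/example_data"), synthetic.STD_V1)

dag = load_obo(paths["obo"])
raw = ann.load_gaf(paths["gaf"])
filtered = ann.filter_evidence(raw)
table = ann.propagate(filtered, dag)
print(f"genes annotated: {len(raw)} raw -> {len(filtered)} after dropping IEA")
mean_before = sum(len(filtered.terms_for(g)) for g in filtered.genes) / len(filtered)
mean_after = sum(len(table.terms_for(g)) for g in table.genes) / len(table)
print(f"mean terms/gene: {mean_before:.1f} direct -> {mean_after:.1f} with ancestors")

ps = curation.load_gmt(paths["gmt"])
ps = curation.deduplicate(ps)
ps = curation.filter_by_name(ps)  # default disease/drug/addiction term lists
ps = curation.filter_annotation_coverage(ps, table, min_annotated=4)
for stage, n, reason in ps.curation_log:
    print(f"  {stage}: removed {n} ({reason})")
print(f"candidate pathway nodes: {len(ps)}")
# Each surviving pathway records its annotated-gene subset, which is the
# query set for the enrichment stage.
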