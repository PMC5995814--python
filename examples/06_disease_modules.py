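"""Mapping disease gene sets onto the network and testing their clustering.

Each disease with >= 4 genes is associated with pathway nodes by one-sided
Fisher tests (raw p < 0.01).  For each disease with >= 2 nodes, the
shortest paths between its nodes are compared to 100 random same-size node
sets with a two-sample KS test: planted diseases should cluster, null
diseases should not.
"""

from pathlib import Path

import pandas as pd

from pathnet import disease, pipeline, synthetic

paths = synthetic.generate_all(Path("scratch/example_data"), synthetic.STD_V1)
res = pipeline.run_all(
    pipeline.PipelineConfig(
        obo=paths["obo"], gaf=paths["gaf"], gmt=paths["gmt"],
        diseases=paths["diseases"],
    )
)

frame = disease.results_frame(res.disease_results)
truth = pd.read_csv(paths["disease_truth"], sep="\t", keep_default_na=False)
frame = frame.merge(truth[["disease", "status"]], on="disease")
print(frame.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

planted = frame[frame.status == "planted"]
print(f"\nplanted diseases with KS p < 0.01: "
      f"{(planted.ks_p < 0.01).sum()}/{len(planted)}")
print("null diseases mapping to >= 2 nodes:", (frame.status == "null").sum())

# name-based system selection, as used for grouping cancers
anns = disease.load_disease_table(paths["diseases"])
cancers = disease.select_by_terms(anns, disease.CANCER_TERMS)
print("cancer-named diseases:", [a.name for a in cancers])
# Shorter observed mean paths than the null mean indicate that a disease's
# pathways sit in one functional neighborhood of the network.
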