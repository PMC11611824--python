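"""Generate the survey-scale synthetic radiation and delineate its taxa.

Builds a dataset of 142 long 16S sequences planted with 6 genera and 90 species
(38 of them represented by a single sequence), runs the full pipeline —
reference screen, conserved-region curation, NJ tree + monophyly filter, 800 bp
length cutoff, 98.7% species clustering, 94.5% genus decomposition — and prints
the recovered structure next to the planted truth.
"""

from cablediv import pipeline
from cablediv import synthetic_data as sd

records, sites, truth, spec = sd.survey_dataset(seed=42)
by_id = {r.id: r for r in records}

result = pipeline.run_pipeline(
    records, sites, pipeline.PipelineConfig(),
    queries=[by_id[q] for q in truth.query_ids],
    outgroup=by_id[truth.outgroup_id],
)

s = result.summary
print(f"input sequences          : {len(records) - 1} (+1 outgroup)")
print(f"planted structure        : {spec.n_genera} genera, "
      f"{spec.n_species} species, {spec.n_singletons} singletons")
print(f"recovered species clades : {s.n_valid_clades}")
print(f"recovered genus clusters : {s.n_genus_clusters}")
print(f"recovered singletons     : {s.n_singletons}")
print(f"min identity inside a cluster  : {s.min_intra_cluster_identity:.2f}%")
print(f"max identity between clusters  : {s.max_inter_cluster_identity:.2f}%")
# The intra minimum sitting well above the inter maximum is what makes the
# 94.5% genus guide workable on this dataset.
for stage, n_in, n_out in result.stage_counts:
    print(f"  stage {stage:<16} {n_in:>4} -> {n_out}")
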