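"""Transcription-factor target enrichment of dose-responsive modules.

The generator plants TF target sets covering half of each module plus
random decoys, written in GMT format. Each dose-significant module is
tested for over-representation of each set (one-sided Fisher exact test
against the analyzed-gene universe) with Benjamini-Hochberg adjustment.
"""

from coexnet import PipelineConfig, SyntheticConfig, generate, run_condition

data = generate(SyntheticConfig(seed=0))
result = run_condition(
    data.expression,
    data.metadata,
    PipelineConfig(condition="estrogen"),
    gene_sets=data.gene_sets,
)

table = result.enrichment
hits = table.loc[table["adj_p"] < 0.01]
print("enriched TF target sets (adjusted p < 0.01):")
print(
    hits[["module", "set_name", "overlap", "set_size", "adj_p"]].to_string(
        index=False, float_format=lambda v: f"{v:.2e}"
    )
)
# Each significant module is enriched for exactly the TF set planted on it
# (set names carry their target module); decoy-only sets stay at p ~ 1.
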