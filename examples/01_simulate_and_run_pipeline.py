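"""Generate a synthetic study and run the full pipeline end-to-end.

Builds a seeded fixture (gene universe with a planted 20-gene causal
pathway, PPI clique, co-expression block and expression peak; 47 normal
+ 90 CNV subjects with a 1-SD planted shift on PCQ3 in carriers), runs
every stage, and prints the gene-count audit trail plus the strongest
circuit-behavior associations.
"""

import tempfile
from pathlib import Path

import pandas as pd

from cnvcircuits import PipelineConfig, run_pipeline
from cnvcircuits.simulate import SimulationDesign, generate_cohort, generate_universe, write_fixture

design = SimulationDesign(rng_seed=42)
universe = generate_universe(design)
cohort = generate_cohort(design, universe.annotation, universe.causal_genes)

workdir = Path(tempfile.mkdtemp(prefix="cnvcircuits_"))
paths = write_fixture(universe, cohort, workdir / "fixture")
report = run_pipeline(
    PipelineConfig(),
    {k: v for k, v in paths.items()},
    workdir / "out",
)

print("Gene counts through the pipeline stages:")
for stage, count in report.stage_counts.items():
    print(f"  {stage:>18}: {count}")
# initial = CNV-derived gene union; post_enrichment = genes in pathways
# significant at alpha=0.001; post_ppi / post_coexpression = survivors of
# the 0.9-confidence interaction and |r|>0.7 co-expression filters.

assoc = pd.read_csv(workdir / "out" / "associations.tsv", sep="\t")
print("\nTop circuit-behavior contrasts (smallest p first):")
cols = ["behavior", "circuit", "n1", "mean1", "n2", "mean2", "p"]
print(assoc.sort_values("p")[cols].head(5).to_string(index=False))
print(
    "\nThe planted effect sits on item "
    f"{design.target_item} in the {design.target_circuit} circuit: carriers "
    "score higher than normal-microarray subjects, so that row should top "
    "the table with p far below 0.05."
)
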