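"""Operating characteristics of the association scan on synthetic cohorts.

Holds the gene universe fixed and resamples cohorts: with no planted
effect the target contrast rejects at the nominal 5% rate; as the
planted shift grows, detection power rises toward 1.  (Small replicate
counts here keep the example quick; the test suite runs the full-size
versions.)
"""

from cnvcircuits.association import compare_groups
from cnvcircuits.simulate import SimulationDesign, generate_cohort, generate_universe

base = SimulationDesign(rng_seed=3)
universe = generate_universe(base)

for delta in (0.0, 0.3, 0.6, 1.0):
    design = SimulationDesign.from_dict({**base.to_dict(), "effect_size_sd": delta})
    hits = 0
    n_rep = 100
    for k in range(n_rep):
        cohort = generate_cohort(design, universe.annotation, universe.causal_genes, seed=k)
        x = [s.pcq[design.target_item] for s in cohort if s.microarray_status == "normal"]
        y = [s.pcq[design.target_item] for s in cohort if s.microarray_status == "cnv"]
        if compare_groups(x, y).p_value <= 0.05:
            hits += 1
    print(f"effect size {delta:.1f} SD -> rejection rate {hits / n_rep:.2f}  ({n_rep} cohorts)")

print("\nAt 0 SD the rate is the type-I error (~0.05) and it climbs with the "
      "planted shift.  This whole-CNV-group contrast is diluted: only half "
      "the CNV subjects carry a causal variant.  The pipeline's per-circuit "
      "contrast compares carriers only, so its power at 1 SD is much higher "
      "(~0.99 in the test suite's full-size run).")
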