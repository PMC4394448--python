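"""Encode proteins and rank features by F-score.

Each protein becomes a vector of 20 amino-acid composition values plus one
binary indicator per functional domain seen in training.  The F-score
measures, per feature, between-class mean separation over within-class
variance; on the strong preset the five planted domains should dominate.
"""

from protint import (
    SamplingConfig,
    assemble,
    build_space,
    sample_negatives,
    synthetic,
)
from protint.pipeline import rank_features

result = synthetic.generate_proteome(synthetic.preset("strong", seed=1))
positives = [result.proteome[a] for a in result.positives]
negatives = sample_negatives(result.proteome, positives, SamplingConfig(seed=1))

space = build_space(positives + negatives)
dataset = assemble(positives, negatives, space, seed=1)
print(f"feature space: 20 amino acids + {len(space.domain_registry)} domains "
      f"= {space.dimension} dimensions")

ranking = rank_features(dataset)
print("\ntop 10 features by F-score:")
print(ranking.head(10).to_string(index=False))
print("\nplanted domains:", ", ".join(result.enriched_domains))
print("dom_* rows are domain-presence indicators, aa_* rows are composition;")
print("high F-score = strong separation between partners and background.")
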