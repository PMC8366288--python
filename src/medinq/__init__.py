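"""medinq: weakly supervised categorization of medical-information inquiries.

The pipeline turns free-text inquiries into sentence-level subcategory
labels in two stages: a heuristic rule engine labels sentences
programmatically from an entity knowledgebase and prioritized relation
rules (weak supervision), and cost-sensitive multi-class classifiers
(one-versus-rest linear models, a weighted-BCE neural head) are trained on
those weak labels. A synthetic corpus generator with ground-truth labels,
class imbalance and transcription noise makes every stage measurable
without proprietary data.
"""

from . import (balancing, classify, evaluate, features, io, knowledgebase,
               preprocessing, resources, rule_engine, synthetic, templates)

__version__ = "0.1.0"

__all__ = [
    "preprocessing", "knowledgebase", "rule_engine", "features",
    "balancing", "classify", "evaluate", "synthetic", "templates",
    "resources", "io", "__version__",
]
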