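"""ClearF: supervised feature scoring via class-wise embedding and reconstruction.

Scores each feature by the difference between its reconstruction error
under a low-dimensional embedding of the whole dataset and the sum of its
reconstruction errors under separate class-wise embeddings — a fast,
discretization-free surrogate for mutual information between feature and
class label, aimed at biomarker ranking in expression-like data.
"""

__version__ = "0.1.0"

from .datasets import (
    CVReport,
    FeatureScoreTable,
    LabeledDataset,
    ReconstructionResult,
    validate_dataset,
)
from .embeddings import (
    EmbeddingSpec,
    ReconstructingEmbedding,
    fit_reconstruct,
    total_squared_error,
)
from .exceptions import ClearFError, IOFormatError, ValidationError
from .io import DatasetFileDialect, read_dataset, write_dataset, write_scores
from .model_selection import (
    SelectionConfig,
    candidate_component_sizes,
    cross_validate,
    select_component_size,
)
from .scoring import ClearF, ScoreConfig, clearf_scores, feature_errors, rank_features
from .simulations import (
    EntropySimResult,
    gaussian_entropy,
    generate_informative,
    generate_two_class_2d,
    simulate_entropy_correlation,
)

__all__ = [
    "ClearF",
    "ClearFError",
    "CVReport",
    "DatasetFileDialect",
    "EmbeddingSpec",
    "EntropySimResult",
    "FeatureScoreTable",
    "IOFormatError",
    "LabeledDataset",
    "ReconstructionResult",
    "ReconstructingEmbedding",
    "ScoreConfig",
    "SelectionConfig",
    "ValidationError",
    "candidate_component_sizes",
    "clearf_scores",
    "cross_validate",
    "feature_errors",
    "fit_reconstruct",
    "gaussian_entropy",
    "generate_informative",
    "generate_two_class_2d",
    "rank_features",
    "read_dataset",
    "select_component_size",
    "simulate_entropy_correlation",
    "total_squared_error",
    "validate_dataset",
    "write_dataset",
    "write_scores",
]
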