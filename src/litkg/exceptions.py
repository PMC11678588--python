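"""Exception hierarchy shared across the package."""


class LitKGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LitKGError):
    """Invalid generator or pipeline configuration; message names the field."""


class ParseError(LitKGError):
    """Malformed table row; message carries the file and line number."""


class IntegrityError(LitKGError):
    """Referential-integrity violation in a knowledge graph."""


class NodeNotFoundError(LitKGError, KeyError):
    """Lookup of a concept identifier that is not in the graph."""


class VocabularyError(LitKGError, KeyError):
    """Lookup of a node type or relation outside the declared vocabulary."""


class SignatureError(LitKGError):
    """A metapath signature inconsistent with the graph's vocabulary or endpoints."""


class ConsistencyError(LitKGError):
    """Summary counts that cannot arise from any triple of sets; names the region."""


class ClassificationError(LitKGError):
    """Evidence classification requested for a node outside the search horizon."""


class EvaluationError(LitKGError):
    """Invalid input to metric evaluation (empty input, missing truth labels)."""
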