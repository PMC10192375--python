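"""Exception hierarchy for tcrscreen."""


class TcrScreenError(Exception):
    """Base class for all package errors."""


class GermlineError(TcrScreenError):
    """Problems loading or validating a germline segment database."""


class SimulationError(TcrScreenError):
    """Repertoire or read simulation failed (e.g. retry budget exhausted)."""


class AnnotationError(TcrScreenError):
    """Invalid input to the V(D)J annotation machinery."""


class ClonotypeError(TcrScreenError):
    """Inconsistent input to pairing/clustering (e.g. duplicate read ids)."""


class DesignError(TcrScreenError):
    """Construct-design failure (duplicate restriction sites, broken ORF...)."""


class ConfigError(TcrScreenError):
    """Invalid pipeline configuration (unknown keys, bad values, barcode clashes)."""
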