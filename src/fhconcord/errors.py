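"""Exception hierarchy.

Configuration problems (bad panel files, malformed rulesets) and data
problems (unparseable inputs, broken joins) are kept distinct so the CLI
can map them to different exit codes.
"""


class FhconcordError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FhconcordError):
    """A configuration input (panel, ruleset, simulation config) is invalid."""


class DataError(FhconcordError):
    """A data input (VCF, annotation table, pedigree) is invalid."""


class VocabularyError(DataError):
    """A value falls outside a closed controlled vocabulary."""


class StructureError(DataError):
    """A pedigree violates structural constraints (e.g. two fathers)."""


class JoinError(DataError):
    """Annotation rows and VCF records do not join one-to-one."""


class ScopingError(DataError):
    """A record references a gene that is not resolvable in the loaded panel."""
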