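"""Exception hierarchy used across the package."""


class PhyloconvError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(PhyloconvError):
    """Sequences of unequal length, or a file that is not a valid alignment."""


class DuplicateTaxonError(PhyloconvError):
    """The same taxon label occurs more than once."""


class AlphabetError(PhyloconvError):
    """A symbol outside the declared alphabet (position is named in the message)."""


class MissingTaxonError(PhyloconvError):
    """A requested taxon is absent from an alignment or site set."""


class TreeError(PhyloconvError):
    """Malformed Newick, duplicate leaves, leaf-set mismatches, or an
    impossible topology construction."""


class ModelError(PhyloconvError):
    """Invalid substitution-model parameters."""


class LikelihoodError(PhyloconvError):
    """Non-finite likelihood or data/tree inconsistency during a fit."""


class ConfigError(PhyloconvError):
    """Pipeline configuration file violates the schema."""
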