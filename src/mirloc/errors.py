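"""Exception hierarchy.

Exit-code classes used by the command line interface:
usage errors -> 2, data errors -> 3, folding-engine errors -> 4.
"""


class MirlocError(Exception):
    """Base class for all package errors."""


# --- data errors (exit 3) -------------------------------------------------

class DataError(MirlocError):
    """Malformed or inconsistent input data."""


class UnbalancedStructure(DataError):
    """Dot-bracket string with a surplus of '(' or ')'."""


class InvalidProbability(DataError):
    """Base-pair probability outside [0,1] or a row summing above 1."""


class InvalidCharacter(DataError):
    """Sequence contains a character outside the ACGTUN alphabet."""


class DuplicateId(DataError):
    """Two FASTA records share an identifier."""


class MultiBranchStructure(DataError):
    """Secondary structure has more than one terminal loop (not a hairpin)."""


class NoPairedBases(DataError):
    """Guide interval contains no paired position; no duplex exists."""


class EmptyPositiveSet(DataError):
    """No annotation survived duplex derivation."""


class TooFewSamples(DataError):
    """Dataset too small for the requested fold count."""


class SingleClassDataset(DataError):
    """Training or scoring requires both class labels."""


class MissingTruth(DataError):
    """A prediction has no matching truth annotation."""


class InvalidParams(DataError):
    """Generator or run parameters outside their documented bounds."""


class EmptyGrid(DataError):
    """No candidate produced a valid duplex; nothing to locate."""


class NoPrediction(DataError):
    """Prediction failed for one pre-miRNA; carries a reason string."""


# --- model artifact errors (exit 3) ---------------------------------------

class UnknownAlgorithm(DataError):
    """Classifier name outside {rf, svm, nb, knn, dt}."""


class UnsupportedAlgorithm(DataError):
    """Operation undefined for this classifier (e.g. Gini on kNN)."""


class CorruptModelFile(DataError):
    """Model file unreadable or missing its header."""


class SchemaMismatch(DataError):
    """Feature schema version of the model differs from the featurizer."""


# --- engine errors (exit 4) ------------------------------------------------

class EngineError(MirlocError):
    """Folding-engine failures."""


class EngineUnavailable(EngineError):
    """No folding engine configured and no precomputed structure supplied."""
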