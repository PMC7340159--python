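"""Exception and warning types shared across the pipeline."""


class DtcPrsError(Exception):
    """Base class for all dtcprs errors."""


class UnrecognizedFormat(DtcPrsError):
    """No vendor dialect matches the input stream (the hard-failure path)."""


class EmptyProfile(DtcPrsError):
    """A genotype file parsed to zero valid variant calls."""


class UnharmonizedProfile(DtcPrsError):
    """An operation requiring allele alignment received a raw profile."""


class DegenerateInput(DtcPrsError):
    """Statistical input on which the requested quantity is undefined."""


class ZeroVariancePanel(DtcPrsError):
    """A weight panel (or reference score set) with zero score variance."""


class InsufficientReference(DtcPrsError):
    """Too few reference scores for empirical normalization."""


class UnknownPopulation(DtcPrsError):
    """A super-population label with no frequency entry."""


class IncompletePanel(DtcPrsError):
    """Panel SNPs missing from the profile under the FAIL policy."""


class InsufficientSites(DtcPrsError):
    """Too few informative sites for ancestry assignment."""


class EmptyMask(DtcPrsError):
    """A vendor mask that covers none of the panel."""


class MissingChromosomeWarning(UserWarning):
    """An autosome (1-22) is entirely absent from a parsed profile."""


class SeparationWarning(UserWarning):
    """Logistic fit drifted toward complete separation (|coef| > 50)."""


class EmptyOverlapWarning(UserWarning):
    """Every panel SNP was missing; the returned score is a placeholder 0."""
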