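"""Exception hierarchy for study design and estimation errors."""


class PairedsseError(Exception):
    """Base class for all package errors."""


class InputError(PairedsseError, ValueError):
    """Malformed or invalid user input (files, counts, parameters)."""


class DegenerateDataError(PairedsseError, ValueError):
    """A disease stratum is empty, so stratum rates are undefined."""


class NoDataError(PairedsseError, ValueError):
    """A computation was requested on an all-zero table."""


class UndefinedEffectError(PairedsseError, ValueError):
    """The hypothesised rate ratio equals 1, so log(gamma) = 0 and the
    sample-size formula is undefined."""


class OrientationError(PairedsseError, ValueError):
    """Test A must be the hypothesised-better test (marginal_a >= marginal_b);
    the caller supplied them swapped."""


class InfeasibleError(PairedsseError, ValueError):
    """A joint probability lies outside the interval permitted by the
    hypothesised marginals."""
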