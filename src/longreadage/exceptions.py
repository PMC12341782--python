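"""Exception hierarchy for longreadage.

All domain errors derive from :class:`LongReadAgeError` so callers (and the
CLI) can distinguish scientific/validation failures from programming errors.
"""


class LongReadAgeError(Exception):
    """Base class for all longreadage domain errors."""


class NoFittableSitesError(LongReadAgeError):
    """The reference dataset contains no site with enough complete,
    non-constant (age, beta) pairs to fit a regression."""


class ConstantAgesError(LongReadAgeError):
    """All reference ages are identical; age correlation is undefined."""


class NoSharedSitesError(LongReadAgeError):
    """A profile (or candidate set) shares no CpG site with the model/atlas."""


class InsufficientSitesError(LongReadAgeError):
    """Fewer usable CpG sites than the configured minimum.

    Carries the observed and required counts so pipelines can report
    attrition precisely.
    """

    def __init__(self, n_usable: int, min_sites: int):
        self.n_usable = n_usable
        self.min_sites = min_sites
        super().__init__(
            f"insufficient intersecting sites: {n_usable} usable, "
            f"{min_sites} required"
        )


class NoMarkersError(LongReadAgeError):
    """No CpG site survived the differential-methylation filters.

    ``diagnostics`` maps filter name -> number of sites passing that filter
    individually, to aid threshold debugging.
    """

    def __init__(self, diagnostics: dict):
        self.diagnostics = dict(diagnostics)
        detail = ", ".join(f"{k}={v}" for k, v in self.diagnostics.items())
        super().__init__(f"no marker CpGs passed all filters ({detail})")


class NoEligibleFragmentsError(LongReadAgeError):
    """Every fragment was filtered out before cell-type assignment."""


class InputFormatError(LongReadAgeError):
    """A text input file failed validation; names file/line where possible."""
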