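"""Exception hierarchy shared across the package."""


class LGQuantError(Exception):
    """Base class for all lgquant errors."""


class FormatError(LGQuantError):
    """An input file could not be interpreted (bad axes, wrong channel count...)."""


class ValidationError(LGQuantError):
    """A domain object or configuration violates its invariants."""


class DegenerateDataError(LGQuantError):
    """Input is valid but the requested quantity is undefined on it
    (constant image under Otsu, zero-variance channel for Pearson, ...)."""


class PackingError(LGQuantError):
    """Requested nuclei cannot be placed at the requested separation."""


class MeasurementError(LGQuantError):
    """A per-nucleus measurement could not be taken (e.g. empty search sphere)."""
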