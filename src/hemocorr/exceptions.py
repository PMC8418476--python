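"""Exception types shared across hemocorr modules."""


class HemocorrError(Exception):
    """Base class for all hemocorr errors."""


class InvalidSpectrumError(HemocorrError, ValueError):
    """Absorbance pair is physically implausible (A600 exceeds A570 beyond noise)."""


class BelowQuantificationError(HemocorrError, ValueError):
    """Hemolysis index below the instrument's quantification range."""


class AssayRangeError(HemocorrError, ValueError):
    """A measurement falls outside the assay's measurable range."""


class DegenerateDesignError(HemocorrError, ValueError):
    """Regression design has no usable spread (all x identical or too few points)."""


class ValidationError(HemocorrError, ValueError):
    """Malformed tabular input (bad header, unparseable row)."""
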