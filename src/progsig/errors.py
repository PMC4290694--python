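"""Exception hierarchy for progsig."""


class ProgsigError(Exception):
    """Base class for all progsig errors."""


class FormatError(ProgsigError):
    """A file could not be parsed (wrong shape, non-numeric cell, bad token)."""


class AlignmentError(ProgsigError):
    """Expression / phenotype / network could not be aligned to a usable dataset."""


class ConfigError(ProgsigError):
    """A run configuration is invalid.

    ``violations`` lists every problem found so users can fix them in one pass.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations))
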