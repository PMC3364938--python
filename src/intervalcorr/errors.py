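"""Control-flow signals shared across the test modules."""


class SkipScope(Exception):
    """A scope (chromosome or genome) cannot be tested; carries the reason.

    Raised when preconditions of a test are unmet (e.g. no query points on
    the chromosome, or too few reference points to define flanking gaps).
    The orchestrator records the reason in the report instead of failing.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
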