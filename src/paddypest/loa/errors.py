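class EvaluationError(RuntimeError):
    """Raised when the objective returns a non-finite value.

    Carries the offending point so the caller can reproduce the failure.
    """

    def __init__(self, point, value):
        self.point = point
        self.value = value
        super().__init__(
            f"objective returned non-finite value {value!r} at point {point!r}"
        )
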