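class EstimationError(RuntimeError):
    """A model fit failed (non-convergence, separation, singular information)."""
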