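"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a model or acquisition-scheme invariant.

    The message names the offending field.
    """


class FitError(RuntimeError):
    """A voxel- or cohort-level fit cannot be carried out at all.

    Per-voxel non-convergence is *not* an error — it is recorded in the
    validity mask; this exception is reserved for structural problems
    (empty ROI, degenerate design, single-class labels, ...).
    """
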