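"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing column,
    malformed header, non-numeric field, ...)."""


class IntegrityError(ValueError):
    """Inputs are syntactically valid but mutually inconsistent
    (duplicate spot positions, layout mismatches, missing spots, ...)."""
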