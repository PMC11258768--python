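"""Exception types shared across the package."""


class StructureFormatError(ValueError):
    """A coordinate file could not be parsed under the requested format."""


class EmptyModelError(ValueError):
    """The selected chain contains no residue with a C-alpha atom."""


class IntegrityError(ValueError):
    """Input data violates an internal consistency requirement."""


class MappingError(ValueError):
    """Transcript and structure model disagree and cannot be aligned."""
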