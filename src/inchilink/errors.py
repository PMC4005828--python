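"""Exception hierarchy shared by all inchilink modules."""


class InChIError(ValueError):
    """Base class for identifier-level problems."""


class InChIFormatError(InChIError):
    """The identifier text violates the layer/sub-layer syntax."""


class InChIStructureError(InChIError):
    """The identifier parses but its parts are mutually inconsistent
    (e.g. a per-component sub-layer with the wrong number of slots)."""


class NotComparableError(InChIError):
    """The identifier carries layers the comparison relation refuses to
    interpret (reconnected layer, other opaque layers, or a fixed-hydrogen
    layer outside plain equality checks)."""


class AdapterUnavailableError(RuntimeError):
    """The external InChI generator executable is not installed/configured."""


class AdapterConversionError(RuntimeError):
    """The external InChI generator rejected a structure file."""


class FixtureError(ValueError):
    """A fixture operation was requested on an input it does not apply to."""
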