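"""Exception hierarchy shared across the package."""


class HistoquantError(Exception):
    """Base class for package errors."""


class FormatError(HistoquantError, ValueError):
    """A file or payload does not follow the expected dialect."""


class StructureError(HistoquantError, ValueError):
    """A data structure violates its invariants (e.g. ontology cycles)."""


class GeometryError(HistoquantError, ValueError):
    """Degenerate or invalid geometric input (e.g. parallel plane vectors)."""
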