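"""Exception types shared across the audit pipeline."""


class FormatError(ValueError):
    """An input file does not conform to the expected tabular/FASTA layout."""


class CatalogueError(ValueError):
    """The taxonomic checklist violates a catalogue invariant."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent
    (e.g. a record country absent from the catalogue's region map)."""
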