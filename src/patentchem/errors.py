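"""Structured exceptions shared across the pipeline."""


class PatentChemError(Exception):
    """Base class for all package errors."""


class ScpnParseError(PatentChemError):
    """A patent identifier failed the SCPN grammar.

    Attributes
    ----------
    component : str
        Which part of the identifier failed: ``"country"``, ``"serial"``,
        ``"kind"`` or ``"format"``.
    """

    def __init__(self, scpn: str, component: str, message: str):
        self.scpn = scpn
        self.component = component
        super().__init__(f"invalid SCPN {scpn!r}: {message} (component: {component})")


class SmilesParseError(PatentChemError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        suffix = f" [{context}]" if context else ""
        super().__init__(f"unparsable SMILES {smiles!r}{suffix}")


class DesaltError(PatentChemError):
    """Desalting failed, e.g. no organic fragment present."""


class DescriptorError(PatentChemError):
    """A descriptor backend failed for a given molecule."""

    def __init__(self, descriptor: str, smiles: str, message: str):
        self.descriptor = descriptor
        super().__init__(f"descriptor {descriptor!r} failed for {smiles!r}: {message}")


class CatalogError(PatentChemError):
    """An alert catalog could not be loaded or compiled."""


class IngestError(PatentChemError):
    """Fatal problem reading a map dump (missing file / column)."""


class GeneratorError(PatentChemError):
    """The synthetic corpus generator could not satisfy its constraints."""
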