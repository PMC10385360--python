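"""Exception hierarchy shared across the package."""


class CamoilError(Exception):
    """Base class for all package errors."""


class RegistryError(CamoilError, KeyError):
    """Unknown fatty-acid species or enzyme name."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class QuantificationError(CamoilError, ValueError):
    """Invalid GC-FID quantification input (e.g. zero internal-standard area)."""


class FormatError(CamoilError, ValueError):
    """Malformed tabular input (missing columns, duplicate keys)."""


class InsufficientDataError(CamoilError, ValueError):
    """Too few timepoints / replicates / series for the requested statistic."""
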