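"""Variable registry: every gridded quantity the pipeline touches.

``kind`` drives two behaviours downstream:

* ``flux``      — regridded conservatively, regionally *integrated*
                  (sums to PgC totals);
* ``intensive`` — regridded bilinearly, regionally *averaged*.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VariableInfo:
    name: str
    kind: str  # "flux" | "intensive"
    default_units: str
    long_name: str


VARIABLES: dict[str, VariableInfo] = {
    v.name: v
    for v in [
        VariableInfo("NBP", "flux", "PgC month-1 cell-1", "net biome productivity"),
        VariableInfo("GPP", "flux", "PgC month-1 cell-1", "gross primary productivity"),
        VariableInfo("RECO", "flux", "PgC month-1 cell-1", "total ecosystem respiration"),
        VariableInfo("Z500", "intensive", "gpm", "500-mb geopotential height"),
        VariableInfo("SLP", "intensive", "mb", "sea-level pressure"),
        VariableInfo("T2M", "intensive", "degC", "2-m air temperature"),
        VariableInfo("SW", "intensive", "% volume", "volumetric soil water content"),
        VariableInfo("SD", "intensive", "cm", "snow depth"),
        VariableInfo("CLOUD", "intensive", "%", "cloud cover fraction"),
        VariableInfo("HT", "intensive", "MW km-1", "vertical integral of eastward heat transport"),
        VariableInfo("VT", "intensive", "g km-1 s-1", "vertical integral of eastward water-vapour transport"),
        VariableInfo("PDSI", "intensive", "1", "Palmer drought severity index"),
    ]
}

#: NDVI lives on a biweekly cadence and is handled by BiweeklyFieldStack only.
NDVI = VariableInfo("NDVI", "intensive", "1", "normalized difference vegetation index")


def require_variable(name: str) -> VariableInfo:
    try:
        return VARIABLES[name]
    except KeyError:
        raise KeyError(
            f"unregistered variable {name!r}; known: {sorted(VARIABLES)}"
        ) from None


def is_flux(name: str) -> bool:
    return require_variable(name).kind == "flux"
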