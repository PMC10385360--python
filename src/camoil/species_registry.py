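"""Registry of the ten seed-oil fatty acids and the biosynthesis-pathway topology.

Camellia seed oil (triacylglycerol) is built from ten fatty-acid species,
from palmitic acid (16:0) to paullinic acid (20:1d13).  This module stores
their chemical metadata (chain length, double bonds, molecular weight,
saturation class, biosynthetic route) and the mapping from the six core
biosynthetic enzymes (KASII, FatB, SAD, FAD2, FAD3, FAE) to the set of
fatty-acid product pools each one feeds.  Downstream modules use the pools
to turn week-over-week pool-content changes into relative enzyme-activity
proxies.

Pathway topology
----------------
Plastidial KAS II elongates 16C to 18C acyl-ACP, so every 18C and 20C
species except the ER-elongase products 18:1d11 and 20:1d13 passes through
it.  SAD desaturates 18:0 to 18:1d9; FAD2 and FAD3 desaturate further to
18:2 and 18:3 in the ER; FatB releases 16:0; the ER elongase complex (FAE)
produces 18:1d11 and 20:1d13.  The pools therefore nest:
FAD3 < FAD2 < SAD < KASII.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, RegistryError

__all__ = [
    "FattyAcidSpecies",
    "SpeciesRegistry",
    "DEFAULT_REGISTRY",
    "ENZYMES",
    "normalize_name",
    "get_species",
    "get_pool",
    "classify_species",
]

SAT_CLASSES = ("SFA", "MUFA", "PUFA")
ROUTES = ("KASII_POOL", "FAE_POOL", "FATB_PRODUCT")
ENZYMES = ("KASII", "FatB", "SAD", "FAD2", "FAD3", "FAE")


@dataclass(frozen=True)
class FattyAcidSpecies:
    """Immutable chemical metadata for one fatty-acid species.

    ``mw`` is the molecular weight of the free fatty acid in g/mol (used for
    the mole-percent transform); ``route`` tags the biosynthetic branch the
    species belongs to.
    """

    name: str
    carbons: int
    double_bonds: int
    db_positions: tuple[int, ...]
    mw: float
    route: str

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if len(self.db_positions) != self.double_bonds:
            raise ValueError("db_positions length must equal double_bonds")

    @property
    def sat_class(self) -> str:
        """SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
        if self.double_bonds == 0:
            return "SFA"
        if self.double_bonds == 1:
            return "MUFA"
        return "PUFA"

    @property
    def chain_class(self) -> str:
        return f"C{self.carbons}"


# Free-fatty-acid molecular weights, g/mol.
_DEFAULT_SPECIES = (
    FattyAcidSpecies("16:0", 16, 0, (), 256.43, "FATB_PRODUCT"),
    FattyAcidSpecies("16:1d9", 16, 1, (9,), 254.41, "FAE_POOL"),
    FattyAcidSpecies("16:1d11", 16, 1, (11,), 254.41, "FAE_POOL"),
    FattyAcidSpecies("18:0", 18, 0, (), 284.48, "KASII_POOL"),
    FattyAcidSpecies("18:1d9", 18, 1, (9,), 282.47, "KASII_POOL"),
    FattyAcidSpecies("18:1d11", 18, 1, (11,), 282.47, "FAE_POOL"),
    FattyAcidSpecies("18:2", 18, 2, (9, 12), 280.45, "KASII_POOL"),
    FattyAcidSpecies("18:3", 18, 3, (9, 12, 15), 278.44, "KASII_POOL"),
    FattyAcidSpecies("20:0", 20, 0, (), 312.54, "KASII_POOL"),
    FattyAcidSpecies("20:1d13", 20, 1, (13,), 310.52, "FAE_POOL"),
)

# Enzyme -> downstream product pool.  KASII covers all 18C/20C species except
# the ER-elongase products; 20:0 is kept in the KASII pool (its 18:0
# precursor passes through KASII even though the final elongation is
# ER-associated).
_ENZYME_POOLS: dict[str, frozenset[str]] = {
    "KASII": frozenset({"18:0", "18:1d9", "18:2", "18:3", "20:0"}),
    "FatB": frozenset({"16:0"}),
    "SAD": frozenset({"18:1d9", "18:2", "18:3"}),
    "FAD2": frozenset({"18:2", "18:3"}),
    "FAD3": frozenset({"18:3"}),
    "FAE": frozenset({"18:1d11", "20:1d13"}),
}

_NAME_RE = re.compile(
    r"^C?(?P<carbons>\d{2}):(?P<db>\d)(?P<rest>.*)$",
)


def normalize_name(name: str) -> str:
    """Normalize a fatty-acid label to the canonical ``"18:1d9"`` form.

    Accepts common variants: delta notation ("18:1Δ9", "18:1^Δ9^"),
    a leading "C" ("C16:0"), omega notation ("C18:1n-9"), and comma-separated
    positions ("18:3Δ9,12,15" -> "18:3").  Polyunsaturated species collapse
    to the bare "carbons:db" label; monounsaturated species keep an explicit
    "d<position>" suffix.
    """
    s = name.strip().replace("^", "").replace("Δ", "d").replace("δ", "d")
    m = _NAME_RE.match(s)
    if not m:
        raise RegistryError(f"cannot parse fatty-acid name {name!r}")
    carbons = int(m.group("carbons"))
    db = int(m.group("db"))
    rest = m.group("rest").strip().lower()
    if db == 0 or db >= 2:
        return f"{carbons}:{db}"
    # one double bond: determine its position
    if not rest:
        # bare "16:1"/"18:1"/"20:1": default to the common delta-9 isomer,
        # except 20:1 where the registry species is the delta-13 isomer
        pos = 13 if carbons == 20 else 9
    elif rest.startswith("d"):
        pos = int(rest[1:].split(",")[0])
    elif rest.startswith(("n-", "n", "w", "ω")):
        omega = int(re.sub(r"[^0-9]", "", rest))
        pos = carbons - omega
    else:
        raise RegistryError(f"cannot parse fatty-acid name {name!r}")
    return f"{carbons}:{db}d{pos}"


class SpeciesRegistry:
    """Lookup table of fatty-acid species plus the enzyme->pool topology."""

    def __init__(
        self,
        species: Iterable[FattyAcidSpecies] = _DEFAULT_SPECIES,
        pools: Mapping[str, frozenset[str]] = _ENZYME_POOLS,
    ) -> None:
        self._species = {sp.name: sp for sp in species}
        self._pools = {e: frozenset(p) for e, p in pools.items()}
        for enzyme, pool in self._pools.items():
            missing = pool - self._species.keys()
            if missing:
                raise ValueError(f"{enzyme} pool references unknown species {missing}")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self._species)

    @property
    def enzymes(self) -> tuple[str, ...]:
        return tuple(self._pools)

    def __contains__(self, name: str) -> bool:
        try:
            return normalize_name(name) in self._species
        except RegistryError:
            return False

    def get_species(self, name: str) -> FattyAcidSpecies:
        key = normalize_name(name)
        try:
            return self._species[key]
        except KeyError:
            raise RegistryError(f"unknown fatty-acid species {name!r}") from None

    def get_pool(self, enzyme: str) -> frozenset[str]:
        """Product pool of one of the six registered enzymes (immutable)."""
        try:
            return self._pools[enzyme]
        except KeyError:
            raise RegistryError(f"unknown enzyme {enzyme!r}") from None

    def classify_species(self, name: str) -> tuple[str, str]:
        """Return ``(sat_class, chain_class)``, e.g. ``("MUFA", "C18")``."""
        sp = self.get_species(name)
        return sp.sat_class, sp.chain_class

    def mw(self, name: str) -> float:
        return self.get_species(name).mw

    # -- TSV serialization ---------------------------------------------------

    def to_tsv(self, path: str | Path | None = None) -> str | None:
        rows = [
            {
                "name": sp.name,
                "carbons": sp.carbons,
                "double_bonds": sp.double_bonds,
                "db_positions": ",".join(map(str, sp.db_positions)),
                "mw": sp.mw,
                "sat_class": sp.sat_class,
                "route": sp.route,
            }
            for sp in self._species.values()
        ]
        df = pd.DataFrame(rows)
        if path is None:
            return df.to_csv(sep="\t", index=False)
        df.to_csv(path, sep="\t", index=False)
        return None

    @classmethod
    def from_tsv(cls, source: str | Path) -> "SpeciesRegistry":
        if isinstance(source, str) and "\t" in source:
            df = pd.read_csv(StringIO(source), sep="\t")
        else:
            df = pd.read_csv(source, sep="\t")
        required = {"name", "carbons", "double_bonds", "mw", "route"}
        if not required.issubset(df.columns):
            raise FormatError(f"registry TSV missing columns {required - set(df.columns)}")
        species = []
        for row in df.itertuples():
            pos_field = getattr(row, "db_positions", "")
            positions = (
                tuple(int(x) for x in str(pos_field).split(",") if x.strip())
                if pd.notna(pos_field)
                else ()
            )
            species.append(
                FattyAcidSpecies(
                    name=row.name,
                    carbons=int(row.carbons),
                    double_bonds=int(row.double_bonds),
                    db_positions=positions,
                    mw=float(row.mw),
                    route=row.route,
                )
            )
        return cls(species)


DEFAULT_REGISTRY = SpeciesRegistry()


def get_species(name: str) -> FattyAcidSpecies:
    return DEFAULT_REGISTRY.get_species(name)


def get_pool(enzyme: str) -> frozenset[str]:
    return DEFAULT_REGISTRY.get_pool(enzyme)


def classify_species(name: str) -> tuple[str, str]:
    return DEFAULT_REGISTRY.classify_species(name)
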