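"""Internal-standard FAME quantification and fatty-acid composition.

Seed kernels are transmethylated in the presence of a known mass of
margaric acid (17:0, default 75 ug) and the resulting fatty-acid methyl
esters (FAMEs) are separated by GC and detected by FID.  Because FID
response is close to proportional to analyte mass, the mass of species *i*
is recovered from its peak area by normalizing to the internal standard:

    mass_i [ug] = is_mass_ug * (area_i / is_area) * rf_i

with per-species response factors ``rf_i`` defaulting to 1.  Content is
expressed as percent of kernel dry mass, total oil as the sum over species,
and composition as mole percent using free-fatty-acid molecular weights.

The module also computes the three composition ratios tracked during seed
desiccation (USFA/SFA, MUFA/PUFA, 18C/16C, all on a mole basis) and reads /
writes long-format time-course tables (cultivar x week x replicate x
species, % dry mass).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, QuantificationError
from .species_registry import DEFAULT_REGISTRY, SpeciesRegistry, normalize_name

__all__ = [
    "PeakTable",
    "FAProfile",
    "FATimeCourse",
    "CompositionRatios",
    "quantify",
    "composition_ratios",
    "read_timecourse",
    "read_timecourses",
    "write_timecourse",
    "write_profile",
]

TIMECOURSE_COLUMNS = ("cultivar", "week", "replicate", "species", "content_pct")


@dataclass(frozen=True)
class PeakTable:
    """One sample's GC-FID peak areas plus internal-standard bookkeeping."""

    sample_id: str
    kernel_mass_mg: float
    is_area: float
    peaks: Mapping[str, float]
    is_mass_ug: float = 75.0

    def __post_init__(self) -> None:
        if self.kernel_mass_mg <= 0:
            raise QuantificationError("kernel_mass_mg must be positive")
        if self.is_area <= 0:
            raise QuantificationError("internal-standard area must be positive")
        if self.is_mass_ug <= 0:
            raise QuantificationError("internal-standard mass must be positive")
        if any(a < 0 for a in self.peaks.values()):
            raise QuantificationError("peak areas must be non-negative")


@dataclass(frozen=True)
class FAProfile:
    """Quantified fatty-acid profile of one sample.

    ``content`` maps species -> % of kernel dry mass; ``mol_pct`` maps
    species -> mole percent of total fatty acids (sums to 100, or is empty
    for an all-zero sample).
    """

    sample_id: str
    content: dict[str, float]
    total_oil: float
    mol_pct: dict[str, float]

    def __post_init__(self) -> None:
        tot = sum(self.content.values())
        if not math.isclose(self.total_oil, tot, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("total_oil must equal the sum of contents")
        if self.mol_pct and not math.isclose(sum(self.mol_pct.values()), 100.0, abs_tol=1e-9):
            raise ValueError("mol_pct must sum to 100")


@dataclass(frozen=True)
class CompositionRatios:
    usfa_sfa: float
    mufa_pufa: float
    c18_c16: float


def quantify(
    peaks: PeakTable,
    response_factors: Mapping[str, float] | None = None,
    registry: SpeciesRegistry = DEFAULT_REGISTRY,
    fame_correction: float = 1.0,
) -> FAProfile:
    """Convert one peak table into contents (% dry mass) and mole percent.

    ``fame_correction`` multiplies every recovered mass and accommodates a
    FAME-to-free-acid mass conversion if the caller wants one; the default
    1.0 reports contents on the as-measured FAME-equivalent scale.
    """
    rf = dict(response_factors or {})
    content: dict[str, float] = {}
    moles: dict[str, float] = {}
    for raw_name, area in peaks.peaks.items():
        name = normalize_name(raw_name)
        sp = registry.get_species(name)  # raises RegistryError on unknowns
        mass_ug = peaks.is_mass_ug * (area / peaks.is_area) * rf.get(name, 1.0)
        mass_ug *= fame_correction
        content[name] = mass_ug / (peaks.kernel_mass_mg * 1000.0) * 100.0
        moles[name] = mass_ug / sp.mw
    total_oil = sum(content.values())
    total_moles = sum(moles.values())
    if total_moles > 0:
        mol_pct = {k: v / total_moles * 100.0 for k, v in moles.items()}
    else:
        mol_pct = {}
        warnings.warn(
            f"sample {peaks.sample_id!r}: no nonzero peaks, mole percent undefined",
            stacklevel=2,
        )
    return FAProfile(peaks.sample_id, content, total_oil, mol_pct)


def composition_ratios(
    profile: FAProfile, registry: SpeciesRegistry = DEFAULT_REGISTRY
) -> CompositionRatios:
    """USFA/SFA, MUFA/PUFA and 18C/16C ratios on the mole-percent basis.

    A zero denominator class yields ``inf`` with a warning rather than an
    error, so a degenerate profile still produces a report.
    """
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0, "C16": 0.0, "C18": 0.0, "C20": 0.0}
    for name, pct in profile.mol_pct.items():
        sat, chain = registry.classify_species(name)
        sums[sat] += pct
        sums[chain] += pct

    def _ratio(num: float, den: float, label: str) -> float:
        if den == 0:
            if num == 0:
                return 0.0
            warnings.warn(f"zero {label} denominator; ratio reported as inf", stacklevel=3)
            return math.inf
        return num / den

    return CompositionRatios(
        usfa_sfa=_ratio(sums["MUFA"] + sums["PUFA"], sums["SFA"], "SFA"),
        mufa_pufa=_ratio(sums["MUFA"], sums["PUFA"], "PUFA"),
        c18_c16=_ratio(sums["C18"], sums["C16"], "C16"),
    )


class FATimeCourse:
    """Weekly fatty-acid contents for one cultivar (long-format backing table).

    Rows are (week, replicate, species) -> content in % dry mass.  Weeks are
    weeks after anthesis and must be strictly increasing; every
    (week, replicate) cell carries the same species set.
    """

    def __init__(self, cultivar: str, data: pd.DataFrame) -> None:
        required = {"week", "replicate", "species", "content_pct"}
        if not required.issubset(data.columns):
            raise FormatError(f"time course missing columns {required - set(data.columns)}")
        if data.duplicated(["week", "replicate", "species"]).any():
            raise FormatError("duplicate (week, replicate, species) keys")
        species_per_cell = data.groupby(["week", "replicate"])["species"].apply(frozenset)
        if species_per_cell.nunique() > 1:
            raise FormatError("every (week, replicate) cell must cover the same species set")
        self.cultivar = cultivar
        self.data = data.sort_values(["week", "replicate", "species"]).reset_index(drop=True)

    @property
    def weeks(self) -> list[int]:
        return sorted(self.data["week"].unique().tolist())

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique().tolist())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())

    def replicate_means(self) -> pd.DataFrame:
        """Week x species matrix of replicate-mean contents (% dry mass)."""
        return (
            self.data.pivot_table(
                index="week", columns="species", values="content_pct", aggfunc="mean"
            )
            .sort_index()
        )

    def replicate_sds(self) -> pd.DataFrame:
        """Week x species matrix of replicate SDs (ddof=1, n-1 denominator)."""
        return (
            self.data.pivot_table(
                index="week",
                columns="species",
                values="content_pct",
                aggfunc=lambda x: x.std(ddof=1),
            )
            .sort_index()
        )

    def total_oil(self) -> pd.Series:
        """Replicate-mean total oil content per week (% dry mass)."""
        return self.replicate_means().sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FATimeCourse):
            return NotImplemented
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        return self.cultivar == other.cultivar and a[list(TIMECOURSE_COLUMNS[1:])].equals(
            b[list(TIMECOURSE_COLUMNS[1:])]
        )


def read_timecourses(path: str | Path) -> dict[str, FATimeCourse]:
    """Read a long-format time-course TSV; returns one course per cultivar."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"time-course TSV missing columns {missing}")
    return {
        cultivar: FATimeCourse(cultivar, sub.drop(columns="cultivar"))
        for cultivar, sub in df.groupby("cultivar")
    }


def read_timecourse(path: str | Path, cultivar: str | None = None) -> FATimeCourse:
    courses = read_timecourses(path)
    if cultivar is not None:
        try:
            return courses[cultivar]
        except KeyError:
            raise FormatError(f"cultivar {cultivar!r} not present in {path}") from None
    if len(courses) != 1:
        raise FormatError(
            f"{path} contains {len(courses)} cultivars; pass cultivar= to select one"
        )
    return next(iter(courses.values()))


def write_timecourse(courses: FATimeCourse | dict[str, FATimeCourse], path: str | Path) -> None:
    if isinstance(courses, FATimeCourse):
        courses = {courses.cultivar: courses}
    frames = []
    for tc in courses.values():
        df = tc.data.copy()
        df.insert(0, "cultivar", tc.cultivar)
        frames.append(df)
    # %.17g round-trips IEEE doubles exactly, so read(write(x)) == x
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_profile(profile: FAProfile, path: str | Path) -> None:
    rows = [
        {
            "sample_id": profile.sample_id,
            "species": sp,
            "content_pct": c,
            "mol_pct": profile.mol_pct.get(sp, float("nan")),
        }
        for sp, c in sorted(profile.content.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def aggregate_replicates(tc: FATimeCourse) -> pd.DataFrame:
    """Long table of mean +/- SD over replicates per (week, species)."""
    mean = tc.replicate_means().stack().rename("mean_pct")
    sd = tc.replicate_sds().stack().rename("sd_pct")
    out = pd.concat([mean, sd], axis=1).reset_index()
    out.insert(0, "cultivar", tc.cultivar)
    return out
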