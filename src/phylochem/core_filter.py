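"""Construction of the chemical core.

Two-step filtration of harmonized occurrence records:

1. **Promiscuity filter** — a compound is removed everywhere if it is
   recorded in more than ``max_families`` families (default: more than six,
   exclusive comparator) or in at least ``max_species_frac`` of all species
   globally (default >= 20%).  These compounds represent broadly shared
   background chemistry rather than lineage-specific traits.
2. **Within-family support filter** — within each family, a compound must
   occur in at least ``min_species_per_family`` species (default 2) or all
   its records in that family are removed.  A compound may survive in one
   family and be dropped in another.

The surviving records form the *chemical core*, summarized by a per-family
accounting of initial/core compounds, retention percentages and
initial/kept species, plus global occurrence retention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "FilterReport",
    "ChemicalCore",
    "OverlapSummary",
    "promiscuity_filter",
    "family_support_filter",
    "build_core",
    "chemical_density",
    "density_from_counts",
    "overlap_summary",
    "overlap_from_counts",
    "retention_pct",
]

logger = logging.getLogger(__name__)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def retention_pct(core: int, initial: int) -> float:
    """Percentage of initial compounds kept in the core, half-up to 1 decimal."""
    if initial <= 0:
        return float("nan")
    return _round_half_up(100.0 * core / initial, 1)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the two-step filtration.

    ``max_families`` is an exclusive bound (a compound in *more than* this
    many families is removed); set ``families_inclusive=True`` to remove at
    >= ``max_families`` instead.  ``max_species_frac`` removal is inclusive
    (removed at >= the fraction).
    """

    max_families: int = 6
    max_species_frac: float = 0.20
    min_species_per_family: int = 2
    families_inclusive: bool = False
    focal_families: Sequence[str] | None = None

    def validate(self) -> None:
        if self.max_families < 1:
            raise ValueError("max_families must be >= 1")
        if not 0 < self.max_species_frac <= 1:
            raise ValueError("max_species_frac must be in (0, 1]")
        if self.min_species_per_family < 1:
            raise ValueError("min_species_per_family must be >= 1")


@dataclass
class FilterReport:
    """Per-family and global accounting of the filtration."""

    per_family: pd.DataFrame  # family, initial_compounds, core_compounds,
                              # retention_pct, initial_species, kept_species
    initial_occurrences: int
    core_occurrences: int
    overall_retention_pct: float
    n_promiscuous_excluded: int

    @classmethod
    def from_counts(
        cls,
        families: Sequence[str],
        initial_compounds: Sequence[int],
        core_compounds: Sequence[int],
        initial_species: Sequence[int],
        kept_species: Sequence[int],
        initial_occurrences: int = 0,
        core_occurrences: int = 0,
        n_promiscuous_excluded: int = 0,
    ) -> "FilterReport":
        """Assemble a report directly from per-family counts.

        Lets published accounting tables be fed through the same retention
        and density arithmetic as freshly filtered data.
        """
        per_family = pd.DataFrame(
            {
                "family": list(families),
                "initial_compounds": list(initial_compounds),
                "core_compounds": list(core_compounds),
                "initial_species": list(initial_species),
                "kept_species": list(kept_species),
            }
        )
        per_family["retention_pct"] = [
            retention_pct(c, i)
            for c, i in zip(per_family["core_compounds"], per_family["initial_compounds"])
        ]
        overall = (
            retention_pct(core_occurrences, initial_occurrences)
            if initial_occurrences else float("nan")
        )
        return cls(per_family, initial_occurrences, core_occurrences, overall,
                   n_promiscuous_excluded)


@dataclass
class ChemicalCore:
    """Filtered occurrence set with incidence/count views.

    ``records`` holds the surviving long-format rows.  Incidence views are
    built on demand: family-pooled compound sets, a binary species x
    compound matrix (per family or global) and family/species x class
    count matrices.
    """

    records: pd.DataFrame
    _family_sets: dict[str, frozenset] | None = field(default=None, repr=False)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ChemicalCore":
        return cls(records.reset_index(drop=True))

    # ---- views ---------------------------------------------------------
    @property
    def families(self) -> list[str]:
        return sorted(self.records["family"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def compounds(self) -> list[str]:
        return sorted(self.records["inchikey"].unique())

    def family_compound_sets(self) -> dict[str, frozenset]:
        if self._family_sets is None:
            self._family_sets = {
                fam: frozenset(grp["inchikey"])
                for fam, grp in self.records.groupby("family")
            }
        return self._family_sets

    def species_incidence(self, family: str | None = None) -> pd.DataFrame:
        """Binary species x compound incidence (optionally one family)."""
        rec = self.records if family is None else self.records[self.records["family"] == family]
        inc = pd.crosstab(rec["species"], rec["inchikey"])
        return (inc > 0).astype(np.int8)

    def family_incidence(self) -> pd.DataFrame:
        """Binary family x compound incidence (species pooled per family)."""
        inc = pd.crosstab(self.records["family"], self.records["inchikey"])
        return (inc > 0).astype(np.int8)

    def class_counts(self, level: str = "family", class_col: str = "class") -> pd.DataFrame:
        """Counts of distinct core compounds per unit per chemical class."""
        if class_col not in self.records.columns:
            raise ValueError(f"no column {class_col!r} in core records")
        unit = "family" if level == "family" else "species"
        rec = self.records.drop_duplicates([unit, "inchikey"])
        return pd.crosstab(rec[unit], rec[class_col])

    def clade_map(self) -> dict[str, str]:
        if "clade" not in self.records.columns:
            return {}
        return (
            self.records.drop_duplicates("family").set_index("family")["clade"].to_dict()
        )


def promiscuity_filter(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove globally promiscuous compounds.

    Returns the kept records and a report of excluded compounds with their
    family breadth and global species counts.  Breadth is computed on the
    dataset as given; the species-fraction denominator is the number of
    distinct species in the input.
    """
    config = config or FilterConfig()
    config.validate()
    if len(records) == 0:
        raise ValueError("empty dataset")
    by_compound = records.groupby("inchikey").agg(
        n_families=("family", "nunique"), n_species=("species", "nunique")
    )
    n_total_species = records["species"].nunique()
    too_broad = (
        by_compound["n_families"] >= config.max_families
        if config.families_inclusive
        else by_compound["n_families"] > config.max_families
    )
    too_common = by_compound["n_species"] / n_total_species >= config.max_species_frac
    excluded = by_compound[too_broad | too_common].reset_index()
    kept = records[~records["inchikey"].isin(set(excluded["inchikey"]))]
    return kept.reset_index(drop=True), excluded


def family_support_filter(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Remove (compound, family) cells with insufficient within-family support."""
    config = config or FilterConfig()
    config.validate()
    support = records.groupby(["inchikey", "family"])["species"].transform("nunique")
    return records[support >= config.min_species_per_family].reset_index(drop=True)


def build_core(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[ChemicalCore, FilterReport]:
    """Apply promiscuity then support filtering and account for the losses."""
    config = config or FilterConfig()
    config.validate()
    initial = records
    kept, excluded = promiscuity_filter(records, config)
    kept = family_support_filter(kept, config)

    focal = config.focal_families
    fams = sorted(initial["family"].unique()) if focal is None else list(focal)
    init_by_fam = initial.groupby("family").agg(
        initial_compounds=("inchikey", "nunique"), initial_species=("species", "nunique")
    )
    core_by_fam = kept.groupby("family").agg(
        core_compounds=("inchikey", "nunique"), kept_species=("species", "nunique")
    )
    rows = []
    for fam in fams:
        if fam not in init_by_fam.index or init_by_fam.loc[fam, "initial_species"] == 0:
            logger.warning("family %s has no species after harmonization; omitted", fam)
            continue
        ic = int(init_by_fam.loc[fam, "initial_compounds"])
        isp = int(init_by_fam.loc[fam, "initial_species"])
        cc = int(core_by_fam["core_compounds"].get(fam, 0))
        ks = int(core_by_fam["kept_species"].get(fam, 0))
        rows.append((fam, ic, cc, retention_pct(cc, ic), isp, ks))
    per_family = pd.DataFrame(
        rows,
        columns=["family", "initial_compounds", "core_compounds", "retention_pct",
                 "initial_species", "kept_species"],
    )
    report = FilterReport(
        per_family=per_family,
        initial_occurrences=len(initial),
        core_occurrences=len(kept),
        overall_retention_pct=retention_pct(len(kept), len(initial)),
        n_promiscuous_excluded=len(excluded),
    )
    return ChemicalCore.from_records(kept), report


def density_from_counts(core_compounds: int, kept_species: int) -> float:
    """Chemical density (compounds per retained species), half-up to 2 decimals."""
    if kept_species <= 0:
        raise ValueError("kept_species must be > 0")
    return _round_half_up(core_compounds / kept_species, 2)


def chemical_density(
    report: FilterReport, clade_map: Mapping[str, str] | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-family and per-clade chemical densities.

    Family density is core compounds / kept species; clade density is the
    unweighted mean of its member families' (unrounded) densities.  Both are
    reported rounded half-up to two decimals.  Families with zero kept
    species are excluded with a warning.
    """
    pf = report.per_family
    usable = pf[pf["kept_species"] > 0]
    dropped = set(pf["family"]) - set(usable["family"])
    if dropped:
        logger.warning("families with zero kept species excluded from densities: %s",
                       sorted(dropped))
    raw = usable["core_compounds"] / usable["kept_species"]
    family_density = pd.Series(
        [_round_half_up(v, 2) for v in raw], index=list(usable["family"]), name="density"
    )
    clade_density = pd.Series(dtype=float, name="density")
    if clade_map:
        clades = usable["family"].map(clade_map)
        means = raw.groupby(clades.to_numpy()).mean()
        clade_density = pd.Series(
            {c: _round_half_up(v, 2) for c, v in means.items()}, name="density"
        )
    return family_density, clade_density


@dataclass(frozen=True)
class OverlapSummary:
    cumulative_family_richness: int
    global_unique: int
    shared: int
    shared_pct: float


def overlap_from_counts(family_richness: Sequence[int], global_unique: int) -> OverlapSummary:
    """Cross-family overlap from per-family richness and the global unique count."""
    cumulative = int(sum(family_richness))
    if cumulative <= 0:
        raise ValueError("empty core")
    shared = cumulative - int(global_unique)
    return OverlapSummary(
        cumulative_family_richness=cumulative,
        global_unique=int(global_unique),
        shared=shared,
        shared_pct=_round_half_up(100.0 * shared / cumulative, 1),
    )


def overlap_summary(core: ChemicalCore) -> OverlapSummary:
    """How much of the core's chemical diversity recurs across families."""
    if len(core.records) == 0:
        raise ValueError("empty core")
    sets = core.family_compound_sets()
    richness = [len(s) for s in sets.values()]
    unique = len(frozenset().union(*sets.values()))
    return overlap_from_counts(richness, unique)
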