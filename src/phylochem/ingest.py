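"""Reading, taxonomic harmonization and structural consolidation.

Occurrence tables are long-format TSV/CSV files, one row per compound
(InChIKey) x species record, carrying taxonomy (species, genus, family,
clade), physicochemical descriptors (MW, XLogP, TPSA, Fsp3, atom counts)
and chemical-class labels.  The synonym backbone maps raw names (accepted,
synonym, orthographic variant, unresolved) to accepted species/genus/family.

Harmonization replaces raw species names by accepted binomials, drops
records whose names cannot be resolved, and never invents records;
consolidation keeps exactly one record per (inchikey, species) pair.
Both operations are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RowParseError",
    "HarmonizationReport",
    "read_occurrences",
    "read_backbone",
    "harmonize_taxa",
    "consolidate_structures",
    "derive_elemental",
    "load_dataset",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("inchikey", "species", "family")
NUMERIC_COLUMNS = ("mw", "xlogp", "tpsa", "fsp3", "n_c", "n_o", "n_n")
OPTIONAL_COLUMNS = NUMERIC_COLUMNS + ("genus", "clade", "pathway", "superclass", "class")

BACKBONE_COLUMNS = ("name_raw", "accepted_species", "genus", "family", "status")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class RowParseError(ValueError):
    """A numeric cell could not be parsed; carries the offending row index."""

    def __init__(self, column: str, row: int, value):
        self.column, self.row, self.value = column, row, value
        super().__init__(f"unparseable value {value!r} in column {column!r} at row {row}")


@dataclass
class HarmonizationReport:
    n_input: int
    n_matched_direct: int
    n_matched_synonym: int
    n_dropped: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_matched_direct": self.n_matched_direct,
            "n_matched_synonym": self.n_matched_synonym,
            "n_dropped": self.n_dropped,
        }


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _normalize_name(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.split().str.join(" ").str.casefold()


def read_occurrences(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an occurrence table from TSV/CSV.

    ``schema`` optionally maps canonical column names to the names used in
    the file.  Missing numeric descriptor cells become NaN (absent), never
    zero; an unparseable non-empty numeric cell raises :class:`RowParseError`
    with the row index.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"occurrence table is missing required column {col!r}")
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col].str.strip()
        parsed = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = raw.ne("") & parsed.isna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(col, idx, raw.iloc[idx])
        df[col] = parsed
    for col in ("species", "family", "genus", "clade"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip()
    if (df["inchikey"].str.len() == 0).any():
        raise SchemaError("empty inchikey values in occurrence table")
    return df


def read_backbone(path) -> pd.DataFrame:
    """Read a synonym backbone table (name_raw -> accepted taxon)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in BACKBONE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"backbone table is missing required column {col!r}")
    df = df.replace({"accepted_species": {"": None}})
    bad = df["accepted_species"].isna() != df["status"].eq("unresolved")
    if bad.any():
        raise SchemaError("accepted_species must be null exactly for status=unresolved rows")
    return df


def harmonize_taxa(
    records: pd.DataFrame, backbone: pd.DataFrame
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Map raw species names to accepted names via the backbone.

    Matching is exact-string after whitespace/case normalization.  Records
    whose name is absent from the backbone, or maps to an unresolved entry,
    are dropped and counted.  The backbone's genus/family assignment is
    authoritative for matched records.
    """
    if len(backbone) == 0:
        raise ValueError("empty synonym backbone")
    bb = backbone.copy()
    bb["_key"] = _normalize_name(bb["name_raw"])
    bb = bb.drop_duplicates("_key")
    lookup = bb.set_index("_key")

    out = records.copy()
    if "species_raw" not in out.columns:
        out["species_raw"] = out["species"]
    keys = _normalize_name(out["species_raw"])
    matched = keys.isin(lookup.index)
    status = keys.map(lookup["status"])
    resolved = matched & status.ne("unresolved")

    n_input = len(out)
    n_direct = int((resolved & status.eq("accepted")).sum())
    n_synonym = int((resolved & status.eq("synonym")).sum())
    n_dropped = n_input - n_direct - n_synonym
    if n_dropped:
        logger.info("harmonization dropped %d unresolved/unmatched records", n_dropped)

    out = out.loc[resolved].copy()
    keys = keys.loc[resolved]
    out["species"] = keys.map(lookup["accepted_species"]).to_numpy()
    out["genus"] = keys.map(lookup["genus"]).to_numpy()
    out["family"] = keys.map(lookup["family"]).to_numpy()
    out = out.reset_index(drop=True)
    return out, HarmonizationReport(n_input, n_direct, n_synonym, n_dropped)


def consolidate_structures(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one record per (inchikey, species) pair.

    Descriptor conflicts among duplicate rows resolve to the first-seen
    values; a warning is logged because per-structure metadata should not
    conflict in clean input.
    """
    dup = records.duplicated(["inchikey", "species"], keep=False)
    if dup.any():
        desc_cols = [c for c in NUMERIC_COLUMNS if c in records.columns]
        if desc_cols:
            nunique = (
                records.loc[dup]
                .groupby(["inchikey", "species"])[desc_cols]
                .nunique(dropna=True)
            )
            n_conflicts = int((nunique > 1).any(axis=1).sum())
            if n_conflicts:
                logger.warning(
                    "descriptor conflicts in %d duplicated (inchikey, species) "
                    "pairs; first-seen values kept", n_conflicts,
                )
    return records.drop_duplicates(["inchikey", "species"], ignore_index=True)


def derive_elemental(records: pd.DataFrame) -> pd.DataFrame:
    """Add the carbon-to-oxygen ratio column.

    ``c_to_o = n_c / n_o`` where oxygen is present; compounds with no oxygen
    atoms keep the record but get an absent (NaN) ratio.
    """
    out = records.copy()
    for col in ("n_c", "n_o", "n_n"):
        if col in out.columns and (out[col].dropna() < 0).any():
            raise ValueError(f"negative atom counts in column {col!r}")
    if "n_c" in out.columns and "n_o" in out.columns:
        n_c = out["n_c"].astype(float)
        n_o = out["n_o"].astype(float)
        out["c_to_o"] = np.where(n_o > 0, n_c / n_o.replace(0, np.nan), np.nan)
    return out


def load_dataset(
    occurrences_path, backbone_path, schema: dict[str, str] | None = None
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Read, harmonize, consolidate and derive elemental ratios in one call."""
    records = read_occurrences(occurrences_path, schema=schema)
    backbone = read_backbone(backbone_path)
    harmonized, report = harmonize_taxa(records, backbone)
    consolidated = consolidate_structures(harmonized)
    return derive_elemental(consolidated), report
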