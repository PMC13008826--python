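"""Synthetic occurrence datasets with known ground truth.

Generates LOTUS-like compound x species occurrence tables for a clade/family
design (by default 3 angiosperm clades x 4 families each, with per-family
species counts spanning two orders of magnitude), together with a taxonomic
synonym backbone and a :class:`GroundTruth` record of every planted feature:

* a *promiscuous background* pool of compounds recurring across many families
  (heavy-tailed family breadth), emulating diffuse metabolic background
  chemistry produced by enzymes with relaxed specificity;
* *family core* compounds supported by >= 2 species within one family;
* per-family *singletons* (one species only), the sampling-noise layer;
* *shared* compounds planted between family pairs (nestedness material);
* clade-shifted physicochemical descriptor distributions (log10 MW, XLogP,
  TPSA, Fsp3, N/C/O atom counts);
* one diagnostic chemical class per family and per clade.

Everything is driven by a single integer seed; identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLADES",
    "SynthConfig",
    "GroundTruth",
    "generate_occurrences",
    "generate_backbone",
    "corrupt_species_names",
    "generate_pair_regime",
    "pair_regime_for_turnover",
    "plant_turnover_pairs",
]

CLADES = ("Magnoliids", "Monocots", "Eudicots")

#: Per-clade descriptor distribution parameters. Locations/scales follow the
#: clade-level contrasts the pipeline is meant to resolve: a lipophilic,
#: nitrogen-rich clade (Magnoliids-like), a hydrophilic high-MW saturated
#: clade (Monocots-like) and an oxygen-rich, nitrogen-poor clade
#: (Eudicots-like).  MW is lognormal (location/scale on log10 Da), TPSA
#: half-normal (scale set so the mean matches the target), Fsp3 normal
#: clipped to [0, 1], atom counts Poisson.
DEFAULT_DESCRIPTOR_PARAMS: dict[str, dict[str, float]] = {
    "Magnoliids": {
        "log10_mw_loc": 2.5366, "log10_mw_scale": 0.16,
        "xlogp_loc": 4.10, "xlogp_scale": 2.91,
        "tpsa_mean": 63.18,
        "fsp3_loc": 0.462, "fsp3_scale": 0.263,
        "n_mean": 0.41, "c_mean": 22.0, "o_mean": 3.74,
    },
    "Monocots": {
        "log10_mw_loc": 2.5657, "log10_mw_scale": 0.20,
        "xlogp_loc": 2.47, "xlogp_scale": 3.82,
        "tpsa_mean": 94.13,
        "fsp3_loc": 0.560, "fsp3_scale": 0.289,
        "n_mean": 0.51, "c_mean": 22.0, "o_mean": 4.16,
    },
    "Eudicots": {
        "log10_mw_loc": 2.5248, "log10_mw_scale": 0.18,
        "xlogp_loc": 3.09, "xlogp_scale": 2.98,
        "tpsa_mean": 80.76,
        "fsp3_loc": 0.515, "fsp3_scale": 0.288,
        "n_mean": 0.26, "c_mean": 22.0, "o_mean": 4.17,
    },
}

#: Chemical classes present in every family (background biosynthesis).
BASE_CLASSES = ("flavonoids", "terpenoids", "phenolic_acids", "fatty_acyls", "steroids")

#: Default per-family species counts (clade-blocked: 4 Magnoliid, 4 Monocot,
#: 4 Eudicot families), spanning ~48..3787 species.
DEFAULT_SPECIES_PER_FAMILY = (306, 268, 48, 125, 211, 55, 218, 186, 3787, 92, 2244, 538)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic occurrence generator.

    ``species_per_family`` is clade-blocked: the first ``families_per_clade``
    entries belong to the first clade, and so on.  ``background_breadth_mean``
    is the mean of the shifted, truncated Poisson from which the number of
    families hosting each background compound is drawn (support
    ``[2, n_families]``).  ``shared_fraction`` scales how many compounds are
    planted as shared between each unordered family pair (relative to
    ``core_compounds_per_family``); it is the generator's nestedness dial.
    """

    n_clades: int = 3
    families_per_clade: int = 4
    species_per_family: Sequence[int] = DEFAULT_SPECIES_PER_FAMILY
    n_background_compounds: int = 350
    background_breadth_mean: float = 8.0
    background_breadth_fixed: int | None = None  # exact families per background compound
    core_compounds_per_family: int = 300
    support_mean: float = 3.0
    singletons_per_family: int = 150
    shared_fraction: float = 0.02
    descriptor_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_DESCRIPTOR_PARAMS
    )
    class_alloc: Mapping[str, Mapping[str, float]] | None = None
    synonym_rate: float = 0.10
    seed: int = 0

    @property
    def n_families(self) -> int:
        return self.n_clades * self.families_per_clade

    def validate(self) -> None:
        counts = {
            "n_clades": self.n_clades,
            "families_per_clade": self.families_per_clade,
            "n_background_compounds": self.n_background_compounds,
            "core_compounds_per_family": self.core_compounds_per_family,
            "singletons_per_family": self.singletons_per_family,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.n_clades < 1 or self.families_per_clade < 1:
            raise ConfigError("need at least one clade and one family per clade")
        for name, value in (("shared_fraction", self.shared_fraction),
                            ("synonym_rate", self.synonym_rate)):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if len(self.species_per_family) != self.n_families:
            raise ConfigError(
                f"species_per_family has length {len(self.species_per_family)}, "
                f"expected n_clades * families_per_clade = {self.n_families}"
            )
        if any(n < 1 for n in self.species_per_family):
            raise ConfigError("every family needs at least one species")
        if self.support_mean < 2:
            raise ConfigError("support_mean must be >= 2 (core compounds need support)")

    # --- derived layout -------------------------------------------------
    def clade_names(self) -> list[str]:
        if self.n_clades <= len(CLADES):
            return list(CLADES[: self.n_clades])
        return list(CLADES) + [f"Clade{i}" for i in range(len(CLADES), self.n_clades)]

    def family_names(self) -> list[str]:
        return [f"Family{i:02d}" for i in range(self.n_families)]

    def family_clades(self) -> dict[str, str]:
        clades = self.clade_names()
        return {
            fam: clades[i // self.families_per_clade]
            for i, fam in enumerate(self.family_names())
        }

    def default_class_alloc(self) -> dict[str, dict[str, float]]:
        """Per-family probability vector over chemical classes.

        Each family gets a diagnostic class (weight 0.35) and its clade a
        clade-diagnostic class (0.15); the rest is spread over the shared
        base classes.
        """
        alloc: dict[str, dict[str, float]] = {}
        clades = self.family_clades()
        base_w = 0.50 / len(BASE_CLASSES)
        for fam in self.family_names():
            probs = {c: base_w for c in BASE_CLASSES}
            probs[f"marker_{fam}"] = 0.35
            probs[f"marker_{clades[fam]}"] = 0.15
            alloc[fam] = probs
        return alloc


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset."""

    roles: dict[str, str]                       # compound -> background|family_core|singleton|shared
    param_clade: dict[str, str]                 # compound -> clade whose distributions generated its descriptors
    family_sets: dict[str, set[str]]            # family -> generated compound set
    pair_counts: dict[tuple[str, str], tuple[int, int, int]]  # (a, b, c) per family pair
    clade_descriptor_means: dict[str, dict[str, float]]
    diagnostic_class: dict[str, str]            # family -> planted family marker class
    clade_diagnostic_class: dict[str, str]      # clade -> planted clade marker class
    family_clades: dict[str, str]
    background_set: set[str]
    singleton_set: set[str]
    n_occurrences: int
    n_unique_pairs: int

    def to_json(self) -> str:
        payload = {
            "roles": self.roles,
            "family_sets": {f: sorted(s) for f, s in self.family_sets.items()},
            "pair_counts": {f"{a}|{b}": list(v) for (a, b), v in self.pair_counts.items()},
            "clade_descriptor_means": self.clade_descriptor_means,
            "diagnostic_class": self.diagnostic_class,
            "clade_diagnostic_class": self.clade_diagnostic_class,
            "family_clades": self.family_clades,
            "n_occurrences": self.n_occurrences,
            "n_unique_pairs": self.n_unique_pairs,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a per-stage generator from the global seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _truncated_shifted_poisson(rng, mean: float, low: int, high: int, size: int):
    """Draw ``low + Poisson(mean - low)`` truncated to ``[low, high]``."""
    lam = max(mean - low, 1e-9)
    draws = low + rng.poisson(lam, size=size)
    return np.clip(draws, low, high)


def _draw_descriptors(rng, params: Mapping[str, float], n: int) -> pd.DataFrame:
    mw = 10.0 ** rng.normal(params["log10_mw_loc"], params["log10_mw_scale"], n)
    xlogp = rng.normal(params["xlogp_loc"], params["xlogp_scale"], n)
    tpsa = np.abs(rng.normal(0.0, params["tpsa_mean"] * np.sqrt(np.pi / 2.0), n))
    fsp3 = np.clip(rng.normal(params["fsp3_loc"], params["fsp3_scale"], n), 0.0, 1.0)
    n_n = rng.poisson(params["n_mean"], n)
    n_c = 1 + rng.poisson(params["c_mean"], n)   # >= 1 carbon
    n_o = rng.poisson(params["o_mean"], n)       # may be 0 -> undefined C/O downstream
    return pd.DataFrame(
        {"mw": mw, "xlogp": xlogp, "tpsa": tpsa, "fsp3": fsp3,
         "n_c": n_c, "n_o": n_o, "n_n": n_n}
    )


def _species_name(fam_idx: int, sp_idx: int) -> str:
    return f"Genus_f{fam_idx} species_{sp_idx}"


def generate_occurrences(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format occurrence table and its ground truth.

    One row per (compound, species) pair with taxonomy, descriptor and
    chemical-class columns.  The compound roles are mutually exclusive:
    every compound is exactly one of background / family_core / singleton /
    shared.
    """
    config.validate()
    families = config.family_names()
    fam_clades = config.family_clades()
    n_species = list(config.species_per_family)
    species_by_family = {
        fam: [_species_name(i, j) for j in range(n_species[i])]
        for i, fam in enumerate(families)
    }
    class_alloc = dict(config.class_alloc) if config.class_alloc else config.default_class_alloc()

    roles: dict[str, str] = {}
    param_clade: dict[str, str] = {}
    compound_class: dict[str, str] = {}
    compound_desc: dict[str, pd.Series] = {}
    family_sets: dict[str, set[str]] = {f: set() for f in families}
    rows: list[tuple] = []   # (inchikey, species, family)

    def _alloc_classes(rng, fam: str, n: int) -> list[str]:
        probs = class_alloc[fam]
        names = list(probs)
        p = np.asarray([probs[c] for c in names], dtype=float)
        p = p / p.sum()
        return [names[k] for k in rng.choice(len(names), size=n, p=p)]

    def _place(rng, key: str, fam: str, support: int) -> None:
        pool = species_by_family[fam]
        support = min(support, len(pool))
        for idx in rng.choice(len(pool), size=support, replace=False):
            rows.append((key, pool[idx], fam))
        family_sets[fam].add(key)

    # -- promiscuous background pool ------------------------------------
    rng = _stage_rng(config.seed, "background")
    if config.background_breadth_fixed is not None:
        breadths = np.full(config.n_background_compounds,
                           min(config.background_breadth_fixed, config.n_families))
    elif config.n_background_compounds:
        breadths = _truncated_shifted_poisson(
            rng, config.background_breadth_mean, 2, config.n_families,
            config.n_background_compounds,
        )
    else:
        breadths = np.empty(0, dtype=int)
    for i in range(config.n_background_compounds):
        key = f"BG{i:06d}"
        roles[key] = "background"
        hosts = rng.choice(config.n_families, size=int(breadths[i]), replace=False)
        home = families[int(hosts[0])]
        for h in hosts:
            fam = families[int(h)]
            support = int(_truncated_shifted_poisson(rng, config.support_mean, 2, 10**9, 1)[0])
            _place(rng, key, fam, support)
        compound_class[key] = _alloc_classes(rng, home, 1)[0]
        param_clade[key] = fam_clades[home]
        compound_desc[key] = _draw_descriptors(
            rng, config.descriptor_params[fam_clades[home]], 1).iloc[0]

    # -- family cores ----------------------------------------------------
    rng = _stage_rng(config.seed, "cores")
    for fi, fam in enumerate(families):
        n = config.core_compounds_per_family
        if n == 0:
            continue
        supports = _truncated_shifted_poisson(
            rng, config.support_mean, 2, len(species_by_family[fam]), n)
        classes = _alloc_classes(rng, fam, n)
        desc = _draw_descriptors(rng, config.descriptor_params[fam_clades[fam]], n)
        for j in range(n):
            key = f"FC{fi:02d}{j:06d}"
            roles[key] = "family_core"
            param_clade[key] = fam_clades[fam]
            _place(rng, key, fam, int(supports[j]))
            compound_class[key] = classes[j]
            compound_desc[key] = desc.iloc[j]

    # -- shared compounds between family pairs ---------------------------
    rng = _stage_rng(config.seed, "shared")
    n_shared_per_pair = int(round(config.shared_fraction * config.core_compounds_per_family))
    if n_shared_per_pair:
        pair_id = 0
        for i in range(len(families)):
            for j in range(i + 1, len(families)):
                fam_i, fam_j = families[i], families[j]
                classes = _alloc_classes(rng, fam_i, n_shared_per_pair)
                for k in range(n_shared_per_pair):
                    key = f"SH{pair_id:03d}{k:04d}"
                    roles[key] = "shared"
                    # descriptors come from one of the two member lineages
                    donor = (fam_i, fam_j)[int(rng.integers(2))]
                    param_clade[key] = fam_clades[donor]
                    compound_desc[key] = _draw_descriptors(
                        rng, config.descriptor_params[fam_clades[donor]], 1).iloc[0]
                    for fam in (fam_i, fam_j):
                        support = int(_truncated_shifted_poisson(
                            rng, config.support_mean, 2,
                            len(species_by_family[fam]), 1)[0])
                        _place(rng, key, fam, support)
                    compound_class[key] = classes[k]
                pair_id += 1

    # -- singletons -------------------------------------------------------
    rng = _stage_rng(config.seed, "singletons")
    for fi, fam in enumerate(families):
        n = config.singletons_per_family
        if n == 0:
            continue
        classes = _alloc_classes(rng, fam, n)
        desc = _draw_descriptors(rng, config.descriptor_params[fam_clades[fam]], n)
        for j in range(n):
            key = f"SG{fi:02d}{j:06d}"
            roles[key] = "singleton"
            param_clade[key] = fam_clades[fam]
            _place(rng, key, fam, 1)
            compound_class[key] = classes[j]
            compound_desc[key] = desc.iloc[j]

    # -- assemble the long table -----------------------------------------
    table = pd.DataFrame(rows, columns=["inchikey", "species", "family"])
    table = table.drop_duplicates(["inchikey", "species"], ignore_index=True)
    table["genus"] = table["species"].str.split(" ").str[0]
    table["clade"] = table["family"].map(fam_clades)
    desc_df = pd.DataFrame({k: v for k, v in compound_desc.items()}).T
    desc_df.index.name = "inchikey"
    table = table.join(desc_df, on="inchikey")
    for col in ("n_c", "n_o", "n_n"):
        table[col] = table[col].astype(int)
    table["class"] = table["inchikey"].map(compound_class)
    table = table.sort_values(["family", "inchikey", "species"], ignore_index=True)

    pair_counts = {}
    for i in range(len(families)):
        for j in range(i + 1, len(families)):
            A, B = family_sets[families[i]], family_sets[families[j]]
            pair_counts[(families[i], families[j])] = (
                len(A & B), len(A - B), len(B - A))

    truth = GroundTruth(
        roles=roles,
        param_clade=param_clade,
        family_sets=family_sets,
        pair_counts=pair_counts,
        clade_descriptor_means={
            clade: {
                "xlogp": p["xlogp_loc"],
                "tpsa": p["tpsa_mean"],
                "fsp3": p["fsp3_loc"],
                "log10_mw": p["log10_mw_loc"],
                "n_n": p["n_mean"],
            }
            for clade, p in config.descriptor_params.items()
            if clade in config.clade_names()
        },
        diagnostic_class={f: f"marker_{f}" for f in families},
        clade_diagnostic_class={c: f"marker_{c}" for c in config.clade_names()},
        family_clades=fam_clades,
        background_set={k for k, r in roles.items() if r == "background"},
        singleton_set={k for k, r in roles.items() if r == "singleton"},
        n_occurrences=len(table),
        n_unique_pairs=len(table),
    )
    return table, truth


def generate_backbone(config: SynthConfig, occurrences: pd.DataFrame) -> pd.DataFrame:
    """Build a synonym backbone for the species present in ``occurrences``.

    Every accepted name maps to itself; a fraction ``synonym_rate`` of
    species additionally receive one or two synonym aliases (including an
    orthographic variant), and a handful of unresolvable names are appended
    with null accepted species.
    """
    config.validate()
    rng = _stage_rng(config.seed, "backbone")
    fam_by_species = occurrences.drop_duplicates("species").set_index("species")["family"]
    rows = []
    for sp, fam in fam_by_species.items():
        genus = sp.split(" ")[0]
        rows.append((sp, sp, genus, fam, "accepted"))
        if config.synonym_rate > 0 and rng.random() < config.synonym_rate:
            n_alias = int(rng.integers(1, 3))
            for k in range(n_alias):
                if k == 0:
                    alias = f"{sp}_syn"             # nomenclatural synonym
                else:
                    alias = sp.replace("species", "speciess")  # orthographic variant
                rows.append((alias, sp, genus, fam, "synonym"))
    n_unresolved = max(1, int(0.01 * len(fam_by_species))) if len(fam_by_species) else 0
    for k in range(n_unresolved):
        rows.append((f"Incertae sedis_{k}", None, "", "", "unresolved"))
    return pd.DataFrame(
        rows, columns=["name_raw", "accepted_species", "genus", "family", "status"]
    )


def corrupt_species_names(
    occurrences: pd.DataFrame, backbone: pd.DataFrame, rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace a fraction of accepted species names with synonym aliases.

    Row count is conserved; only the ``species`` strings change, so that
    harmonization against the backbone must merge them back.
    """
    aliases = (
        backbone[backbone["status"] == "synonym"]
        .groupby("accepted_species")["name_raw"].first()
    )
    rng = np.random.default_rng(seed)
    out = occurrences.copy()
    has_alias = out["species"].isin(aliases.index).to_numpy()
    flip = rng.random(len(out)) < rate
    mask = has_alias & flip
    out.loc[mask, "species"] = out.loc[mask, "species"].map(aliases)
    return out


# ---------------------------------------------------------------------------
# planted pair regimes for the beta-partitioning recovery checks
# ---------------------------------------------------------------------------

def generate_pair_regime(n_a: int, n_b: int, n_shared: int) -> tuple[set[str], set[str]]:
    """Two compound sets with ``|A\\B| = n_a``, ``|B\\A| = n_b``, ``|A&B| = n_shared``."""
    if min(n_a, n_b, n_shared) < 0:
        raise ValueError("counts must be >= 0")
    if n_a + n_shared < 1 or n_b + n_shared < 1:
        raise ValueError("both sets would be empty")
    shared = {f"S{i}" for i in range(n_shared)}
    A = shared | {f"A{i}" for i in range(n_a)}
    B = shared | {f"B{i}" for i in range(n_b)}
    return A, B


def pair_regime_for_turnover(
    turnover_ratio: float, a: int = 200, c: int = 100
) -> tuple[int, int, int]:
    """Integer ``(n_a, n_b, n_shared)`` whose Jaccard turnover share is ~``turnover_ratio``.

    For exclusive counts ``b >= c`` and shared count ``a``, the turnover share
    ``beta_jtu / beta_jac = 2c(a+b+c) / ((a+2c)(b+c))`` is solved for ``b``
    and rounded to the nearest integer.  Requires
    ``turnover_ratio > 2c / (a + 2c)``.
    """
    r = float(turnover_ratio)
    if not 0 < r <= 1:
        raise ValueError("turnover_ratio must be in (0, 1]")
    denom = r * (a + 2 * c) - 2 * c
    if denom <= 0:
        raise ValueError("target ratio unreachable with this (a, c); increase a")
    b = c * (2 * (a + c) - r * (a + 2 * c)) / denom
    return int(round(b)), c, a


def plant_turnover_pairs(
    n_pairs: int, turnover_ratio: float, seed: int = 0,
    a: int = 200, c: int = 100,
) -> list[tuple[set[str], set[str]]]:
    """Independent set pairs each planted at the requested turnover share.

    Pair sizes are jittered (+-20% on the shared count) so the recovered mean
    is a genuine average over heterogeneous pairs, not one repeated case.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        a_i = int(round(a * rng.uniform(0.8, 1.2)))
        c_i = int(round(c * rng.uniform(0.8, 1.2)))
        n_b, n_c, n_shared = pair_regime_for_turnover(turnover_ratio, a=a_i, c=c_i)
        pairs.append(generate_pair_regime(n_b, n_c, n_shared))
    return pairs


def write_outputs(
    occurrences: pd.DataFrame, backbone: pd.DataFrame, truth: GroundTruth, outdir
) -> dict[str, str]:
    """Write occurrences/backbone as TSV and the ground truth as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": str(outdir / "occurrences.tsv"),
        "backbone": str(outdir / "backbone.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    occurrences.to_csv(paths["occurrences"], sep="\t", index=False)
    backbone.to_csv(paths["backbone"], sep="\t", index=False)
    with open(paths["ground_truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
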