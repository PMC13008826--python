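"""End-to-end orchestration: ingest -> core -> diversity -> beta ->
ordination -> traits -> drivers, with a manifest of outputs.

Every stage output is a pure function of (inputs, config, seeds); the
manifest records versions, seeds, input checksums and row counts per stage
so two runs with the same config are identical apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import beta as beta_mod
from . import core_filter, diversity, drivers, ingest, ordination, traits

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    occurrences: str = ""
    backbone: str = ""
    outdir: str = "phylochem_out"
    filter: core_filter.FilterConfig = field(default_factory=core_filter.FilterConfig)
    subsample_n: int = 200
    n_perm: int = 999
    seed: int = 0
    target_coverage: float = 0.95
    class_col: str = "class"
    rf_trees: int = 2000
    bootstrap_n: int = 1000
    run_ordination: bool = True
    run_drivers: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = core_filter.FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    def validate(self) -> None:
        for name in ("occurrences", "backbone"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        self.filter.validate()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_stage(manifest, stage, t0, **counts):
    elapsed = time.monotonic() - t0
    manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3), **counts}
    logger.info("stage %-12s %s (%.2fs)", stage, counts, elapsed)


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "occurrences": {"path": str(config.occurrences),
                            "sha256": _sha256(config.occurrences)},
            "backbone": {"path": str(config.backbone),
                         "sha256": _sha256(config.backbone)},
        },
        "stages": {},
    }

    # --- ingest ---------------------------------------------------------
    t0 = time.monotonic()
    dataset, report = ingest.load_dataset(config.occurrences, config.backbone)
    (outdir / "harmonization_report.json").write_text(json.dumps(report.as_dict(), indent=1))
    dataset.to_csv(outdir / "harmonized_occurrences.tsv", sep="\t", index=False)
    _log_stage(manifest, "ingest", t0, n_records=len(dataset), **report.as_dict())

    # --- chemical core ----------------------------------------------------
    t0 = time.monotonic()
    core, filt_report = core_filter.build_core(dataset, config.filter)
    filt_report.per_family.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    core.records.to_csv(outdir / "core_occurrences.tsv", sep="\t", index=False)
    _, excluded = core_filter.promiscuity_filter(dataset, config.filter)
    excluded.to_csv(outdir / "excluded_promiscuous.tsv", sep="\t", index=False)
    from scipy import sparse
    from scipy.io import mmwrite

    inc = core.species_incidence()
    mmwrite(outdir / "species_incidence.mtx", sparse.csr_matrix(inc.to_numpy()))
    (outdir / "species_incidence.rows.txt").write_text("\n".join(map(str, inc.index)) + "\n")
    (outdir / "species_incidence.cols.txt").write_text("\n".join(map(str, inc.columns)) + "\n")
    clade_map = core.clade_map()
    fam_density, clade_density = core_filter.chemical_density(filt_report, clade_map)
    overlap = core_filter.overlap_summary(core)
    (outdir / "core_summary.json").write_text(json.dumps({
        "initial_occurrences": filt_report.initial_occurrences,
        "core_occurrences": filt_report.core_occurrences,
        "overall_retention_pct": filt_report.overall_retention_pct,
        "n_promiscuous_excluded": filt_report.n_promiscuous_excluded,
        "family_density": fam_density.to_dict(),
        "clade_density": clade_density.to_dict(),
        "overlap": dataclasses.asdict(overlap),
    }, indent=1))
    _log_stage(manifest, "core_filter", t0,
               core_occurrences=filt_report.core_occurrences,
               retention_pct=filt_report.overall_retention_pct)

    # --- diversity --------------------------------------------------------
    t0 = time.monotonic()
    inc_by_family = {fam: core.species_incidence(fam).to_numpy() for fam in core.families}
    profiles = diversity.coverage_rarefy(inc_by_family, config.target_coverage)
    profiles.to_csv(outdir / "hill_profiles.tsv", sep="\t", index=False)
    if config.class_col in core.records.columns:
        cls_counts = core.class_counts("family", config.class_col)
        plast, r, p = diversity.plasticity_index(cls_counts)
        plast.to_csv(outdir / "plasticity.tsv", sep="\t", index=False)
        manifest["plasticity_richness_pearson"] = {"r": r, "p": p}
    _log_stage(manifest, "diversity", t0, n_families=len(profiles))

    # --- beta partitioning ------------------------------------------------
    t0 = time.monotonic()
    partitions = beta_mod.pairwise_family_partitions(core)
    partitions.to_csv(outdir / "beta_partitions.tsv", sep="\t", index=False)
    summary = beta_mod.turnover_summary(partitions, clade_map)
    (outdir / "turnover_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    _log_stage(manifest, "beta", t0, n_pairs=len(partitions),
               mean_turnover_ratio=summary["mean_turnover_ratio"])

    # --- ordination -------------------------------------------------------
    if config.run_ordination:
        t0 = time.monotonic()
        sub = ordination.subsample_species(core, config.subsample_n, seed=config.seed)
        inc = sub.species_incidence()
        fam_of = sub.records.drop_duplicates("species").set_index("species")["family"]
        groups = [fam_of[sp] for sp in inc.index]
        D = ordination.jaccard_distance_matrix(inc)
        res = ordination.pcoa(D)
        pd.DataFrame(res.coordinates, index=list(D.ids)).to_csv(
            outdir / "pcoa_coords.tsv", sep="\t")
        pd.Series(res.eigenvalues).to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t")
        perm = ordination.permanova(D, groups, n_perm=config.n_perm, seed=config.seed)
        (outdir / "permanova.json").write_text(json.dumps(dataclasses.asdict(perm), indent=1))
        clade_groups = [clade_map.get(g, g) for g in groups]
        disp = ordination.betadisper(D, clade_groups, n_perm=config.n_perm, seed=config.seed)
        disp.distances.to_csv(outdir / "dispersion.tsv", sep="\t")
        _log_stage(manifest, "ordination", t0, n_species=D.n,
                   permanova_R2=perm.R2, permanova_p=perm.p_value,
                   betadisper_p=disp.p_value)

    # --- traits -----------------------------------------------------------
    t0 = time.monotonic()
    desc = traits.descriptor_table(core)
    try:
        space = traits.zscore_space(desc)
        space.to_csv(outdir / "hybrid_space.tsv", sep="\t", index=False)
    except ValueError as exc:
        logger.warning("hybrid space skipped: %s", exc)
    summaries = traits.clade_descriptor_summaries(desc)
    summaries.to_csv(outdir / "descriptor_summary.tsv", sep="\t", index=False)
    tests = traits.clade_descriptor_tests(desc)
    tests.to_json(outdir / "descriptor_tests.json", orient="records", indent=1)
    _log_stage(manifest, "traits", t0, n_compound_clade=len(desc))

    # --- drivers ----------------------------------------------------------
    if config.run_drivers and config.class_col in core.records.columns:
        t0 = time.monotonic()
        fam_counts = drivers.class_profile_matrix(core, "family", config.class_col)
        sp_counts = drivers.class_profile_matrix(core, "species", config.class_col)
        sp_clades = (
            core.records.drop_duplicates("species").set_index("species")["clade"]
            .reindex(sp_counts.index)
        )
        rf = drivers.rf_drivers(sp_counts, sp_clades, n_trees=config.rf_trees,
                                seed=config.seed, family_class_counts=fam_counts)
        rf.importance.to_csv(outdir / "drivers.tsv", sep="\t", index=False)
        if rf.family_shares is not None:
            rf.family_shares.to_csv(outdir / "family_driver_shares.tsv", sep="\t")
        ward = drivers.ward_cluster(fam_counts, bootstrap_n=config.bootstrap_n,
                                    seed=config.seed)
        (outdir / "dendrogram.newick").write_text(ward.newick + "\n")
        bip = drivers.bipartite_metrics(fam_counts, seed=config.seed)
        (outdir / "bipartite_metrics.json").write_text(json.dumps({
            "H2_prime": bip.H2_prime, "Q": bip.Q,
            "row_modules": bip.row_modules, "col_modules": bip.col_modules,
            "seed": bip.seed, "restarts": bip.restarts,
        }, indent=1))
        # phenetic tree + phylogenetic signal of plasticity and richness
        fam_sets = core.family_compound_sets()
        fams = sorted(fam_sets)
        import numpy as np

        n = len(fams)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pc = beta_mod.pair_counts(fam_sets[fams[i]], fam_sets[fams[j]])
                dmat[i, j] = dmat[j, i] = beta_mod.jaccard_partition(pc)[0]
        D_fam = ordination.DistanceMatrix(data=dmat, ids=tuple(fams), metric="jaccard")
        newick = drivers.upgma_tree(D_fam)
        (outdir / "upgma.newick").write_text(newick + "\n")
        plast, _, _ = diversity.plasticity_index(fam_counts)
        trait = plast.set_index("family")["plasticity"]
        signal = drivers.blomberg_k(newick, trait, n_perm=config.n_perm,
                                    seed=config.seed, trait_name="plasticity")
        (outdir / "phylosignal.json").write_text(json.dumps({
            "K": signal.K, "p_value": signal.p_value, "trait": signal.trait,
            "n_perm": signal.n_perm, "seed": signal.seed,
        }, indent=1))
        _log_stage(manifest, "drivers", t0, oob_accuracy=rf.oob_accuracy,
                   H2_prime=bip.H2_prime, Q=bip.Q, blomberg_K=signal.K)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
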