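"""Config-driven orchestration of the full assessment experiment.

One :class:`ExperimentConfig` describes a species model, the degradation
grids (fragment counts, incompleteness and contamination levels), the
"tool personas" (gene-calling mode x paralog-splitting, mimicking the
behaviourally relevant differences between Roary-, BPGA- and Anvi'o-style
pipelines), the identity / core-gene threshold grids, mixed-dataset
fractions and replicate counts.  :func:`run_experiment` executes the
stages — species generation, per-grid-cell MAG simulation, gene calling,
pan-genome construction, evaluation statistics, tree comparison and
enrichment — writing long-format TSV tables plus a machine-readable JSON
summary stamped with the config hash.

Seeding: every stage/grid-cell/replicate seed is derived by hashing
``(master_seed, stage, cell key)``, so replicates are independent but any
stage can be re-run reproducibly in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, evaluate, magsim, pangenome, phylo, species
from .errors import ConfigurationError

log = logging.getLogger("panmag")


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic per-stage seed below 2**31."""
    key = "/".join([str(master_seed)] + [str(p) for p in parts])
    digest = hashlib.blake2b(key.encode(), digest_size=8).hexdigest()
    return int(digest, 16) % (2 ** 31)


@dataclass
class ExperimentConfig:
    species: dict = field(default_factory=dict)
    n_genomes: int = 20
    n_donor_genomes: int = 5  # held out of the analyzed dataset
    fragmentation_levels: tuple = magsim.FRAGMENTATION_GRID
    incompleteness_levels: tuple = magsim.INCOMPLETENESS_GRID  # percent
    contamination_levels: tuple = magsim.CONTAMINATION_GRID  # percent
    contamination_scope: str = "intra_species"
    base_fragmentation: int = 100  # fragmentation used by later stages
    base_incompleteness: float = 1.0  # percent, used by the contamination stage
    personas: dict = field(default_factory=lambda: {
        "roary_like": {"mode": "normal", "paralog_split": True},
        "bpga_like": {"mode": "normal", "paralog_split": False},
        "anvio_like": {"mode": "meta", "paralog_split": False},
    })
    si_threshold: float = 90.0
    cg_threshold: float = 100.0
    si_grid: tuple = (95.0, 90.0, 85.0, 80.0)
    cg_grid: tuple = (100.0, 99.0, 98.0, 95.0, 92.0, 90.0)
    mixed_fractions: tuple = (10.0, 40.0, 60.0, 85.0)
    replicates: int = 3
    master_seed: int = 0

    def __post_init__(self):
        self.species = dict(self.species)
        for key in ("gene_length_range", "intergenic_length_range",
                    "accessory_prevalence_range", "category_alphabet"):
            if key in self.species:
                self.species[key] = tuple(self.species[key])
        for name in ("fragmentation_levels", "incompleteness_levels",
                     "contamination_levels", "si_grid", "cg_grid",
                     "mixed_fractions"):
            value = getattr(self, name)
            setattr(self, name, tuple(value))
            if not getattr(self, name):
                raise ConfigurationError(f"{name} must be non-empty")
        if not self.personas:
            raise ConfigurationError("at least one persona is required")
        for pname, p in self.personas.items():
            if set(p) - {"mode", "paralog_split"}:
                raise ConfigurationError(f"persona {pname!r}: unknown keys")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def desk_preset(master_seed: int = 0) -> ExperimentConfig:
    """Desk-scale preset: 20 genomes, 200 core + 150 accessory families.

    Gene count is kept small for clustering tractability while intergenic
    spacers keep the chromosome at a realistic megabase scale, so per-gene
    cut probabilities under the published fragment-count grid match the
    regime of real bacterial genomes (the mechanism driver is
    fragments x gene length / genome length, not gene count).
    """
    return ExperimentConfig(
        species=dict(species_id="synth", n_core_families=200,
                     n_accessory_families=150, unique_genes_per_genome=15,
                     gene_length_range=(300, 1500),
                     intergenic_length_range=(8000, 12000),
                     within_family_divergence=0.01, rng_seed=master_seed),
        master_seed=master_seed)


def tiny_preset(master_seed: int = 0) -> ExperimentConfig:
    """Minutes-scale smoke-test preset."""
    return ExperimentConfig(
        species=dict(species_id="tiny", n_core_families=25,
                     n_accessory_families=15, unique_genes_per_genome=3,
                     gene_length_range=(300, 600),
                     intergenic_length_range=(600, 1200),
                     within_family_divergence=0.01, rng_seed=master_seed),
        n_genomes=8, n_donor_genomes=3,
        fragmentation_levels=(10, 30), incompleteness_levels=(2.0,),
        contamination_levels=(2.0,), base_fragmentation=20,
        cg_grid=(100.0, 90.0), mixed_fractions=(50.0,), replicates=2,
        master_seed=master_seed)


# ---------------------------------------------------------------------------
# experiment stages
# ---------------------------------------------------------------------------

class Experiment:
    """Holds the shared state (genomes, donor pools) between stages."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.model = species.build_species_model(config.species)
        seed = derive_seed(config.master_seed, "species")
        n_total = config.n_genomes + config.n_donor_genomes
        all_genomes = species.sample_genomes(self.model, n_total, seed)
        self.genomes = all_genomes[:config.n_genomes]
        self.donors = all_genomes[config.n_genomes:]
        if config.contamination_scope == "inter_species":
            self.donors = species.sample_genomes(
                self.model, max(2, config.n_donor_genomes),
                derive_seed(config.master_seed, "genus_partner"),
                genus_partner=True)
        self.genome_index = {g.genome_id: g for g in all_genomes + self.donors}
        self.assembly_ids = [g.genome_id for g in self.genomes]

    def persona_params(self, persona: str) -> tuple[calling.CallingParams, bool]:
        p = self.config.personas[persona]
        return (calling.CallingParams(mode=p.get("mode", "normal")),
                bool(p.get("paralog_split", False)))

    def build_pangenome(self, assemblies, persona: str, seed: int,
                        cg_threshold: float | None = None) -> pangenome.PanGenome:
        params, split = self.persona_params(persona)
        calls = calling.call_dataset(assemblies, params, self.genome_index, seed)
        ids = [calling.assembly_id_of(a) for a in assemblies]
        return pangenome.build_pangenome(
            calls, ids, si=self.config.si_threshold,
            cg_threshold=self.config.cg_threshold if cg_threshold is None
            else cg_threshold,
            paralog_split=split)

    def simulate(self, profile: magsim.DegradationProfile, seed: int):
        return magsim.simulate_dataset(self.genomes, profile, self.donors, seed)


def _stage_fragmentation(exp: Experiment) -> pd.DataFrame:
    cfg = exp.config
    rows = []
    for level in cfg.fragmentation_levels:
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.master_seed, "fragmentation", level, rep)
            profile = magsim.DegradationProfile(
                fragmentation_level=int(level), contamination_scope="none")
            mags, _ = exp.simulate(profile, seed)
            for persona in cfg.personas:
                pan = exp.build_pangenome(mags, persona, seed)
                rows.append(dict(stage="fragmentation", level=level, replicate=rep,
                                 persona=persona, label=profile.label,
                                 **pan.counts()))
    return pd.DataFrame(rows)


def _stage_incompleteness(exp: Experiment) -> pd.DataFrame:
    cfg = exp.config
    rows = []
    for level in cfg.incompleteness_levels:
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.master_seed, "incompleteness", level, rep)
            profile = magsim.DegradationProfile(
                fragmentation_level=cfg.base_fragmentation,
                incompleteness_mean=level / 100.0, contamination_scope="none")
            mags, _ = exp.simulate(profile, seed)
            for persona in cfg.personas:
                pan = exp.build_pangenome(mags, persona, seed)
                rows.append(dict(stage="incompleteness", level=level, replicate=rep,
                                 persona=persona, label=profile.label,
                                 **pan.counts()))
    return pd.DataFrame(rows)


def _stage_contamination(exp: Experiment) -> pd.DataFrame:
    cfg = exp.config
    rows = []
    for level in cfg.contamination_levels:
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.master_seed, "contamination", level, rep)
            profile = magsim.DegradationProfile(
                fragmentation_level=cfg.base_fragmentation,
                incompleteness_mean=cfg.base_incompleteness / 100.0,
                contamination_mean=level / 100.0,
                contamination_scope=cfg.contamination_scope)
            mags, _ = exp.simulate(profile, seed)
            for persona in cfg.personas:
                pan = exp.build_pangenome(mags, persona, seed)
                rows.append(dict(stage="contamination", level=level, replicate=rep,
                                 persona=persona, label=profile.label,
                                 **pan.counts()))
    return pd.DataFrame(rows)


def _stage_mixed(exp: Experiment) -> pd.DataFrame:
    cfg = exp.config
    rows = []
    persona = next(iter(cfg.personas))
    for fraction in cfg.mixed_fractions:
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.master_seed, "mixed", fraction, rep)
            profile = magsim.DegradationProfile(
                fragmentation_level=cfg.base_fragmentation,
                incompleteness_mean=cfg.base_incompleteness / 100.0,
                contamination_scope="none")
            mags, _ = exp.simulate(profile, seed)
            mixed = magsim.make_mixed_dataset(exp.genomes, mags, fraction, seed)
            pan = exp.build_pangenome(mixed, persona, seed)
            rows.append(dict(stage="mixed", level=fraction, replicate=rep,
                             persona=persona, label=f"MAG_{fraction:g}",
                             **pan.counts()))
    return pd.DataFrame(rows)


def _stage_thresholds(exp: Experiment) -> pd.DataFrame:
    """Core-gene recovery metrics across the CG-threshold grid."""
    cfg = exp.config
    persona = next(iter(cfg.personas))
    seed = derive_seed(cfg.master_seed, "thresholds")
    profile = magsim.DegradationProfile(
        fragmentation_level=cfg.base_fragmentation,
        incompleteness_mean=cfg.base_incompleteness / 100.0,
        contamination_scope="none")
    mags, _ = exp.simulate(profile, seed)
    ref_base = exp.build_pangenome(exp.genomes, persona, seed)
    sim_base = exp.build_pangenome(mags, persona, seed)
    ref_pans = {t: ref_base.reclassified(t) for t in cfg.cg_grid}
    sim_pans = {t: sim_base.reclassified(t) for t in cfg.cg_grid}
    coverage = evaluate.coverage_of_increased_cgs(sim_pans, ref_pans)
    rows = []
    for t in cfg.cg_grid:
        cmp_ = evaluate.match_cg_sets(sim_pans[t], ref_pans[t])
        rows.append(dict(stage="thresholds", cg_threshold=t, tp=cmp_.tp,
                         fp=cmp_.fp, recall=cmp_.recall, precision=cmp_.precision,
                         f_score=cmp_.f_score,
                         coverage_of_increased_cgs=coverage.get(t)))
    return pd.DataFrame(rows)


def _stage_trees(exp: Experiment) -> pd.DataFrame:
    cfg = exp.config
    persona = next(iter(cfg.personas))
    seed0 = derive_seed(cfg.master_seed, "trees")
    params, _ = exp.persona_params(persona)
    ref_calls = calling.call_dataset(exp.genomes, params, exp.genome_index, seed0)
    ref_pan = exp.build_pangenome(exp.genomes, persona, seed0)
    ref_tree = phylo.nj_tree(*phylo.distance_matrix(
        phylo.build_core_alignment(ref_pan, ref_calls)))
    rows = []
    conditions = {
        "fragmentation": magsim.DegradationProfile(
            fragmentation_level=cfg.base_fragmentation, contamination_scope="none"),
        "full": magsim.DegradationProfile(
            fragmentation_level=cfg.base_fragmentation,
            incompleteness_mean=cfg.base_incompleteness / 100.0,
            contamination_mean=(cfg.contamination_levels[0]) / 100.0,
            contamination_scope=cfg.contamination_scope),
    }
    for name, profile in conditions.items():
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.master_seed, "trees", name, rep)
            mags, _ = exp.simulate(profile, seed)
            mparams, split = exp.persona_params(persona)
            calls = calling.call_dataset(mags, mparams, exp.genome_index, seed)
            # leaf names = parent ids so both trees share a taxon set
            for c in calls:
                c.assembly_id = c.assembly_id.replace("_mag", "")
            pan = pangenome.build_pangenome(
                calls, exp.assembly_ids, si=cfg.si_threshold,
                cg_threshold=cfg.cg_threshold, paralog_split=split)
            try:
                tree = phylo.nj_tree(*phylo.distance_matrix(
                    phylo.build_core_alignment(pan, calls)))
                cmp_ = phylo.compare_trees(ref_tree, tree)
                rows.append(dict(stage="trees", condition=name, replicate=rep,
                                 nrf=cmp_.nrf,
                                 shared_branch_fraction=cmp_.shared_branch_fraction))
            except ConfigurationError as exc:
                rows.append(dict(stage="trees", condition=name, replicate=rep,
                                 nrf=np.nan, shared_branch_fraction=np.nan,
                                 error=str(exc)))
    return pd.DataFrame(rows)


def _stage_enrichment(exp: Experiment) -> pd.DataFrame:
    cfg = exp.config
    persona = next(iter(cfg.personas))
    seed = derive_seed(cfg.master_seed, "enrichment")
    # family -> category, covering shared families and per-genome unique genes
    categories = {}
    for g in exp.genomes:
        for ann in g.annotations:
            categories[ann.family_id] = ann.category
    profile = magsim.DegradationProfile(
        fragmentation_level=cfg.base_fragmentation,
        incompleteness_mean=cfg.base_incompleteness / 100.0,
        contamination_scope="none")
    mags, _ = exp.simulate(profile, seed)
    rows = []
    for dataset, assemblies in (("original", exp.genomes), ("mag", mags)):
        pan = exp.build_pangenome(assemblies, persona, seed)
        for gene_set in ("core", "accessory"):
            try:
                for r in phylo.enrichment(pan, categories, gene_set):
                    rows.append(dict(stage="enrichment", dataset=dataset,
                                     gene_set=gene_set, category=r.category,
                                     observed=r.observed, expected=r.expected,
                                     p_value=r.p_value, adjusted_p=r.adjusted_p))
            except ConfigurationError:
                continue
    return pd.DataFrame(rows)


_STAGES = {
    "fragmentation": _stage_fragmentation,
    "incompleteness": _stage_incompleteness,
    "contamination": _stage_contamination,
    "mixed": _stage_mixed,
    "thresholds": _stage_thresholds,
    "trees": _stage_trees,
    "enrichment": _stage_enrichment,
}


def run_experiment(config: ExperimentConfig, outdir,
                   stages: list[str] | None = None) -> Path:
    """Run the experiment stages and write tables plus ``summary.json``.

    Returns the report directory.  Any stage error aborts with the stage
    name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or _STAGES)
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    config.to_yaml(outdir / "config.yaml")
    exp = Experiment(config)
    summary = {"config_hash": config.config_hash,
               "master_seed": config.master_seed,
               "n_genomes": config.n_genomes,
               "core_families": exp.model.n_core_families,
               "stages": {}}
    for name in stages:
        t0 = time.monotonic()
        log.info("stage %s: start", name)
        try:
            table = _STAGES[name](exp)
        except Exception as exc:
            raise ConfigurationError(f"stage {name!r} failed: {exc}") from exc
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        summary["stages"][name] = dict(
            rows=int(len(table)),
            seed=derive_seed(config.master_seed, name),
        )
        numeric = table.select_dtypes("number")
        if len(numeric):
            summary["stages"][name]["means"] = {
                k: (None if pd.isna(v) else round(float(v), 6))
                for k, v in numeric.mean().items()}
        log.info("stage %s: done in %.1fs", name, time.monotonic() - t0)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return outdir
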