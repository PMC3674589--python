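"""End-to-end orchestration of the synthetic cross-species analysis.

One structured config drives the fixed stage order: simulate species pair ->
preprocess both species -> network/module detection on the reference
(human-like) data -> module eigengene statistics and trait association ->
cross-species module preservation -> per-gene screening in both species and
concordant gene selection -> gene-set over-representation.  Every stage's
outputs are written as TSV before the next stage starts, and a JSON run
manifest records the config snapshot, seed, per-stage shapes and warnings.

A single global seed is fanned out to per-stage child seeds through
numpy's SeedSequence spawning, so any stage can be re-run in isolation and
reproduce its outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, _io
from .enrichment import GeneSet, hypergeometric_enrichment, write_gmt
from .modulestats import module_eigengenes, module_membership, module_trait_table
from .network import GREY, blockwise_modules
from .preservation import module_preservation
from .preprocess import map_orthologs, preprocess_expression
from .screening import select_concordant_genes, screen_numeric_trait, sex_confounding_check
from .synthdata import (
    SyntheticDesign,
    design_from_dict,
    expand_to_probes,
    human_trait_coding,
    mouse_trait_coding,
    simulate_species_pair,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

STAGES = (
    "simulate", "preprocess", "network", "modules",
    "preserve", "screen", "enrich", "manifest",
)


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run, with the package defaults."""

    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    beta: float = 12.0
    min_module_size: int = 30
    deep_split: int = 2
    max_block_size: int = 5000
    merge_cut_height: float = 0.15
    n_perm: int = 200
    seed: int = 0
    outlier_z: float = -2.5
    mm_threshold: float = 0.5
    concordance_threshold: float = 0.5
    fdr: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        design = d.pop("design", {})
        if isinstance(design, dict):
            design = design_from_dict(design)
        return cls(design=design, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_config(config: PipelineConfig) -> list[str]:
    """Return human-readable violations (empty list = valid)."""
    violations = []
    try:
        config.design.validate()
    except ValueError as exc:
        violations.append(f"design: {exc}")
    checks = [
        ("beta", config.beta, config.beta >= 1, ">= 1"),
        ("min_module_size", config.min_module_size, config.min_module_size >= 2, ">= 2"),
        ("deep_split", config.deep_split, config.deep_split in (0, 1, 2, 3, 4), "in {0..4}"),
        ("max_block_size", config.max_block_size,
         config.max_block_size >= config.min_module_size, ">= min_module_size"),
        ("merge_cut_height", config.merge_cut_height,
         0 <= config.merge_cut_height < 1, "in [0, 1)"),
        ("n_perm", config.n_perm, config.n_perm >= 20, ">= 20"),
        ("mm_threshold", config.mm_threshold, -1 <= config.mm_threshold <= 1, "in [-1, 1]"),
        ("concordance_threshold", config.concordance_threshold,
         0 < config.concordance_threshold <= 1, "in (0, 1]"),
        ("fdr", config.fdr, 0 < config.fdr < 1, "in (0, 1)"),
    ]
    for name, value, ok, allowed in checks:
        if not ok:
            violations.append(f"{name}={value!r} not allowed; must be {allowed}")
    return violations


def _stage_seed(seed: int, index: int) -> int:
    """Deterministic child seed (below 2**31) for stage `index`.

    Uses SeedSequence spawn keys so stages can be re-run in isolation with
    reproducible sub-streams.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in fixed order; returns the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "stages": [],
        "warnings": [],
    }

    def log_stage(name, t0, **info):
        manifest["stages"].append(
            {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3), **info}
        )

    design = config.design

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    human, mouse, ortho = simulate_species_pair(design, seed=_stage_seed(config.seed, 0))
    h_probes, h_map = expand_to_probes(
        human["expr"], design.probes_per_gene, seed=_stage_seed(config.seed, 1)
    )
    m_probes, m_map = expand_to_probes(
        mouse["expr"], design.probes_per_gene, seed=_stage_seed(config.seed, 2)
    )
    _io.write_expression_tsv(h_probes, outdir / "human_probes.tsv")
    _io.write_expression_tsv(m_probes, outdir / "mouse_probes.tsv")
    _io.write_metadata_tsv(human["meta"], outdir / "human_metadata.tsv")
    _io.write_metadata_tsv(mouse["meta"], outdir / "mouse_metadata.tsv")
    _io.write_probe_map_tsv(h_map, outdir / "human_probe_map.tsv")
    _io.write_probe_map_tsv(m_map, outdir / "mouse_probe_map.tsv")
    _io.write_ortholog_tsv(ortho, outdir / "orthologs.tsv")
    _io.write_assignment_tsv(human["truth"].assignment, outdir / "true_modules.tsv")
    log_stage("simulate", t0, n_human_probes=h_probes.shape[0],
              n_mouse_probes=m_probes.shape[0], n_human_samples=h_probes.shape[1],
              n_mouse_samples=m_probes.shape[1])

    # --- preprocess ---------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        h_expr, h_info = preprocess_expression(
            h_probes, human["meta"], h_map, z_threshold=config.outlier_z
        )
        m_expr_native, m_info = preprocess_expression(
            m_probes, mouse["meta"], m_map, z_threshold=config.outlier_z
        )
    manifest["warnings"].extend(str(w.message) for w in caught)
    m_expr = map_orthologs(m_expr_native, ortho)
    _io.write_expression_tsv(h_expr, outdir / "human_expression.tsv")
    _io.write_expression_tsv(m_expr, outdir / "mouse_expression_human_ids.tsv")
    log_stage("preprocess", t0, n_human_genes=h_expr.shape[0], n_mouse_genes=m_expr.shape[0],
              human_outliers=h_info["outlier_samples"], mouse_outliers=m_info["outlier_samples"])

    # --- network / module detection ----------------------------------------
    t0 = time.perf_counter()
    assignment, dendrograms = blockwise_modules(
        h_expr,
        beta=config.beta,
        min_module_size=config.min_module_size,
        deep_split=config.deep_split,
        max_block_size=config.max_block_size,
        merge_cut_height=config.merge_cut_height,
        seed=_stage_seed(config.seed, 3),
        return_dendrograms=True,
    )
    _io.write_assignment_tsv(assignment, outdir / "modules.tsv")
    for b, dend in enumerate(dendrograms):
        dend.to_jsonl(outdir / f"dendrogram_block{b + 1}.jsonl")
    module_sizes = assignment.value_counts().to_dict()
    log_stage("network", t0, n_modules=len(set(assignment) - {GREY}),
              module_sizes={k: int(v) for k, v in module_sizes.items()})

    # --- module statistics --------------------------------------------------
    t0 = time.perf_counter()
    mes, varex = module_eigengenes(h_expr, assignment, include_grey=True)
    mm, pmm = module_membership(h_expr, mes)
    trait = human_trait_coding(human["meta"])
    trait_table = module_trait_table(mes, trait, groups=human["meta"]["group"])
    _io.write_table_tsv(mes, outdir / "eigengenes.tsv")
    mm_out = pd.concat(
        {f"MM.{c}": mm[c] for c in mm.columns} | {f"p.MM.{c}": pmm[c] for c in pmm.columns},
        axis=1,
    )
    _io.write_table_tsv(mm_out, outdir / "module_membership.tsv")
    _io.write_table_tsv(trait_table, outdir / "module_trait.tsv")
    log_stage("modules", t0, n_eigengenes=mes.shape[0])

    # --- preservation -------------------------------------------------------
    t0 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        preservation = module_preservation(
            h_expr, assignment, m_expr,
            beta=config.beta, n_perm=config.n_perm, seed=_stage_seed(config.seed, 4),
        )
    manifest["warnings"].extend(str(w.message) for w in caught)
    preservation.insert(0, "nPerm_requested", config.n_perm)
    _io.write_table_tsv(preservation, outdir / "preservation.tsv")
    log_stage("preserve", t0, n_modules_tested=preservation.shape[0])

    # --- screening ----------------------------------------------------------
    t0 = time.perf_counter()
    human_screen = screen_numeric_trait(h_expr, trait)
    mouse_screen = screen_numeric_trait(m_expr_native, mouse["meta"]["week"].astype(float))
    top_module = trait_table["r"].abs().idxmax()
    concordance = select_concordant_genes(
        human_screen, mouse_screen, ortho,
        threshold=config.concordance_threshold,
        mm=mm[top_module], mm_name=f"MM.{top_module}",
    )
    sexcheck = sex_confounding_check(
        h_expr, human["meta"],
        disease_genes=human_screen.index[human_screen["q.Student"] < config.fdr].tolist(),
        fdr=config.fdr,
    )
    _io.write_table_tsv(human_screen, outdir / "human_screening.tsv")
    _io.write_table_tsv(mouse_screen, outdir / "mouse_screening.tsv")
    _io.write_table_tsv(concordance, outdir / "concordant_genes.tsv", index=False)
    log_stage("screen", t0, n_concordant=concordance.shape[0],
              n_sex_associated=sexcheck["n_sex_associated"],
              n_sex_disease_overlap=sexcheck["n_overlap_with_disease"])

    # --- enrichment ---------------------------------------------------------
    # synthetic gene sets: each planted module's gene list plus random decoys,
    # so over-representation has a known positive and known negatives
    t0 = time.perf_counter()
    rng = np.random.default_rng(_stage_seed(config.seed, 5))
    background = h_expr.index.tolist()
    truth_assign = human["truth"].assignment
    sets: dict[str, GeneSet] = {}
    for lab in sorted(set(truth_assign) - {"background"}):
        genes = truth_assign.index[truth_assign == lab].tolist()
        sets[f"planted_{lab}"] = GeneSet(f"planted_{lab}", "planted module gene set", genes)
    for k in range(5):
        decoy = rng.choice(background, size=50, replace=False).tolist()
        sets[f"random_{k + 1}"] = GeneSet(f"random_{k + 1}", "random decoy set", decoy)
    write_gmt(sets, outdir / "genesets.gmt")
    from .enrichment import select_module_genes_by_mm

    query = select_module_genes_by_mm(mm, top_module, config.mm_threshold)
    enrich = hypergeometric_enrichment(query, background, sets)
    _io.write_table_tsv(enrich, outdir / "enrichment.tsv", index=False)
    log_stage("enrich", t0, module=str(top_module), n_query_genes=len(query),
              n_sets_tested=enrich.shape[0])

    # --- manifest -----------------------------------------------------------
    t0 = time.perf_counter()
    log_stage("manifest", t0)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
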