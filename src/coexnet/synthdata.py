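"""Synthetic two-species expression data with planted co-expression modules.

The generator emulates a cross-species transcriptomic study design: a human
cohort of three diagnostic groups (controls, sicca, primary Sjögren's-like
disease) profiled once, and a mouse disease-model time course (5 animals at
each of 5 ages).  Expression follows a latent-factor model: each module m has
a per-sample eigengene ``e_m``; trait-linked modules tilt ``e_m`` toward a
numeric disease coding (0/1/2 for the human groups, standardized week for the
mouse); each module gene is ``x_i = w_i * e_m + sqrt(1 - w_i^2) * eps_i`` with
loading ``w_i`` drawn from ``membership_range`` and independent Gaussian noise
``eps_i``.  Background genes are pure noise.  Because the module eigengene
downstream is the first principal component of the module, this construction
makes every planted quantity (module content, module-trait correlation,
module membership) recoverable and checkable.

Cross-species preservation is planted by reusing the same gene loadings in
both species for preserved modules, and by scrambling the gene labels of all
remaining (non-preserved) genes in the mouse data, which destroys their
within-module topology while keeping marginal distributions intact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "DesignError",
    "simulate_dataset",
    "simulate_species_pair",
    "expand_to_probes",
    "human_trait_coding",
    "mouse_trait_coding",
]

HUMAN_GROUPS = ("control", "sicca", "pSS")
GROUP_CODES = {"control": 0, "sicca": 1, "pSS": 2}


class DesignError(ValueError):
    """A SyntheticDesign field violates its allowed range."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted two-species study.

    Defaults give ~1,000 human genes (6 modules of 100/80/60/50/40/30 genes
    plus 640 background genes), the 25/16/24 human group sizes and the
    5-mice-per-week mouse design, one preserved disease-linked module
    (positive effect, like an immune-infiltration module) and one
    non-preserved disease-linked module (negative effect).
    """

    n_modules: int = 6
    module_sizes: tuple[int, ...] = (100, 80, 60, 50, 40, 30)
    n_background_genes: int = 640
    human_group_sizes: tuple[int, int, int] = (25, 16, 24)
    mouse_weeks: tuple[tuple[int, int], ...] = ((4, 5), (8, 5), (12, 5), (16, 5), (20, 5))
    trait_effects: tuple[float, ...] = (1.0, -0.8, 0.0, 0.0, 0.0, 0.0)
    preserved_flags: tuple[bool, ...] = (True, False, False, False, False, False)
    membership_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 1.0
    batch_offsets: tuple[float, ...] = (0.0, 0.5)
    probes_per_gene: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1:
            raise DesignError("n_modules must be >= 1")
        if len(self.module_sizes) != self.n_modules:
            raise DesignError("module_sizes must have n_modules entries")
        if any(s < 3 for s in self.module_sizes):
            raise DesignError("module_sizes entries must all be >= 3")
        if self.n_background_genes < 0:
            raise DesignError("n_background_genes must be >= 0")
        if len(self.human_group_sizes) != 3 or any(n < 1 for n in self.human_group_sizes):
            raise DesignError("human_group_sizes must be 3 positive counts")
        if not self.mouse_weeks or any(n < 1 for _, n in self.mouse_weeks):
            raise DesignError("mouse_weeks must be nonempty (week, n>=1) pairs")
        if len(self.trait_effects) != self.n_modules:
            raise DesignError("trait_effects must have n_modules entries")
        if len(self.preserved_flags) != self.n_modules:
            raise DesignError("preserved_flags must have n_modules entries")
        lo, hi = self.membership_range
        if not (0.0 < lo <= hi <= 1.0):
            raise DesignError("membership_range must be within (0, 1]")
        if not self.noise_sd > 0:
            raise DesignError("noise_sd must be > 0")
        if len(self.batch_offsets) < 1:
            raise DesignError("batch_offsets must have >= 1 entry")
        if self.probes_per_gene < 1:
            raise DesignError("probes_per_gene must be >= 1")

    @property
    def n_genes(self) -> int:
        return int(sum(self.module_sizes) + self.n_background_genes)

    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_modules)]


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    assignment: pd.Series            # gene_id -> module label, "background" for noise genes
    eigengenes: pd.DataFrame         # module x sample latent eigengenes
    trait_effects: pd.Series         # module -> planted effect size
    preserved_flags: pd.Series       # module -> planted cross-species preservation
    loadings: pd.Series              # gene_id -> loading w_i (0 for background)

    def population_trait_correlation(self, coded_trait: np.ndarray) -> pd.Series:
        """Large-n limit of cor(e_m, coded trait) for each module.

        With e_m = effect * trait + N(0,1) standardized, the population
        correlation is effect*sd(trait) / sqrt(effect^2*var(trait) + 1).
        """
        v = float(np.var(np.asarray(coded_trait, dtype=float)))
        eff = self.trait_effects.to_numpy(dtype=float)
        return pd.Series(
            eff * np.sqrt(v) / np.sqrt(eff ** 2 * v + 1.0),
            index=self.trait_effects.index,
            name="population_r",
        )


def human_trait_coding(meta: pd.DataFrame) -> pd.Series:
    """Ordinal disease coding 0 = control, 1 = sicca, 2 = pSS."""
    return meta["group"].map(GROUP_CODES).astype(float).rename("progression")


def mouse_trait_coding(meta: pd.DataFrame) -> pd.Series:
    """Standardized week-of-age (mean 0, sd 1 across samples)."""
    w = meta["week"].astype(float)
    return ((w - w.mean()) / w.std(ddof=0)).rename("week_std")


def _human_metadata(design: SyntheticDesign, rng: np.random.Generator) -> pd.DataFrame:
    groups = np.repeat(HUMAN_GROUPS, design.human_group_sizes)
    n = len(groups)
    sample_ids = [f"H{i + 1:03d}" for i in range(n)]
    batches = [f"batch{(i % len(design.batch_offsets)) + 1}" for i in range(n)]
    # female predominance among patients, balanced controls (no expression effect)
    p_female = np.where(groups == "control", 0.5, 0.85)
    sex = np.where(rng.random(n) < p_female, "F", "M")
    return pd.DataFrame(
        {"group": groups, "batch": batches, "sex": sex}, index=pd.Index(sample_ids, name="sample_id")
    )


def _mouse_metadata(design: SyntheticDesign, rng: np.random.Generator) -> pd.DataFrame:
    weeks = np.concatenate([[wk] * n for wk, n in design.mouse_weeks])
    n = len(weeks)
    sample_ids = [f"Ms{i + 1:03d}" for i in range(n)]
    batches = [f"batch{(i % len(design.batch_offsets)) + 1}" for i in range(n)]
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    return pd.DataFrame(
        {"week": weeks.astype(int), "batch": batches, "sex": sex},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def _gene_ids(design: SyntheticDesign, prefix: str) -> tuple[list[str], pd.Series]:
    """Gene identifiers and the planted assignment, module genes first."""
    ids: list[str] = []
    labels: list[str] = []
    k = 0
    for m, size in enumerate(design.module_sizes):
        for _ in range(size):
            ids.append(f"{prefix}{k + 1:05d}")
            labels.append(f"M{m + 1}")
            k += 1
    for _ in range(design.n_background_genes):
        ids.append(f"{prefix}{k + 1:05d}")
        labels.append("background")
        k += 1
    return ids, pd.Series(labels, index=pd.Index(ids, name="gene_id"), name="module")


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def _simulate_core(
    design: SyntheticDesign,
    coded_trait: np.ndarray,
    sample_ids: Sequence[str],
    gene_ids: Sequence[str],
    assignment: pd.Series,
    loadings: np.ndarray,
    effects: Sequence[float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent-factor expression matrix given per-gene loadings and effects."""
    n = len(sample_ids)
    eigengenes = np.empty((design.n_modules, n))
    for m in range(design.n_modules):
        e = effects[m] * coded_trait + rng.standard_normal(n)
        eigengenes[m] = _standardize(e)
    x = np.empty((len(gene_ids), n))
    labels = assignment.to_numpy()
    for m in range(design.n_modules):
        rows = np.flatnonzero(labels == f"M{m + 1}")
        w = loadings[rows][:, None]
        eps = rng.standard_normal((rows.size, n)) * design.noise_sd
        x[rows] = w * eigengenes[m][None, :] + np.sqrt(1.0 - w ** 2) * eps
    bg = np.flatnonzero(labels == "background")
    x[bg] = rng.standard_normal((bg.size, n)) * design.noise_sd
    expr = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"), columns=list(sample_ids))
    me = pd.DataFrame(
        eigengenes,
        index=pd.Index([f"M{m + 1}" for m in range(design.n_modules)], name="module"),
        columns=list(sample_ids),
    )
    return expr, me


def _add_batch_effects(
    expr: pd.DataFrame, meta: pd.DataFrame, offsets: Sequence[float], rng: np.random.Generator
) -> pd.DataFrame:
    """Per-gene additive batch shifts centred on each batch's offset."""
    out = expr.to_numpy().copy()
    batch_names = [f"batch{b + 1}" for b in range(len(offsets))]
    for name, off in zip(batch_names, offsets):
        cols = np.flatnonzero((meta["batch"] == name).to_numpy())
        if cols.size == 0 or off == 0.0:
            continue
        shifts = rng.normal(off, 0.5 * abs(off), size=expr.shape[0])
        out[:, cols] += shifts[:, None]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def simulate_dataset(
    design: SyntheticDesign, species: str = "human", seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one expression dataset (genes x samples) with planted modules.

    Parameters
    ----------
    design
        Validated study design.
    species
        ``"human"`` (3-group cross-sectional design, trait coded 0/1/2) or
        ``"mouse"`` (5-point time course, trait = standardized week).
    seed
        Overrides ``design.seed`` when given.

    Returns
    -------
    (expression, metadata, ground_truth)
    """
    design.validate()
    if species not in ("human", "mouse"):
        raise DesignError(f"species must be 'human' or 'mouse', got {species!r}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    if species == "human":
        meta = _human_metadata(design, rng)
        coded = human_trait_coding(meta).to_numpy()
        prefix = "HG"
    else:
        meta = _mouse_metadata(design, rng)
        coded = mouse_trait_coding(meta).to_numpy()
        prefix = "MG"
    gene_ids, assignment = _gene_ids(design, prefix)
    lo, hi = design.membership_range
    loadings = np.where(
        assignment.to_numpy() == "background", 0.0, rng.uniform(lo, hi, size=len(gene_ids))
    )
    expr, me = _simulate_core(
        design, coded, meta.index, gene_ids, assignment, loadings, design.trait_effects, rng
    )
    expr = _add_batch_effects(expr, meta, design.batch_offsets, rng)
    truth = GroundTruth(
        assignment=assignment,
        eigengenes=me,
        trait_effects=pd.Series(design.trait_effects, index=me.index, name="effect"),
        preserved_flags=pd.Series(design.preserved_flags, index=me.index, name="preserved"),
        loadings=pd.Series(loadings, index=assignment.index, name="loading"),
    )
    return expr, meta, truth


def simulate_species_pair(
    design: SyntheticDesign, seed: int | None = None
) -> tuple[dict, dict, pd.DataFrame]:
    """Simulate a linked human/mouse dataset pair with planted preservation.

    Preserved modules reuse the same genes and the same loadings in both
    species, with the trait effect re-expressed on the mouse time axis, so
    their within-module topology carries over.  All other genes (non-preserved
    modules and background) have their mouse gene labels scrambled, so any
    human-defined non-preserved module maps onto an arbitrary mouse gene set
    with background-level co-expression.

    Returns
    -------
    (human_bundle, mouse_bundle, ortholog_table)
        Each bundle is ``{"expr": ..., "meta": ..., "truth": ...}``; the
        ortholog table has columns ``human_gene``/``mouse_gene`` and one row
        per simulated gene.
    """
    design.validate()
    if not any(design.preserved_flags):
        raise DesignError("preserved_flags must mark at least one preserved module")
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    s_shared, s_human, s_mouse, s_scramble = root.spawn(4)
    shared_rng = np.random.default_rng(s_shared)

    human_ids, h_assign = _gene_ids(design, "HG")
    lo, hi = design.membership_range
    loadings = np.where(
        h_assign.to_numpy() == "background", 0.0, shared_rng.uniform(lo, hi, size=len(human_ids))
    )

    h_rng = np.random.default_rng(s_human)
    h_meta = _human_metadata(design, h_rng)
    h_coded = human_trait_coding(h_meta).to_numpy()
    h_expr, h_me = _simulate_core(
        design, h_coded, h_meta.index, human_ids, h_assign, loadings, design.trait_effects, h_rng
    )
    h_expr = _add_batch_effects(h_expr, h_meta, design.batch_offsets, h_rng)

    m_rng = np.random.default_rng(s_mouse)
    m_meta = _mouse_metadata(design, m_rng)
    m_coded = mouse_trait_coding(m_meta).to_numpy()
    # non-preserved modules carry no mouse trait signal; they get scrambled anyway
    m_effects = [
        eff if flag else 0.0 for eff, flag in zip(design.trait_effects, design.preserved_flags)
    ]
    m_expr, m_me = _simulate_core(
        design, m_coded, m_meta.index, human_ids, h_assign, loadings, m_effects, m_rng
    )
    m_expr = _add_batch_effects(m_expr, m_meta, design.batch_offsets, m_rng)

    # scramble mouse gene labels outside the preserved modules
    preserved_modules = {
        f"M{m + 1}" for m, flag in enumerate(design.preserved_flags) if flag
    }
    labels = h_assign.to_numpy()
    pool = np.flatnonzero(~np.isin(labels, list(preserved_modules)))
    perm = np.random.default_rng(s_scramble).permutation(pool)
    new_index = np.array(human_ids, dtype=object)
    new_index[pool] = new_index[perm]
    m_expr = m_expr.set_axis(pd.Index(new_index, name="gene_id"), axis=0)
    m_expr = m_expr.loc[human_ids]  # restore canonical gene order

    to_mouse = {h: "m" + h for h in human_ids}
    m_expr = m_expr.rename(index=to_mouse)
    ortho = pd.DataFrame(
        {"human_gene": human_ids, "mouse_gene": [to_mouse[g] for g in human_ids]}
    )

    m_assign = h_assign.rename(index=to_mouse)
    m_loadings = pd.Series(loadings, index=m_assign.index, name="loading")
    eff = pd.Series(design.trait_effects, index=h_me.index, name="effect")
    flags = pd.Series(design.preserved_flags, index=h_me.index, name="preserved")
    human = {
        "expr": h_expr,
        "meta": h_meta,
        "truth": GroundTruth(h_assign, h_me, eff, flags,
                             pd.Series(loadings, index=h_assign.index, name="loading")),
    }
    mouse = {
        "expr": m_expr,
        "meta": m_meta,
        "truth": GroundTruth(m_assign, m_me, pd.Series(m_effects, index=h_me.index, name="effect"),
                             flags, m_loadings),
    }
    return human, mouse, ortho


def expand_to_probes(
    expr: pd.DataFrame,
    probes_per_gene: int,
    seed: int = 0,
    offset_sd: float = 0.5,
    probe_noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expand a gene-level matrix into redundant probe rows.

    Each gene contributes ``probes_per_gene`` probe rows equal to the gene
    profile plus a probe-specific additive offset (N(0, offset_sd)) and
    independent noise, emulating multiple probe sets per gene on an array.

    Returns the probe-level matrix and a many-to-one probe -> gene map.
    """
    if probes_per_gene < 1:
        raise DesignError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    x = expr.to_numpy()
    n_genes, n_samples = x.shape
    probe_ids, gene_of_probe = [], []
    rows = np.empty((n_genes * probes_per_gene, n_samples))
    k = 0
    for i, gene in enumerate(expr.index):
        for p in range(probes_per_gene):
            offset = rng.normal(0.0, offset_sd) if offset_sd > 0 else 0.0
            noise = (
                rng.normal(0.0, probe_noise_sd, size=n_samples) if probe_noise_sd > 0 else 0.0
            )
            rows[k] = x[i] + offset + noise
            probe_ids.append(f"{gene}_at{p + 1}")
            gene_of_probe.append(gene)
            k += 1
    probe_expr = pd.DataFrame(
        rows, index=pd.Index(probe_ids, name="probe_id"), columns=expr.columns
    )
    probe_map = pd.Series(
        gene_of_probe, index=pd.Index(probe_ids, name="probe_id"), name="gene_id"
    )
    return probe_expr, probe_map


def design_from_dict(d: dict) -> SyntheticDesign:
    """Build a SyntheticDesign from a plain (e.g. YAML-loaded) mapping."""
    allowed = {f.name for f in dataclasses.fields(SyntheticDesign)}
    unknown = set(d) - allowed
    if unknown:
        raise DesignError(f"unknown design fields: {sorted(unknown)}")
    coerced = {}
    for key, value in d.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        coerced[key] = value
    return SyntheticDesign(**coerced)
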