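"""Synthetic expression atlases and qPCR datasets.

Real regulator-mining studies start from a compendium of RNA-Seq samples
(here emulated at the canonical size of 82 samples spanning organs and
treatments) in which biosynthetic pathway branches form co-expressed
modules, each with a handful of regulators sharing the module's activity
profile.  The generator plants that structure explicitly — module genes
follow a shared per-sample activity profile up to a gene-specific scale
and multiplicative log-normal noise, background genes vary independently
— so that every downstream stage (ranking, KNN network, candidate
selection, screening) can be tested against known ground truth.

A companion generator produces qPCR Cq tables with specified true fold
changes, reference genes, amplification efficiencies and technical
replicates, emulating a plate exported per biological replicate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import ExpressionAtlas
from .qpcr import QPCRDataset

__all__ = [
    "ModuleSpec",
    "SyntheticAtlasConfig",
    "PlantedTruth",
    "simulate_atlas",
    "default_atlas_config",
    "QPCRDesign",
    "simulate_qpcr",
]


@dataclasses.dataclass
class ModuleSpec:
    """One planted co-expression module (a pathway branch).

    ``activity_profile`` gives the module's relative activity in each
    sample (non-negative, arbitrary units); all member genes and planted
    regulators follow it up to a per-gene scale factor.
    """

    module_id: str
    member_gene_count: int
    planted_regulator_count: int
    activity_profile: Sequence[float]

    def validate(self, n_samples: int) -> None:
        if self.member_gene_count <= 0:
            raise ValueError(
                f"member_gene_count must be positive for module {self.module_id!r}"
            )
        if self.planted_regulator_count < 0:
            raise ValueError(
                f"planted_regulator_count must be >= 0 for module {self.module_id!r}"
            )
        prof = np.asarray(self.activity_profile, dtype=float)
        if prof.shape != (n_samples,):
            raise ValueError(
                f"activity_profile of module {self.module_id!r} has length "
                f"{prof.size}, expected n_samples={n_samples}"
            )
        if np.isnan(prof).any():
            raise ValueError(
                f"activity_profile of module {self.module_id!r} contains NaN"
            )
        if (prof < 0).any():
            raise ValueError(
                f"activity_profile of module {self.module_id!r} has negative entries"
            )


@dataclasses.dataclass
class SyntheticAtlasConfig:
    """Configuration of a synthetic TPM atlas.

    The seed fully determines the output.  ``n_genes`` may be omitted, in
    which case it is the sum of module members, planted regulators and
    background genes; if given it must equal that sum.
    """

    modules: Sequence[ModuleSpec]
    n_samples: int = 82
    background_gene_count: int = 0
    noise_sd: float = 0.05
    tpm_total: float = 1e6
    seed: int = 0
    n_genes: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tpm_total <= 0:
            raise ValueError("tpm_total must be positive")
        if self.background_gene_count < 0:
            raise ValueError("background_gene_count must be >= 0")
        if not self.modules and self.background_gene_count == 0:
            raise ValueError("modules and background_gene_count are both empty")
        for mod in self.modules:
            mod.validate(self.n_samples)
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("modules: duplicate module_id")
        total = (
            sum(m.member_gene_count + m.planted_regulator_count for m in self.modules)
            + self.background_gene_count
        )
        if self.n_genes is None:
            self.n_genes = total
        elif self.n_genes != total:
            raise ValueError(
                f"n_genes={self.n_genes} does not match module members + "
                f"regulators + background = {total}"
            )
        if self.modules:
            activity = np.array(
                [np.asarray(m.activity_profile, float) for m in self.modules]
            )
            silent = np.where(~(activity > 0).any(axis=0))[0]
            if len(silent) and self.background_gene_count == 0:
                raise ValueError(
                    f"modules: sample index {silent[0]} has no module with "
                    "nonzero activity and there are no background genes"
                )


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth of a simulated atlas: which genes belong where."""

    pathway_genes: dict[str, list[str]]  # module_id -> member (bait-able) genes
    regulator_genes: dict[str, list[str]]  # module_id -> planted regulators
    background_genes: list[str]

    def all_regulators(self) -> list[str]:
        out: list[str] = []
        for mod in sorted(self.regulator_genes):
            out.extend(self.regulator_genes[mod])
        return out

    def all_pathway_genes(self) -> list[str]:
        out: list[str] = []
        for mod in sorted(self.pathway_genes):
            out.extend(self.pathway_genes[mod])
        return out

    def module_of(self, gene: str) -> str | None:
        for mod, genes in self.pathway_genes.items():
            if gene in genes:
                return mod
        for mod, genes in self.regulator_genes.items():
            if gene in genes:
                return mod
        return None


def _module_gene_ids(mod: ModuleSpec) -> tuple[list[str], list[str]]:
    members = [f"{mod.module_id}_P{i:03d}" for i in range(1, mod.member_gene_count + 1)]
    regs = [
        f"{mod.module_id}_R{i:02d}" for i in range(1, mod.planted_regulator_count + 1)
    ]
    return members, regs


def simulate_atlas(config: SyntheticAtlasConfig) -> tuple[ExpressionAtlas, PlantedTruth]:
    """Simulate a TPM atlas with planted co-expression modules.

    Module gene expression in sample ``s`` is ``scale_g * activity(s)``
    with multiplicative log-normal noise (sigma = ``noise_sd`` in natural
    log units) applied per gene per sample; background genes get profiles
    independent of any module.  Every sample column is then rescaled to
    sum to ``tpm_total`` (TPM closure).

    Returns the atlas and the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_samples
    sample_ids = [f"S{i:03d}" for i in range(1, n_samples + 1)]

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    pathway: dict[str, list[str]] = {}
    regulators: dict[str, list[str]] = {}

    for mod in config.modules:
        members, regs = _module_gene_ids(mod)
        pathway[mod.module_id] = members
        regulators[mod.module_id] = regs
        profile = np.asarray(mod.activity_profile, dtype=float)
        for gid in members + regs:
            scale = 10.0 ** rng.uniform(1.0, 3.0)  # 10..1000 TPM-scale spread
            mean = scale * profile
            if config.noise_sd > 0:
                mean = mean * rng.lognormal(0.0, config.noise_sd, size=n_samples)
            rows.append(np.maximum(mean, 0.0))
            gene_ids.append(gid)

    background_ids = [f"BG{i:04d}" for i in range(1, config.background_gene_count + 1)]
    for gid in background_ids:
        scale = 10.0 ** rng.uniform(1.0, 3.0)
        # independent per-sample variation: uncorrelated with any module
        profile = rng.lognormal(0.0, 1.0, size=n_samples)
        if config.noise_sd > 0:
            profile = profile * rng.lognormal(0.0, config.noise_sd, size=n_samples)
        rows.append(np.maximum(scale * profile, 0.0))
        gene_ids.append(gid)

    matrix = np.vstack(rows)
    col_sums = matrix.sum(axis=0)
    if (col_sums == 0).any():
        idx = int(np.argmax(col_sums == 0))
        raise ValueError(f"sample {sample_ids[idx]} has zero total expression")
    matrix = matrix * (config.tpm_total / col_sums)

    values = pd.DataFrame(matrix, index=gene_ids, columns=sample_ids)
    meta = _default_sample_meta(config, sample_ids)
    atlas = ExpressionAtlas(values=values, sample_meta=meta)
    truth = PlantedTruth(
        pathway_genes=pathway,
        regulator_genes=regulators,
        background_genes=background_ids,
    )
    return atlas, truth


def _default_sample_meta(
    config: SyntheticAtlasConfig, sample_ids: list[str]
) -> pd.DataFrame:
    """Label each sample with the dominant module, as an organ/treatment stand-in."""
    organs = []
    for s in range(config.n_samples):
        best = None
        best_act = 0.0
        for mod in config.modules:
            act = float(np.asarray(mod.activity_profile, float)[s])
            if act > best_act:
                best, best_act = mod.module_id, act
        organs.append(best if best is not None else "background")
    return pd.DataFrame(
        {"organ": organs, "treatment": ["none"] * config.n_samples},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def block_profiles(n_modules: int, n_samples: int, high: float = 1.0) -> list[np.ndarray]:
    """Orthogonal block activity profiles: module m is active in block m only.

    Mimics organ/treatment contrasts (root-high, JA-induced, ...) so that
    pathway-branch decoupling can be emulated.
    """
    if n_modules <= 0 or n_samples < n_modules:
        raise ValueError("need n_samples >= n_modules >= 1")
    bounds = np.linspace(0, n_samples, n_modules + 1).astype(int)
    profiles = []
    for m in range(n_modules):
        p = np.zeros(n_samples)
        p[bounds[m] : bounds[m + 1]] = high
        profiles.append(p)
    return profiles


def default_atlas_config(
    seed: int = 0,
    n_samples: int = 82,
    n_modules: int = 3,
    members_per_module: int = 15,
    regulators_per_module: int = 5,
    background_gene_count: int = 400,
    noise_sd: float = 0.05,
) -> SyntheticAtlasConfig:
    """The canonical study-scale configuration: an 82-sample atlas with three
    pathway-branch modules (e.g. a root-specific, an induced and a
    leaf-specific branch), five planted regulators each, and a background
    of unrelated genes."""
    profiles = block_profiles(n_modules, n_samples)
    modules = [
        ModuleSpec(
            module_id=f"M{m + 1}",
            member_gene_count=members_per_module,
            planted_regulator_count=regulators_per_module,
            activity_profile=profiles[m],
        )
        for m in range(n_modules)
    ]
    return SyntheticAtlasConfig(
        modules=modules,
        n_samples=n_samples,
        background_gene_count=background_gene_count,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclasses.dataclass
class QPCRDesign:
    """Design of a simulated qPCR experiment.

    ``fold_changes`` maps gene -> condition -> true fold change relative
    to the control condition (unspecified pairs default to 1).  Reference
    genes must have true fold change 1 everywhere; they vary only by
    noise.  Two technical replicates are simulated and averaged into one
    Cq per biological replicate, as exported plates usually are.
    """

    conditions: Sequence[str]
    control_condition: str
    genes: Sequence[str]
    reference_genes: Sequence[str]
    fold_changes: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=dict
    )
    n_replicates: int = 4
    cq_noise_sd: float = 0.1
    efficiencies: Mapping[str, float] = dataclasses.field(default_factory=dict)
    technical_replicates: int = 2
    base_cq_range: tuple[float, float] = (18.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (biological replicates)")
        if self.control_condition not in self.conditions:
            raise ValueError(
                f"control_condition {self.control_condition!r} not in conditions"
            )
        if not self.reference_genes:
            raise ValueError("need at least one reference gene")
        for ref in self.reference_genes:
            fcs = self.fold_changes.get(ref, {})
            for cond, fc in fcs.items():
                if fc != 1:
                    raise ValueError(
                        f"reference gene {ref!r} must have fold change 1 "
                        f"(got {fc} in {cond!r})"
                    )
        for gene, fcs in self.fold_changes.items():
            for cond, fc in fcs.items():
                if not fc > 0:
                    raise ValueError(
                        f"fold change for gene {gene!r} in condition {cond!r} "
                        f"must be positive, got {fc}"
                    )
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be >= 0")
        if self.technical_replicates < 1:
            raise ValueError("technical_replicates must be >= 1")

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in list(self.genes) + list(self.reference_genes):
            seen.setdefault(g, None)
        return list(seen)

    def efficiency(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, 2.0))


def simulate_qpcr(design: QPCRDesign) -> QPCRDataset:
    """Simulate Cq values realising the design's true fold changes.

    A gene with true fold change F in condition c (relative to control)
    amplifies with efficiency E, so its expected Cq shifts by
    ``-log_E(F)`` cycles versus control.  Gaussian noise of sd
    ``cq_noise_sd`` is added per technical replicate; technical
    replicates are averaged into one Cq per biological replicate.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.all_genes()
    base_cq = {
        g: rng.uniform(*design.base_cq_range) for g in genes
    }
    records = []
    for cond in design.conditions:
        for rep in range(1, design.n_replicates + 1):
            sample = f"{cond}_r{rep}"
            for gene in genes:
                fc = float(design.fold_changes.get(gene, {}).get(cond, 1.0))
                e = design.efficiency(gene)
                shift = -np.log(fc) / np.log(e)
                tech = base_cq[gene] + shift + rng.normal(
                    0.0, design.cq_noise_sd, size=design.technical_replicates
                )
                records.append(
                    {
                        "sample": sample,
                        "condition": cond,
                        "gene": gene,
                        "cq": float(np.mean(tech)),
                    }
                )
    df = pd.DataFrame(records)
    return QPCRDataset(
        data=df,
        reference_genes=list(design.reference_genes),
        control_condition=design.control_condition,
        efficiencies={g: design.efficiency(g) for g in genes},
    )
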