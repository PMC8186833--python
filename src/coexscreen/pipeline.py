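"""End-to-end pipeline: simulate -> network -> select -> groups -> screen.

``run_pipeline`` ties the stages together, writes every stage output as
TSV/CSV under an output directory and records a JSON manifest with the
parameters and a SHA-256 checksum of each output, so that a rerun with
the same seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import io as cio
from .atlas import read_expression_tsv, write_expression_tsv
from .coexpression import build_knn, compute_similarity, export_edges, preprocess_atlas
from .qpcr import apply_gate, fold_changes, followup_list, normalize_qpcr, read_qpcr_csv
from .selection import (
    BaitPanel,
    RegulatorAnnotation,
    assign_groups,
    relative_rank_matrix,
    select_candidates,
)
from .synthetic import QPCRDesign, default_atlas_config, simulate_atlas, simulate_qpcr

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Parameters of a full pipeline run.

    Defaults reproduce the study-scale parameterisation: KNN k = 500,
    per-bait cap = 10, screening groups of up to 4, overexpression gate
    >5-fold, target gate >2-fold at p < 0.05, Pearson on log2(TPM + 1).
    When no atlas path is given a synthetic atlas is simulated and its
    planted baits/regulators are used.
    """

    atlas_path: str | None = None
    baits_path: str | None = None
    regulators_path: str | None = None
    qpcr_path: str | None = None
    k: int = 500
    cap: int = 10
    max_group_size: int = 4
    oe_threshold: float = 5.0
    target_threshold: float = 2.0
    alpha: float = 0.05
    method: str = "pearson"
    log_offset: float = 1.0
    min_expression: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < self.cap:
            raise ValueError(f"k ({self.k}) must be >= cap ({self.cap})")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.max_group_size < 1:
            raise ValueError("max_group_size must be >= 1")
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown similarity method: {self.method!r}")
        if self.atlas_path is not None and (
            self.baits_path is None or self.regulators_path is None
        ):
            raise ValueError("an external atlas needs baits_path and regulators_path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stage outputs (all deterministic given the seed): atlas and gene
    lists (synthetic mode), KNN edge list, candidate table and
    relative-rank matrix, screening groups, qPCR screen results and gate
    decisions, follow-up candidate list, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    truth = None
    if config.atlas_path is None:
        logger.info("[simulate] generating synthetic atlas (seed=%d)", config.seed)
        atlas_config = default_atlas_config(seed=config.seed)
        atlas, truth = simulate_atlas(atlas_config)
        write_expression_tsv(atlas, out("atlas.tsv"))
        atlas.sample_meta.to_csv(out("sample_meta.tsv"), sep="\t")
        bait_ids = truth.all_pathway_genes()
        regulator_ids = truth.all_regulators()
        cio.write_gene_list(bait_ids, out("baits.txt"))
        cio.write_gene_list(regulator_ids, out("regulators.txt"))
        cio.write_planted_truth(truth, out("planted_truth.tsv"))
    else:
        logger.info("[load] reading atlas from %s", config.atlas_path)
        atlas = read_expression_tsv(config.atlas_path)
        bait_ids = cio.read_gene_list(config.baits_path)
        regulator_ids = cio.read_gene_list(config.regulators_path)

    logger.info("[network] ranking %d genes (%s)", atlas.n_genes, config.method)
    pre = preprocess_atlas(
        atlas, log_offset=config.log_offset, min_expression=config.min_expression
    )
    ranking = compute_similarity(pre, method=config.method)
    k_eff = min(config.k, ranking.n_genes - 1)
    if k_eff < config.k:
        logger.info("[network] k truncated to n-1 = %d for this atlas", k_eff)
    network = build_knn(ranking, k_eff)
    export_edges(network, out("edges.tsv"))

    logger.info("[select] %d baits, %d annotated regulators", len(bait_ids),
                len(regulator_ids))
    baits = BaitPanel(gene_ids=bait_ids)
    regulators = RegulatorAnnotation(gene_ids=regulator_ids)
    cap_eff = min(config.cap, k_eff)
    table = select_candidates(network, baits, regulators, cap=cap_eff)
    table.write_tsv(out("candidates.tsv"))
    relative_rank_matrix(table).to_csv(out("relative_ranks.tsv"), sep="\t")

    logger.info("[groups] partitioning %d candidates", len(table.candidates))
    groups = assign_groups(table, max_size=config.max_group_size)
    groups.write_tsv(out("groups.tsv"))

    decisions = {}
    if config.qpcr_path is not None or truth is not None:
        decisions = _screen_stage(config, outdir, out, table, groups, truth)

    manifest = {
        "parameters": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        },
        "n_genes": atlas.n_genes,
        "n_samples": atlas.n_samples,
        "k_effective": k_eff,
        "n_candidates": len(table.candidates),
        "n_groups": groups.n_groups,
        "n_advancing_groups": sum(d.advance for d in decisions.values()),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _screen_stage(config, outdir, out, table, groups, truth):
    """Screen each group through the qPCR gate.

    With an external qPCR file, each group label must appear as a
    condition.  In synthetic mode a qPCR dataset is simulated per group:
    introduced TFs are strongly overexpressed, and the group's associated
    bait genes respond (4-fold) only if the group contains a planted
    regulator of their module.
    """
    logger.info("[screen] gating %d groups", groups.n_groups)
    bait_sets = table.bait_sets()
    decisions = {}
    report_lines = []
    rows = []
    for gi, (label, members) in enumerate(groups.groups.items()):
        targets = sorted(set().union(*(bait_sets[c] for c in members)))[:8]
        if config.qpcr_path is not None:
            dataset = read_qpcr_csv(
                config.qpcr_path,
                reference_genes=["N2227", "SAND"],
                control_condition="GUS",
            )
        else:
            fcs: dict[str, dict[str, float]] = {tf: {label: 50.0} for tf in members}
            for cand in members:
                mod = truth.module_of(cand)
                if mod is not None and cand in truth.regulator_genes.get(mod, []):
                    for bait in targets:
                        if bait in truth.pathway_genes.get(mod, []):
                            fcs.setdefault(bait, {})[label] = 4.0
            design = QPCRDesign(
                conditions=[label, "GUS"],
                control_condition="GUS",
                genes=sorted(set(members) | set(targets)),
                reference_genes=["N2227", "SAND"],
                fold_changes=fcs,
                n_replicates=4,
                cq_noise_sd=0.1,
                seed=(config.seed * 100003 + gi) % (2**31),
            )
            dataset = simulate_qpcr(design)
        nrq = normalize_qpcr(dataset)
        results = fold_changes(nrq, treatment=label)
        decision = apply_gate(
            results,
            oe_genes=members,
            target_genes=targets,
            unit=label,
            oe_threshold=config.oe_threshold,
            target_threshold=config.target_threshold,
            alpha=config.alpha,
        )
        decisions[label] = decision
        report_lines.append(decision.report())
        for gene, row in results.iterrows():
            rows.append(
                {
                    "group": label,
                    "gene": gene,
                    "fc": row["fc"],
                    "p": row["p"],
                    "role": "tf" if gene in members else "target",
                }
            )
    import pandas as pd

    pd.DataFrame(rows, columns=["group", "gene", "fc", "p", "role"]).to_csv(
        out("screen_results.tsv"), sep="\t", index=False
    )
    out("screen_decisions.txt").write_text("\n\n".join(report_lines) + "\n")
    followup = followup_list(decisions, groups.groups)
    cio.write_gene_list(followup, out("followup_candidates.txt"))
    return decisions
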