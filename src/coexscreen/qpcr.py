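"""qPCR relative quantification and the overexpression screening gate.

Quantification follows the standard multi-reference-gene scheme: per
gene, Cq values are centred on the gene's mean Cq and converted to
relative quantities ``RQ = E^(meanCq - Cq)`` with amplification
efficiency E (fold per cycle, 2.0 = 100%); a per-sample normalisation
factor is the geometric mean of the reference-gene RQs; normalised
relative quantities ``NRQ = RQ / NF`` are finally calibrated per gene so
that the control-condition mean equals 1.

Fold changes between conditions are geometric-mean ratios, tested with
the classic equal-variance two-sample Student's t-test on
log2-transformed NRQs.  The screening gate advances a tested unit when
every introduced transcription factor is overexpressed more than 5-fold
and at least one target gene is up more than 2-fold with p < 0.05 (all
inequalities strict).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QPCRDataset",
    "NRQTable",
    "GateDecision",
    "normalize_qpcr",
    "fold_changes",
    "apply_gate",
    "followup_list",
    "read_qpcr_csv",
]

_REQUIRED_COLUMNS = ("sample", "condition", "gene", "cq")


@dataclasses.dataclass
class QPCRDataset:
    """Long-format Cq measurements plus reference genes and efficiencies.

    ``data`` columns: sample, condition, gene, cq.  Every condition needs
    at least two biological replicates and the reference genes must be
    measured in every sample.
    """

    data: pd.DataFrame
    reference_genes: Sequence[str]
    control_condition: str
    efficiencies: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_cols = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"qPCR data missing columns: {missing_cols}")
        if not len(self.data):
            raise ValueError("qPCR data is empty")
        if not np.isfinite(self.data["cq"].to_numpy(dtype=float)).all():
            bad = self.data.loc[~np.isfinite(self.data["cq"].astype(float))].iloc[0]
            raise ValueError(
                f"non-finite Cq for gene {bad['gene']!r} in sample {bad['sample']!r}"
            )
        if not self.reference_genes:
            raise ValueError("need at least one reference gene")
        if self.control_condition not in set(self.data["condition"]):
            raise ValueError(
                f"control condition {self.control_condition!r} absent from data"
            )
        reps = self.data.groupby("condition")["sample"].nunique()
        few = reps[reps < 2]
        if len(few):
            raise ValueError(
                f"condition {few.index[0]!r} has fewer than 2 biological replicates"
            )
        samples = set(self.data["sample"])
        for ref in self.reference_genes:
            measured = set(self.data.loc[self.data["gene"] == ref, "sample"])
            absent = samples - measured
            if absent:
                raise ValueError(
                    f"reference gene {ref!r} not measured in sample "
                    f"{sorted(absent)[0]!r}"
                )
        for gene, e in self.efficiencies.items():
            if not e > 1:
                raise ValueError(
                    f"amplification efficiency for {gene!r} must be > 1, got {e}"
                )

    def efficiency(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, 2.0))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    def condition_of(self) -> pd.Series:
        """Sample -> condition mapping (first occurrence wins)."""
        return self.data.drop_duplicates("sample").set_index("sample")["condition"]


@dataclasses.dataclass
class NRQTable:
    """Normalised relative quantities, calibrated to control mean 1 per gene.

    ``values``: samples x genes DataFrame of positive NRQs;
    ``condition``: per-sample condition labels aligned to the rows.
    """

    values: pd.DataFrame
    condition: pd.Series
    control_condition: str

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("NRQ values must be positive")
        ctrl = self.values.loc[self.condition == self.control_condition]
        err = (ctrl.mean(axis=0) - 1.0).abs().max()
        if err > 1e-9:
            raise ValueError(
                f"control-condition calibration violated (max deviation {err:.3g})"
            )


def normalize_qpcr(dataset: QPCRDataset) -> NRQTable:
    """Compute NRQs from Cq values.

    RQ(g, s) = E_g ** (meanCq_g - Cq(g, s)) with the mean over all
    samples; NF(s) = geometric mean over reference genes of RQ(ref, s);
    NRQ = RQ / NF, then rescaled per gene so the control-condition mean
    is exactly 1.
    """
    cq = dataset.data.pivot_table(
        index="sample", columns="gene", values="cq", aggfunc="mean"
    )
    if cq.isna().any().any():
        gene = cq.columns[cq.isna().any()][0]
        sample = cq.index[cq[gene].isna()][0]
        raise ValueError(f"gene {gene!r} not measured in sample {sample!r}")
    eff = np.array([dataset.efficiency(g) for g in cq.columns])
    rq = pd.DataFrame(
        np.power(eff[None, :], (cq.mean(axis=0).to_numpy()[None, :] - cq.to_numpy())),
        index=cq.index,
        columns=cq.columns,
    )
    log_nf = np.log(rq[list(dataset.reference_genes)]).mean(axis=1)
    nrq = rq.div(np.exp(log_nf), axis=0)
    condition = dataset.condition_of().loc[nrq.index]
    ctrl_mean = nrq.loc[condition == dataset.control_condition].mean(axis=0)
    nrq = nrq.div(ctrl_mean, axis=1)
    return NRQTable(
        values=nrq, condition=condition, control_condition=dataset.control_condition
    )


def fold_changes(
    nrq: NRQTable, treatment: str, control: str | None = None
) -> pd.DataFrame:
    """Per-gene fold change (treatment vs control) and two-sided p-value.

    FC is the geometric-mean ratio, i.e. ``2 ** (mean log2 NRQ_trt -
    mean log2 NRQ_ctl)``; the p-value is a classic equal-variance
    two-sample Student's t-test on the log2 NRQs.  Returns a DataFrame
    indexed by gene with columns fc, log2fc, p.
    """
    control = nrq.control_condition if control is None else control
    for label in (treatment, control):
        n = int((nrq.condition == label).sum())
        if n < 2:
            raise ValueError(f"condition {label!r} has {n} replicates, need >= 2")
    log2 = np.log2(nrq.values)
    trt = log2.loc[nrq.condition == treatment]
    ctl = log2.loc[nrq.condition == control]
    rows = {}
    for gene in log2.columns:
        a = trt[gene].to_numpy()
        b = ctl[gene].to_numpy()
        delta = a.mean() - b.mean()
        pooled_var = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if pooled_var == 0.0:
            p = 1.0 if delta == 0.0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows[gene] = {"fc": float(2.0**delta), "log2fc": float(delta), "p": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


@dataclasses.dataclass
class GateDecision:
    """Outcome of the screening gate for one tested unit (TF or group).

    All flags are pure functions of the recorded numbers and thresholds.
    """

    unit: str
    oe_fold_changes: dict[str, float]
    oe_ok: bool
    targets: pd.DataFrame  # index gene, columns fc, p, hit
    missing_targets: list[str]
    advance: bool
    triggering_targets: list[str]
    thresholds: tuple[float, float, float] = (5.0, 2.0, 0.05)

    def report(self) -> str:
        oe_thr, fc_thr, alpha = self.thresholds
        lines = [f"unit: {self.unit}"]
        for tf, fc in sorted(self.oe_fold_changes.items()):
            lines.append(f"  overexpression {tf}: {fc:.2f}-fold "
                         f"({'ok' if fc > oe_thr else 'insufficient'})")
        for gene, row in self.targets.iterrows():
            mark = "HIT" if row["hit"] else "-"
            lines.append(
                f"  target {gene}: FC={row['fc']:.2f} p={row['p']:.3g} {mark}"
            )
        for gene in self.missing_targets:
            lines.append(f"  target {gene}: not measured (treated as non-hit)")
        lines.append(f"  advance: {'yes' if self.advance else 'no'}"
                     + (f" (triggered by {', '.join(self.triggering_targets)})"
                        if self.advance else ""))
        return "\n".join(lines)


def apply_gate(
    results: pd.DataFrame,
    oe_genes: Sequence[str],
    target_genes: Sequence[str],
    unit: str = "unit",
    oe_threshold: float = 5.0,
    target_threshold: float = 2.0,
    alpha: float = 0.05,
) -> GateDecision:
    """Apply the screening gate to per-gene (fc, p) results.

    Overexpression is successful only if every introduced TF exceeds
    ``oe_threshold`` (strict); a target is a hit if its fold change
    exceeds ``target_threshold`` and p < alpha (both strict).  Targets
    absent from ``results`` are listed and treated as non-hits.
    """
    missing_oe = [g for g in oe_genes if g not in results.index]
    if missing_oe:
        raise ValueError(
            f"overexpression fold change missing for introduced TF(s): {missing_oe}"
        )
    oe_fc = {g: float(results.loc[g, "fc"]) for g in oe_genes}
    oe_ok = all(fc > oe_threshold for fc in oe_fc.values())

    present = [g for g in target_genes if g in results.index]
    missing = [g for g in target_genes if g not in results.index]
    tgt = results.loc[present, ["fc", "p"]].copy()
    tgt["hit"] = (tgt["fc"] > target_threshold) & (tgt["p"] < alpha)
    triggering = sorted(tgt.index[tgt["hit"]])
    advance = bool(oe_ok and len(triggering) > 0)
    return GateDecision(
        unit=unit,
        oe_fold_changes=oe_fc,
        oe_ok=oe_ok,
        targets=tgt,
        missing_targets=missing,
        advance=advance,
        triggering_targets=triggering,
        thresholds=(oe_threshold, target_threshold, alpha),
    )


def followup_list(
    decisions: Mapping[str, GateDecision],
    group_members: Mapping[str, Sequence[str]],
) -> list[str]:
    """Candidates to overexpress individually: members of advancing groups.

    Returns the deduplicated union in deterministic (sorted) order.
    """
    out: set[str] = set()
    for label, decision in decisions.items():
        if decision.advance:
            out.update(group_members[label])
    return sorted(out)


def read_qpcr_csv(
    path: str | Path,
    reference_genes: Iterable[str],
    control_condition: str,
    efficiency_table: str | Path | None = None,
) -> QPCRDataset:
    """Read a long-format qPCR CSV (sample, condition, gene, cq).

    An optional efficiency table CSV (gene, E) supplies per-gene
    amplification efficiencies; unlisted genes default to 2.0.
    """
    df = pd.read_csv(path)
    eff: dict[str, float] = {}
    if efficiency_table is not None:
        et = pd.read_csv(efficiency_table)
        cols = list(et.columns)
        eff = dict(zip(et[cols[0]].astype(str), et[cols[1]].astype(float)))
    return QPCRDataset(
        data=df,
        reference_genes=list(reference_genes),
        control_condition=control_condition,
        efficiencies=eff,
    )
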