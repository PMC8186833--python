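import numpy as np
import pandas as pd
import pytest

from coexscreen import (
    QPCRDataset,
    QPCRDesign,
    apply_gate,
    fold_changes,
    followup_list,
    normalize_qpcr,
    simulate_qpcr,
)
from coexscreen.qpcr import GateDecision


def _dataset(cq_map, conditions=("GUS", "OE"), reps=2, refs=("REF1", "REF2")):
    """Build a dataset from gene -> condition -> Cq (constant across reps)."""
    rows = []
    for cond in conditions:
        for rep in range(1, reps + 1):
            for gene, per_cond in cq_map.items():
                rows.append(
                    {
                        "sample": f"{cond}_r{rep}",
                        "condition": cond,
                        "gene": gene,
                        "cq": per_cond[cond],
                    }
                )
    return QPCRDataset(
        data=pd.DataFrame(rows),
        reference_genes=list(refs),
        control_condition="GUS",
    )


class TestNormalize:
    def test_flat_cq_gives_unit_nrq(self):
        ds = _dataset(
            {
                "REF1": {"GUS": 20, "OE": 20},
                "REF2": {"GUS": 22, "OE": 22},
                "TGT": {"GUS": 25, "OE": 25},
            }
        )
        nrq = normalize_qpcr(ds)
        np.testing.assert_allclose(nrq.values.to_numpy(), 1.0, atol=1e-12)

    def test_two_cycle_drop_quadruples_nrq(self):
        ds = _dataset(
            {
                "REF1": {"GUS": 20, "OE": 20},
                "REF2": {"GUS": 22, "OE": 22},
                "TGT": {"GUS": 25, "OE": 23},
            }
        )
        nrq = normalize_qpcr(ds)
        treatment = nrq.values.loc[nrq.condition == "OE", "TGT"]
        assert treatment.mean() == pytest.approx(4.0, abs=1e-9)

    def test_reference_shift_invariance(self):
        base = {
            "REF1": {"GUS": 20.0, "OE": 21.0},
            "REF2": {"GUS": 22.0, "OE": 21.5},
            "TGT": {"GUS": 25.0, "OE": 23.0},
        }
        shifted = {g: dict(v) for g, v in base.items()}
        for cond in shifted["REF1"]:
            shifted["REF1"][cond] += 3.7  # constant shift of one reference
        nrq_a = normalize_qpcr(_dataset(base)).values
        nrq_b = normalize_qpcr(_dataset(shifted)).values
        pd.testing.assert_frame_equal(nrq_a, nrq_b)

    def test_control_calibration_holds(self):
        design = QPCRDesign(
            conditions=["OE", "GUS"],
            control_condition="GUS",
            genes=["TF1", "TGT"],
            reference_genes=["N2227", "SAND"],
            fold_changes={"TGT": {"OE": 3.0}},
            cq_noise_sd=0.25,
            seed=5,
        )
        nrq = normalize_qpcr(simulate_qpcr(design))
        ctrl = nrq.values.loc[nrq.condition == "GUS"]
        np.testing.assert_allclose(ctrl.mean(axis=0), 1.0, atol=1e-9)

    def test_missing_reference_measurement_names_sample(self):
        ds = _dataset(
            {
                "REF1": {"GUS": 20, "OE": 20},
                "REF2": {"GUS": 22, "OE": 22},
                "TGT": {"GUS": 25, "OE": 24},
            }
        )
        broken = ds.data[
            ~((ds.data["gene"] == "REF2") & (ds.data["sample"] == "OE_r2"))
        ]
        with pytest.raises(ValueError, match="OE_r2"):
            QPCRDataset(
                data=broken, reference_genes=["REF1", "REF2"], control_condition="GUS"
            )

    def test_bad_efficiency_rejected(self):
        ds = _dataset(
            {"REF1": {"GUS": 20, "OE": 20}, "TGT": {"GUS": 25, "OE": 24}},
            refs=("REF1",),
        )
        with pytest.raises(ValueError, match="efficiency"):
            QPCRDataset(
                data=ds.data,
                reference_genes=["REF1"],
                control_condition="GUS",
                efficiencies={"TGT": 0.9},
            )


class TestFoldChanges:
    def test_identical_groups(self):
        ds = _dataset(
            {"REF1": {"GUS": 20, "OE": 20}, "TGT": {"GUS": 25, "OE": 25}},
            refs=("REF1",),
        )
        res = fold_changes(normalize_qpcr(ds), treatment="OE")
        assert res.loc["TGT", "fc"] == pytest.approx(1.0)
        assert res.loc["TGT", "p"] == 1.0

    def test_exact_log2_shift_with_within_group_variance(self):
        rows = []
        ctrl_log2 = [-0.5, 0.5, -1.0, 1.0]
        for i, v in enumerate(ctrl_log2, 1):
            rows.append({"sample": f"GUS_r{i}", "condition": "GUS", "gene": "TGT",
                         "cq": 25.0 - v})
            rows.append({"sample": f"GUS_r{i}", "condition": "GUS", "gene": "REF1",
                         "cq": 20.0})
            rows.append({"sample": f"OE_r{i}", "condition": "OE", "gene": "TGT",
                         "cq": 25.0 - v - 2.0})
            rows.append({"sample": f"OE_r{i}", "condition": "OE", "gene": "REF1",
                         "cq": 20.0})
        ds = QPCRDataset(
            data=pd.DataFrame(rows), reference_genes=["REF1"],
            control_condition="GUS",
        )
        res = fold_changes(normalize_qpcr(ds), treatment="OE")
        assert res.loc["TGT", "fc"] == pytest.approx(4.0, abs=1e-9)
        assert 0.0 < res.loc["TGT", "p"] < 0.05

    def test_target_shift_invariance_of_fc(self):
        base = {
            "REF1": {"GUS": 20.0, "OE": 20.5},
            "TGT": {"GUS": 25.0, "OE": 23.0},
        }
        shifted = {g: dict(v) for g, v in base.items()}
        for cond in shifted["TGT"]:
            shifted["TGT"][cond] += 2.5
        res_a = fold_changes(normalize_qpcr(_dataset(base, refs=("REF1",))), "OE")
        res_b = fold_changes(normalize_qpcr(_dataset(shifted, refs=("REF1",))), "OE")
        assert res_a.loc["TGT", "fc"] == pytest.approx(res_b.loc["TGT", "fc"])

    def test_monte_carlo_power_true_fc4(self):
        """True FC 4 at Cq noise 0.1 with n=4: estimate within [3, 5.3] and
        p < 0.05 in at least 95% of 200 simulated screens."""
        ok = 0
        for rep in range(200):
            design = QPCRDesign(
                conditions=["OE", "GUS"],
                control_condition="GUS",
                genes=["TGT"],
                reference_genes=["N2227", "SAND"],
                fold_changes={"TGT": {"OE": 4.0}},
                n_replicates=4,
                cq_noise_sd=0.1,
                seed=3_000 + rep,
            )
            res = fold_changes(normalize_qpcr(simulate_qpcr(design)), "OE")
            fc, p = res.loc["TGT", "fc"], res.loc["TGT", "p"]
            if 3.0 <= fc <= 5.3 and p < 0.05:
                ok += 1
        assert ok >= 0.95 * 200


class TestGate:
    def _results(self, rows):
        df = pd.DataFrame(rows).set_index("gene")
        return df

    def test_boundary_is_strict(self):
        res = self._results(
            [
                {"gene": "TF1", "fc": 5.0, "p": 1e-6},
                {"gene": "TGT", "fc": 2.0, "p": 0.01},
            ]
        )
        d = apply_gate(res, oe_genes=["TF1"], target_genes=["TGT"])
        assert not d.oe_ok  # 5.0 is not > 5
        assert not d.targets.loc["TGT", "hit"]  # 2.0 is not > 2
        assert not d.advance

    def test_advance_requires_oe_and_hit(self):
        res = self._results(
            [
                {"gene": "TF1", "fc": 100.0, "p": 1e-9},
                {"gene": "TGT", "fc": 3.0, "p": 0.01},
            ]
        )
        d = apply_gate(res, oe_genes=["TF1"], target_genes=["TGT"])
        assert d.oe_ok and d.advance and d.triggering_targets == ["TGT"]

    def test_p_value_gate_blocks(self):
        res = self._results(
            [
                {"gene": "TF1", "fc": 100.0, "p": 1e-9},
                {"gene": "TGT", "fc": 3.0, "p": 0.2},
            ]
        )
        d = apply_gate(res, oe_genes=["TF1"], target_genes=["TGT"])
        assert d.oe_ok and not d.advance

    def test_all_introduced_tfs_must_overexpress(self):
        res = self._results(
            [
                {"gene": "TF1", "fc": 100.0, "p": 1e-9},
                {"gene": "TF2", "fc": 2.0, "p": 0.5},
                {"gene": "TGT", "fc": 3.0, "p": 0.01},
            ]
        )
        d = apply_gate(res, oe_genes=["TF1", "TF2"], target_genes=["TGT"])
        assert not d.oe_ok and not d.advance

    def test_missing_targets_listed_as_non_hits(self):
        res = self._results([{"gene": "TF1", "fc": 100.0, "p": 1e-9}])
        d = apply_gate(res, oe_genes=["TF1"], target_genes=["TGT1", "TGT2"])
        assert d.missing_targets == ["TGT1", "TGT2"]
        assert not d.advance

    def test_missing_oe_measurement_raises(self):
        res = self._results([{"gene": "TGT", "fc": 3.0, "p": 0.01}])
        with pytest.raises(ValueError, match="TF1"):
            apply_gate(res, oe_genes=["TF1"], target_genes=["TGT"])

    def test_gate_monotone_in_target_fc(self):
        for fc in (2.1, 3.0, 10.0, 1e3):
            res = self._results(
                [
                    {"gene": "TF1", "fc": 50.0, "p": 1e-9},
                    {"gene": "TGT", "fc": fc, "p": 0.01},
                ]
            )
            assert apply_gate(res, ["TF1"], ["TGT"]).advance


class TestFollowup:
    def _decision(self, unit, advance):
        return GateDecision(
            unit=unit,
            oe_fold_changes={},
            oe_ok=advance,
            targets=pd.DataFrame(columns=["fc", "p", "hit"]),
            missing_targets=[],
            advance=advance,
            triggering_targets=[],
        )

    def test_no_advancing_group_gives_empty_list(self):
        decisions = {"G1": self._decision("G1", False)}
        assert followup_list(decisions, {"G1": ["c1", "c2"]}) == []

    def test_advancing_groups_union(self):
        decisions = {
            "G1": self._decision("G1", True),
            "G2": self._decision("G2", False),
            "G3": self._decision("G3", True),
        }
        members = {"G1": ["c4", "c1"], "G2": ["c2"], "G3": ["c3", "c1"]}
        assert followup_list(decisions, members) == ["c1", "c3", "c4"]
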