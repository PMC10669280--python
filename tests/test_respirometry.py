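"""Stage extraction, stress-test partition, and ATP-rate conversion."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant.respirometry import (
    BioenergeticConstants,
    RespTrace,
    StageLevels,
    analyze_traces,
    compute_atp_rates,
    compute_mito_stress,
    extract_stage_levels,
    group_summary,
    read_resp_csv,
    trace_recovery_check,
)
from mitoquant.synthetic import gen_resp_trace


def make_trace(ocr_by_stage, ecar_by_stage=None):
    stages, ocr = [], []
    for s, vals in ocr_by_stage.items():
        stages += [s] * len(vals)
        ocr += list(vals)
    ecar = (
        [v for s in ecar_by_stage for v in ecar_by_stage[s]]
        if ecar_by_stage
        else [10.0] * len(ocr)
    )
    return RespTrace("w1", "g", np.arange(len(ocr), dtype=float), stages, ocr, ecar)


class TestStageExtraction:
    def test_last_min_max_min_rules(self):
        tr = make_trace(
            {"basal": [95, 98, 100], "oligomycin": [45, 40, 42], "fccp": [170, 180, 175], "rot_aa": [22, 20, 21]}
        )
        lv = extract_stage_levels(tr)
        assert (lv.basal_last, lv.oligo_min, lv.fccp_max, lv.rot_aa_min) == (100, 40, 180, 20)

    def test_single_sample_per_stage_returns_that_sample(self):
        tr = make_trace({"basal": [90], "oligomycin": [30], "fccp": [150], "rot_aa": [15]})
        lv = extract_stage_levels(tr)
        assert (lv.basal_last, lv.oligo_min, lv.fccp_max, lv.rot_aa_min) == (90, 30, 150, 15)

    def test_basal_ecar_is_last_basal_value(self):
        tr = make_trace(
            {"basal": [90, 95], "oligomycin": [30], "fccp": [150], "rot_aa": [15]},
            {"basal": [18.0, 21.0], "oligomycin": [30.0], "fccp": [30.0], "rot_aa": [25.0]},
        )
        assert extract_stage_levels(tr).basal_ecar == 21.0

    def test_stage_order_violation_rejected(self):
        with pytest.raises(ValueError, match="order"):
            make_trace({"oligomycin": [40], "basal": [100], "fccp": [180], "rot_aa": [20]})

    def test_missing_stage_rejected_by_name(self):
        with pytest.raises(ValueError, match="fccp"):
            make_trace({"basal": [100], "oligomycin": [40], "rot_aa": [20]})


class TestMitoStress:
    def test_worked_partition(self):
        p = compute_mito_stress(StageLevels(100, 40, 180, 20, 20))
        assert (p.non_mito, p.basal, p.proton_leak, p.atp_linked) == (20, 80, 20, 60)
        assert (p.maximal, p.spare) == (160, 80)
        assert p.coupling_efficiency == pytest.approx(0.75)

    def test_perfect_coupling_when_oligo_hits_floor(self):
        p = compute_mito_stress(StageLevels(100, 20, 180, 20, 20))
        assert p.proton_leak == 0
        assert p.coupling_efficiency == 1.0

    def test_zero_spare_when_fccp_equals_basal(self):
        p = compute_mito_stress(StageLevels(100, 40, 100, 20, 20))
        assert p.spare == 0

    def test_no_respiration_above_floor_rejected(self):
        with pytest.raises(ValueError, match="non-mitochondrial"):
            compute_mito_stress(StageLevels(20, 15, 30, 20, 20))

    def test_negative_atp_linked_flagged_not_raised(self):
        p = compute_mito_stress(StageLevels(100, 120, 180, 20, 20))
        assert p.atp_linked < 0
        assert any("atp_linked" in w for w in p.warnings)

    @given(
        rot=st.floats(0, 50),
        leak=st.floats(0, 50),
        atp=st.floats(0.5, 100),
        extra=st.floats(0, 100),
        ecar=st.floats(0, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_identities_hold(self, rot, leak, atp, extra, ecar):
        lv = StageLevels(rot + leak + atp, rot + leak, rot + leak + atp + extra, rot, ecar)
        p = compute_mito_stress(lv)
        assert p.basal == pytest.approx(p.atp_linked + p.proton_leak, abs=1e-9)
        assert p.spare == pytest.approx(p.maximal - p.basal, abs=1e-9)
        assert 0 <= p.coupling_efficiency <= 1 + 1e-12
        r = compute_atp_rates(lv, p)
        assert r.total_atp == r.mito_atp + r.glyco_atp
        assert 0 <= r.glyco_fraction <= 1

    def test_monotonicity_in_fccp_and_oligo(self):
        base = StageLevels(100, 40, 180, 20, 20)
        higher_fccp = StageLevels(100, 40, 200, 20, 20)
        assert compute_mito_stress(higher_fccp).spare > compute_mito_stress(base).spare
        higher_oligo = StageLevels(100, 50, 180, 20, 20)
        assert (
            compute_mito_stress(higher_oligo).coupling_efficiency
            < compute_mito_stress(base).coupling_efficiency
        )


class TestATPRates:
    def test_mito_rate_from_po_ratio(self):
        lv = StageLevels(100, 40, 180, 20, 0.0)
        p = compute_mito_stress(lv)
        r = compute_atp_rates(lv, p)
        assert r.mito_atp == pytest.approx(60 * 2 * 2.75)

    def test_glyco_fraction_identity(self):
        # choose basal ECAR so the glycolysis-attributable efflux is 82.5
        consts = BioenergeticConstants()
        lv = StageLevels(100, 40, 180, 20, consts.buffer_factor * (82.5 + consts.ccf * 80))
        r = compute_atp_rates(lv, compute_mito_stress(lv))
        assert r.glyco_atp == pytest.approx(82.5)
        assert r.glyco_fraction == pytest.approx(82.5 / (330 + 82.5))

    def test_zero_ecar_gives_zero_glycolysis(self):
        lv = StageLevels(100, 40, 180, 20, 0.0)
        r = compute_atp_rates(lv, compute_mito_stress(lv))
        assert r.glyco_atp == 0.0
        assert r.glyco_fraction == 0.0
        assert any("clamped" in w for w in r.warnings)

    def test_bad_constants_rejected(self):
        with pytest.raises(ValueError):
            BioenergeticConstants(buffer_factor=0.0)


class TestRecoveryAndIO:
    def test_zero_noise_traces_reproduce_truth_exactly(self):
        traces, truth = gen_resp_trace(noise_sigma=0.0, noise_sigma_ecar=0.0, n_wells=3, seed=5)
        for tr in traces:
            p = compute_mito_stress(extract_stage_levels(tr))
            report = trace_recovery_check(truth.params, p)
            assert (report["abs_error"] == 0).all()

    def test_noisy_basal_recovery_median_error(self):
        errs = []
        for seed in range(50):
            traces, truth = gen_resp_trace(noise_sigma=2.0, n_wells=1, seed=seed)
            p = compute_mito_stress(extract_stage_levels(traces[0]))
            errs.append(abs(p.basal - truth.params.basal) / truth.params.basal)
        assert np.median(errs) <= 0.05

    def test_csv_roundtrip_and_group_summary(self):
        traces, _ = gen_resp_trace(n_wells=4, seed=2, group="ari_6")
        rows = [
            f"{tr.well_id},{tr.group},{t},{s},{o},{e}"
            for tr in traces
            for t, s, o, e in zip(tr.time_min, tr.stage, tr.ocr, tr.ecar)
        ]
        csv = "well,group,time_min,stage,ocr,ecar\n" + "\n".join(rows)
        back = read_resp_csv(io.StringIO(csv))
        assert len(back) == 4
        per_well = analyze_traces(back)
        assert len(per_well) == 4
        summary = group_summary(per_well)
        assert summary.loc[0, "basal_n"] == 4
        assert summary.loc[0, "basal_mean"] == pytest.approx(per_well["basal"].mean())
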