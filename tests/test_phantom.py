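import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lungdfi as L
from lungdfi.forward import SystemConfig, simulate_scan
from lungdfi.phantom import (
    AIRLESS_TISSUE,
    HEALTHY_LUNG,
    cohort_manifest,
    sample_longitudinal_subgroup,
    severity_from_darkfield,
    tp2_subgroup_presets,
)
from lungdfi.retrieval import retrieve


class TestCalibration:
    @pytest.mark.parametrize("A, D, T", [
        (0.788, 1.475, np.exp(-0.788)),
        (0.0, 0.0, 1.0),
        (np.log(2), 0.2, 0.5),
    ])
    def test_closed_form_inverse(self, A, D, T):
        trans, eps = L.calibrate_parenchyma(A, D)
        assert trans == pytest.approx(T, abs=1e-12)
        assert eps == pytest.approx(D, abs=1e-12)

    def test_negative_targets_rejected(self):
        with pytest.raises(ValueError):
            L.calibrate_parenchyma(-0.1, 0.0)
        with pytest.raises(ValueError):
            L.calibrate_parenchyma(0.0, -0.1)

    @settings(max_examples=40, deadline=None)
    @given(A=st.floats(0, 2.5), D=st.floats(0, 3))
    def test_simulation_roundtrip_reproduces_targets(self, A, D):
        """Any calibrated (A, D): noiseless simulate + retrieve returns it."""
        T, eps = L.calibrate_parenchyma(A, D)

        class _P:
            transmission_map = np.full((4, 4), T)
            extinction_map = np.full((4, 4), eps)
            phase_map = np.zeros((4, 4))
            shape = (4, 4)

        cfg = SystemConfig(noise="none")
        out = retrieve(simulate_scan(_P, cfg), simulate_scan(None, cfg, shape=(4, 4)))
        assert abs(out.absorption[0, 0] - A) < 1e-9
        assert abs(out.darkfield[0, 0] - D) < 1e-9

    def test_severity_interpolates_between_endpoints(self):
        assert severity_from_darkfield(HEALTHY_LUNG[1]) == 0.0
        assert severity_from_darkfield(AIRLESS_TISSUE[1]) == 1.0
        assert 0.0 < severity_from_darkfield(0.7) < 1.0


class TestThoraxPhantom:
    def test_masks_are_consistent(self, healthy_phantom):
        m = healthy_phantom.anatomy_masks
        assert not np.any(m["bone"] & (m["left_lung"] | m["right_lung"]))
        assert not np.any(m["left_lung"] & m["right_lung"])
        assert m["left_lung"].sum() > 1000 and m["right_lung"].sum() > 1000

    def test_healthy_lung_hits_calibration_exactly(self, healthy_phantom):
        ph = healthy_phantom
        left = ph.anatomy_masks["left_lung"]
        A = -np.log(ph.transmission_map)
        assert A[left].mean() == pytest.approx(HEALTHY_LUNG[0], abs=1e-9)
        assert ph.extinction_map[left].mean() == pytest.approx(HEALTHY_LUNG[1], abs=1e-9)

    def test_healthy_bronchi_continuously_traceable_in_truth(self, healthy_phantom):
        """The left lumen mask is connected from carina to the distal end."""
        from scipy.ndimage import label
        lum = healthy_phantom.anatomy_masks["bronchus_left"]
        lab, n = label(lum)
        assert n == 1

    def test_pneumothorax_extinguishes_left_hemithorax(self, pneumothorax_phantom):
        ph = pneumothorax_phantom
        H, W = ph.shape
        xx = np.arange(W)[None, :]
        hemi = ph.anatomy_masks["body"] & (xx > (256 + 42) * W / 512)
        assert ph.extinction_map[hemi].max() == 0.0
        assert (-np.log(ph.transmission_map[ph.anatomy_masks["left_lung"]])).mean() < 0.1

    def test_stenosis_distal_lumen_spans_52_columns(self, stenosis_phantom):
        """1.5 mm calibre at 29 um pixels -> 51.7 px: the widest row of the
        rendered distal lumen spans 52 pixel columns."""
        lum = stenosis_phantom.anatomy_masks["bronchus_left"]
        widths = lum[305:355].sum(axis=1)
        assert widths.max() == 52

    def test_unrenderable_stenosis_rejected(self, geometry):
        import dataclasses
        coarse = dataclasses.replace(geometry, pixel_size_um=300.0)
        with pytest.raises(ValueError, match="renderable|pixels"):
            L.build_thorax_phantom(
                coarse,
                L.PathologySpec(kind="stenosis", stenosis_fraction=0.3, atelectasis_severity=0.2),
                seed=0,
            )

    def test_pathology_spec_validation(self):
        with pytest.raises(ValueError):
            L.PathologySpec(kind="stenosis")  # missing fraction
        with pytest.raises(ValueError):
            L.PathologySpec(kind="none", stenosis_fraction=0.5)
        with pytest.raises(ValueError):
            L.PathologySpec(atelectasis_severity=1.5)


class TestCohortSampling:
    def test_preset_counts(self):
        records = L.sample_cohort(L.tp1_preset(seed=0))
        assert len(records) == 51
        analysable = [r for r in records if not r.excluded]
        assert len(analysable) == 46
        kinds = [r.pathology["TP1"].kind for r in analysable]
        assert kinds.count("stenosis") == 4
        assert kinds.count("truncation") == 10
        assert sum(r.decreased_ventilation for r in analysable) == 24

    def test_same_seed_reproduces_manifest_byte_identically(self):
        a = cohort_manifest(L.sample_cohort(L.tp1_preset(seed=9)))
        b = cohort_manifest(L.sample_cohort(L.tp1_preset(seed=9)))
        assert a == b
        c = cohort_manifest(L.sample_cohort(L.tp1_preset(seed=10)))
        assert a != c

    def test_truncation_gets_highest_severity(self):
        records = [r for r in L.sample_cohort(L.tp1_preset(seed=1)) if not r.excluded]
        sev = {k: [r.severity["TP1"] for r in records if r.pathology["TP1"].kind == k]
               for k in ("truncation", "stenosis", "none")}
        assert min(sev["truncation"]) >= max(sev["stenosis"])
        assert min(sev["stenosis"]) >= max(
            r.severity["TP1"] for r in records if r.pathology["TP1"].kind == "none"
        )

    def test_counts_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError):
            L.CohortParams(
                n_recipients=5,
                transplanted_absorption=(0.9, 0.1), transplanted_darkfield=(0.7, 0.2),
                control_absorption=(0.8, 0.1), control_darkfield=(1.5, 0.2),
                n_pneumothorax=4, n_death=2,
            )

    def test_drawn_darkfield_means_converge_to_preset(self):
        """Grand mean of transplanted dark-field draws over 200 cohorts lies
        within 3 SE of the preset mean."""
        mu, sd = L.tp1_preset().transplanted_darkfield
        vals = []
        for seed in range(200):
            for r in L.sample_cohort(L.tp1_preset(seed=seed)):
                vals.append(r.targets["TP1"]["transplanted"][1])
        vals = np.asarray(vals)
        se = sd / np.sqrt(len(vals))
        assert abs(vals.mean() - mu) < 3 * se

    def test_longitudinal_subgroup_structure(self):
        p1, p2 = tp2_subgroup_presets(seed=4)
        records = sample_longitudinal_subgroup(p1, p2)
        assert len(records) == 27
        assert all("TP1" in r.targets and "TP2" in r.targets for r in records)
        kinds1 = [r.pathology["TP1"].kind for r in records]
        assert kinds1.count("stenosis") == 2 and kinds1.count("truncation") == 6
        # resolution: fewer airway pathologies at TP2 than TP1
        irr1 = sum(k in ("stenosis", "truncation") for k in kinds1)
        kinds2 = [r.pathology["TP2"].kind for r in records]
        irr2 = sum(
            (p.kind == "truncation") or (p.kind == "stenosis" and p.stenosis_fraction < 0.7)
            for p in (r.pathology["TP2"] for r in records)
        )
        assert irr2 < irr1

    def test_tp2_marginals_preserved(self):
        p1, p2 = tp2_subgroup_presets(seed=0)
        vals = []
        for seed in range(150):
            q1, q2 = tp2_subgroup_presets(seed=seed)
            vals += [r.targets["TP2"]["transplanted"][1]
                     for r in sample_longitudinal_subgroup(q1, q2)]
        vals = np.asarray(vals)
        mu, sd = p2.transplanted_darkfield
        assert abs(vals.mean() - mu) < 3 * sd / np.sqrt(len(vals))
        assert abs(vals.std() - sd) < 0.05


class TestTubePhantom:
    def test_lumen_width_matches_request(self):
        ph = L.make_tube_phantom(1.0)
        widths = ph.anatomy_masks["bronchus_left"][40:200].sum(axis=1)
        expect = 1.0 / 0.029
        assert abs(widths.max() - expect) <= 1.0

    def test_too_small_tube_rejected(self):
        with pytest.raises(ValueError):
            L.make_tube_phantom(0.02)
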