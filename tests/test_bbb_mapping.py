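"""Subtraction maps, SSS normalization and ROI readout."""

import numpy as np
import pytest

from qt1bbb import PhantomSpec, QT1Volume, compute_delta, normalize_by_sss, roi_readout, simulate_sessions
from qt1bbb.bbb_mapping import DeltaQT1Map, NormalizationError

NOISELESS = dict(noise_sd=0.0, perturb_translation_mm=0.0, perturb_rotation_deg=0.0)


@pytest.fixture(scope="module")
def noiseless_sessions():
    return simulate_sessions(PhantomSpec(leakage_interictal={"piriform": 0.1}, **NOISELESS))


class TestComputeDelta:
    def test_identical_volumes_give_zero_map(self, noiseless_sessions):
        ses = noiseless_sessions
        nc2 = ses.noncontrast.with_session("interictal")
        dmap = compute_delta(ses.noncontrast, nc2, "ni")
        assert np.all(dmap.data[dmap.mask] == 0.0)

    def test_printed_subtraction_order(self):
        nc = QT1Volume(np.full((2, 2, 2), 1200.0), session="noncontrast")
        ii = QT1Volume(np.full((2, 2, 2), 1100.0), session="interictal")
        pi = QT1Volume(np.full((2, 2, 2), 1000.0), session="postictal")
        assert compute_delta(nc, ii, "ni").data[0, 0, 0] == 100.0
        assert compute_delta(ii, pi, "ip").data[0, 0, 0] == 100.0

    def test_wrong_session_labels_rejected(self):
        nc = QT1Volume(np.ones((2, 2, 2)), session="noncontrast")
        pi = QT1Volume(np.ones((2, 2, 2)), session="postictal")
        with pytest.raises(ValueError):
            compute_delta(nc, pi, "ni")
        with pytest.raises(ValueError):
            compute_delta(nc, pi, "ip")

    def test_grid_mismatch_rejected(self):
        a = QT1Volume(np.ones((2, 2, 2)), session="noncontrast")
        b = QT1Volume(np.ones((3, 2, 2)), session="interictal")
        with pytest.raises(ValueError):
            compute_delta(a, b, "ni")
        c = QT1Volume(np.ones((2, 2, 2)), np.diag([2.0, 1, 1, 1]), "interictal")
        with pytest.raises(ValueError):
            compute_delta(a, c, "ni")

    def test_mask_is_intersection(self):
        a = QT1Volume(np.ones((2, 2, 2)), session="noncontrast")
        data = np.ones((2, 2, 2))
        data[0, 0, 0] = np.nan
        b = QT1Volume(data, session="interictal")
        dmap = compute_delta(a, b, "ni")
        assert not dmap.mask[0, 0, 0] and dmap.mask.sum() == 7


class TestNormalizeBySSS:
    def test_division_by_sss_mean(self, noiseless_sessions):
        ses = noiseless_sessions
        dmap = compute_delta(ses.noncontrast, ses.interictal, "ni")
        norm = normalize_by_sss(dmap, ses.labels)
        sss = ses.labels.mask("sss")
        assert np.mean(norm.data[sss]) == pytest.approx(1.0, abs=1e-12)
        assert norm.sss_mean == pytest.approx(ses.truth[("ni", "sss")], rel=1e-12)
        np.testing.assert_allclose(norm.data[norm.mask] * norm.sss_mean,
                                   dmap.data[dmap.mask], rtol=1e-12)

    def test_scale_invariance(self, noiseless_sessions):
        ses = noiseless_sessions
        dmap = compute_delta(ses.noncontrast, ses.interictal, "ni")
        scaled = DeltaQT1Map(dmap.data * 7.0, "ni", dmap.affine, dmap.mask)
        a = normalize_by_sss(dmap, ses.labels)
        b = normalize_by_sss(scaled, ses.labels)
        np.testing.assert_allclose(b.data[b.mask], a.data[a.mask], rtol=1e-12)

    def test_zero_sss_mean_raises(self, noiseless_sessions):
        ses = noiseless_sessions
        zero = DeltaQT1Map(np.zeros(ses.labels.data.shape), "ni",
                           mask=ses.labels.data > 0)
        with pytest.raises(NormalizationError):
            normalize_by_sss(zero, ses.labels)

    def test_double_normalization_rejected(self, noiseless_sessions):
        ses = noiseless_sessions
        norm = normalize_by_sss(compute_delta(ses.noncontrast, ses.interictal, "ni"),
                                ses.labels)
        with pytest.raises(ValueError):
            normalize_by_sss(norm, ses.labels)


class TestROIReadout:
    def test_constant_roi_mean_and_zero_sd(self, noiseless_sessions):
        ses = noiseless_sessions
        dmap = compute_delta(ses.noncontrast, ses.interictal, "ni")
        df = roi_readout(dmap, ses.labels, rois=("cortex",))
        row = df.iloc[0]
        assert row["mean"] == 0.0 and row["sd"] == 0.0
        assert row["n_voxels"] == int(ses.labels.mask("cortex").sum())

    def test_hand_computed_mean_and_sample_sd(self, noiseless_sessions):
        ses = noiseless_sessions
        data = np.full(ses.labels.data.shape, np.nan)
        m = ses.labels.mask("sss")
        idx = np.argwhere(m)[:3]
        data[tuple(idx.T)] = [1.0, 2.0, 3.0]
        dmap = DeltaQT1Map(data, "ni")
        df = roi_readout(dmap, ses.labels, rois=("sss",))
        assert df.iloc[0]["mean"] == pytest.approx(2.0)
        assert df.iloc[0]["sd"] == pytest.approx(1.0)  # sample SD of {1,2,3}
        assert df.iloc[0]["n_voxels"] == 3

    def test_fully_invalid_roi_yields_missing_value(self, noiseless_sessions):
        ses = noiseless_sessions
        data = np.full(ses.labels.data.shape, np.nan)
        dmap = DeltaQT1Map(data, "ni")
        with pytest.warns(UserWarning):
            df = roi_readout(dmap, ses.labels, rois=("piriform",))
        assert np.isnan(df.iloc[0]["mean"]) and df.iloc[0]["n_voxels"] == 0

    def test_hemisphere_filter_selects_one_side(self, noiseless_sessions):
        ses = noiseless_sessions
        dmap = normalize_by_sss(compute_delta(ses.noncontrast, ses.interictal, "ni"),
                                ses.labels)
        left = roi_readout(dmap, ses.labels, rois=("piriform",), hemisphere="left")
        right = roi_readout(dmap, ses.labels, rois=("piriform",), hemisphere="right")
        both = roi_readout(dmap, ses.labels, rois=("piriform",))
        assert left.iloc[0]["n_voxels"] + right.iloc[0]["n_voxels"] == both.iloc[0]["n_voxels"]


class TestBiomarkerProperties:
    def test_noiseless_roi_means_match_ground_truth_exactly(self, noiseless_sessions):
        ses = noiseless_sessions
        dmap = compute_delta(ses.noncontrast, ses.interictal, "ni")
        df = roi_readout(dmap, ses.labels).set_index("roi")
        for roi in ("cortex", "hippocampus", "amygdala", "piriform"):
            assert df.loc[roi, "mean"] == pytest.approx(ses.truth[("ni", roi)], abs=1e-9)

    def test_leakage_ordering_is_monotone_and_cortex_unchanged(self):
        cortex_means, piriform_means = [], []
        for lam in (0.0, 0.05, 0.1, 0.2):
            ses = simulate_sessions(
                PhantomSpec(leakage_interictal={"piriform": lam}, **NOISELESS)
            )
            norm = normalize_by_sss(compute_delta(ses.noncontrast, ses.interictal, "ni"),
                                    ses.labels)
            df = roi_readout(norm, ses.labels).set_index("roi")
            cortex_means.append(df.loc["cortex", "mean"])
            piriform_means.append(df.loc["piriform", "mean"])
        assert np.all(np.diff(piriform_means) > 0)
        np.testing.assert_allclose(cortex_means, cortex_means[0], atol=1e-12)
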