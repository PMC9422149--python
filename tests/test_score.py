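import numpy as np
import pandas as pd
import pytest

from cortexscore import (
    BinningSpec,
    DataError,
    ValidationError,
    bin_index,
    fit_score_model,
    kernel_weights,
    load_model,
    probability_matrix,
    save_model,
    score_matrix,
    total_score,
)
from cortexscore.grouping import GroupWindows, assign_groups, mean_thickness
from cortexscore.roi import ROISet
from cortexscore.score import ScoreMatrix, classify_images


class TestBinning:
    def test_examples(self):
        b = BinningSpec()
        assert bin_index(2.5, b) == 13
        assert bin_index(0.0, b) == 1
        assert bin_index(0.2, b) == 2  # boundary belongs to the upper bin
        assert bin_index(5.999, b) == 30

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            bin_index(6.0)
        with pytest.raises(ValidationError):
            bin_index(-0.01)

    def test_binning_spec_must_cover_six_mm(self):
        with pytest.raises(ValidationError):
            BinningSpec(delta=0.2, m_max=25)
        assert BinningSpec(delta=0.1, m_max=60).upper == pytest.approx(6.0)


class TestKernel:
    def test_integer_ratio_values(self):
        k = kernel_weights("integer-ratio")
        assert k.weights[4] == pytest.approx(56 / 200)
        assert k.weights[0] == pytest.approx(1 / 200)
        assert sum(k.weights) == pytest.approx(1.0, abs=1e-15)
        assert k.sigma == pytest.approx(1.435, abs=5e-4)

    def test_erf_recursion_mass_and_symmetry(self):
        k = kernel_weights("erf-recursion")
        assert k.mass == pytest.approx(1.0, abs=0.01)
        w = np.asarray(k.weights)
        assert np.allclose(w, w[::-1])
        assert w[4] == max(w)

    def test_delta_is_a_point_mass(self):
        k = kernel_weights("delta")
        assert k.weights[4] == 1.0 and k.mass == 1.0 and k.sigma == 0.0

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            kernel_weights("gaussian")


def _pmatrix(values, vertex_ids, metadata, cohort, kernel):
    matrix = pd.DataFrame(values, index=vertex_ids,
                          columns=metadata["image_id"].tolist())
    roi = ROISet(group="A", cutoff=0.0, vertex_ids=np.array(vertex_ids))
    return probability_matrix(matrix, metadata, roi, cohort, kernel=kernel)


def _meta(cohorts):
    ids = [f"i{j}" for j in range(len(cohorts))]
    return pd.DataFrame({"image_id": ids, "subject_id": ids, "cohort": cohorts})


class TestProbabilityMatrix:
    def test_delta_kernel_hand_count(self):
        P = _pmatrix([[2.5, 2.7]], ["v1"], _meta(["CN", "CN"]), "CN", kernel_weights("delta"))
        assert P.values[0, 12] == 0.5 and P.values[0, 13] == 0.5
        assert P.values.sum() == pytest.approx(1.0)

    def test_integer_kernel_convolution_by_hand(self):
        P = _pmatrix([[2.5]], ["v1"], _meta(["CN"]), "CN", kernel_weights("integer-ratio"))
        expected = np.zeros(30)
        expected[8:17] = np.array([1, 7, 21, 43, 56, 43, 21, 7, 1]) / 200
        assert np.allclose(P.values[0], expected, atol=1e-15)

    def test_edge_truncation_is_recorded(self):
        P = _pmatrix([[0.1]], ["v1"], _meta(["CN"]), "CN", kernel_weights("integer-ratio"))
        # bin 1: offsets -4..-1 fall off the lower edge
        assert P.values[0].sum() == pytest.approx((56 + 43 + 21 + 7 + 1) / 200)
        assert P.truncated[0] == pytest.approx((1 + 7 + 21 + 43) / 200)
        assert P.values[0].sum() + P.truncated[0] == pytest.approx(1.0)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(DataError):
            _pmatrix([[2.5]], ["v1"], _meta(["CN"]), "AD", kernel_weights("delta"))


class TestScoreMatrix:
    def test_uniform_rows_closed_form(self):
        # two vertices, each uniform over the 30 bins: S = -ln((1/30)/(1/2)) = ln 15
        P = _pmatrix([[0.1 + 0.2 * k for k in range(30)],
                      [0.1 + 0.2 * k for k in range(30)]],
                     ["v1", "v2"], _meta(["CN"] * 30), "CN", kernel_weights("delta"))
        S = score_matrix(P)
        assert np.allclose(S.values, np.log(15.0), atol=1e-12)

    def test_zero_probability_entries_capped(self):
        P = _pmatrix([[2.5, 2.7]], ["v1"], _meta(["CN", "CN"]), "CN", kernel_weights("delta"))
        S = score_matrix(P, cap=50.0)
        assert S.values[0, 0] == 50.0
        assert (S.values[0] == 50.0).sum() == 28

    def test_score_strictly_decreasing_in_probability(self):
        P = _pmatrix([[2.11, 2.13, 2.13, 2.33]], ["v1"], _meta(["CN"] * 4), "CN",
                     kernel_weights("integer-ratio"))
        S = score_matrix(P)
        p, s = P.values[0], S.values[0]
        nz = p > 0
        order = np.argsort(p[nz])
        assert (np.diff(s[nz][order]) <= 1e-12).all()

    def test_delta_mode_simplification(self):
        """With point-mass rows summing to 1, S = -ln P - ln N_p where P > 0."""
        rng = np.random.default_rng(4)
        vals = rng.uniform(2.0, 3.0, size=(6, 40))
        P = _pmatrix(vals, [f"v{i}" for i in range(6)], _meta(["CN"] * 40), "CN",
                     kernel_weights("delta"))
        assert np.allclose(P.values.sum(axis=1), 1.0, atol=1e-12)
        S = score_matrix(P)
        nz = P.values > 0
        expected = -np.log(P.values[nz]) + np.log(1.0 / 6)
        assert np.allclose(S.values[nz], expected, atol=1e-10)

    def test_all_zero_row_is_an_error(self):
        P = _pmatrix([[2.5]], ["v1"], _meta(["CN"]), "CN", kernel_weights("delta"))
        P.values[0] = 0.0
        with pytest.raises(DataError):
            score_matrix(P)


def _toy_smatrices(values_by_cohort, vertex_ids):
    out = {}
    for k, vals in values_by_cohort.items():
        out[k] = ScoreMatrix(cohort=k, vertex_ids=np.array(vertex_ids),
                             values=np.asarray(vals, float), cap=50.0)
    return out


class TestTotalScore:
    def test_argmin_and_tie_break(self):
        v = np.zeros((1, 30))
        sm = _toy_smatrices({"CN": v + 10, "MCI": v + 12, "AD": v + 15}, ["v1"])
        got = total_score(pd.Series({"v1": 2.5}), sm)
        assert got.predicted == "CN" and got.scores == {"CN": 10, "MCI": 12, "AD": 15}
        sm = _toy_smatrices({"CN": v + 10, "MCI": v + 10, "AD": v + 15}, ["v1"])
        assert total_score(pd.Series({"v1": 2.5}), sm).predicted == "CN"

    def test_single_vertex_model_prefers_low_score_cohort(self):
        cn = np.full((1, 30), 5.0)
        ad = np.full((1, 30), 5.0)
        ad[0, 12] = 1.0  # bin of t = 2.5
        sm = _toy_smatrices({"CN": cn, "MCI": cn + 1, "AD": ad}, ["v1"])
        assert total_score(pd.Series({"v1": 2.5}), sm).predicted == "AD"

    def test_missing_vertex_is_an_error(self):
        sm = _toy_smatrices({"CN": np.zeros((1, 30)), "MCI": np.zeros((1, 30)),
                             "AD": np.zeros((1, 30))}, ["v1"])
        with pytest.raises(DataError):
            total_score(pd.Series({"v2": 2.5}), sm)

    def test_classification_invariant_under_constant_score_shift(
        self, toy_matrix, toy_metadata, single_window
    ):
        model = _fit_toy(toy_matrix, toy_metadata, single_window)
        before = classify_images(model, toy_matrix)["predicted"]
        for gm in model.groups.values():
            for k in gm.S:
                gm.S[k].values = gm.S[k].values + 7.5
        after = classify_images(model, toy_matrix)["predicted"]
        assert (before == after).all()


def _fit_toy(matrix, metadata, windows, kernel=None):
    means = mean_thickness(matrix)
    assignment = assign_groups(means, windows)
    roisets = {"A": ROISet(group="A", cutoff=0.0, vertex_ids=matrix.index.to_numpy(), essential=True)}
    return fit_score_model(matrix, metadata, assignment, windows, roisets,
                           kernel=kernel or kernel_weights())


class TestFitScoreModel:
    def test_missing_cohort_error_names_group_and_cohort(self, toy_matrix, toy_metadata, single_window):
        meta = toy_metadata[toy_metadata["cohort"] != "MCI"]
        with pytest.raises(DataError, match="group A.*MCI"):
            _fit_toy(toy_matrix, meta, single_window)

    def test_delta_and_smoothed_kernels_agree_on_modal_bins(self, toy_matrix, toy_metadata, single_window):
        delta = _fit_toy(toy_matrix, toy_metadata, single_window, kernel_weights("delta"))
        smooth = _fit_toy(toy_matrix, toy_metadata, single_window, kernel_weights("integer-ratio"))
        for k in ("CN", "MCI", "AD"):
            pd_ = delta.groups["A"].P[k].values
            ps = smooth.groups["A"].P[k].values
            assert ((ps > 0).sum(axis=1) >= (pd_ > 0).sum(axis=1)).all()  # smoother rows
            # where the point-mass histogram has a unique mode, smoothing keeps it
            for p in range(pd_.shape[0]):
                top = pd_[p].max()
                if (pd_[p] == top).sum() == 1:
                    assert pd_[p].argmax() == ps[p].argmax()

    def test_model_serialization_round_trips_bit_identically(
        self, tmp_path, toy_matrix, toy_metadata, single_window
    ):
        model = _fit_toy(toy_matrix, toy_metadata, single_window)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.windows.windows == model.windows.windows
        for label, gm in model.groups.items():
            bm = back.groups[label]
            assert list(bm.vertex_ids) == list(gm.vertex_ids)
            for k in gm.S:
                assert (bm.S[k].values == gm.S[k].values).all()
                assert (bm.P[k].values == gm.P[k].values).all()
            assert (bm.train_mean == gm.train_mean).all()
            assert (bm.train_sigma == gm.train_sigma).all()
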