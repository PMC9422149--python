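import numpy as np
import pandas as pd
import pytest

from cortexscore import (
    DataError,
    covariance_correlation,
    fit_severity,
    normalize_profiles,
    reorder_by_severity,
    severity_degree,
    severity_for_new,
)


def _four_image_profiles():
    """CN1=(1,0), CN2=(0,1), AD1=(-1,0), AD2=(0,-1) as normalised profiles."""
    tp = pd.DataFrame(
        [[1.0, 0.0, -1.0, 0.0], [0.0, 1.0, 0.0, -1.0]],
        index=["v1", "v2"], columns=["CN1", "CN2", "AD1", "AD2"],
    )
    cohorts = pd.Series({"CN1": "CN", "CN2": "CN", "AD1": "AD", "AD2": "AD"})
    return tp, cohorts


def test_normalize_hand_example_and_idempotence():
    m = pd.DataFrame([[2.0, 2.2]], index=["v1"], columns=["i1", "i2"])
    prof = normalize_profiles(m)
    assert np.allclose(prof.values.to_numpy(), [[-1.0, 1.0]])
    assert prof.sigma["v1"] == pytest.approx(0.1)  # population convention
    again = normalize_profiles(prof.values)
    assert np.allclose(again.values.to_numpy(), prof.values.to_numpy(), atol=1e-12)


def test_constant_vertex_is_an_error_naming_it():
    m = pd.DataFrame([[2.0, 2.0], [2.0, 2.2]], index=["flat", "ok"], columns=["i1", "i2"])
    with pytest.raises(DataError, match="flat"):
        normalize_profiles(m)


def test_covariance_correlation_hand_gram():
    tp, _ = _four_image_profiles()
    C = covariance_correlation(tp)
    assert C.max_gram == pytest.approx(1.0)
    vals = C.values
    assert np.allclose(np.diag(vals), 1.0)
    assert vals.loc["CN1", "AD1"] == pytest.approx(-1.0)
    assert vals.loc["CN1", "CN2"] == pytest.approx(0.0)
    assert np.allclose(vals, vals.T)


def test_duplicated_profile_has_unit_correlation():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(2.5, 0.1, size=(10, 3)),
                     index=[f"v{i}" for i in range(10)], columns=["a", "b", "c"])
    m["twin"] = m["a"]
    C = covariance_correlation(normalize_profiles(m))
    assert C.values.loc["a", "twin"] == pytest.approx(C.values.loc["a", "a"], abs=1e-12)


def test_severity_four_subject_example():
    tp, cohorts = _four_image_profiles()
    C = covariance_correlation(tp)
    table, constants = severity_degree(C, cohorts)
    assert np.allclose(table["cbar_ad_cn"], [-1.0, -1.0, 1.0, 1.0])
    assert np.allclose(table["SD"], [0.0, 0.0, 1.0, 1.0])
    assert constants["cbar_ad"] - constants["cbar_cn"] == pytest.approx(2.0)


@pytest.mark.parametrize("seed", [0, 1, 5])
@pytest.mark.parametrize("include_self", [True, False])
def test_anchor_identities_hold_exactly(seed, include_self):
    """Mean SD over CN is 0 and over AD is 1 on any data, by construction."""
    rng = np.random.default_rng(seed)
    n = 24
    m = pd.DataFrame(rng.normal(2.5, 0.2, size=(15, n)),
                     index=[f"v{i}" for i in range(15)],
                     columns=[f"i{j}" for j in range(n)])
    cohorts = pd.Series(rng.permutation(["CN"] * 8 + ["MCI"] * 8 + ["AD"] * 8), index=m.columns)
    table, _, _ = fit_severity(m, cohorts, include_self=include_self)
    assert table.loc[cohorts == "CN", "SD"].mean() == pytest.approx(0.0, abs=1e-10)
    assert table.loc[cohorts == "AD", "SD"].mean() == pytest.approx(1.0, abs=1e-10)


def test_sd_invariant_under_positive_scaling_of_profiles():
    tp, cohorts = _four_image_profiles()
    base, _ = severity_degree(covariance_correlation(tp), cohorts)
    scaled, _ = severity_degree(covariance_correlation(tp * 3.7), cohorts)
    assert np.allclose(base["SD"], scaled["SD"], atol=1e-12)


class TestSeverityForNew:
    def _model(self, seed=3):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(2.5, 0.2, size=(20, 18)),
                         index=[f"v{i}" for i in range(20)],
                         columns=[f"i{j}" for j in range(18)])
        m.iloc[:5, 12:] -= 0.5  # make AD images distinct
        cohorts = pd.Series(["CN"] * 6 + ["MCI"] * 6 + ["AD"] * 6, index=m.columns)
        table, C, model = fit_severity(m, cohorts)
        return m, cohorts, table, model

    def test_training_image_reproduces_its_training_sd(self):
        m, _, table, model = self._model()
        got = severity_for_new(m[["i13"]], model)
        assert got["i13"] == pytest.approx(table.loc["i13", "SD"], abs=1e-10)

    def test_cn_centroid_scores_near_zero(self):
        m, cohorts, _, model = self._model()
        centroid = m.loc[:, cohorts == "CN"].mean(axis=1).to_frame("q")
        got = severity_for_new(centroid, model)
        assert abs(got["q"]) < 0.15

    def test_interpolated_profile_is_monotone_in_lambda(self):
        m, cohorts, _, model = self._model()
        cn = m.loc[:, cohorts == "CN"].mean(axis=1)
        ad = m.loc[:, cohorts == "AD"].mean(axis=1)
        lams = np.linspace(0, 1, 11)
        queries = pd.DataFrame({f"q{i}": (1 - lam) * cn + lam * ad for i, lam in enumerate(lams)})
        sd = severity_for_new(queries, model)
        assert (np.diff(sd.to_numpy()) >= -1e-12).all()


def test_reorder_by_severity_idempotent_and_blockwise():
    rng = np.random.default_rng(7)
    ids = [f"i{j}" for j in range(12)]
    C = pd.DataFrame(rng.normal(size=(12, 12)), index=ids, columns=ids)
    C = (C + C.T) / 2
    table = pd.DataFrame(
        {
            "cohort": ["MCI"] * 4 + ["AD"] * 4 + ["CN"] * 4,
            "SD": rng.uniform(-0.2, 1.2, 12),
        },
        index=ids,
    )
    perm, C1 = reorder_by_severity(C, table)
    perm2, C2 = reorder_by_severity(C1, table)
    assert perm2 == perm  # same final order: idempotent
    assert np.allclose(C1.to_numpy(), C2.to_numpy())
    blocks = table.loc[perm, "cohort"].to_numpy()
    assert list(blocks) == ["CN"] * 4 + ["MCI"] * 4 + ["AD"] * 4
    sd_sorted = table.loc[perm, "SD"]
    for k in ("CN", "MCI", "AD"):
        assert sd_sorted[blocks == k].is_monotonic_increasing


def test_planted_block_structure_in_reordered_matrix(separated_study, separated_fit):
    """AD images correlate more with each other than with CN images."""
    from cortexscore import severity_by_group

    matrix, metadata, _ = separated_study
    table, per_group = severity_by_group(matrix, metadata, separated_fit.assignment,
                                         separated_fit.essential)
    label, (C, _model) = next(iter(per_group.items()))
    cohorts = table.loc[C.values.index, "cohort"]
    vals = C.values.to_numpy()
    ad = (cohorts == "AD").to_numpy()
    cn = (cohorts == "CN").to_numpy()
    within_ad = vals[np.ix_(ad, ad)][np.triu_indices(ad.sum(), 1)].mean()
    between = vals[np.ix_(ad, cn)].mean()
    assert within_ad > between
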