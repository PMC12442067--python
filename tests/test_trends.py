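import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pyreneclar.annelation import PATTERNS
from pyreneclar.clar import pattern_delta_clar
from pyreneclar.trends import (FitModel, HARTREE_TO_KCALMOL, TrendsError,
                               check_gap_consistency, fit_erel_model,
                               pattern_summary, predict_erel,
                               regress_property_vs_deltaclar, relative_energy,
                               _sample_strain_averages)

TABLE_ORDER = ["aa", "aab", "a", "aabb", "ab", "abb", "b", "bb"]


def pattern_points(alpha=0.8, beta=-0.3, gamma=13.4, noise=None, rng=None):
    """The 8 pattern-level points with E_rel on a given plane."""
    avg = _sample_strain_averages()
    rows = []
    for p in PATTERNS:
        dc = pattern_delta_clar(p).delta_clar
        erel = alpha * avg[p] + beta * dc + gamma
        if noise:
            erel += rng.normal(0.0, noise)
        rows.append({"pattern": p, "n_strain_avg": avg[p], "delta_clar": dc,
                     "Erel_kcalmol_mean": erel})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relative energy


def test_relative_energy_hartree_conversion():
    df = pd.DataFrame({"id": ["x", "y"], "n_rings": [5, 5],
                       "Etot": [-100.0, -99.99], "Etot_unit": ["hartree"] * 2})
    out = relative_energy(df)
    assert out["Erel_kcalmol"].tolist() == pytest.approx([0.0, 6.275095])


def test_relative_energy_groupwise_minimum():
    df = pd.DataFrame({"id": list("abcd"), "n_rings": [5, 5, 6, 6],
                       "Etot": [3.0, 1.0, 10.0, 10.0],
                       "Etot_unit": ["kcal/mol"] * 4})
    out = relative_energy(df)
    assert out["Erel_kcalmol"].tolist() == [2.0, 0.0, 0.0, 0.0]


def test_relative_energy_translation_invariant():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"id": range(6), "n_rings": [5] * 3 + [6] * 3,
                       "Etot": rng.normal(size=6), "Etot_unit": ["kcal/mol"] * 6})
    base = relative_energy(df)["Erel_kcalmol"]
    shifted = df.assign(Etot=df["Etot"] + 42.0)
    assert relative_energy(shifted)["Erel_kcalmol"].tolist() == pytest.approx(
        base.tolist())


def test_relative_energy_rejects_mixed_units():
    df = pd.DataFrame({"id": ["x", "y"], "n_rings": [5, 5],
                       "Etot": [0.0, 1.0], "Etot_unit": ["hartree", "kcal/mol"]})
    with pytest.raises(TrendsError, match="mixed"):
        relative_energy(df)


def test_gap_consistency_flags_violations():
    df = pd.DataFrame({"HOMO_eV": [-5.0, -5.0], "LUMO_eV": [-1.0, -1.0],
                       "gap_eV": [4.0, 4.5]})
    assert check_gap_consistency(df).index.tolist() == [1]


# ---------------------------------------------------------------------------
# summaries


def test_pattern_summary_identity_pipe():
    """A property equal to delta_clar summarises to the Clar table."""
    rows = []
    for p in PATTERNS:
        dc = pattern_delta_clar(p).delta_clar
        for k in range(3):
            rows.append({"id": f"{p}{k}", "pattern": p, "gap_eV": float(dc)})
    summary = pattern_summary(pd.DataFrame(rows), properties=["gap_eV"])
    for _, row in summary.iterrows():
        assert row["gap_eV_mean"] == row["delta_clar"]
        assert row["gap_eV_sd"] == 0.0


def test_pattern_summary_order_invariant():
    rng = np.random.default_rng(5)
    rows = pd.DataFrame({
        "id": [str(i) for i in range(40)],
        "pattern": rng.choice(PATTERNS, size=40),
        "gap_eV": rng.normal(size=40),
    })
    a = pattern_summary(rows, properties=["gap_eV"])
    b = pattern_summary(rows.sample(frac=1, random_state=0), properties=["gap_eV"])
    pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                  b.reset_index(drop=True))


def test_pattern_summary_rejects_unclassified():
    df = pd.DataFrame({"id": ["x"], "gap_eV": [1.0]})
    with pytest.raises(TrendsError):
        pattern_summary(df)
    with pytest.raises(TrendsError, match="unclassified"):
        pattern_summary(df, patterns={})


def test_sample_strain_averages():
    avg = _sample_strain_averages()
    assert avg["a"] == pytest.approx(1.0)
    assert avg["ab"] == pytest.approx((5.0 + 2.4) / 2)
    assert avg["aab"] == pytest.approx((8.6 + 6.0 + 3.4) / 3)
    assert avg["aabb"] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# regressions


def test_regression_recovers_exact_line():
    df = pd.DataFrame({"delta_clar": [-2, -1, 0, 1, 2],
                       "gap_eV_mean": [2 * x + 1 for x in (-2, -1, 0, 1, 2)]})
    out = regress_property_vs_deltaclar(df, "gap_eV")
    assert out.loc[0, "slope"] == pytest.approx(2.0)
    assert out.loc[0, "intercept"] == pytest.approx(1.0)
    assert out.loc[0, "r_squared"] == pytest.approx(1.0)


def test_regression_constant_property():
    df = pd.DataFrame({"delta_clar": [-2, 0, 2], "gap_eV_mean": [1.0] * 3})
    out = regress_property_vs_deltaclar(df, "gap_eV")
    assert out.loc[0, "slope"] == 0.0
    assert np.isnan(out.loc[0, "r_squared"])


def test_regression_skips_degenerate_subgroups():
    df = pd.DataFrame({"delta_clar": [-2, 0, 2, 0], "gap_eV_mean": [1, 2, 3, 4.0],
                       "n_rings": [5, 5, 5, 6]})
    out = regress_property_vs_deltaclar(df, "gap_eV", split="n_rings")
    assert out["group"].tolist() == [5]


def test_regression_size_split_preserves_slope_ordering():
    """Steeper simulated slopes in smaller molecules stay steeper."""
    rows = []
    for n_rings, slope in [(5, -0.5), (8, -0.1)]:
        for dc in (-2, -1, 0, 1, 2, 3, 4):
            rows.append({"n_rings": n_rings, "delta_clar": dc,
                         "gap_eV_mean": slope * dc + 4.0})
    out = regress_property_vs_deltaclar(pd.DataFrame(rows), "gap_eV",
                                        split="n_rings").set_index("group")
    assert out.loc[5, "slope"] < out.loc[8, "slope"] < 0


# ---------------------------------------------------------------------------
# the E_rel model


def test_fit_recovers_exact_plane():
    model = fit_erel_model(pattern_points())
    assert model.alpha == pytest.approx(0.8)
    assert model.beta == pytest.approx(-0.3)
    assert model.gamma == pytest.approx(13.4)
    assert model.r_squared == pytest.approx(1.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5), gamma=st.floats(-50, 50))
def test_fit_recovers_any_exact_plane(alpha, beta, gamma):
    assume(abs(alpha) + abs(beta) > 1e-6)  # flat planes have undefined R²
    model = fit_erel_model(pattern_points(alpha, beta, gamma))
    assert model.alpha == pytest.approx(alpha, abs=1e-8)
    assert model.beta == pytest.approx(beta, abs=1e-8)
    assert model.gamma == pytest.approx(gamma, abs=1e-8)


def test_fit_noise_bias_vanishes():
    """Mean coefficient error shrinks as the noise level drops."""
    biases = []
    for sigma in (2.0, 0.5, 0.05):
        rng = np.random.default_rng(42)
        alphas = [fit_erel_model(pattern_points(noise=sigma, rng=rng)).alpha
                  for _ in range(50)]
        biases.append(abs(np.mean(alphas) - 0.8))
        se = np.std(alphas, ddof=1) / np.sqrt(len(alphas))
        assert abs(np.mean(alphas) - 0.8) < 3 * se + 1e-9
    assert biases[-1] < biases[0]
    assert biases[-1] < 0.01


def test_fit_requires_enough_points():
    with pytest.raises(TrendsError, match="at least 4"):
        fit_erel_model(pattern_points().head(3))


def test_predicted_pattern_order():
    """Model predictions order the patterns b < a < bb < aa < ab < abb < aab < aabb."""
    model = FitModel(alpha=0.8, beta=-0.3, gamma=13.4, r_squared=1.0)
    points = pattern_points()
    pred = {row.pattern: predict_erel(model, row.n_strain_avg, row.delta_clar)
            for row in points.itertuples()}
    ordered = sorted(pred, key=pred.get)
    assert ordered == ["b", "a", "bb", "aa", "ab", "abb", "aab", "aabb"]
    assert predict_erel(model, 0.0, 0.0) == pytest.approx(13.4)
    assert predict_erel(FitModel(0, 0, 7.5, 0), 3.0, -2.0) == 7.5
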