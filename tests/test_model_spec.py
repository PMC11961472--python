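import numpy as np
import pytest

from tailorcut import (ModelSyntaxError, ParameterSet, add_residual_correlations,
                       implied_covariance, parse_model, split_factor)


@pytest.mark.parametrize("text, q, df", [
    ("f1 =~ x1 + x2 + x3", 6, 0),                       # just-identified
    ("f1 =~ x1 + x2 + x3 + x4 + x5", 10, 5),            # one-factor, 5 items
    ("f1 =~ x1 + x2 + x3\nf2 =~ x4 + x5 + x6", 13, 8),  # two factors, free corr
])
def test_free_parameter_and_df_counting(text, q, df):
    m = parse_model(text)
    assert (m.q, m.df) == (q, df)


def test_identification_modes_same_df():
    text = "f1 =~ x1 + x2 + x3 + x4 + x5"
    assert parse_model(text, "marker_loading").df == \
        parse_model(text, "unit_factor_variance").df == 5


def test_marker_default_fixes_first_loading():
    m = parse_model("f1 =~ x1 + x2 + x3")
    assert not m.lam_free[0, 0] and m.lam_fixed[0, 0] == 1.0
    assert m.lam_free[1, 0] and m.lam_free[2, 0]
    assert m.psi_free[0, 0]


def test_explicit_fixed_loading_replaces_marker():
    m = parse_model("f1 =~ x1 + 0.5*x2 + x3")
    # user fixed a loading, so no additional marker is imposed
    assert m.lam_free[0, 0] and not m.lam_free[1, 0]
    assert m.lam_fixed[1, 0] == 0.5


def test_fixed_factor_covariance():
    m = parse_model("f1 =~ x1 + x2 + x3\nf2 =~ x4 + x5 + x6\nf1 ~~ 0.7*f2")
    assert not m.psi_free[0, 1] and m.psi_fixed[0, 1] == 0.7
    assert m.df == 9  # one parameter fewer than the free-correlation model


def test_free_residual_covariance_statement():
    m = parse_model("f1 =~ x1 + x2 + x3 + x4\nx1 ~~ x2")
    assert m.theta_free[0, 1]
    assert m.df == 1


@pytest.mark.parametrize("text, match", [
    ("f1 =~ x1 + x2\ny1 ~ x1", "regression"),
    ("f1 =~ x1 + x1 + x2", "duplicate"),
    ("f1 =~ x1 + x2 + x3\nx1 ~~ z9", "z9"),
    ("f1 =~ x1 + x2 + x3\nx1 ~~ x2\nx1 ~~ x2", "duplicate"),
    ("x1 ~~ x2", "no factors"),
    ("f1 =~ x1 + x2 + x3\nf1 ~~ x1", "f1|x1"),
    ("f1 =~ 1.5x1", "parse"),
])
def test_syntax_errors(text, match):
    with pytest.raises(ModelSyntaxError, match=match):
        parse_model(text)


def test_error_reports_line_number():
    with pytest.raises(ModelSyntaxError, match="line 3"):
        parse_model("# comment\nf1 =~ x1 + x2 + x3\nbogus statement here")


def test_comments_and_blank_lines_ignored():
    m = parse_model("# a CFA\n\nf1 =~ x1 + x2 + x3  # items\n")
    assert m.item_names == ["x1", "x2", "x3"]


@pytest.mark.parametrize("lam, psi, theta, expected", [
    ([[1.0], [1.0]], [[1.0]], np.eye(2), [[2.0, 1.0], [1.0, 2.0]]),
    ([[0.0], [0.0]], [[1.0]], np.diag([2.0, 3.0]), [[2.0, 0.0], [0.0, 3.0]]),
])
def test_implied_covariance_hand_cases(lam, psi, theta, expected):
    ps = ParameterSet(lam, psi, theta)
    assert np.allclose(ps.implied_covariance(), expected)


def test_implied_covariance_standardized_one_factor(pop5):
    lam = np.full((5, 1), 0.7)
    ps = ParameterSet(lam, np.eye(1), np.eye(5) * 0.51)
    sigma = ps.implied_covariance()
    assert np.allclose(np.diag(sigma), 1.0)
    off = sigma[~np.eye(5, dtype=bool)]
    assert np.allclose(off, 0.49)


def test_implied_covariance_invariant_to_factor_relabeling(rng):
    lam = rng.uniform(0.4, 0.9, size=(6, 2))
    psi = np.array([[1.0, 0.3], [0.3, 1.0]])
    theta = np.diag(rng.uniform(0.3, 0.8, 6))
    ps = ParameterSet(lam, psi, theta)
    perm = [1, 0]
    ps2 = ParameterSet(lam[:, perm], psi[np.ix_(perm, perm)], theta)
    assert np.allclose(ps.implied_covariance(), ps2.implied_covariance())


class TestSplitFactor:
    def test_r_one_is_identity_on_implied_covariance(self, pop5):
        out = split_factor(pop5, [["x1", "x2"], ["x3", "x4", "x5"]], 1.0)
        assert np.allclose(out.implied_covariance(),
                           pop5.implied_covariance(), atol=1e-15)

    def test_r_one_identity_for_nonunit_factor_variance(self, pop5):
        pop = ParameterSet(pop5.lam, [[0.47]], pop5.theta, pop5.item_names)
        out = split_factor(pop, [[0, 1], [2, 3, 4]], 1.0)
        assert np.allclose(out.implied_covariance(), pop.implied_covariance())

    def test_r_zero_cross_block_covariances_vanish(self, pop5):
        out = split_factor(pop5, [[0, 1], [2, 3, 4]], 0.0)
        sigma = out.implied_covariance()
        assert np.allclose(sigma[:2, 2:], 0.0)
        assert np.allclose(sigma[:2, :2], pop5.implied_covariance()[:2, :2])

    def test_r_seventy_scales_cross_block(self, pop5):
        out = split_factor(pop5, [[0, 1], [2, 3, 4]], 0.70)
        assert np.allclose(out.implied_covariance()[:2, 2:],
                           0.70 * pop5.implied_covariance()[:2, 2:])

    def test_errors(self, pop5):
        with pytest.raises(ValueError, match="outside"):
            split_factor(pop5, [[0, 1], [2, 3, 4]], 1.5)
        with pytest.raises(ValueError, match="empty"):
            split_factor(pop5, [[], [0, 1, 2, 3, 4]], 0.7)
        with pytest.raises(ValueError, match="cover"):
            split_factor(pop5, [[0, 1], [2, 3]], 0.7)
        two = split_factor(pop5, [[0, 1], [2, 3, 4]], 0.7)
        with pytest.raises(ValueError, match="one-factor"):
            split_factor(two, [[0], [1, 2, 3, 4]], 0.7)


class TestResidualCorrelations:
    def test_r_zero_identity(self, pop5):
        out = add_residual_correlations(pop5, [("x1", "x2")], 0.0)
        assert np.allclose(out.implied_covariance(), pop5.implied_covariance())

    def test_sqrt_product_scaling(self):
        ps = ParameterSet(np.full((4, 1), 0.6), np.eye(1), np.eye(4) * 0.5)
        out = add_residual_correlations(ps, [(0, 1)], 0.50)
        assert out.theta[0, 1] == pytest.approx(0.25)
        assert out.theta[2, 3] == 0.0

    def test_unknown_item(self, pop5):
        with pytest.raises(ValueError, match="unknown item"):
            add_residual_correlations(pop5, [("x1", "zz")], 0.5)

    def test_non_pd_result_rejected(self):
        # zero loadings: implied covariance is theta itself, and three
        # pairwise correlations of -0.9 cannot be embedded in a PD matrix
        ps = ParameterSet(np.zeros((3, 1)), np.eye(1), np.eye(3))
        with pytest.raises(ValueError, match="non-PD"):
            add_residual_correlations(ps, [(0, 1), (1, 2), (0, 2)], -0.9)

    def test_duplicate_pair_rejected(self, pop5):
        with pytest.raises(ValueError, match="duplicate"):
            add_residual_correlations(pop5, [(0, 1), (1, 0)], 0.3)


@pytest.mark.parametrize("identification", ["marker_loading", "unit_factor_variance"])
@pytest.mark.parametrize("text", [
    "f1 =~ x1 + x2 + x3 + x4 + x5",
    "f1 =~ x1 + x2 + x3\nf2 =~ x4 + x5 + x6\nf1 ~~ 0.7*f2\nx1 ~~ x4",
    "f1 =~ x1 + 0.5*x2 + x3",
])
def test_parse_serialize_roundtrip(text, identification):
    m1 = parse_model(text, identification)
    m2 = parse_model(m1.serialize(), identification)
    assert m1.item_names == m2.item_names
    assert m1.factor_names == m2.factor_names
    for attr in ("lam_free", "psi_free", "theta_free"):
        assert np.array_equal(getattr(m1, attr), getattr(m2, attr)), attr
    for attr in ("lam_fixed", "psi_fixed", "theta_fixed"):
        assert np.allclose(getattr(m1, attr), getattr(m2, attr)), attr
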