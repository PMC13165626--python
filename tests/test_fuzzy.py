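import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzyrula import fuzzy
from fuzzyrula.errors import ConfigError, FrameInvalidError, NoActivationError
from fuzzyrula.fuzzy import (
    FuzzyRule,
    FuzzySystemConfig,
    TrapezoidParams,
    config_checksum,
    default_config,
    trapezoid_membership,
)
from fuzzyrula.kinematics import JointAngleSet

from conftest import brute_force_infer, random_membership_table, trapezoid_oracle

#: Pinned SHA-256 of the shipped default configuration.
DEFAULT_CONFIG_SHA256 = (
    "f0989c532ae0a320a2abde5b2686efe5ede071d0aefef602109b1492a2f65498"
)


def angles(shoulder_elev, elbow_interior, trunk_dev, rotation=None):
    """JointAngleSet from the membership-table scales (elevation/interior/deviation)."""
    return JointAngleSet(
        frame_index=0,
        theta_shoulder=180.0 - shoulder_elev,
        theta_elbow=180.0 - elbow_interior,
        theta_trunk=trunk_dev,
        trunk_rotation=rotation,
    )


class TestTrapezoid:
    @pytest.mark.parametrize("x,expected", [
        (9.9, 0.0),          # below support
        (40.1, 0.0),         # above support
        (15.0, 0.5),         # midpoint of the rising ramp
        (25.0, 1.0),         # plateau
        (35.0, 0.5),         # midpoint of the falling ramp
    ])
    def test_branches(self, x, expected):
        p = TrapezoidParams(10, 20, 30, 40)
        assert trapezoid_membership(x, p) == pytest.approx(expected)

    def test_triangle_apex(self):
        p = TrapezoidParams(0, 5, 5, 10)
        assert trapezoid_membership(5.0, p) == 1.0

    def test_crisp_left_shoulder(self):
        p = TrapezoidParams(5, 5, 8, 10)
        assert trapezoid_membership(5.0, p) == 1.0
        assert trapezoid_membership(4.999, p) == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            TrapezoidParams(10, 5, 20, 30)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(x=st.floats(-50, 250), breaks=st.lists(
        st.floats(0, 180), min_size=4, max_size=4))
    def test_matches_independent_oracle_and_bounds(self, x, breaks):
        a, b, c, d = sorted(breaks)
        p = TrapezoidParams(a, b, c, d)
        m = trapezoid_membership(x, p)
        assert 0.0 <= m <= 1.0
        assert m == pytest.approx(trapezoid_oracle(x, a, b, c, d), abs=1e-12)


class TestFuzzify:
    def test_plateau_center_full_membership(self, default_cfg):
        table = fuzzy.fuzzify(angles(7.5, 160.0, 7.5), default_cfg)
        assert table["shoulder"]["low"] == 1.0
        assert table["elbow"]["neutral"] == 1.0
        assert table["trunk"]["upright"] == 1.0

    @pytest.mark.parametrize("var,make", [
        ("shoulder", lambda x: angles(x, 160, 5)),
        ("elbow", lambda x: angles(7, x, 5)),
        ("trunk", lambda x: angles(7, 160, x)),
    ])
    def test_complementary_overlap_sums_to_one(self, default_cfg, var, make):
        cfg_var = default_cfg.inputs[var]
        trapz = list(cfg_var.labels.values())
        # probe the midpoint of every inter-label transition
        for left, right in zip(trapz, trapz[1:]):
            lo = min(left.c, right.c)
            hi = max(left.b, right.b)
            for x in np.linspace(lo + 1e-6, hi - 1e-6, 7):
                table = fuzzy.fuzzify(make(float(x)), default_cfg)
                assert sum(table[var].values()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_required_angle_flags_frame(self, default_cfg):
        bad = JointAngleSet(frame_index=3, theta_shoulder=90.0,
                            theta_elbow=math.nan, theta_trunk=5.0)
        with pytest.raises(FrameInvalidError, match="frame 3"):
            fuzzy.fuzzify(bad, default_cfg)

    def test_optional_rotation_channel_absent_is_fine(self, default_cfg):
        table = fuzzy.fuzzify(angles(7.5, 160, 5), default_cfg)
        assert "trunk_rotation" not in table
        table = fuzzy.fuzzify(angles(7.5, 160, 5, rotation=50.0), default_cfg)
        assert table["trunk_rotation"]["twisted"] == 1.0


class TestInfer:
    def test_single_full_rule_reproduces_consequent(self):
        cfg = default_config()
        one = FuzzySystemConfig(
            inputs=cfg.inputs, output=cfg.output,
            rules=[FuzzyRule(rule_id="r", antecedents={"shoulder": "low"},
                             consequent="medium")],
        )
        memberships = {"shoulder": {"low": 1.0, "medium": 0, "high": 0, "very_high": 0}}
        mu = fuzzy.infer(memberships, one)
        expected = cfg.output.labels["medium"].membership(one.engine().grid)
        np.testing.assert_allclose(mu, expected)

    def test_no_firing_gives_zero_everywhere(self, default_cfg):
        memberships = {
            name: {lab: 0.0 for lab in var.labels}
            for name, var in default_cfg.inputs.items()
        }
        assert np.all(fuzzy.infer(memberships, default_cfg) == 0.0)

    def test_matches_brute_force_enumeration(self, default_cfg):
        rng = np.random.default_rng(7)
        grid = default_cfg.engine().grid
        coarse = grid[::10]  # keep the pure-python oracle affordable
        for _ in range(50):
            table = random_membership_table(default_cfg, rng)
            mu = fuzzy.infer(table, default_cfg)[::10]
            oracle = brute_force_infer(table, default_cfg, coarse)
            np.testing.assert_allclose(mu, oracle, atol=1e-12)

    def test_rule_weight_caps_firing_strength(self):
        cfg = default_config()
        weighted = FuzzySystemConfig(
            inputs=cfg.inputs, output=cfg.output,
            rules=[FuzzyRule(rule_id="r", antecedents={"shoulder": "low"},
                             consequent="medium", weight=0.4)],
        )
        memberships = {"shoulder": {"low": 1.0, "medium": 0, "high": 0, "very_high": 0}}
        mu = fuzzy.infer(memberships, weighted)
        assert mu.max() == pytest.approx(0.4)

    def test_adding_a_rule_never_decreases_mu(self, default_cfg):
        rng = np.random.default_rng(11)
        base_rules = list(default_cfg.rules)
        extended = FuzzySystemConfig(
            inputs=default_cfg.inputs, output=default_cfg.output,
            rules=base_rules + [FuzzyRule(
                rule_id="extra", antecedents={"trunk": "slight_forward"},
                consequent="very_high")],
        )
        for _ in range(20):
            table = random_membership_table(default_cfg, rng)
            mu0 = fuzzy.infer(table, default_cfg)
            mu1 = fuzzy.infer(table, extended)
            assert np.all(mu1 >= mu0 - 1e-15)

    def test_empty_rule_base_rejected(self, default_cfg):
        with pytest.raises(ConfigError, match="empty"):
            FuzzySystemConfig(inputs=default_cfg.inputs,
                              output=default_cfg.output, rules=[])


class TestDefuzzify:
    def test_rectangle_centroid_is_its_center(self, default_cfg):
        grid = default_cfg.engine().grid
        mu = np.where((grid >= 3.0) & (grid <= 5.0), 1.0, 0.0)
        assert fuzzy.defuzzify_centroid(mu, default_cfg) == pytest.approx(4.0)

    def test_symmetric_triangle_centroid(self, default_cfg):
        grid = default_cfg.engine().grid
        mu = np.maximum(0.0, 1.0 - np.abs(grid - 6.0))
        assert fuzzy.defuzzify_centroid(mu, default_cfg) == pytest.approx(6.0)

    def test_matches_refined_quadrature(self, default_cfg):
        rng = np.random.default_rng(3)
        engine = default_cfg.engine()
        fine = np.linspace(1.0, 7.0, (len(engine.grid) - 1) * 10 + 1)
        for _ in range(50):
            table = random_membership_table(default_cfg, rng)
            strengths = engine.firing_strengths(table)
            mu_fine = np.zeros_like(fine)
            for rule, s in zip(default_cfg.rules, strengths):
                shape = default_cfg.output.labels[rule.consequent].membership(fine)
                mu_fine = np.maximum(mu_fine, np.minimum(shape, s))
            area = np.trapezoid(mu_fine, fine)
            if area == 0:
                continue
            oracle = np.trapezoid(fine * mu_fine, fine) / area
            got = fuzzy.defuzzify_centroid(fuzzy.infer(table, default_cfg), default_cfg)
            assert got == pytest.approx(oracle, abs=1e-4)

    def test_zero_area_raises_no_activation(self, default_cfg):
        mu = np.zeros_like(default_cfg.engine().grid)
        with pytest.raises(NoActivationError):
            fuzzy.defuzzify_centroid(mu, default_cfg)


class TestScoreFrame:
    def test_low_plateau_posture_scores_in_low_band(self, default_cfg):
        s = fuzzy.score_frame(angles(7.5, 160, 7.5), default_cfg)
        assert 1.0 <= s <= 2.0

    def test_worst_posture_scores_at_least_six(self, default_cfg):
        s = fuzzy.score_frame(angles(137.5, 50, 120, rotation=100.0), default_cfg)
        assert s >= 6.0

    def test_representative_rule_ordering_r1_below_r4(self, default_cfg):
        # R1 posture: low shoulder, neutral elbow, upright trunk
        s_r1 = fuzzy.score_frame(angles(7.5, 160, 7.5), default_cfg)
        # R4 posture: high shoulder, extreme elbow, bent trunk
        s_r4 = fuzzy.score_frame(angles(67.5, 50, 120), default_cfg)
        assert s_r1 < s_r4

    def test_pure_function_bitwise_determinism(self, default_cfg):
        a = angles(33.3, 123.4, 17.8)
        s1 = fuzzy.score_frame(a, default_cfg)
        s2 = fuzzy.score_frame(a, fuzzy.default_config())
        assert s1 == s2

    def test_score_within_activated_consequent_hull(self, default_cfg):
        rng = np.random.default_rng(5)
        engine = default_cfg.engine()
        for _ in range(50):
            table = random_membership_table(default_cfg, rng)
            strengths = engine.firing_strengths(table)
            active = [r.consequent for r, s in zip(default_cfg.rules, strengths) if s > 0]
            if not active:
                continue
            lo = min(default_cfg.output.labels[c].a for c in active)
            hi = max(default_cfg.output.labels[c].d for c in active)
            s = fuzzy.defuzzify_centroid(fuzzy.infer(table, default_cfg), default_cfg)
            assert lo - 1e-9 <= s <= hi + 1e-9

    def test_monotone_sweep_per_input(self, default_cfg):
        """Moving any one input from its mildest to its severest plateau
        (others at their mildest plateau centers) never lowers the score."""
        sweeps = {
            "shoulder": (lambda x: angles(x, 160, 7.5), 7.5, 137.5),
            "elbow": (lambda x: angles(7.5, x, 7.5), 160.0, 50.0),
            "trunk": (lambda x: angles(7.5, 160, x), 7.5, 120.0),
        }
        for name, (make, start, stop) in sweeps.items():
            xs = np.linspace(start, stop, int(abs(stop - start)) + 1)
            scores = [fuzzy.score_frame(make(float(x)), default_cfg) for x in xs]
            diffs = np.diff(scores)
            assert np.all(diffs >= -1e-9), f"{name} sweep decreased"


class TestConfigRoundTrip:
    def test_default_checksum_pinned(self, default_cfg):
        assert config_checksum(default_cfg) == DEFAULT_CONFIG_SHA256

    def test_yaml_round_trip_preserves_checksum(self, default_cfg, tmp_path):
        path = tmp_path / "cfg.yaml"
        fuzzy.save_config(default_cfg, path)
        again = fuzzy.load_config(path)
        assert config_checksum(again) == config_checksum(default_cfg)

    def test_table1_rules_present_verbatim(self, default_cfg):
        by_id = {r.rule_id: r for r in default_cfg.rules}
        assert by_id["R1"].antecedents == {
            "shoulder": "low", "elbow": "neutral", "trunk": "upright"}
        assert by_id["R1"].consequent == "low"
        assert by_id["R4"].consequent == "very_high"
        assert by_id["R8"].antecedents["trunk_rotation"] == "twisted"
        assert len([r for r in default_cfg.rules if r.rule_id.startswith("R")]) == 8

    def test_unknown_label_in_rule_rejected(self, default_cfg):
        with pytest.raises(ConfigError, match="no label"):
            FuzzySystemConfig(
                inputs=default_cfg.inputs, output=default_cfg.output,
                rules=[FuzzyRule(rule_id="x", antecedents={"shoulder": "huge"},
                                 consequent="low")],
            )

    def test_coarse_grid_rejected(self, default_cfg):
        with pytest.raises(ConfigError, match="601"):
            FuzzySystemConfig(
                inputs=default_cfg.inputs, output=default_cfg.output,
                rules=list(default_cfg.rules), grid_step=0.5,
            )


class TestNoActivationPolicies:
    @pytest.fixture
    def narrow_cfg(self, default_cfg):
        """A deliberately sparse rule base that fires only for a bent trunk."""
        return FuzzySystemConfig(
            inputs=default_cfg.inputs, output=default_cfg.output,
            rules=[FuzzyRule(rule_id="only", antecedents={"trunk": "bent"},
                             consequent="high")],
            no_activation="error",
        )

    def test_error_policy_raises(self, narrow_cfg):
        with pytest.raises(NoActivationError):
            fuzzy.score_frame(angles(7.5, 160, 5.0), narrow_cfg)

    def test_neutral_policy_returns_one(self, narrow_cfg):
        cfg = FuzzySystemConfig(
            inputs=narrow_cfg.inputs, output=narrow_cfg.output,
            rules=list(narrow_cfg.rules), no_activation="neutral")
        out = fuzzy.score_sequence([angles(7.5, 160, 5.0)], cfg)
        assert out[0] == 1.0

    def test_carry_policy_repeats_last_valid(self, narrow_cfg):
        cfg = FuzzySystemConfig(
            inputs=narrow_cfg.inputs, output=narrow_cfg.output,
            rules=list(narrow_cfg.rules), no_activation="carry")
        seq = [angles(7.5, 160, 120.0), angles(7.5, 160, 5.0)]
        out = fuzzy.score_sequence(seq, cfg)
        assert out[1] == out[0]
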