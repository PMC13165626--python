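import math

import numpy as np
import pytest

from fuzzyrula import fuzzy, synthetic
from fuzzyrula.pose import PoseFrame, PoseSequence


@pytest.fixture(scope="session")
def default_cfg():
    return fuzzy.default_config()


@pytest.fixture(scope="session")
def profiles():
    return synthetic.default_profiles()


def arm_frame(shoulder_deg, elbow_vec_deg, trunk_dev_deg=0.0, index=0,
              scale=1.0):
    """Build a frame whose right-side angles are exactly the given values.

    Same constructive layout as the synthetic generator but written
    independently: torso tilted by the trunk deviation, arm chain in the
    sagittal plane with in-plane rotations equal to the requested angles.
    """
    def u(psi):
        p = math.radians(psi)
        return np.array([math.sin(p), -math.cos(p), 0.0])

    tr = math.radians(trunk_dev_deg)
    mid_hip = np.zeros(3)
    neck = mid_hip + 0.5 * np.array([math.sin(tr), math.cos(tr), 0.0])
    psi0 = 25.0
    r_shoulder = neck + 0.2 * u(psi0)
    r_elbow = r_shoulder + 0.3 * u(psi0 + shoulder_deg)
    r_wrist = r_elbow + 0.25 * u(psi0 + shoulder_deg + elbow_vec_deg)
    joints = {
        "neck": tuple(neck * scale),
        "r_shoulder": tuple(r_shoulder * scale),
        "r_elbow": tuple(r_elbow * scale),
        "r_wrist": tuple(r_wrist * scale),
        "l_hip": tuple((mid_hip + [0, 0, 0.1]) * scale),
        "r_hip": tuple((mid_hip + [0, 0, -0.1]) * scale),
    }
    return PoseFrame(index=index, joints=joints)


@pytest.fixture
def tiny_sequence():
    frames = tuple(arm_frame(90.0 + i, 20.0, 5.0, index=i) for i in range(3))
    return PoseSequence(frames=frames, fps=30.0, task="sliding_door")


def trapezoid_oracle(x, a, b, c, d):
    """Independent piecewise trapezoid evaluation (pure python)."""
    if x < a or x > d:
        return 0.0
    if b <= x <= c:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (d - x) / (d - c)


def brute_force_infer(memberships, config, grid):
    """Exhaustive rule-firing oracle: pure-python loops over rules and grid."""
    out = []
    labels = {lab: (p.a, p.b, p.c, p.d) for lab, p in config.output.labels.items()}
    for r in grid:
        best = 0.0
        for rule in config.rules:
            strength = rule.weight
            for var, lab in rule.antecedents.items():
                if var not in memberships:
                    strength = 0.0
                    break
                strength = min(strength, memberships[var][lab])
            best = max(best, min(strength, trapezoid_oracle(r, *labels[rule.consequent])))
        out.append(best)
    return np.array(out)


def random_membership_table(config, rng):
    return {
        name: {lab: float(rng.uniform()) for lab in var.labels}
        for name, var in config.inputs.items()
    }
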