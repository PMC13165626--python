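"""Fuzzy ergonomic risk scoring (Mamdani inference over joint angles).

A crisp joint-angle set is mapped to a continuous risk score in [1, 7]:

1. **Fuzzification** — each input variable (shoulder, elbow, trunk, and an
   optional trunk-rotation channel) is mapped to degrees of membership in
   its linguistic labels through trapezoidal membership functions with
   parameters ``a <= b <= c <= d`` (0 outside [a, d], 1 on [b, c], linear
   ramps between).
2. **Weighted rule firing** — each rule's firing strength is the minimum of
   its antecedent memberships, capped by the rule's importance weight
   ``min(strength, w)``.
3. **Aggregation** — each fired rule clips its consequent risk trapezoid at
   its strength; the aggregate membership over the risk universe is the
   pointwise maximum of all clipped consequents (the "bottleneck"
   principle: the worst-loaded structure dominates).
4. **Centroid defuzzification** — the crisp score is the centre of mass
   of the aggregate, computed by trapezoidal quadrature on a uniform grid.

The rule base combines representative multi-joint rules with
single-antecedent backbone rules (one per non-neutral joint label), so the
aggregation reduces to the per-joint max–min form for loaded postures and
every point of the input space activates at least one rule.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, FrameInvalidError, NoActivationError
from .kinematics import JointAngleSet

__all__ = [
    "TrapezoidParams", "LinguisticVariable", "FuzzyRule", "FuzzySystemConfig",
    "trapezoid_membership", "fuzzify", "infer", "defuzzify_centroid",
    "score_frame", "score_sequence", "default_config", "load_config",
    "config_checksum",
]

#: Transforms from raw kinematic channels to the scale a membership table uses.
_TRANSFORMS = {
    "identity": lambda x: x,
    "supplement": lambda x: 180.0 - x,
}

#: JointAngleSet channels a variable may read.
_CHANNELS = ("theta_shoulder", "theta_elbow", "theta_trunk", "trunk_rotation")


@dataclass(frozen=True)
class TrapezoidParams:
    """Breakpoints a <= b <= c <= d of one trapezoidal membership function."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigError(
                f"trapezoid requires a<=b<=c<=d, got ({self.a},{self.b},{self.c},{self.d})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.b + self.c)

    def membership(self, x):
        """Vectorised membership; crisp shoulders where a==b or c==d."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        a, b, c, d = self.a, self.b, self.c, self.d
        out = np.where((x >= b) & (x <= c), 1.0, out)
        if b > a:
            ramp = (x - a) / (b - a)
            out = np.where((x >= a) & (x < b), ramp, out)
        if d > c:
            ramp = (d - x) / (d - c)
            out = np.where((x > c) & (x <= d), ramp, out)
        return out


def trapezoid_membership(x: float, p: TrapezoidParams) -> float:
    """Membership of a scalar ``x`` under trapezoid ``p`` (in [0, 1])."""
    return float(p.membership(x))


@dataclass(frozen=True)
class LinguisticVariable:
    """A named input/output quantity with ordered fuzzy labels.

    ``labels`` are ordered by severity; validation requires their trapezoid
    centers to be strictly monotone (increasing or decreasing — the elbow
    table runs high-angle→low-angle because a smaller interior angle means
    a more flexed, higher-load arm).
    """

    name: str
    universe: tuple[float, float]
    labels: Mapping[str, TrapezoidParams]
    source: str | None = None          # JointAngleSet channel (inputs only)
    transform: str = "identity"
    optional: bool = False

    def __post_init__(self):
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigError(f"variable '{self.name}': empty universe [{lo},{hi}]")
        if not self.labels:
            raise ConfigError(f"variable '{self.name}': no labels")
        if self.transform not in _TRANSFORMS:
            raise ConfigError(f"variable '{self.name}': unknown transform '{self.transform}'")
        if self.source is not None and self.source not in _CHANNELS:
            raise ConfigError(f"variable '{self.name}': unknown source '{self.source}'")
        for lab, p in self.labels.items():
            if p.a < lo - 1e-9 or p.d > hi + 1e-9:
                raise ConfigError(
                    f"variable '{self.name}': label '{lab}' support [{p.a},{p.d}] "
                    f"outside universe [{lo},{hi}]"
                )
        centers = [p.center for p in self.labels.values()]
        diffs = np.diff(centers)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ConfigError(
                f"variable '{self.name}': label centers not monotone ({centers})"
            )
        self.check_coverage()

    def check_coverage(self, n: int = 721) -> None:
        """Warn if some universe point has zero membership under every label."""
        grid = np.linspace(self.universe[0], self.universe[1], n)
        total = np.zeros_like(grid)
        for p in self.labels.values():
            total = np.maximum(total, p.membership(grid))
        if np.any(total <= 0):
            warnings.warn(
                f"variable '{self.name}': labels do not cover the universe",
                stacklevel=3,
            )

    def crisp_value(self, angles: JointAngleSet) -> float | None:
        """Raw channel value mapped onto this variable's scale, or None."""
        raw = getattr(angles, self.source)
        if raw is None or not math.isfinite(raw):
            return None
        return _TRANSFORMS[self.transform](float(raw))


@dataclass(frozen=True)
class FuzzyRule:
    """IF (var is label AND ...) THEN risk is label, with weight in (0, 1]."""

    rule_id: str
    antecedents: Mapping[str, str]
    consequent: str
    weight: float = 1.0

    def __post_init__(self):
        if not self.antecedents:
            raise ConfigError(f"rule {self.rule_id}: empty antecedents")
        if not (0.0 < self.weight <= 1.0):
            raise ConfigError(f"rule {self.rule_id}: weight must be in (0,1], got {self.weight}")


@dataclass
class FuzzySystemConfig:
    """Complete fuzzy system: input variables, output variable, rule base.

    ``no_activation`` decides what :func:`score_sequence` does for a frame
    where no rule fires: ``"error"`` (default — the shipped tables make
    this unreachable, so hitting it flags a configuration mistake),
    ``"neutral"`` (emit score 1.0) or ``"carry"`` (repeat the last valid
    score).
    """

    inputs: Mapping[str, LinguisticVariable]
    output: LinguisticVariable
    rules: Sequence[FuzzyRule]
    grid_step: float = 0.01
    no_activation: str = "error"
    _engine: "FuzzyEngine | None" = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if not self.rules:
            raise ConfigError("rule base is empty")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")
        span = self.output.universe[1] - self.output.universe[0]
        if span / self.grid_step + 1 < 601:
            raise ConfigError("defuzzification grid must have at least 601 points")
        if self.no_activation not in ("error", "neutral", "carry"):
            raise ConfigError(f"unknown no_activation policy '{self.no_activation}'")
        for r in self.rules:
            for var, lab in r.antecedents.items():
                if var not in self.inputs:
                    raise ConfigError(f"rule {r.rule_id}: unknown variable '{var}'")
                if lab not in self.inputs[var].labels:
                    raise ConfigError(
                        f"rule {r.rule_id}: variable '{var}' has no label '{lab}'"
                    )
            if r.consequent not in self.output.labels:
                raise ConfigError(
                    f"rule {r.rule_id}: unknown risk label '{r.consequent}'"
                )

    def engine(self) -> "FuzzyEngine":
        if self._engine is None:
            self._engine = FuzzyEngine(self)
        return self._engine

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def var_dict(v: LinguisticVariable, is_input: bool) -> dict:
            d = {
                "universe": list(v.universe),
                "labels": {k: [p.a, p.b, p.c, p.d] for k, p in v.labels.items()},
            }
            if is_input:
                d["source"] = v.source
                d["transform"] = v.transform
                d["optional"] = v.optional
            return d

        return {
            "variables": {k: var_dict(v, True) for k, v in self.inputs.items()},
            "output": {self.output.name: var_dict(self.output, False)},
            "rules": [
                {
                    "id": r.rule_id,
                    "if": dict(r.antecedents),
                    "then": r.consequent,
                    "weight": r.weight,
                }
                for r in self.rules
            ],
            "defuzz": {
                "grid_step": self.grid_step,
                "no_activation": self.no_activation,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzySystemConfig":
        try:
            inputs = {
                name: LinguisticVariable(
                    name=name,
                    universe=tuple(vdef["universe"]),
                    labels={
                        lab: TrapezoidParams(*params)
                        for lab, params in vdef["labels"].items()
                    },
                    source=vdef.get("source", name if name in _CHANNELS else None),
                    transform=vdef.get("transform", "identity"),
                    optional=bool(vdef.get("optional", False)),
                )
                for name, vdef in d["variables"].items()
            }
            (out_name, out_spec), = d["output"].items()
            output = LinguisticVariable(
                name=out_name,
                universe=tuple(out_spec["universe"]),
                labels={
                    lab: TrapezoidParams(*params)
                    for lab, params in out_spec["labels"].items()
                },
            )
            rules = [
                FuzzyRule(
                    rule_id=str(r.get("id", f"rule{i}")),
                    antecedents=dict(r["if"]),
                    consequent=r["then"],
                    weight=float(r.get("weight", 1.0)),
                )
                for i, r in enumerate(d["rules"])
            ]
            defuzz = d.get("defuzz", {})
            return cls(
                inputs=inputs,
                output=output,
                rules=rules,
                grid_step=float(defuzz.get("grid_step", 0.01)),
                no_activation=defuzz.get("no_activation", "error"),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed fuzzy config: {exc}") from exc


def load_config(path: str | Path) -> FuzzySystemConfig:
    """Load a fuzzy-system configuration from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return FuzzySystemConfig.from_dict(doc)


def save_config(config: FuzzySystemConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def config_checksum(config: FuzzySystemConfig) -> str:
    """SHA-256 of the canonical JSON serialisation (pins shipped defaults)."""
    # label order is semantic (severity ordering), so keys keep insertion order
    blob = json.dumps(config.to_dict(), separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

def default_config() -> FuzzySystemConfig:
    """The shipped fuzzy system.

    Input scales
    ------------
    * **shoulder** — arm elevation, the supplement (180° − θ) of the raw
      neck→shoulder / shoulder→elbow angle, so a hanging arm scores near 0°
      and a fully raised arm near 180°. Breakpoints at 20°/45°/90° follow
      the classical RULA upper-arm bands, with ±5° complementary ramps.
    * **elbow** — interior (anatomical) elbow angle, the supplement of the
      vector-convention angle; a straight arm is 180°. Severity grows as
      the arm flexes (interior angle shrinks): neutral ≥ 140°, moderate
      110–130°, extreme ≤ 100°, ±5° ramps. The moderate plateau brackets
      the flexed-elbow envelope characteristic of low-drawer reaches.
    * **trunk** — deviation from vertical (upright seated trunk = 0°), with
      RULA-style trunk breakpoints 20°/60° and ±5° ramps.
    * **trunk_rotation** — optional axial-twist channel; rules that mention
      it stay inert unless the caller supplies a rotation angle.

    Output: risk over [1, 7] with plateaus on the standard action bands
    1–2 / 3–4 / 5–6 / 7 and ±0.5 overlap ramps.

    Rules: the eight representative multi-joint rules R1–R8 plus one
    single-antecedent backbone rule per non-neutral (joint, label) pair, so
    each joint alone can escalate risk to its own band — the per-joint
    max–min aggregation — while the all-neutral rule R1 anchors the low
    band. A relaxed joint therefore never dilutes the risk asserted by a
    loaded one, and every posture in the input space fires at least one
    rule (any point with all severe memberships zero is all-neutral, which
    fires R1). All weights default to 1.0; per-rule override in config.
    """
    t = TrapezoidParams
    inputs = {
        "shoulder": LinguisticVariable(
            name="shoulder", universe=(0.0, 180.0),
            source="theta_shoulder", transform="supplement",
            labels={
                "low": t(0, 0, 15, 25),
                "medium": t(15, 25, 40, 50),
                "high": t(40, 50, 85, 95),
                "very_high": t(85, 95, 180, 180),
            },
        ),
        "elbow": LinguisticVariable(
            name="elbow", universe=(0.0, 180.0),
            source="theta_elbow", transform="supplement",
            labels={
                "neutral": t(130, 140, 180, 180),
                "moderate": t(100, 110, 130, 140),
                "extreme": t(0, 0, 100, 110),
            },
        ),
        "trunk": LinguisticVariable(
            name="trunk", universe=(0.0, 180.0),
            source="theta_trunk", transform="identity",
            labels={
                "upright": t(0, 0, 15, 25),
                "slight_forward": t(15, 25, 55, 65),
                "bent": t(55, 65, 180, 180),
            },
        ),
        "trunk_rotation": LinguisticVariable(
            name="trunk_rotation", universe=(0.0, 180.0),
            source="trunk_rotation", transform="identity", optional=True,
            labels={
                "not_twisted": t(0, 0, 20, 30),
                "twisted": t(20, 30, 180, 180),
            },
        ),
    }
    output = LinguisticVariable(
        name="risk", universe=(1.0, 7.0),
        labels={
            "low": t(1, 1, 2, 3),
            "medium": t(2, 3, 4, 5),
            "high": t(4, 5, 6, 7),
            "very_high": t(6, 7, 7, 7),
        },
    )
    rep = [
        ("R1", {"shoulder": "low", "elbow": "neutral", "trunk": "upright"}, "low"),
        ("R2", {"shoulder": "medium", "elbow": "neutral", "trunk": "slight_forward"}, "medium"),
        ("R3", {"shoulder": "high", "elbow": "moderate", "trunk": "slight_forward"}, "high"),
        ("R4", {"shoulder": "high", "elbow": "extreme", "trunk": "bent"}, "very_high"),
        ("R5", {"shoulder": "medium", "elbow": "moderate", "trunk": "bent"}, "high"),
        ("R6", {"shoulder": "low", "elbow": "moderate", "trunk": "upright"}, "medium"),
        ("R7", {"shoulder": "high", "elbow": "neutral", "trunk_rotation": "twisted"}, "high"),
        ("R8", {"shoulder": "very_high", "elbow": "extreme", "trunk_rotation": "twisted"}, "very_high"),
    ]
    backbone = [
        ("B1", {"shoulder": "medium"}, "medium"),
        ("B2", {"shoulder": "high"}, "high"),
        ("B3", {"shoulder": "very_high"}, "very_high"),
        ("B4", {"elbow": "moderate"}, "medium"),
        ("B5", {"elbow": "extreme"}, "very_high"),
        ("B6", {"trunk": "slight_forward"}, "medium"),
        ("B7", {"trunk": "bent"}, "very_high"),
    ]
    rules = [
        FuzzyRule(rule_id=rid, antecedents=ants, consequent=cons)
        for rid, ants, cons in rep + backbone
    ]
    return FuzzySystemConfig(inputs=inputs, output=output, rules=rules)


# ---------------------------------------------------------------------------
# Inference engine
# ---------------------------------------------------------------------------

class FuzzyEngine:
    """Precomputed grids for fast repeated inference under one config."""

    def __init__(self, config: FuzzySystemConfig):
        self.config = config
        lo, hi = config.output.universe
        n = int(round((hi - lo) / config.grid_step)) + 1
        self.grid = np.linspace(lo, hi, n)
        self._consequents = {
            lab: p.membership(self.grid) for lab, p in config.output.labels.items()
        }
        # rows aligned with config.rules
        self._rule_consequents = np.stack(
            [self._consequents[r.consequent] for r in config.rules]
        )
        self._weights = np.array([r.weight for r in config.rules])

    # -- stages ------------------------------------------------------------

    def fuzzify(self, angles: JointAngleSet) -> dict[str, dict[str, float]]:
        table: dict[str, dict[str, float]] = {}
        for name, var in self.config.inputs.items():
            x = var.crisp_value(angles)
            if x is None:
                if var.optional:
                    continue
                raise FrameInvalidError(
                    f"frame {angles.frame_index}: required input '{name}' is invalid"
                )
            table[name] = {
                lab: trapezoid_membership(x, p) for lab, p in var.labels.items()
            }
        return table

    def firing_strengths(self, memberships: Mapping[str, Mapping[str, float]]) -> np.ndarray:
        strengths = np.empty(len(self.config.rules))
        for i, rule in enumerate(self.config.rules):
            s = 1.0
            for var, lab in rule.antecedents.items():
                if var not in memberships:
                    s = 0.0  # optional channel absent: rule is inert
                    break
                s = min(s, memberships[var][lab])
            strengths[i] = min(s, rule.weight)
        return strengths

    def infer(self, memberships: Mapping[str, Mapping[str, float]]) -> np.ndarray:
        strengths = self.firing_strengths(memberships)
        clipped = np.minimum(self._rule_consequents, strengths[:, None])
        return clipped.max(axis=0)

    def defuzzify(self, mu_total: np.ndarray) -> float:
        area = float(np.trapezoid(mu_total, self.grid))
        if area <= 0.0:
            raise NoActivationError("no rule fired: aggregated membership is zero")
        moment = float(np.trapezoid(self.grid * mu_total, self.grid))
        return moment / area

    def score(self, angles: JointAngleSet) -> float:
        return self.defuzzify(self.infer(self.fuzzify(angles)))


# -- functional surface ------------------------------------------------------

def fuzzify(angles: JointAngleSet, config: FuzzySystemConfig) -> dict[str, dict[str, float]]:
    """Membership table variable → (label → degree) for one frame."""
    return config.engine().fuzzify(angles)


def infer(memberships: Mapping[str, Mapping[str, float]],
          config: FuzzySystemConfig) -> np.ndarray:
    """Aggregated output membership μ_total on the defuzzification grid."""
    return config.engine().infer(memberships)


def defuzzify_centroid(mu_total: np.ndarray, config: FuzzySystemConfig) -> float:
    """Centroid ∫r·μ dr / ∫μ dr over the risk universe (trapezoid rule)."""
    return config.engine().defuzzify(np.asarray(mu_total, dtype=float))


def score_frame(angles: JointAngleSet, config: FuzzySystemConfig) -> float:
    """Continuous risk score S_raw in [1, 7] for one frame."""
    return config.engine().score(angles)


def score_sequence(angle_sets: Sequence[JointAngleSet],
                   config: FuzzySystemConfig) -> np.ndarray:
    """Per-frame raw scores; invalid frames become NaN.

    Applies the configured no-activation policy: ``error`` raises,
    ``neutral`` substitutes 1.0, ``carry`` repeats the last valid score
    (NaN if none yet).
    """
    engine = config.engine()
    out = np.full(len(angle_sets), np.nan)
    last = math.nan
    for i, angles in enumerate(angle_sets):
        try:
            out[i] = engine.score(angles)
            last = out[i]
        except FrameInvalidError:
            continue
        except NoActivationError:
            if config.no_activation == "error":
                raise
            out[i] = 1.0 if config.no_activation == "neutral" else last
    return out
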