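"""Threshold-rule quality classifiers over the eigenvalue spectrum.

Three published rule sets are shipped as frozen constants: a two-rule
decision tree (CART), a four-rule tree (C4.5) and a three-rule
first-match rule list (RIPPER).  All thresholds are stored as log10
constants, but comparisons run in the linear domain (lambda vs 10^T) so
that exactly-zero eigenvalues from singular covariances are handled
without taking a logarithm.  Unacceptable (UN) is the positive class for
sensitivity/specificity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .covariance import EigenSpectrum
from .errors import InputError
from .io import QualityLabel

_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


@dataclass(frozen=True)
class Conjunct:
    """One comparison: eigenvalue index (1-based), comparator, log10 threshold."""

    eigen_index: int
    op: str
    log10_threshold: float

    def __post_init__(self) -> None:
        if not 1 <= self.eigen_index <= 8:
            raise InputError(f"eigen index {self.eigen_index} outside 1..8")
        if self.op not in _COMPARATORS:
            raise InputError(f"unknown comparator {self.op!r}")
        if not math.isfinite(self.log10_threshold):
            raise InputError("threshold must be finite")

    def holds(self, lambdas_linear) -> bool:
        value = float(lambdas_linear[self.eigen_index - 1])
        return _COMPARATORS[self.op](value, 10.0 ** self.log10_threshold)


@dataclass(frozen=True)
class ThresholdRule:
    """A conjunction of threshold comparisons implying a label."""

    conjuncts: tuple[Conjunct, ...]
    label: QualityLabel

    def holds(self, lambdas_linear) -> bool:
        return all(c.holds(lambdas_linear) for c in self.conjuncts)


@dataclass(frozen=True)
class RuleSet:
    """An ordered first-match rule list with a default label.

    The first rule whose conjunction holds decides the label; the default
    applies when none fires.
    """

    name: str
    rules: tuple[ThresholdRule, ...]
    default: QualityLabel
    metadata: dict = field(default_factory=dict, compare=False)

    def apply(self, spectrum: EigenSpectrum) -> tuple[QualityLabel, int]:
        """Classify a spectrum; returns (label, 1-based firing rule index).

        The default counts as rule ``len(rules) + 1``, matching how
        published rule tables list the fall-through as the final rule.
        """
        lam = spectrum.lambdas
        for i, rule in enumerate(self.rules):
            if rule.holds(lam):
                return rule.label, i + 1
        return self.default, len(self.rules) + 1

    def classify(self, spectrum: EigenSpectrum) -> QualityLabel:
        return self.apply(spectrum)[0]


def _rule(label: str, *conjuncts: tuple[int, str, float]) -> ThresholdRule:
    return ThresholdRule(
        conjuncts=tuple(Conjunct(i, op, t) for i, op, t in conjuncts),
        label=QualityLabel(label),
    )


#: CART tree: UN on a collapsed signal space (lambda_8 below T1, a sign of
#: disconnected leads), else UN on an inflated lambda_1 (T2), else AC.
CART_RULES = RuleSet(
    name="cart",
    rules=(
        _rule("UN", (8, "<", 0.145)),
        _rule("UN", (1, ">=", 5.08)),
    ),
    default=QualityLabel.AC,
    metadata={"thresholds_log10": {"T1": 0.145, "T2": 5.08}},
)

#: C4.5 tree, reconstructed from the published narrative: lambda_8 gate,
#: then an AC band on lambda_1, an upper UN gate on lambda_1, and a final
#: lambda_6 gate ("too much energy outside the three main eigenvalues").
C45_RULES = RuleSet(
    name="c45",
    rules=(
        _rule("UN", (8, "<=", 0.0870)),
        _rule("AC", (1, "<=", 4.86)),
        _rule("UN", (1, ">=", 7.91)),
        _rule("UN", (6, ">=", 2.23)),
    ),
    default=QualityLabel.AC,
    metadata={
        "thresholds_log10": {"T1'": 0.0870, "T2'": 4.86, "T3'": 7.91, "T4'": 2.23},
        "note": (
            "tree topology reconstructed from the published narrative; "
            "the original tree figure is not machine-readable"
        ),
    },
)

#: RIPPER first-match rule list (UN rules, AC default).
RIPPER_RULES = RuleSet(
    name="ripper",
    rules=(
        _rule("UN", (8, "<=", 0.0863)),
        _rule("UN", (1, ">=", 4.85), (3, ">=", 4.06)),
        _rule("UN", (1, ">=", 5.09), (2, ">=", 3.75)),
    ),
    default=QualityLabel.AC,
    metadata={
        "thresholds_log10": {
            "T1*": 0.0863, "T2*": 4.85, "T3*": 4.06, "T4*": 5.09, "T5*": 3.75,
        }
    },
)

REGISTRY: dict[str, RuleSet] = {
    "cart": CART_RULES,
    "c45": C45_RULES,
    "ripper": RIPPER_RULES,
}


def get_ruleset(name: str) -> RuleSet:
    try:
        return REGISTRY[name]
    except KeyError:
        raise InputError(
            f"unknown model {name!r}; expected one of {sorted(REGISTRY)}"
        ) from None


def classify_cart(spectrum: EigenSpectrum) -> QualityLabel:
    """UN if log10(lambda_8) < 0.145; else UN if log10(lambda_1) >= 5.08; else AC."""
    return CART_RULES.classify(spectrum)


def classify_c45(spectrum: EigenSpectrum) -> QualityLabel:
    return C45_RULES.classify(spectrum)


def classify_ripper(spectrum: EigenSpectrum) -> QualityLabel:
    return RIPPER_RULES.classify(spectrum)


# ---------------------------------------------------------------------------
# Rule-registry serialisation (bit-exact JSON round trip)
# ---------------------------------------------------------------------------

def ruleset_to_dict(ruleset: RuleSet) -> dict:
    return {
        "name": ruleset.name,
        "default": ruleset.default.value,
        "rules": [
            {
                "label": rule.label.value,
                "conjuncts": [
                    {
                        "eigen_index": c.eigen_index,
                        "op": c.op,
                        "log10_threshold": c.log10_threshold,
                    }
                    for c in rule.conjuncts
                ],
            }
            for rule in ruleset.rules
        ],
        "metadata": ruleset.metadata,
    }


def ruleset_from_dict(data: dict) -> RuleSet:
    try:
        rules = tuple(
            ThresholdRule(
                conjuncts=tuple(
                    Conjunct(c["eigen_index"], c["op"], c["log10_threshold"])
                    for c in rule["conjuncts"]
                ),
                label=QualityLabel(rule["label"]),
            )
            for rule in data["rules"]
        )
        return RuleSet(
            name=data["name"],
            rules=rules,
            default=QualityLabel(data["default"]),
            metadata=data.get("metadata", {}),
        )
    except (KeyError, ValueError) as exc:
        raise InputError(f"malformed rule registry: {exc}") from exc


def save_ruleset(ruleset: RuleSet, path: str) -> str:
    with open(path, "w") as fh:
        json.dump(ruleset_to_dict(ruleset), fh, indent=2)
    return path


def load_ruleset(path: str) -> RuleSet:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except OSError as exc:
        raise InputError(f"cannot read rule registry {path!r}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise InputError(f"rule registry {path!r} is not valid JSON: {exc}") from exc
    return ruleset_from_dict(data)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalMetrics:
    """Binary classification metrics with UN as the positive class."""

    tp: int  # UN predicted UN
    tn: int  # AC predicted AC
    fp: int  # AC predicted UN
    fn: int  # UN predicted AC

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        """Proportion of UN records classified UN; NaN if no UN records."""
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        """Proportion of AC records classified AC; NaN if no AC records."""
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
        }


def evaluate_labels(
    predicted: list[QualityLabel], truth: list[QualityLabel]
) -> EvalMetrics:
    """Confusion counts and derived metrics; UN is the positive class."""
    if len(predicted) != len(truth):
        raise InputError(
            f"{len(predicted)} predictions vs {len(truth)} truth labels"
        )
    if not truth:
        raise InputError("cannot evaluate an empty label list")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if t == QualityLabel.UN:
            if p == QualityLabel.UN:
                tp += 1
            else:
                fn += 1
        else:
            if p == QualityLabel.AC:
                tn += 1
            else:
                fp += 1
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn)
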