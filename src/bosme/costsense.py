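"""Cost-sensitive machinery built on the translation ("Folk") theorem.

With misclassification costs c+ (false negative) and c− (false positive),
rescaling the class prior by the costs — p̃± = C·p±·c± with
C = 1/(p+·c+ + p−·c−) — makes the accuracy-optimal classifier under the new
prior coincide with the expected-cost-optimal classifier under the original
one.  The minority proportion to aim for when over-sampling is therefore
q = p̃+ = m+·γ / (m+·γ + m−) with γ = c+/c− > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import POS, NEG, ClassBalance, PreconditionError


@dataclass(frozen=True)
class CostSpec:
    """Misclassification costs: c+ for a false negative, c− for a false positive.

    The over-sampling application assumes γ = c+/c− > 1 (enforced by
    :func:`target_q`, not here — the decision rule itself is valid for any
    positive costs).
    """

    c_plus: float
    c_minus: float = 1.0

    def __post_init__(self):
        if self.c_plus <= 0 or self.c_minus <= 0:
            raise PreconditionError("costs must be positive")

    @classmethod
    def from_gamma(cls, gamma: float) -> "CostSpec":
        return cls(c_plus=float(gamma), c_minus=1.0)

    @property
    def gamma(self) -> float:
        return self.c_plus / self.c_minus


@dataclass(frozen=True)
class ReweightedDistribution:
    """Cost-reweighted class prior (p̃+, p̃−) and its normalizing constant C."""

    p_tilde_plus: float
    p_tilde_minus: float
    C: float


def target_q(balance: ClassBalance, costs: CostSpec) -> float:
    """Target minority proportion q = m+·γ / (m+·γ + m−); requires γ > 1.

    By construction q lies strictly between the original minority proportion
    and 1, so enlargement is always meaningful.
    """
    g = costs.gamma
    if g <= 1:
        raise PreconditionError(f"cost ratio gamma must exceed 1, got {g}")
    return balance.m_plus * g / (balance.m_plus * g + balance.m_minus)


def reweighted_distribution(p_plus: float, costs: CostSpec) -> ReweightedDistribution:
    """Folk-theorem prior: p̃± = C·p±·c±, C = 1/(p+·c+ + p−·c−)."""
    if not 0 < p_plus < 1:
        raise PreconditionError("p_plus must lie in (0, 1)")
    p_minus = 1.0 - p_plus
    C = 1.0 / (p_plus * costs.c_plus + p_minus * costs.c_minus)
    return ReweightedDistribution(
        p_tilde_plus=C * p_plus * costs.c_plus,
        p_tilde_minus=C * p_minus * costs.c_minus,
        C=C,
    )


def min_cost_label(p_plus: float, costs: CostSpec) -> str:
    """Label minimizing expected cost: '+' iff c−·p− < c+·p+ (tie → '+')."""
    if not 0 <= p_plus <= 1:
        raise PreconditionError("p_plus must lie in [0, 1]")
    p_minus = 1.0 - p_plus
    return POS if costs.c_minus * p_minus <= costs.c_plus * p_plus else NEG


def expected_cost(confusion: dict[str, int], costs: CostSpec) -> float:
    """Per-instance expected cost (FN·c+ + FP·c−)/total from TP/FP/TN/FN counts."""
    tp, fp = confusion.get("TP", 0), confusion.get("FP", 0)
    tn, fn = confusion.get("TN", 0), confusion.get("FN", 0)
    if min(tp, fp, tn, fn) < 0:
        raise PreconditionError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise PreconditionError("empty confusion matrix")
    return (fn * costs.c_plus + fp * costs.c_minus) / total
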