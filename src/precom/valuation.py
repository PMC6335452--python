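"""Value and probability equations for effort- and delay-based choice with precommitment.

Two competing accounts of why people precommit are expressed as pairs of
models sharing a hyperbolic-discounting core:

* **Motivation maximization (MM)** — the net motivational value of the costly
  large reward (LR) is its discounted subjective value minus the opportunity
  cost of forgoing the free/immediate small reward (SR); precommitment is
  worth the gap ``SV_LR - SV_SR``.
* **Willpower (WP)** — during choice the decision-maker wilfully suppresses
  the SR's subjective value by a factor ``iota`` in [0, 1]; precommitment is
  worth taking when suppression is anticipated to fail,
  ``iota_reward * SV_SR - SV_LR``.

All functions are vectorized over numpy arrays and are the single source of
truth for downstream simulation and fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ChoiceModelParams",
    "PrecomModelParams",
    "OptionPair",
    "subjective_value",
    "net_value_mm",
    "net_value_wp",
    "p_choice_lr",
    "v_precom_mm",
    "v_precom_wp",
    "p_precommit",
]


@dataclass(frozen=True)
class ChoiceModelParams:
    """Free parameters of a choice model.

    Parameters
    ----------
    discount_rate : float
        Steepness of hyperbolic discounting (effort rate or delay rate); >= 0.
    inverse_temperature : float
        Softmax sensitivity ``gamma``; >= 0.
    willpower : float or None
        Multiplicative suppression ``iota`` of the SR value in [0, 1];
        ``None`` for the MM model (no suppression parameter).
    """

    discount_rate: float
    inverse_temperature: float
    willpower: float | None = None

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be non-negative")
        if self.willpower is not None and not 0.0 <= self.willpower <= 1.0:
            raise ValueError("willpower must lie in [0, 1]")


@dataclass(frozen=True)
class PrecomModelParams:
    """Free parameters of a precommitment model: sensitivity ``theta`` >= 0
    and bias ``b`` in [-5, 5]."""

    sensitivity: float
    bias: float

    def __post_init__(self) -> None:
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be non-negative")
        if not -5.0 <= self.bias <= 5.0:
            raise ValueError("bias must lie in [-5, 5]")


@dataclass(frozen=True)
class OptionPair:
    """One offered pair: LR magnitude, SR magnitude, and the LR's cost
    (squeezes for the effort task, seconds for the delay task)."""

    m_lr: float
    m_sr: float
    cost: float
    task: str = "effort"

    def __post_init__(self) -> None:
        if not self.m_lr > self.m_sr >= 0:
            raise ValueError("require M_LR > M_SR >= 0")
        if self.cost < 0:
            raise ValueError("cost must be non-negative")


def subjective_value(magnitude, cost, discount_rate):
    """Hyperbolically discounted subjective value ``M / (1 + k * cost)``.

    ``cost`` is effort units or delay seconds; ``discount_rate`` is the
    subject's effort or delay discounting rate.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    cost = np.asarray(cost, dtype=float)
    k = np.asarray(discount_rate, dtype=float)
    if np.any(magnitude < 0) or np.any(cost < 0) or np.any(k < 0):
        raise ValueError("magnitude, cost and discount_rate must be non-negative")
    return magnitude / (1.0 + k * cost)


def net_value_mm(pair: OptionPair, params: ChoiceModelParams):
    """MM net motivational value of the LR: ``SV_LR - OC_LR`` where the
    opportunity cost is the undiscounted SR value ``M_SR``."""
    sv_lr = subjective_value(pair.m_lr, pair.cost, params.discount_rate)
    return sv_lr - pair.m_sr


def net_value_wp(pair: OptionPair, params: ChoiceModelParams):
    """WP net value of the LR: ``SV_LR - iota * M_SR``; ``iota`` suppresses
    the tempting SR during choice (iota=1 → identical to MM)."""
    if params.willpower is None:
        raise ValueError("WP model requires the willpower parameter iota")
    sv_lr = subjective_value(pair.m_lr, pair.cost, params.discount_rate)
    return sv_lr - params.willpower * pair.m_sr


def p_choice_lr(delta_v, inverse_temperature):
    """Softmax probability of choosing the LR: ``1 / (1 + exp(-gamma * dV))``.

    Overflow-safe for arbitrarily large ``|gamma * dV|``.
    """
    gamma = np.asarray(inverse_temperature, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("inverse temperature must be non-negative")
    return expit(gamma * np.asarray(delta_v, dtype=float))


def v_precom_mm(sv_lr, sv_sr):
    """MM value of precommitting: ``SV_LR - SV_SR`` (positive exactly when
    the LR is the preferred option)."""
    return np.asarray(sv_lr, dtype=float) - np.asarray(sv_sr, dtype=float)


def v_precom_wp(sv_lr, sv_sr, iota_reward):
    """WP value of precommitting: ``iota_reward * SV_SR - SV_LR`` (positive
    when even the suppressed SR outweighs the LR, i.e. anticipated willpower
    failure)."""
    iota = np.asarray(iota_reward, dtype=float)
    if np.any((iota < 0) | (iota > 1)):
        raise ValueError("iota_reward must lie in [0, 1]")
    return iota * np.asarray(sv_sr, dtype=float) - np.asarray(sv_lr, dtype=float)


def p_precommit(v_precom, params: PrecomModelParams):
    """Probability of accepting precommitment:
    ``1 / (1 + exp(-(theta * V + b)))``; ``b`` shifts the propensity at V=0."""
    return expit(params.sensitivity * np.asarray(v_precom, dtype=float) + params.bias)
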