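"""Strategy switching: relative gains against two social thresholds.

Once per season every skipper weighs the relative change in payoff
``dS/S = (S_new - S_old) / S_old`` that the opposite strategy would bring:

* a standard fisher tempted to whitewash switches only if the gain exceeds
  their *aversion to super fishing* (ATSF);
* a super fisher pressed to stop switches only if the loss is smaller in
  magnitude than the *social pressure* they feel (stored signed, ``<= 0``).

Because the super payoff is exactly ``(1 + psi)`` times the standard one at
equal neighbourhood and stock, the relative gain is a constant of the game:
``+psi`` for standard -> super and ``-psi / (1 + psi)`` for super ->
standard, independent of who the neighbours are and how much crab is left.
That identity collapses the stationary fleet composition into three regimes
— all super, all standard, or an alternating half/half mixture — separated
by the lines ``atsf = psi`` and ``|social_pressure| = psi / (1 + psi)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .crab import RegimeLabel
from .network import GameParams, NeighborhoodCounts, Strategy, payoff

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SocialParams:
    """Behavioural thresholds, identical for all skippers and fixed per run.

    ``atsf >= 0`` is the minimum relative gain a standard fisher demands
    before whitewashing.  ``social_pressure <= 0`` is signed as plotted on
    the regime-map axis; its magnitude is the largest relative loss a super
    fisher will absorb to go straight.
    """

    atsf: float = 0.5
    social_pressure: float = -0.1

    def __post_init__(self) -> None:
        if self.atsf < 0:
            raise ValueError(f"atsf must be >= 0, got {self.atsf}")
        if self.social_pressure > 0:
            raise ValueError(
                f"social_pressure must be <= 0, got {self.social_pressure}"
            )


def relative_gain(
    current: Strategy,
    k: NeighborhoodCounts,
    gp: GameParams,
    x_prev: float,
) -> float:
    """Relative payoff change of adopting the opposite strategy.

    Computed from the two payoff-matrix entries; by the proportionality
    identity the value is ``psi`` for a standard fisher and
    ``-psi / (1 + psi)`` for a super fisher regardless of ``k`` and
    ``x_prev``.  A vanishing current payoff (zero stock or zero share) gives
    no incentive either way and returns 0.
    """
    c = payoff(Strategy.STANDARD, k, gp, x_prev)
    d = payoff(Strategy.SUPER, k, gp, x_prev)
    s_old, s_new = (c, d) if current == Strategy.STANDARD else (d, c)
    if s_old == 0.0:
        logger.debug(
            "zero current payoff (x_prev=%g, a=%g); relative gain defined as 0",
            x_prev, gp.a,
        )
        return 0.0
    return (s_new - s_old) / s_old


def decide_switch(rel_gain: float, sp: SocialParams) -> bool:
    """Threshold rule for one skipper's once-per-season decision.

    Positive gains (a standard fisher tempted): switch iff the gain strictly
    exceeds ``atsf``.  Negative gains (a super fisher pressed): switch iff
    the loss is strictly smaller in magnitude than ``|social_pressure|``.
    Zero gain never switches; exact threshold ties never switch.
    """
    if rel_gain < -1.0:
        raise ValueError(
            f"relative gain below -1 is impossible (cannot lose more than the "
            f"current extraction), got {rel_gain}"
        )
    if rel_gain > 0.0:
        return rel_gain > sp.atsf
    if rel_gain < 0.0:
        return -rel_gain < -sp.social_pressure
    return False


def classify_regime(sp: SocialParams, psi: float) -> RegimeLabel:
    """Predicted stationary fleet composition from an all-super start.

    With the constant gains ``+psi`` and ``-psi / (1 + psi)``:

    * ``|social_pressure| < psi / (1 + psi)`` — no super fisher ever accepts
      the loss: the fleet stays ALL_SUPER;
    * otherwise, if ``atsf > psi`` — supers go straight and no standard is
      ever tempted back: ALL_STANDARD;
    * otherwise both switches fire every season and the fleet alternates,
      averaging half standard: MIXED_HALF.
    """
    if psi <= 0:
        raise ValueError(f"psi must be positive, got {psi}")
    if -sp.social_pressure < psi / (1.0 + psi):
        return RegimeLabel.ALL_SUPER
    if sp.atsf > psi:
        return RegimeLabel.ALL_STANDARD
    return RegimeLabel.MIXED_HALF
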