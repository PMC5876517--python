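"""Transmission power control over RSSI feedback.

Implements an energy-efficient TPC policy (ETPC) as a pure state
transition over periodic RSSI feedback windows, plus a constant-power
baseline.  Per feedback period the controller

1. takes ``R_lowest``, the minimum RSSI among received samples in the
   window (falling back to the previous running average when every
   packet was lost),
2. classifies the channel good/bad by whether the window's mean received
   RSSI reaches the target ``R_target``, selecting the averaging weight
   ``alpha1`` (good) or ``alpha2`` (bad),
3. updates the running average ``R_bar = alpha*R_lowest + (1-alpha)*R_bar``
   (an EWMA anchored to the worst sample, which protects reliability),
4. sets the adaptive upper threshold ``TRH_var = TRL + sigma`` with
   ``sigma`` the population standard deviation of the window's received
   RSSI,
5. picks the power step: +2 levels if ``R_bar < TRL``, -1 level if
   ``R_bar > TRH_var``, else 0 (boundaries resolve to 0), and
6. clamps the new level into the radio's discrete power table.

The asymmetric step — climb fast when the link degrades, back off one
level at a time when it is comfortable — trades a little energy for
reliability.  The constant baseline transmits at a fixed level (by
default the table maximum) regardless of feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TpcConfig",
    "TpcState",
    "PolicyDecision",
    "TpcError",
    "ewma_update",
    "update_threshold",
    "power_step",
    "apply_step",
    "etpc_step",
    "constant_tpc_step",
    "initial_state",
]


class TpcError(ValueError):
    """Invalid TPC configuration or state transition input."""


#: Default CC2540-class discrete TX power table, dBm.
DEFAULT_POWER_LEVELS = (-23.0, -20.0, -16.0, -12.0, -8.0, -4.0, 0.0, 4.0)


@dataclass(frozen=True)
class TpcConfig:
    """ETPC controller parameters.

    ``r_target`` (dBm) splits good from bad channels; ``trl`` is the
    constant lower RSSI threshold below which power climbs; the upper
    threshold adapts as ``trl + sigma``.  ``alpha1``/``alpha2`` are the
    EWMA weights used in good/bad channel states.  ``constant_level_dbm``
    configures the constant-TPC baseline (None = table maximum).
    """

    r_target: float = -85.0
    trl: float = -88.0
    alpha1: float = 0.9
    alpha2: float = 0.6
    power_levels: tuple[float, ...] = DEFAULT_POWER_LEVELS
    step_up: int = 2
    step_down: int = 1
    window_n: int = 10
    constant_level_dbm: float | None = None

    def __post_init__(self) -> None:
        if not self.trl < self.r_target:
            raise TpcError(
                f"trl ({self.trl}) must be below r_target ({self.r_target})"
            )
        levels = tuple(float(p) for p in self.power_levels)
        object.__setattr__(self, "power_levels", levels)
        if len(levels) < 1 or any(
            b <= a for a, b in zip(levels, levels[1:])
        ):
            raise TpcError(f"power_levels must be strictly increasing: {levels}")
        for name in ("alpha1", "alpha2"):
            a = getattr(self, name)
            if not (0.0 < a <= 1.0):
                raise TpcError(f"{name} must lie in (0, 1], got {a}")
        if self.window_n < 1:
            raise TpcError(f"window_n must be >= 1, got {self.window_n}")
        if self.step_up < 1 or self.step_down < 1:
            raise TpcError("step_up and step_down must be >= 1")
        if (
            self.constant_level_dbm is not None
            and self.constant_level_dbm not in levels
        ):
            raise TpcError(
                f"constant_level_dbm {self.constant_level_dbm} not in power table"
            )

    @property
    def constant_level(self) -> float:
        if self.constant_level_dbm is None:
            return self.power_levels[-1]
        return self.constant_level_dbm


@dataclass(frozen=True)
class TpcState:
    """Controller state between feedback periods.

    ``window`` keeps the last feedback seen, as (rssi_dbm, received)
    pairs, for logging/inspection; it does not feed the next update.
    """

    r_bar: float
    trh_var: float
    level_index: int
    window: tuple[tuple[float, bool], ...] = ()


@dataclass(frozen=True)
class PolicyDecision:
    """One feedback period's outcome: commanded power and updated stats."""

    tx_power: float
    delta_p: int
    r_bar_after: float
    trh_var_after: float


def initial_state(config: TpcConfig, level_index: int | None = None) -> TpcState:
    """Fresh controller state: R_bar at target, threshold collapsed to TRL,
    power at the table maximum unless told otherwise (a conservative start
    that the controller then ratchets down)."""
    if level_index is None:
        level_index = len(config.power_levels) - 1
    if not (0 <= level_index < len(config.power_levels)):
        raise TpcError(f"level_index {level_index} outside power table")
    return TpcState(
        r_bar=config.r_target, trh_var=config.trl, level_index=level_index
    )


def ewma_update(r_bar: float, r_lowest: float, alpha: float) -> float:
    """EWMA of the per-window lowest RSSI:
    ``alpha * r_lowest + (1 - alpha) * r_bar``; alpha = 1 tracks the
    latest window exactly."""
    if not (0.0 < alpha <= 1.0):
        raise TpcError(f"alpha must lie in (0, 1], got {alpha}")
    return alpha * r_lowest + (1.0 - alpha) * r_bar


def update_threshold(
    window_rssi: Sequence[float], trl: float
) -> tuple[float, float]:
    """Adaptive upper threshold: ``TRH_var = TRL + sigma`` with sigma the
    population standard deviation of the window (0 for a single sample)."""
    arr = np.asarray(window_rssi, dtype=np.float64)
    if arr.size == 0:
        raise TpcError("RSSI window is empty")
    sigma = float(np.std(arr))
    return trl + sigma, sigma


def power_step(
    r_bar: float,
    trl: float,
    trh_var: float,
    step_up: int = 2,
    step_down: int = 1,
) -> int:
    """Three-branch step rule on the running average RSSI.

    +step_up when below TRL, -step_down when above TRH_var, 0 inside the
    closed band [TRL, TRH_var] (boundary ties hold power).
    """
    if trl > trh_var:
        raise TpcError(f"trl ({trl}) exceeds trh_var ({trh_var})")
    if r_bar < trl:
        return step_up
    if r_bar > trh_var:
        return -step_down
    return 0


def apply_step(level_index: int, delta_p: int, table_size: int) -> int:
    """Move ``delta_p`` entries through the power table, clamped to its ends."""
    if not (0 <= level_index < table_size):
        raise TpcError(f"level_index {level_index} outside table of {table_size}")
    return min(max(level_index + delta_p, 0), table_size - 1)


def etpc_step(
    state: TpcState,
    config: TpcConfig,
    feedback: Sequence[tuple[float, bool]],
) -> tuple[PolicyDecision, TpcState]:
    """One ETPC feedback period (steps 1-6 of the module docstring).

    ``feedback`` is the window of (rssi_dbm, received) pairs since the
    last decision.  RSSI can only be measured on received packets, so a
    window that lost everything carries no usable statistics: R_bar and
    TRH_var hold their previous values and the controller takes the
    step-up branch outright — total loss means the link is in outage
    below any measurable RSSI, and freezing power there would make
    outage an absorbing state.  A window with any loss at all classifies
    the channel as bad (a good channel has both high RSSI and no drops);
    an all-received window is good iff its mean RSSI reaches R_target.
    """
    if len(feedback) == 0:
        raise TpcError("feedback window is empty")
    received = [float(r) for r, ok in feedback if ok]

    if received:
        r_lowest = min(received)
        good = len(received) == len(feedback) and (
            float(np.mean(received)) >= config.r_target
        )
        alpha = config.alpha1 if good else config.alpha2
        r_bar = ewma_update(state.r_bar, r_lowest, alpha)
        trh_var, _sigma = update_threshold(received, config.trl)
        delta_p = power_step(
            r_bar, config.trl, trh_var, config.step_up, config.step_down
        )
    else:
        r_bar = state.r_bar
        trh_var = state.trh_var
        delta_p = config.step_up
    level = apply_step(state.level_index, delta_p, len(config.power_levels))
    decision = PolicyDecision(
        tx_power=config.power_levels[level],
        delta_p=delta_p,
        r_bar_after=r_bar,
        trh_var_after=trh_var,
    )
    new_state = TpcState(
        r_bar=r_bar,
        trh_var=trh_var,
        level_index=level,
        window=tuple((float(r), bool(ok)) for r, ok in feedback),
    )
    return decision, new_state


def constant_tpc_step(
    state: TpcState,
    config: TpcConfig,
    feedback: Sequence[tuple[float, bool]] = (),
) -> tuple[PolicyDecision, TpcState]:
    """Constant-TPC baseline: always the configured fixed level (default the
    table maximum); feedback is ignored and state passes through unchanged."""
    decision = PolicyDecision(
        tx_power=config.constant_level,
        delta_p=0,
        r_bar_after=state.r_bar,
        trh_var_after=state.trh_var,
    )
    return decision, state
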