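"""CBF recovery rates and the binary high/low recovery label.

The recovery rate is the carotid flow achieved by chest compressions
expressed as a percentage of the pre-arrest baseline flow. Rates of at
least 30 % define group 1 (high recovery); 30–40 % of normal cerebral
blood flow is the accepted threshold for recovery of brain function.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import CBFTrace

__all__ = ["RECOVERY_THRESHOLD_PCT", "RecoveryLabel", "recovery_rate", "to_group",
           "recovery_rate_from_trace", "label"]

#: division criterion between low (group 0) and high (group 1) recovery
RECOVERY_THRESHOLD_PCT = 30.0

#: flow averaging window preceding each pause, seconds (the source protocol
#: does not state one; 10 s of steady compressions is used)
DEFAULT_FLOW_WINDOW_S = 10.0


@dataclass(frozen=True)
class RecoveryLabel:
    recovery_rate: float  # %
    group: int  # 0 (low) or 1 (high)
    threshold: float = RECOVERY_THRESHOLD_PCT

    def __post_init__(self) -> None:
        if self.group != (1 if self.recovery_rate >= self.threshold else 0):
            raise ValueError("group inconsistent with recovery rate and threshold")


def recovery_rate(cbf_during_period: float, cbf_baseline: float) -> float:
    """100 * (mean CBF during the CPR period) / (pre-arrest baseline CBF)."""
    if not cbf_baseline > 0:
        raise ValueError(f"baseline CBF must be positive, got {cbf_baseline}")
    return 100.0 * cbf_during_period / cbf_baseline


def to_group(rate: float, threshold: float = RECOVERY_THRESHOLD_PCT) -> int:
    """1 if the recovery rate meets the threshold (>= 30 %), else 0."""
    if rate < 0:
        raise ValueError(f"recovery rate must be nonnegative, got {rate}")
    return 1 if rate >= threshold else 0


def recovery_rate_from_trace(
    cbf: CBFTrace, pause_start: float, window_s: float = DEFAULT_FLOW_WINDOW_S
) -> float:
    """Recovery rate from the mean flow over the window preceding a pause."""
    if not cbf.baseline_value > 0:
        raise ValueError("trace has no positive baseline flow")
    mean_flow = cbf.mean_flow(pause_start - window_s, pause_start)
    return recovery_rate(mean_flow, cbf.baseline_value)


def label(rate: float, threshold: float = RECOVERY_THRESHOLD_PCT) -> RecoveryLabel:
    return RecoveryLabel(rate, to_group(rate, threshold), threshold)
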