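"""Microdialysis observation model.

Retrodialysis by drug estimates each probe's in vivo relative recovery by
loss, RL = (C_in - C_out)/C_in x 100, from three consecutive perfusate
intervals; the mean RL corrects dialysate concentrations to unbound tissue
concentrations.  Because a dialysate fraction integrates the tissue
concentration over its collection interval, model predictions are interval
averages (AUC over the interval divided by its length), not point values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationResult, compute_auc

__all__ = [
    "PROBE_SITES",
    "PROBE_TRACKER",
    "RecoveryEstimate",
    "recovery_by_loss",
    "correct_dialysate",
    "predict_interval_average",
]

PROBE_SITES = ("blood", "muscle", "kidney")

#: Probe site -> AUC tracker registered by build_whole_body_model.
PROBE_TRACKER = {
    "blood": "auc_unbound_plasma",
    "muscle": "auc_muscle_interstitium",
    "kidney": "auc_cortex_interstitium",
}


@dataclass(frozen=True)
class RecoveryEstimate:
    """Per-probe retrodialysis recovery (percent loss of perfused drug)."""

    animal_id: str
    probe_site: str
    drug: str
    interval_values: tuple        # RL (%) per retrodialysis interval
    valid: tuple                  # parallel flags; invalid intervals excluded

    @property
    def mean(self) -> float:
        values = [v for v, ok in zip(self.interval_values, self.valid) if ok]
        return float(np.mean(values))


def recovery_by_loss(
    c_in: float,
    c_out_list,
    animal_id: str = "",
    probe_site: str = "",
    drug: str = "",
) -> RecoveryEstimate:
    """Relative recovery by loss from perfusate/dialysate concentration pairs.

    Each interval gives ``RL = (c_in - c_out)/c_in * 100``.  Intervals with
    ``c_out >= c_in`` (RL <= 0, impossible for loss) are flagged invalid
    and excluded from the mean with a warning.
    """
    if c_in <= 0:
        raise ValueError("retrodialysis perfusate concentration must be > 0")
    c_out = np.asarray(list(c_out_list), dtype=float)
    if c_out.size == 0:
        raise ValueError("need at least one dialysate interval")
    rl = (c_in - c_out) / c_in * 100.0
    valid = rl > 0
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} retrodialysis interval(s) with C_out >= C_in "
            f"({animal_id}/{probe_site}/{drug}); excluded from the mean recovery",
            RuntimeWarning,
        )
    if not valid.any():
        raise ValueError("no valid retrodialysis interval (all C_out >= C_in)")
    return RecoveryEstimate(
        animal_id, probe_site, drug, tuple(float(v) for v in rl), tuple(bool(v) for v in valid)
    )


def correct_dialysate(samples: pd.DataFrame, recovery: RecoveryEstimate) -> pd.DataFrame:
    """Divide dialysate concentrations by the mean recovery fraction.

    ``samples`` is a long-format frame (columns animal_id, probe_site, drug,
    t_start_h, t_end_h, conc_mg_L); all rows must match the recovery's
    probe, animal and drug.  Returns a copy with a
    ``conc_corrected_mg_L`` column holding unbound tissue concentrations
    attached to the same collection intervals.
    """
    for column, expected in (
        ("animal_id", recovery.animal_id),
        ("probe_site", recovery.probe_site),
        ("drug", recovery.drug),
    ):
        if column in samples and expected and not (samples[column] == expected).all():
            mismatched = sorted(set(samples[column]) - {expected})
            raise ValueError(
                f"dialysate/recovery pairing error: {column} {mismatched} does "
                f"not match recovery {column} {expected!r}"
            )
    if recovery.mean <= 0:
        raise ValueError("mean recovery must be > 0 to correct dialysate")
    out = samples.copy()
    out["conc_corrected_mg_L"] = out["conc_mg_L"] / (recovery.mean / 100.0)
    return out


def predict_interval_average(
    result: SimulationResult, probe_or_tracker: str, t_start: float, t_end: float
) -> float:
    """Model-predicted dialysate-equivalent concentration over an interval.

    Returns AUC(t_start, t_end)/(t_end - t_start) of the unbound
    concentration seen by the probe: unbound plasma for the blood probe,
    muscle interstitium for the muscle probe, renal cortex interstitium for
    the kidney probe.  A tracker name registered on the network is accepted
    directly.
    """
    tracker = PROBE_TRACKER.get(probe_or_tracker, probe_or_tracker)
    if t_end <= t_start:
        raise ValueError("need t_start < t_end")
    return compute_auc(result, tracker, t_start, t_end) / (t_end - t_start)
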