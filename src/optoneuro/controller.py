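"""Closed-loop trigger logic for organoid-driven robot control.

A state machine watches windowed firing rates from a MEA well. When the
mean firing rate over at least ``min_active_electrodes`` active electrodes
rises at least ``min_fold_increase``-fold above the pre-stimulation
baseline, one avoidance command is emitted for the episode; after
stimulation ends and the trigger stays quiet for a full evaluation window,
a resume command follows.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from . import mea
from .types import (
    ControllerEvent,
    ControllerLog,
    MEARecording,
    SpikeTrainSet,
    StimSchedule,
    TriggerRule,
)

log = logging.getLogger(__name__)


def window_rates(
    trains: SpikeTrainSet, start: float, end: float
) -> dict[str, float]:
    """Per-electrode firing rate (Hz) inside the half-open window [start, end)."""
    width = end - start
    if width <= 0:
        raise ValueError("window must have positive width")
    return {
        e: float(np.sum((t >= start) & (t < end))) / width
        for e, t in trains.trains.items()
    }


def estimate_baseline(
    trains: SpikeTrainSet, window: float, t_ref: float | None = None
) -> dict[str, float]:
    """Per-electrode baseline MFR over the trailing pre-stimulation window.

    ``t_ref`` is the first stimulation time (defaults to the recording end,
    i.e. the whole recording is baseline).
    """
    if t_ref is None:
        t_ref = trains.duration
    if window < 5.0:
        raise ValueError("baseline window must be >= 5 s")
    start = t_ref - window
    if start < 0:
        raise ValueError("not enough pre-stimulation data for the baseline window")
    return window_rates(trains, start, t_ref)


MIN_RATE_PER_MIN = 5.0  # active-electrode rule, spikes per minute


def evaluate_trigger(
    current_rates: dict[str, float],
    baseline: dict[str, float],
    rule: TriggerRule,
) -> tuple[bool, int, float, float]:
    """Evaluate the fold-increase trigger on one window of rates.

    Returns (triggered, n_active, mean_current, mean_baseline). Active
    electrodes are those meeting the 5 spikes/min rule over the *baseline*
    epoch; conditioning the active set on spiking within the evaluated
    window would bias the conditional mean rate upward (by 1/(1-e^-lambda))
    and fire the trigger on unmodulated activity. The trigger compares the
    mean current rate over the active set against ``min_fold_increase``
    times their mean baseline rate. A zero baseline never triggers.
    """
    if set(current_rates) != set(baseline):
        raise ValueError("electrode sets of current and baseline rates differ")
    active = [e for e, r in baseline.items() if r >= MIN_RATE_PER_MIN / 60.0]
    n_active = len(active)
    if n_active == 0:
        return False, 0, 0.0, 0.0
    mean_cur = float(np.mean([current_rates[e] for e in active]))
    mean_base = float(np.mean([baseline[e] for e in active]))
    if mean_base <= 0:
        log.warning("zero baseline rate: trigger disabled for this window")
        return False, n_active, mean_cur, mean_base
    triggered = (
        n_active >= rule.min_active_electrodes
        and mean_cur >= rule.min_fold_increase * mean_base
    )
    return triggered, n_active, mean_cur, mean_base


def run_controller(
    source: MEARecording | SpikeTrainSet,
    stim: StimSchedule,
    rule: TriggerRule | None = None,
    noise_reference: str = "raw",
) -> ControllerLog:
    """Run the avoidance/resume state machine over a recording.

    Spike detection (for a raw recording) uses the controller's
    ``spike_threshold_sd`` (default 3 SD) relative to the raw-trace noise
    level, distinct from the 5.5-SD analysis path. The trigger is evaluated
    at every ``evaluation_window`` boundary; one avoidance command is
    emitted per episode, and a resume command once the trigger has been
    false for a full window after stimulation end.
    """
    if rule is None:
        rule = TriggerRule()
    if isinstance(source, MEARecording):
        trains = mea.detect_spike_trains(
            source, k_sd=rule.spike_threshold_sd, noise_reference=noise_reference
        )
    else:
        trains = source
    for t in trains.trains.values():
        if np.any(np.diff(t) < 0):
            raise ValueError("spike stream timestamps out of order")

    t_first = float(stim.pulse_times[0]) if stim.pulse_times.size else trains.duration
    stim_end = (
        float(stim.pulse_times[-1]) + stim.pulse_width
        if stim.pulse_times.size
        else trains.duration
    )
    baseline = estimate_baseline(trains, rule.baseline_window, t_first)

    n_windows = math.floor(trains.duration / rule.evaluation_window)
    events: list[ControllerEvent] = []
    state = "FORWARD"
    quiet_after_stim = 0
    for i in range(n_windows):
        w0 = i * rule.evaluation_window
        w1 = w0 + rule.evaluation_window
        rates = window_rates(trains, w0, w1)
        trig, n_active, cur, base = evaluate_trigger(rates, baseline, rule)
        command = None
        if state == "FORWARD" and trig:
            state = "AVOID"
            command = "AVOID"
            quiet_after_stim = 0
        elif state == "AVOID":
            if not trig and w0 >= stim_end:
                quiet_after_stim += 1
                if quiet_after_stim >= 1 and w1 - stim_end >= rule.evaluation_window:
                    state = "FORWARD"
                    command = "RESUME"
            elif trig:
                quiet_after_stim = 0
        events.append(
            ControllerEvent(
                time=w1,
                state=state,
                mfr_baseline=base,
                mfr_current=cur,
                n_active_electrodes=n_active,
                command=command,
            )
        )
    return ControllerLog(events)


def n_avoidance_commands(logbook: ControllerLog) -> int:
    return sum(1 for _, c in logbook.commands if c == "AVOID")
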