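"""Ground-truthed synthetic data: calcium movies and MEA recordings.

The calcium generator renders a 2D network in which one stimulated cell
launches a propagating activation wave; each activated cell emits a calcium
transient (fast rise, slow exponential decay) on a noisy baseline. The MEA
generator draws inhomogeneous-Poisson spikes whose rate is multiplicatively
elevated, with latency jitter, during light pulses, and renders them as
biphasic waveforms on Gaussian noise.

Both generators are deterministic given their integer seed and return the
exact ground truth used for rendering, so every downstream detector can be
scored against known events.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .types import (
    CalciumGroundTruth,
    CalciumMovie,
    MEAGroundTruth,
    MEARecording,
    NetworkModel,
    SpikeTrainSet,
    StimSchedule,
)

REFRACTORY_S = 0.0025  # absolute refractory enforced between ground-truth spikes


def make_stim_schedule(
    frequency: float,
    pulse_width: float = 0.010,
    t_start: float = 0.0,
    t_end: float = 10.0,
    intensity_label: str = "",
) -> StimSchedule:
    """Periodic pulse schedule: onsets t_start, t_start + 1/f, ... < t_end."""
    if t_end <= t_start:
        raise ValueError("t_end must be > t_start")
    if frequency * pulse_width >= 1:
        raise ValueError("duty cycle frequency*pulse_width must be < 1")
    times = np.arange(t_start, t_end, 1.0 / frequency)
    return StimSchedule(times, pulse_width, intensity_label)


def generate_network(
    n_cells: int,
    field_shape: tuple[int, int] = (64, 64),
    mean_degree: float = 4.0,
    delay_range: tuple[float, float] = (0.2, 0.8),
    min_separation: float = 5.0,
    seed: int = 0,
) -> NetworkModel:
    """Random symmetric network of cells placed uniformly in the field.

    Somata are placed by rejection sampling so no two centres come closer
    than ``min_separation`` pixels (cell bodies do not overlap). Each
    unordered pair is connected independently with probability
    ``mean_degree / (n_cells - 1)``; per-edge conduction delays are uniform
    in ``delay_range``. The stimulated cell is the one nearest the field
    centre (a proxy for the focally illuminated neuron).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells > 1 and mean_degree >= n_cells:
        raise ValueError("mean_degree must be < n_cells")
    if delay_range[0] <= 0 or delay_range[1] < delay_range[0]:
        raise ValueError("delay_range must be positive and ordered")
    if min(field_shape) < 4:
        raise ValueError("field_shape is degenerate")

    rng = np.random.default_rng(seed)
    h, w = field_shape
    # keep a 2-px margin so pixel masks stay inside the field
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_cells:
        cand = np.array([rng.uniform(2, h - 2), rng.uniform(2, w - 2)])
        if all(np.linalg.norm(cand - p) >= min_separation for p in placed):
            placed.append(cand)
        attempts += 1
        if attempts > 1000 * n_cells:
            raise ValueError(
                "could not place cells with the requested min_separation"
            )
    pos = np.vstack(placed)
    adj = np.zeros((n_cells, n_cells), dtype=bool)
    delays = np.full((n_cells, n_cells), np.nan)
    if n_cells > 1:
        p = mean_degree / (n_cells - 1)
        iu = np.triu_indices(n_cells, k=1)
        connected = rng.random(len(iu[0])) < p
        d = rng.uniform(delay_range[0], delay_range[1], len(iu[0]))
        adj[iu] = connected
        delays[iu] = d
        adj |= adj.T
        delays = np.where(np.isnan(delays), delays.T, delays)
        delays[~adj] = np.nan

    centre = np.array([h / 2, w / 2])
    stimulated = int(np.argmin(np.linalg.norm(pos - centre, axis=1)))
    return NetworkModel(pos, adj, delays, stimulated, tuple(field_shape))


def shortest_path_delays(network: NetworkModel) -> np.ndarray:
    """Seconds of conduction delay from the stimulated cell to every cell.

    Unreachable cells get ``inf``; the stimulated cell gets 0.
    """
    n = network.n_cells
    if n == 1:
        return np.zeros(1)
    g = np.where(network.adjacency, network.conduction_delay, 0.0)
    return dijkstra(g, directed=False, indices=network.stimulated_cell)


def calcium_kernel(
    t: np.ndarray, rise: float = 0.1, decay: float = 1.5
) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak."""
    if not decay > rise > 0:
        raise ValueError("kernel requires decay > rise > 0")
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


def _cell_pixel_mask(pos: np.ndarray, field_shape: tuple[int, int], radius: int = 2) -> np.ndarray:
    """Pixel coordinates of a small disk around a cell centre."""
    r0, c0 = int(round(pos[0])), int(round(pos[1]))
    rows, cols = [], []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                r, c = r0 + dr, c0 + dc
                if 0 <= r < field_shape[0] and 0 <= c < field_shape[1]:
                    rows.append(r)
                    cols.append(c)
    return np.column_stack([rows, cols])


def simulate_calcium_movie(
    network: NetworkModel,
    stim: StimSchedule,
    frame_rate: float = 30.0,
    duration: float = 20.0,
    kernel: tuple[float, float, float] = (0.1, 1.5, 10.0),
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    extra_spikes: dict[int, list[float]] | None = None,
    activation_probability: float = 1.0,
    seed: int = 0,
) -> tuple[CalciumMovie, CalciumGroundTruth]:
    """Render a propagating activation wave as a fluorescence movie.

    Cell ``j`` activates at ``stim.pulse_times[0] + shortest-path delay`` from
    the stimulated cell and emits one transient per activation (plus any
    ``extra_spikes``). ``activation_probability < 1`` drops cells at random
    for negative-control fixtures.
    """
    rise, decay, amplitude = kernel
    if not (decay > rise > 0):
        raise ValueError("kernel requires decay > rise > 0")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate

    dists = shortest_path_delays(network)
    pulse0 = float(stim.pulse_times[0]) if stim.pulse_times.size else 0.0
    activation = pulse0 + dists
    if activation_probability < 1.0:
        drop = rng.random(network.n_cells) > activation_probability
        drop[network.stimulated_cell] = False
        activation[drop] = np.inf

    truncated = bool(np.any(np.isfinite(activation) & (activation > duration)))
    if truncated:
        warnings.warn(
            "wave outran the movie duration; ground truth truncated", stacklevel=2
        )
    activation[activation > duration] = np.inf

    spike_times: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    movie = np.full((n_frames, *network.field_shape), baseline, dtype=float)
    for j in range(network.n_cells):
        events = [] if np.isinf(activation[j]) else [activation[j]]
        if extra_spikes and j in extra_spikes:
            events.extend(float(e) for e in extra_spikes[j] if e < duration)
        events = np.sort(np.asarray(events))
        spike_times.append(events)
        mask = _cell_pixel_mask(network.cell_positions[j], network.field_shape)
        masks.append(mask)
        if events.size:
            trace = np.zeros(n_frames)
            for e in events:
                trace += amplitude * calcium_kernel(t - e, rise, decay)
            movie[:, mask[:, 0], mask[:, 1]] += trace[:, None]

    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, movie.shape)

    gt = CalciumGroundTruth(
        spike_times=spike_times,
        activation_time=np.where(np.isinf(activation), np.nan, activation),
        cell_pixel_masks=masks,
        truncated=truncated,
    )
    return CalciumMovie(movie, frame_rate, stim.pulse_times), gt


def biphasic_template(
    fs: float, amplitude_uv: float = 50.0, width_ms: float = 1.0
) -> np.ndarray:
    """Negative-then-positive extracellular spike template, peak = amplitude."""
    n = max(int(round(width_ms * 1e-3 * fs)), 4)
    phase = np.linspace(0, 2 * np.pi, n, endpoint=False)
    w = -np.sin(phase) * np.hanning(n)
    return amplitude_uv * w / np.max(np.abs(w))


def _thinned_poisson_train(
    rng: np.random.Generator,
    duration: float,
    baseline_rate: float,
    evoked_windows: np.ndarray,
    evoked_multiplier: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson spikes by thinning; returns (times, evoked mask)."""
    peak = baseline_rate * max(evoked_multiplier, 1.0)
    if peak <= 0:
        return np.array([]), np.array([], dtype=bool)
    n = rng.poisson(peak * duration)
    cand = np.sort(rng.uniform(0, duration, n))
    in_window = np.zeros(n, dtype=bool)
    for s, e in evoked_windows:
        in_window |= (cand >= s) & (cand < e)
    rate = np.where(in_window, baseline_rate * evoked_multiplier, baseline_rate)
    keep = rng.random(n) < rate / peak
    times, evoked = cand[keep], in_window[keep]
    if times.size:  # absolute refractory between ground-truth spikes
        ok = np.ones(times.size, dtype=bool)
        last = -np.inf
        for i, s in enumerate(times):
            if s - last < REFRACTORY_S:
                ok[i] = False
            else:
                last = s
        times, evoked = times[ok], evoked[ok]
    return times, evoked


def simulate_mea_spike_trains(
    n_electrodes: int = 16,
    duration: float = 120.0,
    baseline_rate: float = 1.0,
    evoked_multiplier: float = 3.0,
    evoked_latency: tuple[float, float] = (0.0125, 0.0075),
    response_span: float = 0.8,
    stim: StimSchedule | None = None,
    responding_electrodes: set[int] | None = None,
    seed: int = 0,
) -> MEAGroundTruth:
    """Ground-truth spike trains only (no trace rendering).

    During each pulse the firing rate on responding electrodes is multiplied
    by ``evoked_multiplier`` inside the window ``[pulse + latency_mean -
    jitter, pulse + latency_mean + jitter + response_span]``.
    """
    if evoked_multiplier < 0:
        raise ValueError("evoked_multiplier must be >= 0")
    rng = np.random.default_rng(seed)
    lat_mean, jitter = evoked_latency
    if responding_electrodes is None:
        responding_electrodes = set(range(n_electrodes))

    trains: dict[str, np.ndarray] = {}
    evoked_mask: dict[str, np.ndarray] = {}
    unit_labels: dict[str, np.ndarray] = {}
    for i in range(n_electrodes):
        eid = f"E{i:02d}"
        windows = np.empty((0, 2))
        if stim is not None and i in responding_electrodes and stim.pulse_times.size:
            starts = stim.pulse_times + lat_mean - jitter
            ends = stim.pulse_times + lat_mean + jitter + response_span
            windows = np.column_stack([np.maximum(starts, 0), np.minimum(ends, duration)])
        times, evoked = _thinned_poisson_train(
            rng, duration, baseline_rate, windows, evoked_multiplier
        )
        trains[eid] = times
        evoked_mask[eid] = evoked
        unit_labels[eid] = np.zeros(times.size, dtype=int)
    return MEAGroundTruth(
        SpikeTrainSet(trains, duration), unit_labels, evoked_mask
    )


def simulate_mea_recording(
    n_electrodes: int = 16,
    fs: float = 20_000.0,
    duration: float = 60.0,
    baseline_rate: float = 1.0,
    evoked_multiplier: float = 3.0,
    evoked_latency: tuple[float, float] = (0.0125, 0.0075),
    response_span: float = 0.8,
    stim: StimSchedule | None = None,
    waveform: tuple[float, float] = (50.0, 1.0),  # amplitude uV, width ms
    noise_sd: float = 5.0,
    responding_electrodes: set[int] | None = None,
    seed: int = 0,
) -> tuple[MEARecording, MEAGroundTruth]:
    """Render ground-truth spike trains as biphasic waveforms on noise."""
    if fs < 10_000:
        raise ValueError("fs must be >= 10 kHz")
    if noise_sd > 0 and waveform[0] / noise_sd <= 6:
        raise ValueError("waveform amplitude / noise_sd must exceed 6")
    gt = simulate_mea_spike_trains(
        n_electrodes=n_electrodes,
        duration=duration,
        baseline_rate=baseline_rate,
        evoked_multiplier=evoked_multiplier,
        evoked_latency=evoked_latency,
        response_span=response_span,
        stim=stim,
        responding_electrodes=responding_electrodes,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n_samples = int(round(duration * fs))
    template = biphasic_template(fs, *waveform)
    raw = np.empty((n_electrodes, n_samples), dtype=np.float32)
    for i, eid in enumerate(gt.trains.electrodes):
        tr = rng.normal(0.0, noise_sd, n_samples)
        for t_spk in gt.trains.trains[eid]:
            i0 = int(round(t_spk * fs))
            i1 = min(i0 + template.size, n_samples)
            tr[i0:i1] += template[: i1 - i0]
        raw[i] = tr
    stim_times = stim.pulse_times if stim is not None else np.array([])
    rec = MEARecording(raw, fs, stim_times, electrode_ids=gt.trains.electrodes)
    return rec, gt
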