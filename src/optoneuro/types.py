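"""Domain containers shared across the pipelines.

Conventions used throughout the package: times are seconds from recording
start; windows are half-open ``[start, end)``; pixel coordinates are 0-based
row-major (row = y); electrode ids are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StimSchedule:
    """Optical stimulation schedule: pulse onset times plus pulse width."""

    pulse_times: np.ndarray  # seconds, strictly ascending
    pulse_width: float  # seconds
    intensity_label: str = ""

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be > 0")
        if self.pulse_times.size and np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly ascending")


@dataclass
class NetworkModel:
    """2D cell network with conduction delays and one optically stimulated cell.

    ``adjacency`` is a symmetric boolean matrix with zero diagonal;
    ``conduction_delay[i, j]`` (seconds) is meaningful only where
    ``adjacency[i, j]`` is True.
    """

    cell_positions: np.ndarray  # (n_cells, 2) pixel coordinates (row, col)
    adjacency: np.ndarray  # (n_cells, n_cells) bool
    conduction_delay: np.ndarray  # (n_cells, n_cells) seconds
    stimulated_cell: int
    field_shape: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.cell_positions)
        a = np.asarray(self.adjacency, bool)
        if a.shape != (n, n) or np.any(np.diag(a)):
            raise ValueError("adjacency must be square with zero diagonal")
        if np.any(self.conduction_delay[a] <= 0):
            raise ValueError("all conduction delays must be > 0")
        if not (0 <= self.stimulated_cell < n):
            raise ValueError("stimulated_cell out of range")

    @property
    def n_cells(self) -> int:
        return len(self.cell_positions)


@dataclass
class CalciumGroundTruth:
    """Per-cell ground truth backing a simulated movie."""

    spike_times: list[np.ndarray]  # per cell, seconds
    activation_time: np.ndarray  # per cell, seconds; NaN if never activated
    cell_pixel_masks: list[np.ndarray]  # per cell, (k, 2) pixel indices
    truncated: bool = False  # True if the wave outran the movie duration


@dataclass
class CalciumMovie:
    """Fluorescence movie: frames x height x width with acquisition metadata."""

    data: np.ndarray
    frame_rate: float  # Hz
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("movie must be frames x height x width with >= 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[0] / self.frame_rate

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PixelMask:
    """Boolean mask of pixels retained for analysis."""

    mask: np.ndarray  # bool, height x width
    range_threshold: float  # fluorescence units used for the max-min cut


@dataclass
class SpikeEventList:
    """Calcium events detected on one trace via the instantaneous phase."""

    times: np.ndarray  # seconds, ascending
    prominences: np.ndarray  # phase prominence (radians) of each event
    evoked_index: int | None = None  # index of the stimulus-evoked event
    amplitudes: np.ndarray | None = None  # fluorescence prominence per event


@dataclass
class ActivationTimeMap:
    """Per-pixel latency T(x, y) from the stimulus to the evoked event (s)."""

    T: np.ndarray  # height x width, NaN where no clear event
    reference: str = "stimulation pulse"
    n_pre_stimulus_rejected: int = 0


@dataclass
class SpikeCountMap:
    """Per-pixel number of detected calcium events."""

    counts: np.ndarray  # int, height x width
    multi_mask: np.ndarray  # bool, counts > 1


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rank correlations between ROI traces."""

    rho: np.ndarray
    labels: list[str]


@dataclass
class MixtureFit:
    """Gaussian mixture fitted to activation-time samples."""

    k: int
    means: np.ndarray  # seconds, ascending
    sds: np.ndarray  # seconds
    weights: np.ndarray  # sums to 1
    selection_scores: dict[int, float]  # candidate k -> BIC


@dataclass
class MEARecording:
    """Raw multichannel extracellular recording."""

    raw: np.ndarray  # (n_electrodes, n_samples), microvolts
    fs: float  # Hz
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))
    layout: dict[str, tuple[int, int]] | None = None
    electrode_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.raw = np.atleast_2d(np.asarray(self.raw))
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.electrode_ids is None:
            self.electrode_ids = [f"E{i:02d}" for i in range(self.raw.shape[0])]

    @property
    def duration(self) -> float:
        return self.raw.shape[1] / self.fs


@dataclass
class SpikeTrainSet:
    """Per-electrode ascending spike times over a common duration."""

    trains: dict[str, np.ndarray]  # electrode id -> seconds, ascending
    duration: float

    def __post_init__(self) -> None:
        self.trains = {
            k: np.sort(np.asarray(v, dtype=float)) for k, v in self.trains.items()
        }
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def electrodes(self) -> list[str]:
        return list(self.trains)


@dataclass
class MEAGroundTruth:
    """Ground-truth spikes behind a simulated MEA recording."""

    trains: SpikeTrainSet
    unit_labels: dict[str, np.ndarray]  # per-spike unit id
    evoked_mask: dict[str, np.ndarray]  # per-spike bool: fired inside a stim window


@dataclass
class Burst:
    start: float
    end: float
    n_spikes: int


@dataclass
class BurstSet:
    """Per-electrode single-channel bursts and the detection parameters."""

    bursts: dict[str, list[Burst]]
    max_isi: float
    min_spikes: int


@dataclass
class NetworkBurst:
    start: float
    end: float
    n_spikes: int
    electrodes: set[str]


@dataclass
class SynchronyMatrix:
    """Pairwise spike-time tiling coefficients over active electrodes."""

    sttc: np.ndarray
    labels: list[str]
    dt: float


@dataclass
class LZCResult:
    """Lempel-Ziv complexity of a binarized spike train."""

    n: int
    c_n: int
    lzc: float  # c(n)/n * log2(n)
    binarization: str


@dataclass
class SortResult:
    """Spike-sorting output: unit labels and per-unit mean waveforms."""

    labels: np.ndarray  # per-spike unit id
    mean_waveforms: np.ndarray  # (n_units, n_samples)
    n_units: int
    pc_scores: np.ndarray  # (n_spikes, n_pcs)
    gap_scores: np.ndarray  # gap statistic per candidate k


@dataclass
class TriggerRule:
    """Closed-loop trigger: fold-increase of mean firing rate over baseline.

    Defaults encode the published rule: spikes at 3 SD above noise, at least
    8 active electrodes (half of a 16-electrode well), and at least a twofold
    mean-rate increase over the pre-stimulation baseline.
    """

    spike_threshold_sd: float = 3.0
    min_active_electrodes: int = 8
    min_fold_increase: float = 2.0
    baseline_window: float = 30.0  # seconds before the first pulse
    evaluation_window: float = 1.0  # seconds between trigger evaluations

    def __post_init__(self) -> None:
        if min(
            self.spike_threshold_sd,
            self.min_active_electrodes,
            self.min_fold_increase,
            self.baseline_window,
            self.evaluation_window,
        ) <= 0:
            raise ValueError("all TriggerRule fields must be positive")


@dataclass
class ControllerEvent:
    time: float
    state: str  # FORWARD | AVOID
    mfr_baseline: float
    mfr_current: float
    n_active_electrodes: int
    command: str | None  # AVOID | RESUME | None


@dataclass
class ControllerLog:
    events: list[ControllerEvent]

    @property
    def commands(self) -> list[tuple[float, str]]:
        return [(e.time, e.command) for e in self.events if e.command]


@dataclass
class ThermometryCalibration:
    """Arrhenius calibration of pipette resistance against temperature."""

    E_a: float  # activation energy, J/mol
    T_0: float  # reference temperature, K
    R_0: float  # pipette resistance at T_0, ohm
    R_gas: float = 8.314  # J/(mol K)

    def __post_init__(self) -> None:
        if self.E_a <= 0 or self.T_0 <= 0 or self.R_0 <= 0:
            raise ValueError("E_a, T_0 and R_0 must be positive")
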