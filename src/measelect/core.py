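"""Core domain types shared across the pipeline.

Conventions used throughout the package:

* electrode ids are 1-based, numbered row-major over the array grid;
* absolute spike and stimulus times are seconds from recording start;
* post-stimulus latencies, bin widths and windows are milliseconds;
* every interval is half-open ``[a, b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArrayGeometry",
    "ProtocolSpec",
    "SpikeTrainSet",
    "StimulationLog",
    "WindowSpec",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Planar electrode grid (default: 8x8 electrodes, 150 um pitch, 50 um size)."""

    n_rows: int = 8
    n_cols: int = 8
    electrode_pitch: float = 150.0
    electrode_size: float = 50.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not (self.electrode_pitch > self.electrode_size > 0):
            raise ValueError("electrode pitch must exceed electrode size, both > 0")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def position(self, electrode_id: int) -> tuple[int, int]:
        """(row, col), 0-based, for a 1-based row-major electrode id."""
        if not 1 <= electrode_id <= self.n_electrodes:
            raise ValueError(f"electrode id {electrode_id} outside 1..{self.n_electrodes}")
        idx = electrode_id - 1
        return idx // self.n_cols, idx % self.n_cols

    def grid(self, values: np.ndarray) -> np.ndarray:
        """Arrange a per-electrode vector (length n_electrodes) onto the grid."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_electrodes,):
            raise ValueError(f"expected {self.n_electrodes} values, got {values.shape}")
        return values.reshape(self.n_rows, self.n_cols)


def _default_site_order(n_sites: int, blocks_per_site: int) -> tuple[str, ...]:
    # interleaved blocks: S1, S2, ..., Sn repeated blocks_per_site times
    labels = [f"S{i + 1}" for i in range(n_sites)]
    return tuple(labels * blocks_per_site)


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol: blocks of stimuli delivered alternately to each site.

    The default reproduces a two-site trial of two 15-stimulus blocks per site
    (30 stimuli per site in total), delivered as S1-block, S2-block, S1-block,
    S2-block, with the inter-stimulus interval matched to the spontaneous
    inter-burst interval (10-20 s).
    """

    n_sites: int = 2
    stimuli_per_block: int = 15
    blocks_per_site: int = 2
    inter_stimulus_interval: float | None = None  # seconds; None -> drawn from burst range
    site_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.stimuli_per_block < 1 or self.blocks_per_site < 1:
            raise ValueError("protocol counts must be positive")
        if self.inter_stimulus_interval is not None and self.inter_stimulus_interval <= 0:
            raise ValueError("inter-stimulus interval must be positive")
        if not self.site_order:
            object.__setattr__(
                self, "site_order", _default_site_order(self.n_sites, self.blocks_per_site)
            )
        expected = {f"S{i + 1}": self.blocks_per_site for i in range(self.n_sites)}
        seen: dict[str, int] = {}
        for label in self.site_order:
            seen[label] = seen.get(label, 0) + 1
        if seen != expected:
            raise ValueError(
                f"site_order must contain each of {sorted(expected)} "
                f"exactly {self.blocks_per_site} times, got {self.site_order}"
            )

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_sites))

    @property
    def stimuli_per_site(self) -> int:
        return self.stimuli_per_block * self.blocks_per_site

    @property
    def total_stimuli(self) -> int:
        return self.stimuli_per_site * self.n_sites


@dataclass
class StimulationLog:
    """Ordered stimulation events: onset times (s) and site labels."""

    times: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sites = np.asarray(self.sites, dtype=object)
        if self.times.ndim != 1 or self.times.shape != self.sites.shape:
            raise ValueError("times and sites must be 1-d arrays of equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("stimulation times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def site_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.sites:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def indices_for(self, site: str) -> np.ndarray:
        return np.flatnonzero(self.sites == site)

    def blocks(self) -> list[tuple[str, np.ndarray]]:
        """Consecutive runs of same-site stimuli, in stimulation order."""
        out: list[tuple[str, np.ndarray]] = []
        start = 0
        for i in range(1, len(self.times) + 1):
            if i == len(self.times) or self.sites[i] != self.sites[start]:
                out.append((str(self.sites[start]), np.arange(start, i)))
                start = i
        return out


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike times (seconds) for one recording."""

    trains: dict[int, np.ndarray]
    n_electrodes: int
    duration: float
    geometry: ArrayGeometry | None = None

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for eid, times in self.trains.items():
            eid = int(eid)
            if not 1 <= eid <= self.n_electrodes:
                raise ValueError(f"electrode id {eid} outside 1..{self.n_electrodes}")
            arr = np.sort(np.asarray(times, dtype=float))
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite spike time on electrode {eid}")
            clean[eid] = arr
        self.trains = clean

    def train(self, electrode_id: int) -> np.ndarray:
        return self.trains.get(electrode_id, np.empty(0))

    @property
    def electrode_ids(self) -> list[int]:
        return list(range(1, self.n_electrodes + 1))

    @property
    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains.values()))

    def spikes_in(self, electrode_id: int, t0: float, t1: float) -> np.ndarray:
        """Spike times in [t0, t1) on one electrode."""
        t = self.train(electrode_id)
        lo, hi = np.searchsorted(t, [t0, t1], side="left")
        return t[lo:hi]

    def shifted(self, offset: float) -> "SpikeTrainSet":
        return SpikeTrainSet(
            {e: t + offset for e, t in self.trains.items()},
            n_electrodes=self.n_electrodes,
            duration=self.duration + offset,
            geometry=self.geometry,
        )


@dataclass(frozen=True)
class WindowSpec:
    """Post-stimulus analysis window (ms): 15 bins of 20 ms covering [0, 300),
    with spikes before the synaptic onset (15 ms) discarded as non-synaptic."""

    response_window: float = 300.0
    synaptic_onset: float = 15.0
    bin_width: float = 20.0
    n_bins: int = 15

    def __post_init__(self) -> None:
        if not np.isclose(self.n_bins * self.bin_width, self.response_window):
            raise ValueError("n_bins * bin_width must equal response_window")
        if not 0 <= self.synaptic_onset < self.response_window:
            raise ValueError("synaptic_onset must lie in [0, response_window)")

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in ms, aligned to the stimulus at 0."""
        return np.arange(self.n_bins + 1, dtype=float) * self.bin_width
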