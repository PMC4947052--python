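"""Per-stimulus response feature extraction and inclusion filters.

For each stimulus a response pattern is built: spike counts per electrode in
20 ms bins over the 300 ms post-stimulus window, the activation time (latency
of the first synaptically evoked spike), and the total spike count.  Spikes in
the first 15 ms are discarded as non-synaptic.  The inclusion filters select

* *active* electrodes — at least one spike within the window in **more than**
  80 % of the stimuli (strict inequality),
* *stable* bins — at least one spike in the bin in **at least** 80 % of the
  stimuli (inclusive inequality),
* *stationary* electrodes — no significant rank-sum difference of the total
  spike count between the two repeated blocks of either site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stats import rank_sum_p
from .core import SpikeTrainSet, StimulationLog, WindowSpec

__all__ = [
    "ResponsePattern",
    "FilterReport",
    "extract_response",
    "extract_patterns",
    "population_psth",
    "active_electrodes",
    "stable_bins",
    "stationarity_filter",
    "build_filter_report",
]


@dataclass
class ResponsePattern:
    """One stimulus's response: electrodes x bins spike counts plus per-electrode
    activation time (ms; NaN when no synaptic spike was evoked)."""

    stimulus_index: int
    site: str
    counts: np.ndarray  # (n_electrodes, n_bins) non-negative ints
    activation_time: np.ndarray  # (n_electrodes,) ms, NaN = missing

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.activation_time = np.asarray(self.activation_time, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.counts.shape[0] != self.activation_time.shape[0]:
            raise ValueError("counts and activation_time disagree on electrode count")
        empty = self.counts.sum(axis=1) == 0
        if np.any(~np.isnan(self.activation_time[empty])):
            raise ValueError("activation time present for an electrode with zero spikes")

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def total_spike_count(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def extract_response(
    spikes: SpikeTrainSet,
    stim_time: float,
    window: WindowSpec | None = None,
    stimulus_index: int = 0,
    site: str = "S1",
    t_stop: float | None = None,
) -> ResponsePattern:
    """Bin one stimulus's spikes into a response pattern.

    Latencies in [0, synaptic_onset) ms are discarded; latencies in
    [synaptic_onset, response_window) fall into half-open 20 ms bins aligned
    to the stimulus.  ``t_stop`` (absolute s) truncates the window if the
    next stimulus arrives sooner than the full response window.
    """
    window = window or WindowSpec()
    limit_ms = window.response_window
    if t_stop is not None:
        limit_ms = min(limit_ms, (t_stop - stim_time) * 1000.0)
    counts = np.zeros((spikes.n_electrodes, window.n_bins), dtype=int)
    activation = np.full(spikes.n_electrodes, np.nan)
    for e in spikes.electrode_ids:
        lat = (spikes.spikes_in(e, stim_time, stim_time + limit_ms / 1000.0) - stim_time) * 1000.0
        lat = lat[(lat >= window.synaptic_onset) & (lat < limit_ms)]
        if lat.size:
            counts[e - 1] = np.histogram(lat, bins=window.edges)[0]
            activation[e - 1] = lat.min()
    return ResponsePattern(stimulus_index, site, counts, activation)


def extract_patterns(
    spikes: SpikeTrainSet, stims: StimulationLog, window: WindowSpec | None = None
) -> list[ResponsePattern]:
    """Response patterns for every stimulus in the log, in stimulation order."""
    window = window or WindowSpec()
    out = []
    for i, (t, site) in enumerate(zip(stims.times, stims.sites)):
        t_stop = stims.times[i + 1] if i + 1 < len(stims) else None
        out.append(
            extract_response(spikes, t, window, stimulus_index=i, site=str(site), t_stop=t_stop)
        )
    return out


def population_psth(patterns: list[ResponsePattern], mode: str = "mean") -> np.ndarray:
    """Per-bin total spike count over all electrodes, averaged (``mean``) or
    summed (``sum``) over stimuli."""
    if not patterns:
        raise ValueError("population_psth requires at least one pattern")
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    stacked = np.stack([p.counts.sum(axis=0) for p in patterns])
    return stacked.mean(axis=0) if mode == "mean" else stacked.sum(axis=0)


def _site_groups(patterns: list[ResponsePattern], per_site: bool) -> list[list[ResponsePattern]]:
    if not per_site:
        return [patterns]
    sites: list[str] = []
    for p in patterns:
        if p.site not in sites:
            sites.append(p.site)
    return [[p for p in patterns if p.site == s] for s in sites]


def active_electrodes(
    patterns: list[ResponsePattern], threshold_frac: float = 0.8, per_site: bool = True
) -> np.ndarray:
    """Boolean mask of electrodes responding (>=1 spike in the window) in
    strictly more than ``threshold_frac`` of stimuli.  With ``per_site`` the
    criterion must hold for each site separately (default)."""
    if not patterns:
        raise ValueError("no patterns")
    mask = np.ones(patterns[0].n_electrodes, dtype=bool)
    for group in _site_groups(patterns, per_site):
        responded = np.stack([p.total_spike_count >= 1 for p in group])
        mask &= responded.mean(axis=0) > threshold_frac
    return mask


def stable_bins(
    patterns: list[ResponsePattern], threshold_frac: float = 0.8, per_site: bool = True
) -> np.ndarray:
    """Boolean (electrodes x bins) mask of bins with >=1 spike in at least
    ``threshold_frac`` of stimuli (inclusive, unlike the active-electrode
    criterion)."""
    if not patterns:
        raise ValueError("no patterns")
    mask = np.ones_like(patterns[0].counts, dtype=bool)
    for group in _site_groups(patterns, per_site):
        nonzero = np.stack([p.counts >= 1 for p in group])
        mask &= nonzero.mean(axis=0) >= threshold_frac
    return mask


def stationarity_filter(
    patterns: list[ResponsePattern],
    alpha: float = 0.05,
    electrodes: np.ndarray | None = None,
    min_samples: int = 3,
) -> np.ndarray:
    """Boolean mask of electrodes whose responses are stationary across the
    repeated blocks of each site.

    Per electrode and site, the total spike counts of the site's first block
    are compared with its second block by a two-sided Mann-Whitney test;
    only responses with at least one spike enter the comparison.  An
    electrode is non-stationary if any site shows p < alpha.  Blocks whose
    non-empty samples are smaller than ``min_samples`` are not testable and
    count as stationary.
    """
    if not patterns:
        raise ValueError("no patterns")
    runs: list[tuple[str, list[ResponsePattern]]] = []
    for p in patterns:
        if runs and runs[-1][0] == p.site:
            runs[-1][1].append(p)
        else:
            runs.append((p.site, [p]))
    by_site: dict[str, list[list[ResponsePattern]]] = {}
    for site, group in runs:
        by_site.setdefault(site, []).append(group)
    for site, blocks in by_site.items():
        if len(blocks) < 2:
            raise ValueError(f"site {site} was not stimulated in two separate blocks")

    n_e = patterns[0].n_electrodes
    candidates = np.ones(n_e, dtype=bool) if electrodes is None else np.asarray(electrodes, bool)
    stationary = candidates.copy()
    for e in np.nonzero(candidates)[0]:
        for site, blocks in by_site.items():
            t1 = np.array([p.total_spike_count[e] for p in blocks[0]])
            t2 = np.array([p.total_spike_count[e] for p in blocks[1]])
            t1, t2 = t1[t1 > 0], t2[t2 > 0]
            if t1.size < min_samples or t2.size < min_samples:
                continue
            if rank_sum_p(t1, t2) < alpha:
                stationary[e] = False
                break
    return stationary


@dataclass
class FilterReport:
    """Outcome of the three inclusion filters.

    ``stable`` is defined only on active electrodes (False elsewhere);
    ``stationary`` is a subset of ``active``.
    """

    active: np.ndarray
    stable: np.ndarray
    stationary: np.ndarray
    n_excluded_inactive: int = 0
    n_excluded_nonstationary: int = 0

    @property
    def eligible_cells(self) -> np.ndarray:
        """(electrodes x bins) mask of cells entering the signatures:
        stable bins of active, stationary electrodes."""
        return self.stable & self.stationary[:, None]

    def to_dict(self) -> dict:
        return {
            "active_electrodes": [int(i + 1) for i in np.nonzero(self.active)[0]],
            "stationary_electrodes": [int(i + 1) for i in np.nonzero(self.stationary)[0]],
            "stable_bins": {
                str(i + 1): [int(b) for b in np.nonzero(self.stable[i])[0]]
                for i in range(self.stable.shape[0])
                if self.stable[i].any()
            },
            "n_excluded_inactive": int(self.n_excluded_inactive),
            "n_excluded_nonstationary": int(self.n_excluded_nonstationary),
        }


def build_filter_report(
    patterns: list[ResponsePattern],
    active_threshold: float = 0.8,
    stable_threshold: float = 0.8,
    stationarity_alpha: float = 0.05,
    per_site: bool = True,
) -> FilterReport:
    active = active_electrodes(patterns, active_threshold, per_site)
    stable = stable_bins(patterns, stable_threshold, per_site) & active[:, None]
    stationary = stationarity_filter(patterns, stationarity_alpha, electrodes=active)
    return FilterReport(
        active=active,
        stable=stable,
        stationary=stationary,
        n_excluded_inactive=int((~active).sum()),
        n_excluded_nonstationary=int((active & ~stationary).sum()),
    )
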