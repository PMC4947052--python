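"""Synthetic MEA recording generator.

Emulates stimulus-evoked population bursts on an electrode array so that the
downstream analysis (feature extraction, selectivity statistics, decoding) can
be validated by parameter recovery.  The statistical structure is:

* each stimulus evokes, on each responsive electrode (Bernoulli thinning with
  probability ``p[e, site]``), spikes from a binned inhomogeneous Poisson
  process over the post-stimulus window, restricted to latencies after the
  synaptic onset;
* the first-spike latency is controlled independently of the rate: when
  latency jitter is enabled the earliest evoked spike of a response is moved
  to a draw from a truncated normal distribution, so activation time and
  spike rate can carry site information separately;
* spontaneous bursts recruiting all electrodes are inserted at renewal times
  with uniform inter-burst intervals (10-20 s by default) and may contaminate
  response windows, as in real recordings;
* optional raw-trace synthesis embeds a biphasic ~1 ms spike template in
  band-limited Gaussian noise at 20 kHz for validating the detector.

Per-electrode expected total evoked spike count is exactly
``p[e, s] * sum_b rate[e, s, b]`` (Poisson thinning), which unit tests use as
an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ArrayGeometry, ProtocolSpec, SpikeTrainSet, StimulationLog, WindowSpec

__all__ = [
    "ResponseModel",
    "RawTraceSpec",
    "GroundTruth",
    "RawRecording",
    "burst_envelope",
    "make_response_model",
    "generate_recording",
    "generate_raw_trace",
]


def burst_envelope(
    n_bins: int = 15, peak_bin: int = 3, peak_rate: float = 2.0
) -> np.ndarray:
    """Gamma-shaped per-bin rate envelope: fast rise, slow decay, peaking at
    ``peak_bin`` (0-based; default bin 3 = 60-80 ms, within the 50-100 ms
    range where evoked bursts peak)."""
    if not 0 <= peak_bin < n_bins:
        raise ValueError("peak_bin outside bin range")
    x = np.arange(1, n_bins + 1, dtype=float)
    theta = (peak_bin + 1) / 2.0  # mode of x^2 exp(-x/theta) is 2 theta
    env = x**2 * np.exp(-x / theta)
    return peak_rate * env / env.max()


@dataclass
class ResponseModel:
    """Ground-truth response statistics per electrode and stimulation site.

    Shapes: ``response_prob`` and ``latency_mean``/``latency_sd`` are
    (n_electrodes, n_sites); ``rate`` is (n_electrodes, n_sites, n_bins)
    expected spikes per bin. ``block2_scale`` multiplies rates during the
    second block of each site, to model non-stationary electrodes.
    """

    response_prob: np.ndarray
    latency_mean: np.ndarray
    latency_sd: np.ndarray
    rate: np.ndarray
    spontaneous_rate: np.ndarray
    burst_interval: tuple[float, float] = (10.0, 20.0)
    block2_scale: np.ndarray | None = None
    spontaneous: bool = True
    latency_jitter: bool = True
    window: WindowSpec = field(default_factory=WindowSpec)
    #: optional second response motif per site: with probability ``motif_prob``
    #: a stimulus evokes rates from ``rate_alt`` instead of ``rate`` (the whole
    #: network switches coherently, emulating multiple response types per site)
    rate_alt: np.ndarray | None = None
    motif_prob: float = 0.0

    def __post_init__(self) -> None:
        self.response_prob = np.asarray(self.response_prob, dtype=float)
        self.latency_mean = np.asarray(self.latency_mean, dtype=float)
        self.latency_sd = np.asarray(self.latency_sd, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.spontaneous_rate = np.asarray(self.spontaneous_rate, dtype=float)
        n_e, n_s, n_b = self.rate.shape
        for name, arr, shape in [
            ("response_prob", self.response_prob, (n_e, n_s)),
            ("latency_mean", self.latency_mean, (n_e, n_s)),
            ("latency_sd", self.latency_sd, (n_e, n_s)),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if self.spontaneous_rate.shape != (n_e, n_b):
            raise ValueError("spontaneous_rate must have shape (n_electrodes, n_bins)")
        if not np.all(np.isfinite(self.rate)) or np.any(self.rate < 0):
            raise ValueError("rates must be finite and non-negative")
        if np.any(self.spontaneous_rate < 0) or not np.all(np.isfinite(self.spontaneous_rate)):
            raise ValueError("spontaneous rates must be finite and non-negative")
        if np.any(self.response_prob < 0) or np.any(self.response_prob > 1):
            raise ValueError("response probabilities must lie in [0, 1]")
        if np.any(self.latency_sd <= 0):
            raise ValueError("latency sd must be positive")
        lo, hi = self.burst_interval
        if not 0 < lo <= hi:
            raise ValueError("burst interval bounds must satisfy 0 < lo <= hi")
        if self.block2_scale is None:
            self.block2_scale = np.ones(n_e)
        else:
            self.block2_scale = np.asarray(self.block2_scale, dtype=float)
            if self.block2_scale.shape != (n_e,):
                raise ValueError("block2_scale must have shape (n_electrodes,)")
        if n_b != self.window.n_bins:
            raise ValueError("rate bins must match the window's n_bins")
        if not 0 <= self.motif_prob <= 1:
            raise ValueError("motif_prob must lie in [0, 1]")
        if self.rate_alt is not None:
            self.rate_alt = np.asarray(self.rate_alt, dtype=float)
            if self.rate_alt.shape != self.rate.shape:
                raise ValueError("rate_alt must match rate's shape")
            if np.any(self.rate_alt < 0) or not np.all(np.isfinite(self.rate_alt)):
                raise ValueError("alternative rates must be finite and non-negative")

    @property
    def n_electrodes(self) -> int:
        return self.rate.shape[0]

    @property
    def n_sites(self) -> int:
        return self.rate.shape[1]

    def marginal_rate(self) -> np.ndarray:
        """Motif-probability-weighted expected rate per (electrode, site, bin)."""
        if self.rate_alt is None or self.motif_prob == 0:
            return self.rate
        return (1 - self.motif_prob) * self.rate + self.motif_prob * self.rate_alt

    def selective_cells(self) -> frozenset[tuple[int, int]]:
        """(electrode_id, bin) cells whose expected rate differs across sites.

        Motif mixtures enter through their marginal mean, so electrodes whose
        motifs differ across sites only jointly (identical marginals) are
        correctly not marked selective at the single-electrode level.
        """
        diff = np.ptp(self.marginal_rate(), axis=1) > 1e-12
        return frozenset(
            (int(e + 1), int(b)) for e, b in zip(*np.nonzero(diff))
        )

    def selective_electrodes(self) -> frozenset[int]:
        """Electrode ids with any site-dependent rate, latency or probability."""
        rate_diff = np.any(np.ptp(self.marginal_rate(), axis=1) > 1e-12, axis=1)
        lat_diff = np.ptp(self.latency_mean, axis=1) > 0
        p_diff = np.ptp(self.response_prob, axis=1) > 0
        return frozenset(int(e + 1) for e in np.nonzero(rate_diff | lat_diff | p_diff)[0])


def make_response_model(
    n_electrodes: int = 64,
    n_sites: int = 2,
    window: WindowSpec | None = None,
    response_prob: float = 0.95,
    latency_mean_ms: float = 40.0,
    latency_sd_ms: float = 8.0,
    peak_rate: float = 2.0,
    peak_bin: int = 3,
    selective_electrodes: tuple[int, ...] = (),
    selective_bins: tuple[int, ...] | None = None,
    rate_gain: float = 2.0,
    latency_shift_ms: float = 0.0,
    spontaneous: bool = True,
    burst_interval: tuple[float, float] = (10.0, 20.0),
    block2_scale: dict[int, float] | None = None,
    latency_jitter: bool = True,
    motif_electrodes: tuple[int, ...] = (),
    motif_gain: float = 3.0,
    motif_prob: float = 0.5,
) -> ResponseModel:
    """Build a two-or-more-site model from scalar knobs.

    Site differences are introduced on ``selective_electrodes`` (1-based ids):
    site 2 rates are multiplied by ``rate_gain`` on ``selective_bins``
    (all bins if None) and site-2 latency means shifted by
    ``latency_shift_ms``.  With no selective electrodes the model is null:
    identical statistics for every site.

    ``motif_electrodes`` (two-site models only) configures a pair of response
    motifs per site on those electrodes, arranged so that the two sites have
    identical per-electrode marginals but opposite cross-electrode structure
    (site 1 motifs anticorrelated across the two halves of the group, site 2
    correlated).  Such responses separate the sites only jointly and
    non-linearly — single-electrode statistics carry no site information.
    """
    window = window or WindowSpec()
    n_bins = window.n_bins
    env = burst_envelope(n_bins, peak_bin=peak_bin, peak_rate=peak_rate)
    rate = np.tile(env, (n_electrodes, n_sites, 1))
    lat = np.full((n_electrodes, n_sites), latency_mean_ms)
    for eid in selective_electrodes:
        bins = range(n_bins) if selective_bins is None else selective_bins
        for b in bins:
            rate[eid - 1, 1:, b] *= rate_gain
        lat[eid - 1, 1:] += latency_shift_ms
    scale = np.ones(n_electrodes)
    for eid, factor in (block2_scale or {}).items():
        scale[eid - 1] = factor
    rate_alt = None
    if motif_electrodes:
        if n_sites != 2:
            raise ValueError("motif electrodes require a two-site model")
        if len(motif_electrodes) < 2:
            raise ValueError("need at least two motif electrodes")
        rate_alt = rate.copy()
        hi, lo = env * motif_gain, env / motif_gain
        half = len(motif_electrodes) // 2
        group_a = [e - 1 for e in motif_electrodes[:half]]
        group_b = [e - 1 for e in motif_electrodes[half:]]
        rate[group_a, 0], rate[group_b, 0] = hi, lo        # site 1 base: A hi, B lo
        rate_alt[group_a, 0], rate_alt[group_b, 0] = lo, hi  # site 1 alt: A lo, B hi
        rate[group_a, 1], rate[group_b, 1] = hi, hi        # site 2 base: both hi
        rate_alt[group_a, 1], rate_alt[group_b, 1] = lo, lo  # site 2 alt: both lo
    return ResponseModel(
        response_prob=np.full((n_electrodes, n_sites), response_prob),
        latency_mean=lat,
        latency_sd=np.full((n_electrodes, n_sites), latency_sd_ms),
        rate=rate,
        spontaneous_rate=np.tile(env, (n_electrodes, 1)),
        burst_interval=burst_interval,
        block2_scale=scale,
        spontaneous=spontaneous,
        latency_jitter=latency_jitter,
        window=window,
        rate_alt=rate_alt,
        motif_prob=motif_prob if motif_electrodes else 0.0,
    )


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery validation."""

    selective_electrodes: frozenset[int]
    selective_cells: frozenset[tuple[int, int]]
    inter_stimulus_interval: float
    spontaneous_burst_times: np.ndarray
    seed: int


@dataclass
class RawTraceSpec:
    """Raw-trace synthesis parameters (default 20 kHz, 10-40 uV spikes)."""

    sampling_rate: float = 20_000.0
    noise_sd: float = 3.0
    spike_amplitude_range: tuple[float, float] = (10.0, 40.0)
    template_duration_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 8000:
            raise ValueError("sampling rate must exceed twice the 8 kHz band edge")
        lo, hi = self.spike_amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("spike amplitudes must be positive, lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class RawRecording:
    """Multi-channel extracellular trace in uV; channels are electrode ids 1..n."""

    data: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


def _bin_supports(window: WindowSpec, clip_onset: bool) -> tuple[np.ndarray, np.ndarray]:
    lo = window.edges[:-1].copy()
    hi = window.edges[1:].copy()
    if clip_onset:
        lo = np.maximum(lo, window.synaptic_onset)
    return lo, hi


def _burst_spikes(
    counts: np.ndarray, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place per-(electrode, bin) counts uniformly in each bin's support.

    Returns (electrode_index_0based, latency_ms) for all spikes of one burst.
    """
    n_e, n_b = counts.shape
    flat = counts.ravel()
    total = int(flat.sum())
    if total == 0:
        return np.empty(0, dtype=int), np.empty(0)
    e_idx = np.repeat(np.repeat(np.arange(n_e), n_b), flat)
    b_idx = np.repeat(np.tile(np.arange(n_b), n_e), flat)
    u = rng.random(total)
    t_ms = lo[b_idx] + u * (hi[b_idx] - lo[b_idx])
    return e_idx, t_ms


def generate_recording(
    geometry: ArrayGeometry,
    protocol: ProtocolSpec,
    model: ResponseModel,
    seed: int,
    start_pad: float | None = None,
    end_pad: float = 2.0,
) -> tuple[SpikeTrainSet, StimulationLog, GroundTruth]:
    """Simulate one stimulation trial.

    Deterministic for a fixed seed: a master ``numpy`` generator is spawned
    into independent streams for protocol timing, evoked responses and
    spontaneous activity, so toggling one component leaves the others'
    draws unchanged.
    """
    if geometry.n_electrodes != model.n_electrodes:
        raise ValueError("geometry and model disagree on electrode count")
    if protocol.n_sites != model.n_sites:
        raise ValueError("protocol and model disagree on site count")
    master = np.random.default_rng(seed)
    stim_rng, resp_rng, spont_rng = master.spawn(3)
    window = model.window

    isi = protocol.inter_stimulus_interval
    if isi is None:
        isi = float(stim_rng.uniform(*model.burst_interval))
    t0 = start_pad if start_pad is not None else isi
    stim_times = t0 + isi * np.arange(protocol.total_stimuli)
    sites = np.concatenate(
        [[label] * protocol.stimuli_per_block for label in protocol.site_order]
    )
    log = StimulationLog(stim_times, sites)
    duration = float(stim_times[-1] + window.response_window / 1000.0 + end_pad)

    site_index = {label: i for i, label in enumerate(protocol.site_labels)}
    # which block (0 or 1) of its own site each stimulus belongs to
    block_of: np.ndarray = np.zeros(len(log), dtype=int)
    seen: dict[str, int] = {}
    for site_label, idx in log.blocks():
        block_of[idx] = seen.get(site_label, 0)
        seen[site_label] = seen.get(site_label, 0) + 1

    lo, hi = _bin_supports(window, clip_onset=True)
    n_e = model.n_electrodes
    per_electrode: list[list[np.ndarray]] = [[] for _ in range(n_e)]

    for i, (t_s, site_label) in enumerate(zip(log.times, log.sites)):
        s = site_index[str(site_label)]
        use_alt = (
            model.rate_alt is not None
            and model.motif_prob > 0
            and resp_rng.random() < model.motif_prob
        )
        lam = (model.rate_alt if use_alt else model.rate)[:, s, :].copy()
        if block_of[i] == 1:
            lam *= model.block2_scale[:, None]
        responders = resp_rng.random(n_e) < model.response_prob[:, s]
        counts = resp_rng.poisson(lam) * responders[:, None]
        e_idx, t_ms = _burst_spikes(counts, lo, hi, resp_rng)
        if model.latency_jitter:
            totals = counts.sum(axis=1)
            firing = np.nonzero(totals > 0)[0]
            if firing.size:
                mu = model.latency_mean[firing, s]
                sd = model.latency_sd[firing, s]
                a = (window.synaptic_onset - mu) / sd
                b = (window.response_window - mu) / sd
                lat = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=resp_rng)
                lat = np.atleast_1d(lat)
                order = np.argsort(t_ms, kind="stable")
                first_pos: dict[int, int] = {}
                for pos in order:
                    e = int(e_idx[pos])
                    if e not in first_pos:
                        first_pos[e] = int(pos)
                for e, l in zip(firing, lat):
                    t_ms[first_pos[int(e)]] = l
        t_abs = t_s + t_ms / 1000.0
        for e in np.unique(e_idx):
            per_electrode[int(e)].append(t_abs[e_idx == e])

    burst_times: list[float] = []
    if model.spontaneous:
        t = float(spont_rng.uniform(*model.burst_interval))
        lo_s, hi_s = _bin_supports(window, clip_onset=False)
        while t < duration - window.response_window / 1000.0:
            burst_times.append(t)
            counts = spont_rng.poisson(model.spontaneous_rate)
            e_idx, t_ms = _burst_spikes(counts, lo_s, hi_s, spont_rng)
            t_abs = t + t_ms / 1000.0
            for e in np.unique(e_idx):
                per_electrode[int(e)].append(t_abs[e_idx == e])
            t += float(spont_rng.uniform(*model.burst_interval))

    trains = {
        e + 1: np.sort(np.concatenate(parts)) if parts else np.empty(0)
        for e, parts in enumerate(per_electrode)
    }
    spikes = SpikeTrainSet(trains, n_electrodes=n_e, duration=duration, geometry=geometry)
    truth = GroundTruth(
        selective_electrodes=model.selective_electrodes(),
        selective_cells=model.selective_cells(),
        inter_stimulus_interval=isi,
        spontaneous_burst_times=np.asarray(burst_times),
        seed=seed,
    )
    return spikes, log, truth


def spike_template(spec: RawTraceSpec) -> tuple[np.ndarray, int]:
    """Biphasic unit-amplitude template and the sample offset of its peak."""
    n = max(int(round(spec.template_duration_ms * 1e-3 * spec.sampling_rate)), 8)
    t = np.arange(n) / n
    w = -np.sin(2 * np.pi * t) * np.exp(-3.0 * t)  # negative-leading biphasic
    w /= np.max(np.abs(w))
    return w, int(np.argmax(np.abs(w)))


def generate_raw_trace(
    spikes: SpikeTrainSet,
    spec: RawTraceSpec,
    seed: int,
    duration: float | None = None,
) -> RawRecording:
    """Render spike trains as raw extracellular traces: Gaussian noise plus a
    biphasic template at each spike time, amplitude drawn uniformly from the
    configured range.  The template's extremum lands on the spike's sample."""
    duration = duration if duration is not None else spikes.duration
    n_samples = int(round(duration * spec.sampling_rate))
    rng = np.random.default_rng(seed)
    template, peak_off = spike_template(spec)
    data = rng.normal(0.0, spec.noise_sd, size=(spikes.n_electrodes, n_samples))
    lo_amp, hi_amp = spec.spike_amplitude_range
    for e in spikes.electrode_ids:
        times = spikes.train(e)
        if times.size and (times.min() < 0 or times.max() >= duration):
            raise ValueError(f"spike time outside trace duration on electrode {e}")
        idx = np.round(times * spec.sampling_rate).astype(int)
        amps = rng.uniform(lo_amp, hi_amp, size=idx.size)
        row = data[e - 1]
        for i, a in zip(idx, amps):
            start = i - peak_off
            t0 = max(0, -start)
            t1 = min(len(template), n_samples - start)
            if t1 > t0:
                row[start + t0 : start + t1] += a * template[t0:t1]
    return RawRecording(data=data, sampling_rate=spec.sampling_rate)
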