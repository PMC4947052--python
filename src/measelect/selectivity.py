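"""Selectivity statistics: rank-sum tests and the K-means misclassification
overlap, assembled into per-electrode / per-bin signatures.

The *overlap* quantifies how separable two sets of responses are without
using their labels: both sets are pooled and split into two clusters by
K-means (k = 2); clusters are then matched to the source labels by the
assignment that minimizes misclassification, and the overlap is the percent
of responses on the wrong side, ``100 * N_c / n_total``.  Label matching
bounds the overlap to [0, 50]: 0 % means the two sites' responses are fully
separable, 50 % means chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._stats import rank_sum_p
from .core import ArrayGeometry, WindowSpec
from .features import FilterReport, ResponsePattern

__all__ = [
    "OverlapResult",
    "SelectivityTest",
    "SelectivitySignature",
    "OverlapSignature",
    "statistical_selectivity",
    "overlap",
    "build_signatures",
    "spatial_overlap_map",
]

#: default significance levels: whole-response features per electrode vs per-bin tests
ALPHA_ELECTRODE = 0.001
ALPHA_BIN = 0.05


@dataclass(frozen=True)
class SelectivityTest:
    selective: bool
    p_value: float
    alpha: float


def statistical_selectivity(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float = ALPHA_ELECTRODE
) -> SelectivityTest:
    """Two-sided Mann-Whitney rank-sum test; selective iff p < alpha."""
    p = rank_sum_p(values_a, values_b)
    return SelectivityTest(selective=bool(p < alpha), p_value=p, alpha=alpha)


@dataclass(frozen=True)
class OverlapResult:
    """K-means misclassification overlap between two labelled response sets.

    ``n_a`` counts set-B responses assigned to set A's cluster, ``n_b`` the
    converse; ``n_c = n_a + n_b`` misclassified out of ``n_total`` pooled
    responses, and ``overlap_percent = 100 * n_c / n_total``.
    """

    overlap_percent: float
    n_a: int
    n_b: int
    n_total: int
    degenerate: bool = False

    @property
    def n_c(self) -> int:
        return self.n_a + self.n_b


def overlap(
    values_a: np.ndarray,
    values_b: np.ndarray,
    random_state: int = 0,
    n_init: int = 10,
) -> OverlapResult:
    """Compute the overlap between two response sets (scalars or vectors).

    Scalar inputs are clustered in one dimension; vector inputs (e.g. whole
    spike-rate patterns) use the Euclidean metric.  K-means is run with
    seeded k-means++ and ``n_init`` restarts so the statistic is
    reproducible.  Degenerate input (all pooled values identical) carries no
    information: all responses fall into one cluster, giving the chance-level
    overlap for balanced sets, and the result is flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("the two sets must have the same feature dimension")
    n_a_rows, n_b_rows = a.shape[0], b.shape[0]
    n_total = n_a_rows + n_b_rows
    if n_total < 4:
        raise ValueError("overlap requires at least 4 responses in total")
    x = np.vstack([a, b])
    if not np.all(np.isfinite(x)):
        raise ValueError("responses must be finite")
    is_b = np.zeros(n_total, dtype=bool)
    is_b[n_a_rows:] = True

    if np.all(x == x[0]):
        # no information: every response in one cluster; misclassification is
        # the minority class, i.e. chance level for balanced sets
        n_mis = min(n_a_rows, n_b_rows)
        n_a = n_mis if n_b_rows <= n_a_rows else 0
        n_b = n_mis - n_a
        return OverlapResult(100.0 * n_mis / n_total, n_a, n_b, n_total, degenerate=True)

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*smaller than n_clusters.*")
        km = KMeans(n_clusters=2, n_init=n_init, random_state=random_state)
        # fit on canonically sorted rows so the clustering depends only on the
        # pooled multiset of responses, making the overlap invariant to the
        # order of the inputs and to relabelling A <-> B
        km.fit(x[np.lexsort(x.T[::-1])])
        assign = km.predict(x)

    # matching 0: cluster 0 is A'; matching 1: cluster 1 is A'
    mis0 = int(np.sum((assign == 0) & is_b) + np.sum((assign == 1) & ~is_b))
    mis1 = int(np.sum((assign == 1) & is_b) + np.sum((assign == 0) & ~is_b))
    a_cluster = 0 if mis0 <= mis1 else 1  # tie broken toward cluster 0 = A'
    n_a = int(np.sum((assign == a_cluster) & is_b))
    n_b = int(np.sum((assign != a_cluster) & ~is_b))
    return OverlapResult(100.0 * (n_a + n_b) / n_total, n_a, n_b, n_total)


@dataclass
class SelectivitySignature:
    """Electrodes x bins statistical-selectivity flags; NaN-padded p-values.
    Cells outside ``valid`` (inactive electrode / unstable bin) are
    not-applicable."""

    flags: np.ndarray  # bool (n_e, n_bins)
    valid: np.ndarray  # bool (n_e, n_bins)
    p_values: np.ndarray  # float (n_e, n_bins), NaN where invalid
    alpha: float
    test: str = "mann-whitney"


@dataclass
class OverlapSignature:
    """Electrodes x bins overlap percentages, NaN where not applicable."""

    overlaps: np.ndarray  # float (n_e, n_bins), NaN where invalid
    valid: np.ndarray
    degenerate: np.ndarray  # bool, cells where the overlap was degenerate

    def __post_init__(self) -> None:
        defined = self.overlaps[self.valid]
        if defined.size and (np.nanmin(defined) < 0 or np.nanmax(defined) > 50):
            raise ValueError("overlap values must lie in [0, 50]")


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    passed = ranked <= alpha * (np.arange(1, m + 1) / m)
    out = np.zeros(m, dtype=bool)
    if passed.any():
        out[order[: np.max(np.nonzero(passed)[0]) + 1]] = True
    return out


def build_signatures(
    patterns: list[ResponsePattern],
    filters: FilterReport,
    feature: str = "bin_rate",
    alpha: float | None = None,
    compute_overlap: bool = True,
    random_state: int = 0,
    window: WindowSpec | None = None,
    bh_correction: bool = False,
) -> tuple[SelectivitySignature, OverlapSignature]:
    """Assemble selectivity and overlap signatures over eligible cells.

    ``feature``:
      * ``bin_rate`` — per-(electrode, bin) spike counts; zero-count
        responses are retained in the samples; alpha defaults to 0.05;
        signature shape (n_electrodes, n_bins);
      * ``total_count`` — per-electrode total spike count over the window;
      * ``activation_time`` — per-electrode first-spike latency, missing
        values imputed with the window upper bound.

    Whole-response features yield single-column signatures over stationary
    active electrodes with alpha defaulting to 0.001.
    """
    if feature not in ("bin_rate", "total_count", "activation_time"):
        raise ValueError(f"unknown feature {feature!r}")
    if not patterns:
        raise ValueError("no patterns")
    sites = []
    for p in patterns:
        if p.site not in sites:
            sites.append(p.site)
    if len(sites) != 2:
        raise ValueError("signatures require exactly two stimulation sites")
    mask_a = np.array([p.site == sites[0] for p in patterns])
    n_e, n_b = patterns[0].counts.shape

    if feature == "bin_rate":
        alpha = ALPHA_BIN if alpha is None else alpha
        valid = filters.eligible_cells.copy()
        counts = np.stack([p.counts for p in patterns])  # (S, E, B)
        values_a, values_b = counts[mask_a], counts[~mask_a]
        shape = (n_e, n_b)
    else:
        alpha = ALPHA_ELECTRODE if alpha is None else alpha
        valid = (filters.active & filters.stationary)[:, None]
        shape = (n_e, 1)
        if feature == "total_count":
            vals = np.stack([p.total_spike_count for p in patterns])[:, :, None]
        else:
            window = window or WindowSpec()
            act = np.stack([p.activation_time for p in patterns])
            act = np.where(np.isnan(act), window.response_window, act)
            vals = act[:, :, None]
        values_a, values_b = vals[mask_a], vals[~mask_a]

    if not valid.any():
        warnings.warn("no eligible cells; signatures are empty", stacklevel=2)

    p_values = np.full(shape, np.nan)
    overlaps = np.full(shape, np.nan)
    degenerate = np.zeros(shape, dtype=bool)
    for e, b in zip(*np.nonzero(valid)):
        sample_a = values_a[:, e, b]
        sample_b = values_b[:, e, b]
        p_values[e, b] = rank_sum_p(sample_a, sample_b)
        if compute_overlap:
            res = overlap(sample_a, sample_b, random_state=random_state)
            overlaps[e, b] = res.overlap_percent
            degenerate[e, b] = res.degenerate

    if bh_correction:
        flags = np.zeros(shape, dtype=bool)
        idx = np.nonzero(valid)
        if idx[0].size:
            flags[idx] = _benjamini_hochberg(p_values[idx], alpha)
    else:
        flags = (p_values < alpha) & valid
    sel = SelectivitySignature(flags=flags, valid=valid, p_values=p_values, alpha=alpha)
    ov = OverlapSignature(overlaps=overlaps, valid=valid & compute_overlap, degenerate=degenerate)
    return sel, ov


def spatial_overlap_map(
    signature: OverlapSignature, bin_index: int, geometry: ArrayGeometry
) -> np.ndarray:
    """Arrange one bin's overlaps on the electrode grid (NaN where N/A)."""
    if not 0 <= bin_index < signature.overlaps.shape[1]:
        raise ValueError("bin index out of range")
    return geometry.grid(signature.overlaps[:, bin_index])
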