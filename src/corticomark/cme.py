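"""Corticomotor excitability (CME) metrics from TMS motor maps.

A mapping session delivers TMS pulses over a 1 cm-spaced scalp grid and
records motor evoked potentials (MEPs) from the target muscle. Per-site MEP
amplitudes form a motor map; CME is summarised as *map volume* (sum of mean
amplitudes over active sites) or *map area* (count of active sites).
Participants whose map volume increases from day 0 to day 5 of the prolonged
pain model are *facilitators*; those whose volume decreases (or is
unchanged) are *depressors*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: default MEP latency window after the TMS pulse, in milliseconds
DEFAULT_LATENCY_WINDOW = (5.0, 50.0)

#: default active-site rule: site mean amplitude >= 10% of map maximum
DEFAULT_ACTIVE_FRACTION = 0.10

FACILITATOR = "facilitator"
DEPRESSOR = "depressor"


@dataclass
class EMGTrace:
    """Single-trial EMG around one TMS pulse."""

    samples: np.ndarray  # mV
    sfreq: float
    stimulus_index: int
    site: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0 <= self.stimulus_index < self.samples.size:
            raise ValueError("stimulus_index must lie inside the trace")


@dataclass
class MapGrid:
    """Per-site mean MEP amplitudes on an integer (row, col) lattice.

    Grid spacing is 1 cm by convention; spacing is metadata and does not
    enter the volume/area metrics.
    """

    site_coords: np.ndarray      # (n_sites, 2) integer lattice
    site_amplitude: np.ndarray   # (n_sites,) mV
    session_day: int = 0

    def __post_init__(self) -> None:
        self.site_coords = np.asarray(self.site_coords, dtype=int)
        self.site_amplitude = np.asarray(self.site_amplitude, dtype=float)
        if self.site_coords.ndim != 2 or self.site_coords.shape[1] != 2:
            raise ValueError("site_coords must be (n_sites, 2)")
        if self.site_amplitude.shape[0] != self.site_coords.shape[0]:
            raise ValueError("coords and amplitudes are misaligned")
        if np.any(self.site_amplitude < 0):
            raise ValueError("MEP amplitudes must be nonnegative")
        coords = {tuple(c) for c in self.site_coords}
        if len(coords) != self.site_coords.shape[0]:
            raise ValueError("duplicate grid coordinates")

    @property
    def n_sites(self) -> int:
        return self.site_coords.shape[0]


@dataclass
class CMEMetrics:
    """Change in corticomotor excitability between two mapping sessions."""

    metric: str                 # "volume" | "area"
    value_day0: float
    value_day5: float
    delta: float
    cme_class: str              # facilitator | depressor

    @property
    def is_facilitator(self) -> bool:
        return self.cme_class == FACILITATOR


def extract_mep_amplitude(trace: EMGTrace,
                          latency_window: tuple[float, float] = DEFAULT_LATENCY_WINDOW
                          ) -> float:
    """Peak-to-peak amplitude (mV) inside the post-stimulus latency window."""
    lo_ms, hi_ms = latency_window
    if hi_ms <= lo_ms:
        raise ValueError("latency window must satisfy low < high")
    lo = trace.stimulus_index + int(round(lo_ms * trace.sfreq / 1000.0))
    hi = trace.stimulus_index + int(round(hi_ms * trace.sfreq / 1000.0))
    if lo < 0 or hi > trace.samples.size or lo >= hi:
        raise ValueError(
            f"latency window {latency_window} ms maps to samples "
            f"[{lo}, {hi}) outside the trace of length {trace.samples.size}")
    seg = trace.samples[lo:hi]
    return float(seg.max() - seg.min())


def build_map(per_site_amplitudes: dict[tuple[int, int], "np.ndarray | list[float]"],
              session_day: int = 0) -> MapGrid:
    """Average per-trial MEP amplitudes into a per-site motor map.

    Duplicate keys cannot occur in a dict; trials listed under one site are
    averaged. Negative trial amplitudes are rejected.
    """
    if not per_site_amplitudes:
        raise ValueError("empty map input")
    coords, means = [], []
    for site, trials in per_site_amplitudes.items():
        arr = np.asarray(trials, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError(f"site {site} has no trials")
        if np.any(arr < 0):
            raise ValueError(f"negative MEP amplitude at site {site}")
        coords.append(site)
        means.append(float(arr.mean()))
    return MapGrid(np.array(coords, dtype=int), np.array(means), session_day)


def build_map_from_table(rows, session_day: int = 0) -> MapGrid:
    """Build a map from an iterable of (row, col, amplitude) trial records,
    merging duplicate sites with a warning (e.g. re-measured grid points)."""
    acc: dict[tuple[int, int], list[float]] = {}
    dupes = set()
    for r, c, a in rows:
        key = (int(r), int(c))
        if key in acc:
            dupes.add(key)
        acc.setdefault(key, []).append(float(a))
    if dupes:
        warnings.warn(f"merged duplicate site entries at {sorted(dupes)}",
                      stacklevel=2)
    return build_map(acc, session_day)


def active_sites(grid: MapGrid,
                 threshold_fraction: float = DEFAULT_ACTIVE_FRACTION
                 ) -> np.ndarray:
    """Indices of active sites: mean amplitude >= fraction of map maximum.

    An all-zero map has no active sites. ``threshold_fraction=0`` marks
    every covered site active.
    """
    if grid.n_sites == 0:
        raise ValueError("empty map")
    peak = grid.site_amplitude.max()
    if peak <= 0:
        return np.array([], dtype=int)
    return np.flatnonzero(grid.site_amplitude >= threshold_fraction * peak)


def map_volume(grid: MapGrid,
               threshold_fraction: float = DEFAULT_ACTIVE_FRACTION) -> float:
    """Sum of mean MEP amplitudes over active sites (mV * sites)."""
    idx = active_sites(grid, threshold_fraction)
    return float(grid.site_amplitude[idx].sum())


def map_area(grid: MapGrid,
             threshold_fraction: float = DEFAULT_ACTIVE_FRACTION) -> int:
    """Number of active sites."""
    return int(active_sites(grid, threshold_fraction).size)


def classify_cme(map_day0: MapGrid, map_day5: MapGrid,
                 metric: str = "volume",
                 threshold_fraction: float = DEFAULT_ACTIVE_FRACTION
                 ) -> CMEMetrics:
    """Classify facilitator/depressor from the day-5 minus day-0 change.

    ``delta > 0`` is a facilitator; ``delta <= 0`` a depressor (a strict
    increase is required for facilitation; an exactly unchanged map falls
    in the conservative risk class).
    """
    if map_day0 is None or map_day5 is None:
        raise ValueError("both day-0 and day-5 maps are required")
    if metric == "volume":
        v0, v5 = (map_volume(m, threshold_fraction) for m in (map_day0, map_day5))
    elif metric == "area":
        v0, v5 = (float(map_area(m, threshold_fraction)) for m in (map_day0, map_day5))
    else:
        raise ValueError(f"unknown CME metric {metric!r}; use 'volume' or 'area'")
    delta = v5 - v0
    cls = FACILITATOR if delta > 0 else DEPRESSOR
    return CMEMetrics(metric=metric, value_day0=v0, value_day5=v5,
                      delta=delta, cme_class=cls)


def normalize_map(grid: MapGrid) -> MapGrid:
    """Express site amplitudes as percent of the maximal site amplitude."""
    peak = grid.site_amplitude.max() if grid.n_sites else 0.0
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero map")
    return MapGrid(grid.site_coords.copy(),
                   100.0 * grid.site_amplitude / peak,
                   grid.session_day)
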