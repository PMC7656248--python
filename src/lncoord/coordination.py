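"""Coordination-state analysis of ion-peptide trajectories.

Implements the classifiers used to characterise lanthanide binding by the
six-donor peptide site: hysteresis (dual-threshold) coordination calling on
donor-ion distance series, carboxylate mono/bidentate chelation mode,
first-shell water counting, the five-state complex classification

    (i)   N5-Od1 bound,   0 waters
    (ii)  N5-Od1 bound,   1 water
    (iii) N5-Od1 unbound, 1 water
    (iv)  N5-Od1 unbound, 2 waters
    (v)   N5-Od1 unbound, 0 waters

(plus catch-alls ``other`` for unlisted water counts and ``broken`` when any
of the five continuously-bound sites has released the ion), and transition/
occupancy bookkeeping against the allowed transition-path edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ATOMIC_NUMBER
from .geometry import minimum_image_distance
from .traj_io import AtomSelection, Topology, Trajectory, single_atom_index

__all__ = [
    "CoordinationParams",
    "DistanceSeries",
    "BinaryStateSeries",
    "ChelationSeries",
    "ComplexStateSeries",
    "TransitionReport",
    "distance_series",
    "hysteresis_states",
    "chelation_mode",
    "water_coordination_count",
    "classify_complex_state",
    "transition_stats",
    "mean_distance_by_ion",
    "conditional_proximity",
    "DEFAULT_ALLOWED_EDGES",
]

#: Allowed complex-state transition edges (undirected).
DEFAULT_ALLOWED_EDGES = frozenset(
    {frozenset(e) for e in (("i", "ii"), ("ii", "iii"), ("iii", "iv"),
                            ("i", "v"), ("v", "iii"))}
)


@dataclass(frozen=True)
class CoordinationParams:
    """Distance cutoffs in nm.

    ``r_on``/``r_off`` are the hysteresis thresholds (coordinated below
    0.3 nm, dissociated above 0.4 nm); ``r_water`` bounds the first
    solvation shell and ``r_chel`` a carboxylate oxygen's bound state.
    """

    r_on: float = 0.30
    r_off: float = 0.40
    r_water: float = 0.30
    r_chel: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.r_on < self.r_off:
            raise ValueError("need 0 < r_on < r_off")
        if self.r_water <= 0 or self.r_chel <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class DistanceSeries:
    times: np.ndarray   # ps
    values: np.ndarray  # nm
    pair: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinaryStateSeries:
    labels: np.ndarray  # 'bound' / 'unbound'
    r_on: float
    r_off: float

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ChelationSeries:
    labels: np.ndarray  # bidentate | monodentate_O1 | monodentate_O2 | dissociated
    carboxylate: str = ""

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ComplexStateSeries:
    labels: np.ndarray       # i|ii|iii|iv|v|other|broken
    water_counts: np.ndarray
    n5_labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TransitionReport:
    counts: pd.DataFrame                      # from-label x to-label
    off_path: list[tuple[int, str, str]]      # (frame of arrival, from, to)
    occupancy: dict[str, float]


def _resolve_single(topology: Topology | None, sel) -> int:
    if isinstance(sel, (int, np.integer)):
        return int(sel)
    if isinstance(sel, AtomSelection):
        if len(sel) != 1:
            raise ValueError(
                f"selection {sel.expression!r} matched {len(sel)} atoms; expected 1 "
                "(use conditional_proximity for sets)"
            )
        return int(sel.indices[0])
    if topology is None:
        raise ValueError("topology required to resolve a string selection")
    return single_atom_index(topology, sel)


def distance_series(
    traj: Trajectory,
    sel_a,
    sel_b,
    topology: Topology | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> DistanceSeries:
    """Per-frame minimum-image distance (nm) between two single atoms."""
    ia = _resolve_single(topology, sel_a)
    ib = _resolve_single(topology, sel_b)
    d = minimum_image_distance(
        traj.coordinates[:, ia], traj.coordinates[:, ib], traj.box
    )
    return DistanceSeries(traj.times, d, labels)


def hysteresis_states(
    series: DistanceSeries, params: CoordinationParams | None = None
) -> BinaryStateSeries:
    """Dual-threshold coordination calling with memory.

    Frame k is ``bound`` below ``r_on``, ``unbound`` above ``r_off``, and
    inherits the previous frame's label inside the gap.  A first frame in
    the gap takes the label of the nearer threshold (tie -> unbound).
    """
    params = params or CoordinationParams()
    v = series.values
    if len(v) == 0:
        raise ValueError("empty distance series")
    labels = np.empty(len(v), dtype=object)
    if v[0] < params.r_on:
        labels[0] = "bound"
    elif v[0] > params.r_off:
        labels[0] = "unbound"
    else:
        # nearer threshold wins; an (fp-tolerant) tie resolves to unbound
        labels[0] = (
            "bound"
            if (v[0] - params.r_on) < (params.r_off - v[0]) - 1e-12
            else "unbound"
        )
    for k in range(1, len(v)):
        if v[k] < params.r_on:
            labels[k] = "bound"
        elif v[k] > params.r_off:
            labels[k] = "unbound"
        else:
            labels[k] = labels[k - 1]
    return BinaryStateSeries(labels, params.r_on, params.r_off)


def chelation_mode(
    traj: Trajectory,
    ion_sel,
    o1_sel,
    o2_sel,
    params: CoordinationParams | None = None,
    topology: Topology | None = None,
    carboxylate: str = "",
) -> ChelationSeries:
    """Mono/bidentate classification of one carboxylate.

    ``bidentate`` when both oxygens are within ``r_chel`` of the ion,
    ``monodentate_O1``/``monodentate_O2`` when only one is, ``dissociated``
    when neither.
    """
    params = params or CoordinationParams()
    d1 = distance_series(traj, ion_sel, o1_sel, topology).values
    d2 = distance_series(traj, ion_sel, o2_sel, topology).values
    in1, in2 = d1 <= params.r_chel, d2 <= params.r_chel
    labels = np.where(
        in1 & in2, "bidentate",
        np.where(in1, "monodentate_O1", np.where(in2, "monodentate_O2", "dissociated")),
    ).astype(object)
    return ChelationSeries(labels, carboxylate)


def water_coordination_count(
    traj: Trajectory,
    ion_sel,
    water_oxygens: np.ndarray,
    params: CoordinationParams | None = None,
    topology: Topology | None = None,
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """First-shell water count per frame plus the contributing oxygen indices."""
    params = params or CoordinationParams()
    ion = _resolve_single(topology, ion_sel)
    water_oxygens = np.asarray(water_oxygens, dtype=int)
    n = traj.n_frames
    if water_oxygens.size == 0:
        return np.zeros(n, dtype=int), [() for _ in range(n)]
    d = minimum_image_distance(
        traj.coordinates[:, ion, None, :],
        traj.coordinates[:, water_oxygens, :],
        traj.box[:, None, :],
    )
    within = d <= params.r_water
    counts = within.sum(axis=1)
    ids = [tuple(water_oxygens[within[f]]) for f in range(n)]
    return counts.astype(int), ids


def classify_complex_state(
    n5: BinaryStateSeries,
    water_counts: np.ndarray,
    five_site_states: list[BinaryStateSeries],
) -> ComplexStateSeries:
    """Assign each frame one of the states (i)-(v), ``other`` or ``broken``.

    ``broken`` whenever any of the five continuously-bound sites is
    unbound; otherwise the (N5 state, water count) pair selects the state,
    with unlisted combinations (e.g. N5 bound with two waters) labelled
    ``other``.  Pure per-frame function: permuting frames permutes labels.
    """
    water_counts = np.asarray(water_counts, dtype=int)
    n = len(n5)
    if len(water_counts) != n or any(len(s) != n for s in five_site_states):
        raise ValueError("all inputs must share n_frames")
    broken = np.zeros(n, dtype=bool)
    for s in five_site_states:
        broken |= s.labels == "unbound"
    n5_bound = n5.labels == "bound"
    table = {
        (True, 0): "i", (True, 1): "ii",
        (False, 1): "iii", (False, 2): "iv", (False, 0): "v",
    }
    labels = np.array(
        [
            "broken" if broken[k]
            else table.get((bool(n5_bound[k]), int(water_counts[k])), "other")
            for k in range(n)
        ],
        dtype=object,
    )
    return ComplexStateSeries(labels, water_counts, n5.labels.copy())


def transition_stats(
    states: ComplexStateSeries,
    allowed_edges: frozenset = DEFAULT_ALLOWED_EDGES,
) -> TransitionReport:
    """Adjacent-frame transition counts, occupancies, and off-path flags.

    Transitions outside the allowed edge set are reported, not rejected:
    frame sampling can skip short-lived intermediates.
    """
    labels = states.labels
    if len(labels) == 0:
        raise ValueError("empty state series")
    seen = sorted(set(labels), key=str)
    counts = pd.DataFrame(0, index=seen, columns=seen, dtype=int)
    off_path: list[tuple[int, str, str]] = []
    for k in range(1, len(labels)):
        a, b = labels[k - 1], labels[k]
        if a == b:
            continue
        counts.loc[a, b] += 1
        if frozenset((a, b)) not in allowed_edges:
            off_path.append((k, str(a), str(b)))
    vals, freq = np.unique(labels.astype(str), return_counts=True)
    occupancy = {str(k): float(c) / len(labels) for k, c in zip(vals, freq)}
    return TransitionReport(counts, off_path, occupancy)


def mean_distance_by_ion(
    series_by_ion: dict[str, list[DistanceSeries]],
) -> pd.DataFrame:
    """Mean/SD donor-ion distance per ion, ordered by atomic number.

    Pools all frames of all series supplied for an ion; SD is the
    population standard deviation.
    """
    rows = []
    for ion, series_list in series_by_ion.items():
        if not series_list or all(len(s) == 0 for s in series_list):
            raise ValueError(f"no frames supplied for ion {ion}")
        pooled = np.concatenate([s.values for s in series_list])
        rows.append(
            {
                "ion": ion,
                "mean_nm": float(pooled.mean()),
                "sd_nm": float(pooled.std()),
                "n_frames": int(pooled.size),
            }
        )
    df = pd.DataFrame(rows)
    df["_z"] = df["ion"].map(ATOMIC_NUMBER)
    df = df.sort_values("_z").drop(columns="_z").reset_index(drop=True)
    return df


def conditional_proximity(
    traj: Trajectory,
    probe_sel,
    water_oxygens: np.ndarray,
    condition: ChelationSeries,
    topology: Topology | None = None,
    bins: int = 30,
) -> dict[str, dict]:
    """Per-frame minimum probe-water distance stratified by a label series.

    Returns, per condition label, the mean, median, count and a histogram
    (counts, bin edges) of the frame-wise minimum distances.  With no
    waters the summaries are empty rather than an error.
    """
    probe = _resolve_single(topology, probe_sel)
    if len(condition) != traj.n_frames:
        raise ValueError("condition length must equal n_frames")
    water_oxygens = np.asarray(water_oxygens, dtype=int)
    if water_oxygens.size == 0:
        return {}
    d = minimum_image_distance(
        traj.coordinates[:, probe, None, :],
        traj.coordinates[:, water_oxygens, :],
        traj.box[:, None, :],
    ).min(axis=1)
    out: dict[str, dict] = {}
    hist_range = (float(d.min()), float(d.max()) + 1e-12)
    for lab in sorted(set(condition.labels), key=str):
        sub = d[condition.labels == lab]
        hist, edges = np.histogram(sub, bins=bins, range=hist_range)
        out[str(lab)] = {
            "mean": float(sub.mean()),
            "median": float(np.median(sub)),
            "n": int(sub.size),
            "histogram": (hist, edges),
        }
    return out
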