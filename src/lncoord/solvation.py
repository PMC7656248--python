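"""Radial distribution functions around a single reference atom.

g(r) is estimated from minimum-image distances between one reference atom
(the ion, or an amide proton probe) and a target atom set (typically water
oxygens), normalised by the ideal 4 pi r^2 dr shell volume at the mean
target number density.  The running coordination number n(r) integrates
g(r) and, up to binning error, equals the direct mean count of targets
within r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image_distance
from .traj_io import Topology, Trajectory
from .coordination import _resolve_single

__all__ = ["RDFResult", "rdf", "coordination_number", "first_minimum", "NoMinimumError"]


class NoMinimumError(ValueError):
    """g(r) has no first minimum in the searched window."""


@dataclass
class RDFResult:
    r: np.ndarray        # bin centres, nm
    g: np.ndarray
    n: np.ndarray        # running coordination number
    rho: float           # target number density, nm^-3
    n_frames: int
    dr: float


def rdf(
    traj: Trajectory,
    ref_sel,
    target_indices: np.ndarray,
    r_max: float = 1.0,
    dr: float = 0.002,
    topology: Topology | None = None,
) -> RDFResult:
    """Reference-atom RDF with running coordination number.

    ``r_max`` must not exceed half the smallest box edge (minimum-image
    validity).  Zero targets yield g = 0 with rho = 0.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    half_min_edge = float(traj.box.min()) / 2.0
    if r_max > half_min_edge + 1e-12:
        raise ValueError(
            f"r_max {r_max} nm exceeds half the smallest box edge ({half_min_edge:.4f} nm)"
        )
    ref = _resolve_single(topology, ref_sel)
    target_indices = np.asarray(target_indices, dtype=int)
    nbins = int(np.ceil(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    centers = 0.5 * (edges[:-1] + edges[1:])
    vol = float(np.mean(np.prod(traj.box, axis=1)))
    if target_indices.size == 0:
        z = np.zeros(nbins)
        return RDFResult(centers, z, z.copy(), 0.0, traj.n_frames, dr)
    d = minimum_image_distance(
        traj.coordinates[:, ref, None, :],
        traj.coordinates[:, target_indices, :],
        traj.box[:, None, :],
    )
    counts, _ = np.histogram(d.ravel(), bins=edges)
    mean_counts = counts / traj.n_frames
    rho = target_indices.size / vol
    shell = 4.0 * np.pi * centers**2 * dr
    g = mean_counts / (shell * rho)
    n = np.cumsum(mean_counts)
    return RDFResult(centers, g, n, rho, traj.n_frames, dr)


def coordination_number(rdfres: RDFResult, r_cut: float) -> float:
    """n(r_cut) = 4 pi rho * sum g(r) r^2 dr over bins below r_cut."""
    if r_cut > rdfres.r[-1] + rdfres.dr / 2:
        raise ValueError("r_cut exceeds the RDF range")
    mask = rdfres.r + rdfres.dr / 2 <= r_cut + 1e-12
    return float(
        4.0 * np.pi * rdfres.rho
        * np.sum(rdfres.g[mask] * rdfres.r[mask] ** 2 * rdfres.dr)
    )


def first_minimum(
    rdfres: RDFResult, window: tuple[float, float] = (0.0, 1.0)
) -> float:
    """First local minimum of g(r) after its first maximum.

    g is smoothed with a 3-bin moving average before the discrete search;
    the search is confined to ``window`` (nm).
    """
    g = np.convolve(rdfres.g, np.ones(3) / 3.0, mode="same")
    r = rdfres.r
    sel = (r >= window[0]) & (r <= window[1])
    g, r = g[sel], r[sel]
    if len(g) < 3:
        raise NoMinimumError("window too narrow")
    imax = None
    for k in range(1, len(g) - 1):
        if g[k] > g[k - 1] and g[k] >= g[k + 1]:
            imax = k
            break
    if imax is None:
        raise NoMinimumError("no maximum of g(r) in the window")
    for k in range(imax + 1, len(g) - 1):
        if g[k] < g[k - 1] and g[k] <= g[k + 1]:
            return float(r[k])
    raise NoMinimumError("no local minimum after the first maximum")
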