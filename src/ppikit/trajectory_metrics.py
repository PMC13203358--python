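"""Trajectory stability metrics: RMSD, partner COM distance, Rg.

These are the per-replica time series used to judge whether a simulated
two-partner complex has settled: superposition RMSD against a reference
frame, the mass-weighted centre-of-mass separation between the two binding
partners, and the radius of gyration of a selection.  A cross-replica mean
series accompanies every metric, mirroring the usual "average trace over
replicas" presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ppikit.structure_io import Structure, TrajectoryEnsemble

__all__ = [
    "MetricSeries", "kabsch_superpose", "rmsd_series",
    "com_distance_series", "rg_series", "stability_call",
]


class DegenerateGeometryError(ValueError):
    """Superposition target has fewer than 3 atoms or is collinear."""


@dataclass
class MetricSeries:
    """One metric over the frames of one replica (or the replica mean).

    times are in ns, values in Angstrom.  replica_id -1 denotes the
    cross-replica mean series.
    """

    metric_name: str
    replica_id: int
    times: np.ndarray
    values: np.ndarray
    selection: str = "all"
    reference_frame: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.metric_name}: values must be >= 0")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of mobile onto reference (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimises the (weighted) RMSD to
    reference.  The rotation is proper (det = +1).  Fewer than 3 points or
    a collinear reference raise :class:`DegenerateGeometryError`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or w.sum() <= 0:
            raise ValueError("weights must be positive and match atom count")
        w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    # collinearity check on the reference point cloud
    cov_ref = ref_c.T @ (w[:, None] * ref_c)
    if np.linalg.matrix_rank(cov_ref, tol=1e-10 * max(1.0, np.trace(cov_ref))) < 2:
        raise DegenerateGeometryError("reference points are collinear")

    h = mob_c.T @ (w[:, None] * ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ((w[:, None] * reference).sum(axis=0)
                   - rotation @ (w[:, None] * mobile).sum(axis=0))
    diff = mob_c @ rotation.T - ref_c
    msd = float((w * np.einsum("ij,ij->i", diff, diff)).sum())
    return rotation, translation, float(np.sqrt(max(msd, 0.0)))


def _mean_series(series: list[MetricSeries], name: str,
                 selection: str, reference_frame: int | None = None,
                 ) -> MetricSeries:
    values = np.mean([s.values for s in series], axis=0)
    return MetricSeries(name, -1, series[0].times, values,
                        selection=selection, reference_frame=reference_frame)


def rmsd_series(ens: TrajectoryEnsemble, selection: str = "name CA",
                reference_frame: int = 0,
                mass_weighted: bool = False) -> list[MetricSeries]:
    """Per-replica superposition RMSD versus a reference frame.

    Each frame is superposed onto the reference frame of its own replica
    on the selected atoms before the RMSD is taken.  The returned list
    holds one series per replica plus the cross-replica mean (replica_id
    -1).  Default selection is the C-alpha trace with uniform weights.
    """
    idx = ens.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    weights = ens.topology.masses[idx] if mass_weighted else None
    out: list[MetricSeries] = []
    for r, frames in enumerate(ens.replicas):
        if not 0 <= reference_frame < frames.shape[0]:
            raise IndexError(
                f"reference frame {reference_frame} out of range for "
                f"replica {r} with {frames.shape[0]} frames")
        ref = frames[reference_frame][idx]
        vals = np.array([kabsch_superpose(f[idx], ref, weights)[2]
                         for f in frames])
        out.append(MetricSeries("rmsd", r, ens.frame_times[r], vals,
                                selection=selection,
                                reference_frame=reference_frame))
    out.append(_mean_series(out, "rmsd", selection, reference_frame))
    return out


def com_distance_series(ens: TrajectoryEnsemble) -> list[MetricSeries]:
    """Mass-weighted centre-of-mass distance between the two partners."""
    top = ens.topology
    ia, ib = top.partner_indices("A"), top.partner_indices("B")
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both partners must contain atoms")
    masses = top.masses
    ma, mb = masses[ia], masses[ib]
    if ma.sum() <= 0 or mb.sum() <= 0:
        raise ValueError("partner with zero total mass")
    out: list[MetricSeries] = []
    for r, frames in enumerate(ens.replicas):
        com_a = (frames[:, ia] * ma[None, :, None]).sum(axis=1) / ma.sum()
        com_b = (frames[:, ib] * mb[None, :, None]).sum(axis=1) / mb.sum()
        vals = np.linalg.norm(com_a - com_b, axis=1)
        out.append(MetricSeries("com_distance", r, ens.frame_times[r], vals,
                                selection="partners A|B"))
    out.append(_mean_series(out, "com_distance", "partners A|B"))
    return out


def rg_series(ens: TrajectoryEnsemble, selection: str = "all",
              ) -> list[MetricSeries]:
    """Mass-weighted radius of gyration of the selection, per replica."""
    idx = ens.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    m = ens.topology.masses[idx]
    if m.sum() <= 0:
        raise ValueError("selection has zero total mass")
    out: list[MetricSeries] = []
    for r, frames in enumerate(ens.replicas):
        sub = frames[:, idx]
        com = (sub * m[None, :, None]).sum(axis=1) / m.sum()
        d2 = ((sub - com[:, None, :]) ** 2).sum(axis=2)
        vals = np.sqrt((d2 * m[None, :]).sum(axis=1) / m.sum())
        out.append(MetricSeries("rg", r, ens.frame_times[r], vals,
                                selection=selection))
    out.append(_mean_series(out, "rg", selection))
    return out


def stability_call(series: MetricSeries, window_fraction: float = 0.2,
                   drift_threshold: float = 1.0) -> bool:
    """Reporting heuristic: is the tail of a metric series settled?

    The series is called stable when the sliding-window mean over the last
    window_fraction of frames drifts less than drift_threshold (A) from
    the window's own mean.  Purely descriptive; no statistical claim.
    """
    n = len(series.values)
    w = max(2, int(round(window_fraction * n)))
    tail = series.values[-w:]
    return bool(np.ptp(tail) < drift_threshold or
                abs(tail.mean() - series.values[-1]) < drift_threshold)
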