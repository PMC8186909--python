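"""Collective motion: superposition, essential dynamics and domain angles.

The essential-dynamics pipeline mirrors standard practice for channel-gating
trajectories: monitor an inter-domain center-of-mass distance, discard frames
after a sharp change (where strong external forces have distorted the global
conformation), superpose the retained frames, run PCA on the covariance of
the superposed coordinates, and read domain motion off the leading
components.  The tilt/rotation angles of an amphipathic domain are measured
against the initial conformation: tilt is the change of the angle between the
domain axis and z; rotation is the signed angle between the XY-plane
projections of the axis, positive for a clockwise rotation viewed from the
intracellular side (-z), which is a right-handed rotation about +z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .structure import Structure, Trajectory, center_of_mass_coords, element_masses

__all__ = [
    "Transform",
    "PCAModel",
    "AngleSeries",
    "superpose",
    "superpose_trajectory",
    "com_distance_series",
    "sharp_change_filter",
    "fit_pca",
    "extreme_structures",
    "domain_axis",
    "tilt_angle",
    "rotation_angle",
    "angle_series",
]


@dataclass(frozen=True)
class Transform:
    """Rigid transform x -> R (x - centroid_mobile) + centroid_ref."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[Transform, float]:
    """Least-squares rigid superposition (Kabsch), proper rotation enforced.

    Returns the transform mapping ``mobile`` onto ``reference`` and the RMSD
    after superposition.  Chirality is preserved: when the best orthogonal
    map would be a reflection, the nearest proper rotation is used instead
    and the residual RMSD stays positive.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise AnalysisError("mobile and reference must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise AnalysisError("need at least 3 atoms to superpose")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = (P * w[:, None]).sum(axis=0)
    cq = (Q * w[:, None]).sum(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-12 and S[-2] < 1e-12:
        raise AnalysisError("degenerate (collinear) geometry: superposition undefined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return Transform(rotation=R, translation=t), rmsd


def superpose_trajectory(
    trajectory: Trajectory, fit_selection, reference_frame: int = 0
) -> Trajectory:
    """Superpose every frame onto a reference frame using a fitting selection."""
    sel = np.asarray(fit_selection, dtype=int)
    ref = trajectory.coords[reference_frame][sel]
    out = np.empty_like(trajectory.coords)
    for i in range(trajectory.n_frames):
        tf, _ = superpose(trajectory.coords[i][sel], ref)
        out[i] = tf.apply(trajectory.coords[i])
    return Trajectory(
        topology=trajectory.topology,
        coords=out,
        times=trajectory.times,
        box=trajectory.box,
    )


def com_distance_series(trajectory: Trajectory, sel_a, sel_b) -> np.ndarray:
    """Per-frame distance (nm) between the centers of mass of two selections."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    m_a = element_masses(trajectory.topology.element[sel_a])
    m_b = element_masses(trajectory.topology.element[sel_b])
    out = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        ca = center_of_mass_coords(trajectory.coords[i][sel_a], m_a)
        cb = center_of_mass_coords(trajectory.coords[i][sel_b], m_b)
        out[i] = np.linalg.norm(ca - cb)
    return out / 10.0  # Angstrom -> nm


def sharp_change_filter(
    series: np.ndarray,
    baseline_window: int | None = None,
    threshold_sd: float = 5.0,
    min_persist: int = 3,
    abs_threshold: float | None = None,
) -> int:
    """Frames to retain before the first sharp, persistent change of a series.

    The baseline mean and SD come from the first ``baseline_window`` frames
    (default: the first 10% of the series).  The change point is the first
    index whose deviation from the baseline mean exceeds ``threshold_sd``
    baseline SDs for at least ``min_persist`` consecutive frames; all frames
    strictly before it are retained.  With no such point the whole series is
    retained.  Returns the retained prefix length.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if baseline_window is None:
        baseline_window = max(2, n // 10)
    if n <= baseline_window:
        raise AnalysisError("series must be longer than the baseline window")
    mu = x[:baseline_window].mean()
    sd = x[:baseline_window].std(ddof=0)
    if sd == 0:
        if abs_threshold is None:
            warnings.warn(
                "baseline SD is zero; falling back to any absolute deviation"
            )
            abs_threshold = 0.0
        exceed = np.abs(x - mu) > abs_threshold
    else:
        exceed = np.abs(x - mu) > threshold_sd * sd
    run = 0
    for i, flag in enumerate(exceed):
        run = run + 1 if flag else 0
        if run >= min_persist:
            return i - min_persist + 1
    return n


@dataclass
class PCAModel:
    """Essential-dynamics PCA of superposed coordinates.

    ``components`` are orthonormal rows in descending eigenvalue order;
    eigenvalues are in Angstrom^2; ``projections`` are the per-frame scores
    of the fitted frames.
    """

    mean: np.ndarray  # (3N,)
    components: np.ndarray  # (k, 3N)
    eigenvalues: np.ndarray  # (k,)
    projections: np.ndarray  # (n_frames, k)
    selection: np.ndarray | None = None
    source_labels: np.ndarray | None = None  # optional per-frame group labels
    meta: dict = field(default_factory=dict)

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Scores of (n_frames, n_atoms, 3) or (n_atoms, 3) coordinates."""
        X = np.asarray(coords, dtype=float)
        single = X.ndim == 2
        X = X.reshape(1 if single else X.shape[0], -1)
        scores = (X - self.mean) @ self.components.T
        return scores[0] if single else scores

    def orient(self, component: int, positive_labels, reference_label) -> None:
        """Fix a component's sign so a labelled group projects positively.

        Used to make 'larger score = more dilated' hold when push/pull labels
        exist: the mean projection of ``reference_label`` frames is made
        positive on ``component``.
        """
        if self.source_labels is None:
            raise AnalysisError("no source labels stored; cannot orient")
        mask = self.source_labels == reference_label
        if not mask.any():
            raise AnalysisError(f"no frames labelled {reference_label!r}")
        if self.projections[mask, component].mean() < 0:
            self.components[component] *= -1
            self.projections[:, component] *= -1
        _ = positive_labels  # kept for symmetry with config-driven callers


def fit_pca(
    frames: np.ndarray,
    selection=None,
    n_components: int | None = None,
    source_labels=None,
) -> PCAModel:
    """PCA of concatenated, superposed frames.

    ``frames`` is (n_frames, n_atoms, 3), already filtered and superposed;
    ``selection`` optionally restricts to an atom subset (e.g. C-alphas).
    Eigenpairs come from the SVD of the centered coordinate matrix, which is
    the covariance eigendecomposition without forming the covariance.
    """
    X = np.asarray(frames, dtype=float)
    if X.ndim != 3:
        raise AnalysisError("frames must have shape (n_frames, n_atoms, 3)")
    if X.shape[0] < 2:
        raise AnalysisError("PCA needs at least 2 frames")
    if selection is not None:
        X = X[:, np.asarray(selection, dtype=int), :]
    n_frames = X.shape[0]
    flat = X.reshape(n_frames, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = S**2 / (n_frames - 1)
    k = n_components or len(eigvals)
    labels = None if source_labels is None else np.asarray(source_labels)
    return PCAModel(
        mean=mean,
        components=Vt[:k],
        eigenvalues=eigvals[:k],
        projections=centered @ Vt[:k].T,
        selection=None if selection is None else np.asarray(selection, dtype=int),
        source_labels=labels,
    )


def extreme_structures(model: PCAModel, component: int) -> tuple[int, int]:
    """Frame indices with minimal/maximal projection on a component.

    Ties resolve to the earlier frame (numpy argmin/argmax convention).
    """
    scores = model.projections[:, component]
    return int(np.argmin(scores)), int(np.argmax(scores))


def domain_axis(
    coords: np.ndarray, reference_direction=(0.0, 0.0, 1.0)
) -> np.ndarray:
    """Dominant principal axis (unit vector) of a coordinate set.

    The direction of largest spread of the (C-alpha) coordinates, with the
    sign fixed by a positive dot product with ``reference_direction`` so the
    axis is stable across contiguous frames.
    """
    X = np.asarray(coords, dtype=float)
    if X.shape[0] < 2:
        raise AnalysisError("need at least 2 points for an axis")
    centered = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    ref = np.asarray(reference_direction, dtype=float)
    if axis @ ref < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


_Z = np.array([0.0, 0.0, 1.0])


def tilt_angle(axis: np.ndarray, axis0: np.ndarray) -> float:
    """Change (deg) of the angle between the domain axis and z vs the reference."""
    a = np.asarray(axis, dtype=float)
    a0 = np.asarray(axis0, dtype=float)
    th = np.degrees(np.arccos(np.clip(a @ _Z / np.linalg.norm(a), -1.0, 1.0)))
    th0 = np.degrees(np.arccos(np.clip(a0 @ _Z / np.linalg.norm(a0), -1.0, 1.0)))
    return float(th - th0)


def rotation_angle(axis: np.ndarray, axis0: np.ndarray) -> float:
    """Signed angle (deg) between the XY projections of axis and reference.

    Positive = clockwise viewed from the intracellular side (-z), i.e. a
    right-handed rotation about +z.  Returns NaN when either projection
    vanishes (axis parallel to z).
    """
    p = np.asarray(axis, dtype=float)[:2]
    p0 = np.asarray(axis0, dtype=float)[:2]
    if np.linalg.norm(p) < 1e-9 or np.linalg.norm(p0) < 1e-9:
        return float("nan")
    cross = p0[0] * p[1] - p0[1] * p[0]
    dot = p0 @ p
    return float(np.degrees(np.arctan2(cross, dot)))


@dataclass
class AngleSeries:
    """Per-frame tilt and signed rotation of a domain vs frame 0."""

    times: np.ndarray
    tilt_deg: np.ndarray
    rotation_deg: np.ndarray  # NaN where the axis is parallel to z
    selection_name: str = ""
    reference_frame: int = 0


def angle_series(
    trajectory: Trajectory,
    selection,
    fit_selection=None,
    reference_frame: int = 0,
    reference_direction=(0.0, 0.0, 1.0),
    selection_name: str = "",
) -> AngleSeries:
    """Tilt/rotation series of a domain, after optional global superposition.

    ``fit_selection`` (e.g. the immobile TM core) removes overall rigid-body
    motion before the domain axis is measured.
    """
    traj = trajectory
    if fit_selection is not None:
        traj = superpose_trajectory(trajectory, fit_selection, reference_frame)
    sel = np.asarray(selection, dtype=int)
    axis0 = domain_axis(traj.coords[reference_frame][sel], reference_direction)
    tilts = np.empty(traj.n_frames)
    rots = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        ax = domain_axis(traj.coords[i][sel], reference_direction)
        tilts[i] = tilt_angle(ax, axis0)
        rots[i] = rotation_angle(ax, axis0)
    return AngleSeries(
        times=traj.times.copy(),
        tilt_deg=tilts,
        rotation_deg=rots,
        selection_name=selection_name,
        reference_frame=reference_frame,
    )
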