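"""Pore-radius profiles along the permeation axis (largest inscribed sphere).

The profiler follows the classic inscribed-sphere idea: at each position z
along the pore axis, the pore radius is the radius of the largest sphere
centered in that plane that touches no van der Waals surface,

    r(z) = max over in-plane centers c of  min_i ( |p_i - c| - vdw_i )

over the atoms i of a slab around z.  The in-plane maximization uses a
gradient-free compass (pattern) search seeded at the previous slice's center,
which is robust for near-axial channel pores; the full simulated-annealing
machinery of HOLE is unnecessary here.  Slabs overlap (half-width equal to
the grid step) so that sparse atom layers never produce empty slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.structure.info import vdw_radius_single as _vdw_single

from .errors import AnalysisError
from .structure import BACKBONE_ATOMS, Structure, Trajectory

__all__ = [
    "PoreProfile",
    "default_vdw_table",
    "pore_profile",
    "min_radius_near",
    "profile_series",
    "count_waters_in_gate",
]

_FALLBACK_VDW = 1.5  # Angstrom, for exotic elements missing from the table


def default_vdw_table() -> dict[str, float]:
    """Single-atom van der Waals radii (Angstrom) for common elements."""
    table = {}
    for el in ("H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I", "NA", "K"):
        r = _vdw_single(el.capitalize())
        if r is not None:
            table[el] = float(r)
    return table


@dataclass
class PoreProfile:
    """Radius (Angstrom) of the largest inscribed sphere per axial position."""

    z: np.ndarray
    radius: np.ndarray  # clamped to >= 0; np.inf where unbounded
    centers: np.ndarray  # (n, 2) in-plane sphere centers
    occluded: np.ndarray  # True where the raw maximum was negative
    unbounded: np.ndarray  # True where no atoms were near the slice
    backbone_only: bool = False
    probe: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.z) > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        finite = self.radius[np.isfinite(self.radius)]
        if finite.size and np.any(finite < 0):
            raise ValueError("radii must be clamped to >= 0")


def _compass_search(f, x0, step0=1.0, min_step=0.05, max_iter=500):
    """Maximize f over the plane with a 4-direction compass search."""
    x = np.asarray(x0, dtype=float)
    fx = f(x)
    step = step0
    dirs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    for _ in range(max_iter):
        moved = False
        for d in dirs:
            cand = x + step * d
            fc = f(cand)
            if fc > fx:
                x, fx = cand, fc
                moved = True
        if not moved:
            step /= 2.0
            if step < min_step:
                break
    return x, fx


def pore_profile(
    frame: Structure,
    pore_selection,
    z_range: tuple[float, float],
    z_step: float = 0.5,
    vdw_table: dict[str, float] | None = None,
    backbone_only: bool = False,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    neighbor_cutoff: float = 15.0,
) -> PoreProfile:
    """Pore-radius profile of one frame along z.

    ``pore_selection`` are atom indices lining the pore; ``axis_xy`` seeds the
    in-plane search at the first slice (the pore must be roughly aligned with
    z — orient the structure first).  Slices with no atom center within
    ``neighbor_cutoff`` of the axis seed in the slab are marked unbounded.
    """
    sel = np.asarray(pore_selection, dtype=int)
    if sel.size == 0:
        raise AnalysisError("empty pore selection")
    sub = frame.subset(sel)
    if backbone_only:
        keep = np.isin(sub.atom_name, BACKBONE_ATOMS)
        if not keep.any():
            raise AnalysisError("backbone-only selection matches no atoms")
        sub = sub.subset(np.flatnonzero(keep))
    table = dict(default_vdw_table())
    if vdw_table:
        table.update({k.upper(): v for k, v in vdw_table.items()})
    vdw = np.array([table.get(el.upper(), _FALLBACK_VDW) for el in sub.element])

    z_lo, z_hi = z_range
    if z_hi <= z_lo:
        raise AnalysisError("z_range must be increasing")
    grid = np.arange(z_lo, z_hi + 1e-9, z_step)
    coords = sub.coords
    radii = np.empty(len(grid))
    centers = np.empty((len(grid), 2))
    occluded = np.zeros(len(grid), dtype=bool)
    unbounded = np.zeros(len(grid), dtype=bool)
    seed = np.asarray(axis_xy, dtype=float)

    for i, z in enumerate(grid):
        slab = np.abs(coords[:, 2] - z) <= z_step
        pts = coords[slab]
        rad = vdw[slab]
        near = pts[
            np.hypot(pts[:, 0] - seed[0], pts[:, 1] - seed[1]) <= neighbor_cutoff
        ]
        if near.shape[0] == 0:
            radii[i] = np.inf
            centers[i] = seed
            unbounded[i] = True
            continue

        def clearance(c, pts=pts, rad=rad, z=z):
            d = np.sqrt(
                (pts[:, 0] - c[0]) ** 2 + (pts[:, 1] - c[1]) ** 2 + (pts[:, 2] - z) ** 2
            )
            return float(np.min(d - rad))

        best_c, best_r = _compass_search(clearance, seed)
        centers[i] = best_c
        if best_r < 0:
            occluded[i] = True
            radii[i] = 0.0
        else:
            radii[i] = best_r
        seed = best_c  # seed the next slice

    return PoreProfile(
        z=grid,
        radius=radii,
        centers=centers,
        occluded=occluded,
        unbounded=unbounded,
        backbone_only=backbone_only,
        probe={"z_step": z_step, "neighbor_cutoff": neighbor_cutoff},
    )


def min_radius_near(
    profile: PoreProfile, z_center: float, window: float
) -> tuple[float, float]:
    """Minimum radius within +/- window of z_center: returns (z_at_min, radius).

    Unbounded slices are ignored; ties resolve to the smaller z.
    """
    mask = np.abs(profile.z - z_center) <= window
    mask &= ~profile.unbounded
    if not mask.any():
        raise AnalysisError(
            f"window {z_center} +/- {window} does not intersect the profile grid"
        )
    idx = np.flatnonzero(mask)
    r = profile.radius[idx]
    best = idx[np.argmin(r)]  # argmin returns the first (smallest z) minimum
    return float(profile.z[best]), float(profile.radius[best])


def profile_series(
    trajectory: Trajectory, pore_selection, z_range, **kwargs
) -> list[PoreProfile]:
    """One pore profile per trajectory frame (radius vs z vs time)."""
    return [
        pore_profile(trajectory.frame(i), pore_selection, z_range, **kwargs)
        for i in range(trajectory.n_frames)
    ]


def count_waters_in_gate(
    frame: Structure,
    water_selection,
    gate_center,
    radius: float,
    half_height: float,
) -> int:
    """Water oxygens inside the axis-aligned cylinder at the gate.

    An opening pore hydrates: this count rising over a trajectory is the
    standard secondary indicator of dilation.
    """
    sel = np.asarray(water_selection, dtype=int)
    if sel.size == 0:
        import warnings

        warnings.warn("empty water selection: gate water count is 0")
        return 0
    sub = frame.subset(sel)
    oxy = sub.coords[np.char.upper(sub.element.astype(str)) == "O"]
    c = np.asarray(gate_center, dtype=float)
    in_z = np.abs(oxy[:, 2] - c[2]) <= half_height
    in_r = np.hypot(oxy[:, 0] - c[0], oxy[:, 1] - c[1]) <= radius
    return int(np.count_nonzero(in_z & in_r))
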