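"""Synthetic systems with known ground truth for every analysis stage.

Every generator here is a pure function of its arguments (including the
seed), so each analysis operation in the package can be validated against a
constructed truth without any external data: a supercoiled bead-spring with
known stiffness for the mechanics layer, cylinders with known radius profiles
for the pore profiler, drifting ions with a generation-time crossing log for
the permeation detector, rigid rotations with known angles, distance traces
with injected jumps for the sharp-change filter, and donor/acceptor toys that
straddle the hydrogen-bond criterion.

Generator APIs use nm/ps/pN natively; coordinates are converted to Angstrom
at the Structure/Trajectory boundary.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import AnalysisError, SimulationUnstableError
from .mechanics import ForceTrace
from .permeation import CrossingEvent
from .structure import DomainMap, Structure, Trajectory
from .units import BOLTZMANN_PN_NM, KJ_MOL_NM_IN_PN

__all__ = [
    "SpringModel",
    "ToyRunResult",
    "make_helical_spring",
    "simulate_overdamped",
    "ar_length_series",
    "make_pore_cylinder",
    "make_ion_drift_trajectory",
    "make_rigid_rotation_trajectory",
    "make_distance_trace_with_jump",
    "make_hbond_toy",
    "make_delayed_force_traces",
    "make_channel_model",
    "channel_model_domain_map",
]

_CHAIN_IDS = string.ascii_uppercase


# ---------------------------------------------------------------------------
# bead-spring model of the AR supercoil


@dataclass
class SpringModel:
    """A four-chain supercoiled bead-spring emulating the AR helix bundle.

    One bead per ankyrin repeat plus a restrained head bead per chain (the
    linker-helix anchor).  Consecutive beads are joined by harmonic springs
    whose constants are series-composed so that the end-to-end stiffness of a
    chain is ``k_chain_pn_per_nm``.  The defaults encode the studied system:
    four chains of 29 repeats whose relaxed bundle is 15 nm long, a per-chain
    stiffness of 3 pN/nm, and a flat-bottom lateral confinement of radius
    3 nm with the 100 kJ mol^-1 nm^-2 stiffness used for such restraints.
    """

    n_chains: int = 4
    n_beads_per_chain: int = 29
    helix_radius_nm: float = 2.0
    rise_per_bead_nm: float = 15.0 / 29.0
    twist_per_bead_deg: float = 360.0 / 29.0
    k_chain_pn_per_nm: float = 3.0
    head_stiffness_pn_per_nm: float = 100.0 * KJ_MOL_NM_IN_PN  # 100 kJ/mol/nm^2
    confine_radius_nm: float = 3.0
    confine_stiffness_pn_per_nm: float = 100.0 * KJ_MOL_NM_IN_PN
    friction_pn_ps_per_nm: float = 10.0

    def __post_init__(self):
        if self.n_chains < 1 or self.n_beads_per_chain < 1:
            raise ValueError("need at least one chain and one bead")
        for name in (
            "helix_radius_nm",
            "rise_per_bead_nm",
            "k_chain_pn_per_nm",
            "head_stiffness_pn_per_nm",
            "friction_pn_ps_per_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k_bond_pn_per_nm(self) -> float:
        """Per-bond stiffness: n_beads springs in series give k_chain."""
        return self.k_chain_pn_per_nm * self.n_beads_per_chain

    @property
    def rest_length_nm(self) -> float:
        """End-to-end (head-to-tail) relaxed length: n_beads x rise."""
        return self.n_beads_per_chain * self.rise_per_bead_nm

    def relaxed_positions_nm(self) -> np.ndarray:
        """Relaxed bead positions, shape (n_chains, n_beads+1, 3), nm.

        Bead 0 of each chain is the head (z = 0); bead i sits at z = i x rise
        on a helix of the configured radius and twist, chains phased by
        2 pi / n_chains so the bundle is C_{n_chains}-symmetric about z.
        """
        n = self.n_beads_per_chain
        twist = np.deg2rad(self.twist_per_bead_deg)
        i = np.arange(n + 1)
        pos = np.empty((self.n_chains, n + 1, 3))
        for c in range(self.n_chains):
            phase = 2.0 * np.pi * c / self.n_chains
            ang = phase + i * twist
            pos[c, :, 0] = self.helix_radius_nm * np.cos(ang)
            pos[c, :, 1] = self.helix_radius_nm * np.sin(ang)
            pos[c, :, 2] = i * self.rise_per_bead_nm
        return pos

    @property
    def bond_rest_length_nm(self) -> float:
        twist = np.deg2rad(self.twist_per_bead_deg)
        chord = 2.0 * self.helix_radius_nm * np.sin(twist / 2.0)
        return float(np.hypot(chord, self.rise_per_bead_nm))


def make_helical_spring(spec: SpringModel) -> Structure:
    """Relaxed bead-spring structure (coordinates in Angstrom)."""
    pos = spec.relaxed_positions_nm()
    n_chains, n_beads1, _ = pos.shape
    total = n_chains * n_beads1
    chain_id = np.repeat([_CHAIN_IDS[c] for c in range(n_chains)], n_beads1)
    res_id = np.tile(np.arange(n_beads1), n_chains)
    return Structure(
        chain_id=np.asarray(chain_id),
        res_id=res_id,
        ins_code=np.full(total, ""),
        res_name=np.full(total, "BDS"),
        atom_name=np.full(total, "BD"),
        element=np.full(total, "C"),
        occupancy=np.ones(total),
        coords=pos.reshape(total, 3) * 10.0,  # nm -> Angstrom
    )


@dataclass
class ToyRunResult:
    """Output of :func:`simulate_overdamped`."""

    model: SpringModel
    trajectory: Trajectory  # Angstrom / ps
    force_trace: ForceTrace  # head-restraint reaction forces, pN
    applied_force_pn: float  # signed force per chain along z, on the tail bead
    seed: int

    def __post_init__(self):
        if self.force_trace.n_frames != self.trajectory.n_frames:
            raise ValueError("reaction-force record must match frame count")


def simulate_overdamped(
    model: SpringModel,
    start: Structure | None = None,
    force_per_chain_pn: float = 0.0,
    dt_ps: float = 0.02,
    n_steps: int = 200_000,
    temperature_K: float = 300.0,
    seed: int = 0,
    record_every: int = 20,
) -> ToyRunResult:
    """Brownian (overdamped Langevin) dynamics of the bead-spring bundle.

    Bonds are shape-preserving harmonic springs on the bond *vector* (the
    reference vectors come from the relaxed helix), which keeps the
    supercoiled geometry stable under compression — a freely-jointed chain of
    length-only springs would simply buckle, which the solid ankyrin stack
    does not do.  The series composition still makes the end-to-end axial
    stiffness of each chain exactly ``k_chain``.  The head bead of each chain
    is harmonically restrained to its start position and its per-step
    restraint reaction force is recorded; the signed external force acts on
    the tail bead along z (negative = toward the head = compression); the
    tail bead additionally feels the flat-bottom lateral confinement.
    Identical arguments (including seed) give identical output.
    """
    if dt_ps <= 0 or n_steps <= 0:
        raise ValueError("dt and n_steps must be positive")
    rng = np.random.default_rng(seed)
    if start is None:
        x = model.relaxed_positions_nm()
    else:
        x = (
            np.asarray(start.coords, dtype=float).reshape(
                model.n_chains, model.n_beads_per_chain + 1, 3
            )
            / 10.0
        )
    x = x.copy()
    relaxed = model.relaxed_positions_nm()
    bond_ref = relaxed[:, 1:, :] - relaxed[:, :-1, :]  # reference bond vectors
    head_ref = x[:, 0, :].copy()
    tail_ref_xy = x[:, -1, :2].copy()
    d0 = model.bond_rest_length_nm
    k_bond = model.k_bond_pn_per_nm
    gamma = model.friction_pn_ps_per_nm
    mobility = dt_ps / gamma
    noise_scale = np.sqrt(2.0 * BOLTZMANN_PN_NM * temperature_K * dt_ps / gamma)

    n_rec = n_steps // record_every
    rec_coords = np.empty((n_rec, x.shape[0] * x.shape[1], 3))
    rec_forces = np.empty((n_rec, model.n_chains, 3))
    rec_times = np.empty(n_rec)
    rec = 0

    for step in range(1, n_steps + 1):
        forces = np.zeros_like(x)
        # shape-preserving harmonic bonds along each chain
        d = x[:, 1:, :] - x[:, :-1, :]
        dev = d - bond_ref
        dev_norm = np.linalg.norm(dev, axis=2)
        if np.any(dev_norm > 10.0 * d0):
            raise SimulationUnstableError(
                f"bond deviation exceeded 10x rest length at step {step} "
                f"(max {dev_norm.max():.2f} nm, rest {d0:.2f} nm); reduce dt"
            )
        bond_force = k_bond * dev  # force on the earlier bead of each bond
        forces[:, :-1, :] += bond_force
        forces[:, 1:, :] -= bond_force
        # head restraint
        head_disp = x[:, 0, :] - head_ref
        restraint_force = -model.head_stiffness_pn_per_nm * head_disp
        forces[:, 0, :] += restraint_force
        # flat-bottom lateral confinement on the tail bead
        lat = x[:, -1, :2] - tail_ref_xy
        r = np.linalg.norm(lat, axis=1)
        over = r > model.confine_radius_nm
        if over.any():
            pull = (
                -model.confine_stiffness_pn_per_nm
                * (r[over] - model.confine_radius_nm)
                / r[over]
            )
            forces[over, -1, :2] += pull[:, None] * lat[over]
        # external force on the tail bead, along z
        forces[:, -1, 2] += force_per_chain_pn

        x += mobility * forces
        if temperature_K > 0:
            x += noise_scale * rng.standard_normal(x.shape)

        if step % record_every == 0:
            rec_coords[rec] = x.reshape(-1, 3) * 10.0
            rec_forces[rec] = -model.head_stiffness_pn_per_nm * (x[:, 0, :] - head_ref)
            rec_times[rec] = step * dt_ps
            rec += 1

    topology = make_helical_spring(model) if start is None else start
    trajectory = Trajectory(topology=topology, coords=rec_coords, times=rec_times)
    trace = ForceTrace(
        times=rec_times,
        forces=rec_forces,
        application_points=head_ref * 10.0,  # Angstrom
        meta={
            "restrained": "head beads",
            "source": "simulate_overdamped",
            "seed": seed,
            "force_per_chain_pn": force_per_chain_pn,
        },
    )
    return ToyRunResult(
        model=model,
        trajectory=trajectory,
        force_trace=trace,
        applied_force_pn=force_per_chain_pn,
        seed=seed,
    )


def ar_length_series(result: ToyRunResult) -> np.ndarray:
    """Per-frame spring length in nm: mean over chains of z(tail) - z(head)."""
    n1 = result.model.n_beads_per_chain + 1
    coords = result.trajectory.coords.reshape(
        result.trajectory.n_frames, result.model.n_chains, n1, 3
    )
    return (coords[:, :, -1, 2] - coords[:, :, 0, 2]).mean(axis=1) / 10.0


# ---------------------------------------------------------------------------
# pore fixtures


def make_pore_cylinder(
    radius_profile: float | Callable[[float], float],
    atom_vdw: float = 1.7,
    axial_extent: float = 30.0,
    ring_density: int = 24,
    ring_spacing: float = 0.5,
) -> Structure:
    """Rings of atoms whose accessible pore radius at z equals the profile.

    ``radius_profile`` maps z (Angstrom) to the accessible radius (Angstrom);
    atom centers are placed at ``profile(z) + atom_vdw`` so that an inscribed
    probe touching the van der Waals surface reads exactly the profile.
    """
    if callable(radius_profile):
        prof = radius_profile
    else:
        r_const = float(radius_profile)
        prof = lambda z: r_const  # noqa: E731
    zs = np.arange(-axial_extent / 2.0, axial_extent / 2.0 + 1e-9, ring_spacing)
    coords = []
    for iz, z in enumerate(zs):
        r = prof(z)
        if r < 0:
            raise ValueError("radius profile must be non-negative")
        ring_r = r + atom_vdw
        offset = 0.5 * (iz % 2) * 2.0 * np.pi / ring_density  # stagger rings
        ang = offset + 2.0 * np.pi * np.arange(ring_density) / ring_density
        ring = np.column_stack(
            [ring_r * np.cos(ang), ring_r * np.sin(ang), np.full(ring_density, z)]
        )
        coords.append(ring)
    coords = np.concatenate(coords, axis=0)
    n = len(coords)
    return Structure(
        chain_id=np.full(n, "A"),
        res_id=np.repeat(np.arange(1, len(zs) + 1), ring_density),
        ins_code=np.full(n, ""),
        res_name=np.full(n, "CYL"),
        atom_name=np.full(n, "C"),
        element=np.full(n, "C"),
        occupancy=np.ones(n),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# ion drift fixture with generation-time crossing log


def make_ion_drift_trajectory(
    n_ions: int = 20,
    drift_nm_per_ns: float = 0.0,
    diffusion_nm2_per_ns: float = 1.0,
    box_z_nm: float = 12.0,
    cylinder_z_nm: tuple[float, float] = (4.0, 8.0),
    cylinder_radius_nm: float = 1.0,
    lateral_sd_nm: float = 0.2,
    n_frames: int = 500,
    dt_ps: float = 10.0,
    seed: int = 0,
    species: str = "K+",
    charge_e: float = 1.0,
) -> tuple[Trajectory, list[CrossingEvent]]:
    """Ions drifting/diffusing along z in a periodic box, plus the truth log.

    Returns the (z-wrapped) trajectory with box information and the list of
    complete cylinder traversals computed from the continuous, unwrapped
    paths during generation; periodic re-entry from the far side never counts
    as a traversal.
    """
    rng = np.random.default_rng(seed)
    dt_ns = dt_ps * 1e-3
    z0 = rng.uniform(0.0, box_z_nm, size=n_ions)
    z_unwrapped = np.empty((n_frames, n_ions))
    z_unwrapped[0] = z0
    steps = drift_nm_per_ns * dt_ns + np.sqrt(
        2.0 * diffusion_nm2_per_ns * dt_ns
    ) * rng.standard_normal((n_frames - 1, n_ions))
    z_unwrapped[1:] = z0 + np.cumsum(steps, axis=0)
    # lateral jitter well inside the cylinder radius
    lat = lateral_sd_nm * rng.standard_normal((n_frames, n_ions, 2))
    np.clip(lat, -0.9 * cylinder_radius_nm, 0.9 * cylinder_radius_nm, out=lat)

    z_wrapped = np.mod(z_unwrapped, box_z_nm)
    times = dt_ps * np.arange(n_frames)

    # ground-truth log from the continuous paths
    z_lo, z_hi = cylinder_z_nm
    truth: list[CrossingEvent] = []
    for ion in range(n_ions):
        zw = z_wrapped[:, ion]
        r = np.linalg.norm(lat[:, ion, :], axis=1)

        def region(z):
            if z < z_lo:
                return -1
            if z > z_hi:
                return 1
            return 0

        state = region(zw[0])
        origin = state if state != 0 else None
        entry = None
        bad = state == 0 and r[0] >= cylinder_radius_nm
        for i in range(1, n_frames):
            new = region(zw[i])
            # a periodic wrap appears as a direct above<->below transition of
            # the continuous path; it never passes through the interior
            if new == 0:
                if state != 0:
                    origin, entry, bad = state, times[i], False
                if r[i] >= cylinder_radius_nm:
                    bad = True
            else:
                if state == 0 and origin is not None and new != origin and not bad:
                    truth.append(
                        CrossingEvent(
                            ion_id=ion,
                            species=species,
                            charge_e=charge_e,
                            entry_time_ps=float(entry),
                            exit_time_ps=float(times[i]),
                            direction=1 if new == 1 else -1,
                        )
                    )
                origin, entry, bad = new, None, False
            state = new
    truth.sort(key=lambda e: e.exit_time_ps)

    coords_nm = np.concatenate(
        [lat, z_wrapped[:, :, None]], axis=2
    )  # (n_frames, n_ions, 3)
    topo = Structure(
        chain_id=np.full(n_ions, "I"),
        res_id=np.arange(1, n_ions + 1),
        ins_code=np.full(n_ions, ""),
        res_name=np.full(n_ions, "ION"),
        atom_name=np.full(n_ions, "K"),
        element=np.full(n_ions, "K"),
        occupancy=np.ones(n_ions),
        coords=coords_nm[0] * 10.0,
    )
    lateral_box = 10.0 * max(4.0 * cylinder_radius_nm, 2.0)
    box = np.tile([lateral_box, lateral_box, box_z_nm * 10.0], (n_frames, 1))
    traj = Trajectory(
        topology=topo, coords=coords_nm * 10.0, times=times, box=box
    )
    return traj, truth


# ---------------------------------------------------------------------------
# rigid rotations, distance traces, H-bond toys, delayed force traces


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def make_rigid_rotation_trajectory(
    structure: Structure,
    selection,
    tilt_series_deg: Sequence[float],
    rotation_series_deg: Sequence[float],
    domain_axis: np.ndarray | None = None,
) -> Trajectory:
    """Frames in which the selection is rigidly tilted/rotated by known angles.

    Frame i applies, about the selection centroid, first a tilt by
    ``tilt_series_deg[i]`` away from z (in the plane spanned by the domain
    axis and z), then a rotation by ``rotation_series_deg[i]`` about z
    (right-handed about +z, i.e. clockwise viewed from the intracellular -z
    side).  Atoms outside the selection are untouched.
    """
    tilt = np.asarray(tilt_series_deg, dtype=float)
    rot = np.asarray(rotation_series_deg, dtype=float)
    if tilt.shape != rot.shape:
        raise ValueError("tilt and rotation series must have equal length")
    sel = np.asarray(selection, dtype=int)
    base = structure.coords
    centroid = base[sel].mean(axis=0)
    if domain_axis is None:
        centered = base[sel] - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        domain_axis = vt[0]
    a = np.asarray(domain_axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    tilt_axis = np.cross(a, z)
    if np.linalg.norm(tilt_axis) < 1e-12:
        tilt_axis = np.array([1.0, 0.0, 0.0])  # axis on z: any in-plane axis
    tilt_axis = tilt_axis / np.linalg.norm(tilt_axis)

    frames = np.tile(base, (len(tilt), 1, 1))
    for i, (t_deg, r_deg) in enumerate(zip(tilt, rot)):
        # rotating about (a x z) by -t moves the axis away from z by +t
        R = _rotation_about(z, np.deg2rad(r_deg)) @ _rotation_about(
            tilt_axis, -np.deg2rad(t_deg)
        )
        frames[i, sel] = (base[sel] - centroid) @ R.T + centroid
    return Trajectory(
        topology=structure, coords=frames, times=np.arange(len(tilt), dtype=float)
    )


def make_distance_trace_with_jump(
    n_frames: int,
    baseline: float,
    noise_sd: float,
    jump_at_frame: int | None = None,
    jump_amplitude: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian noise around a baseline with an optional step at a frame."""
    rng = np.random.default_rng(seed)
    series = baseline + noise_sd * rng.standard_normal(n_frames)
    if jump_at_frame is not None and jump_amplitude != 0.0:
        series[jump_at_frame:] += jump_amplitude
    return series


def make_hbond_toy(d_da: float, angle_dha_deg: float, with_hydrogen: bool = True) -> Structure:
    """One donor-H-acceptor triple with exactly the requested geometry.

    The donor N sits at the origin, the acceptor O at (d_da, 0, 0), and the
    hydrogen at 1.0 Angstrom from the donor such that the D-H-A angle equals
    ``angle_dha_deg`` (solved from the triangle's law of sines).
    """
    if d_da <= 0:
        raise ValueError("donor-acceptor distance must be positive")
    theta = np.deg2rad(angle_dha_deg)
    d_dh = 1.0
    names = ["N", "O"]
    res_ids = [1, 2]
    res_names = ["DON", "ACC"]
    elements = ["N", "O"]
    coords = [[0.0, 0.0, 0.0], [d_da, 0.0, 0.0]]
    if with_hydrogen:
        if d_da < d_dh and angle_dha_deg < 90:
            raise ValueError("geometry infeasible")
        sin_beta = np.clip(d_dh * np.sin(theta) / d_da, -1.0, 1.0)
        beta = np.arcsin(sin_beta)  # angle at the acceptor
        alpha = np.pi - theta - beta  # angle at the donor
        coords.append([d_dh * np.cos(alpha), d_dh * np.sin(alpha), 0.0])
        names.append("H")
        res_ids.append(1)
        res_names.append("DON")
        elements.append("H")
    n = len(coords)
    return Structure(
        chain_id=np.full(n, "A"),
        res_id=np.asarray(res_ids),
        ins_code=np.full(n, ""),
        res_name=np.asarray(res_names),
        atom_name=np.asarray(names),
        element=np.asarray(elements),
        occupancy=np.ones(n),
        coords=np.asarray(coords, dtype=float),
    )


def make_delayed_force_traces(
    delay_ps: float,
    duration_ps: float = 40.0,
    dt_ps: float = 0.01,
    baseline_sd_pn: float = 0.5,
    step_pn: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Free and perturbed net-force traces whose difference departs at a delay.

    Emulates a finite signal speed: the perturbed trace is baseline noise
    identical in distribution to the free trace until ``delay_ps``, then
    shifts by ``step_pn``.  Returns (times, free, perturbed).
    """
    if delay_ps <= 0 or delay_ps >= duration_ps:
        raise ValueError("delay must fall inside the trace duration")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_ps, dt_ps)
    free = baseline_sd_pn * rng.standard_normal(len(times))
    perturbed = baseline_sd_pn * rng.standard_normal(len(times))
    perturbed[times >= delay_ps] += step_pn
    return times, free, perturbed


# ---------------------------------------------------------------------------
# synthetic channel model (stand-in for a real cryo-EM tetramer)


def make_channel_model() -> Structure:
    """SYNTHETIC stand-in for a tetrameric mechanosensitive channel model.

    This is a programmatically constructed mimic, not a deposited structure:
    a C4 tetramer (chains A-D) with (i) a transmembrane pore lined by rings
    of atoms whose accessible radius narrows to 0.5 Angstrom at the gate
    residue ILE 1554 (hourglass profile over z in [-15, 15]), with a wider
    backbone-only (CA) shell; (ii) a 29-repeat ankyrin spring per chain whose
    AR1-to-AR29 center-of-mass extent is 15 nm; and (iii) the TRP-LH and
    AR-LH interface residues placed so that the hydrogen-bond census known
    for the real closed-state model holds by construction: W1572-S1421
    (backbone O), K1244-E1571 and D1236-R1581 within the geometric criterion,
    Q1253-S1577 too far, plus the W1115-D1142 and R1127-E1163 pairs at the
    AR29-LH interface.  No hydrogens are present, as in a typical cryo-EM
    deposition, so detection uses the heavy-atom fallback.
    """
    chain_id, res_id, res_name, atom_name, element, coords = [], [], [], [], [], []

    def add(ch, rid, rname, aname, el, xyz):
        chain_id.append(ch)
        res_id.append(rid)
        res_name.append(rname)
        atom_name.append(aname)
        element.append(el)
        coords.append(xyz)

    vdw_c = 1.7

    # --- transmembrane pore: hourglass accessible radius, min 0.5 A at z=0
    n_ring = 8
    for iz, z in enumerate(np.arange(-15.0, 15.0 + 1e-9, 1.0)):
        rid = 1539 + iz  # gate ring (z=0) gets residue 1554
        acc = 0.5 + 0.018 * z * z
        rname = "ILE" if rid == 1554 else "ALA"
        aname = "CD1" if rid == 1554 else "CB"
        ring_r = acc + vdw_c
        ang = 2.0 * np.pi * np.arange(n_ring) / n_ring + (iz % 2) * np.pi / n_ring
        for j in range(n_ring):
            ch = _CHAIN_IDS[j // (n_ring // 4)]
            add(
                ch,
                rid,
                rname,
                aname,
                "C",
                [ring_r * np.cos(ang[j]), ring_r * np.sin(ang[j]), z],
            )
        # backbone shell (CA), 2.5 A further out: backbone-only profiles are wider
        ca_r = ring_r + 2.5
        for j in range(4):
            a = ang[2 * j]
            ch = _CHAIN_IDS[j]
            add(ch, rid, rname, "CA", "C", [ca_r * np.cos(a), ca_r * np.sin(a), z])

    # --- ankyrin spring: 29 repeats per chain, AR1 COM to AR29 COM = 150 A
    ar_start = 174  # AR i covers residues ar_start+33(i-1) .. ar_start+33i-1
    helix_r = 20.0
    z_top, z_bottom = -20.0, -170.0
    for c in range(4):
        phase = 2.0 * np.pi * c / 4.0
        for i in range(1, 30):
            zc = z_top + (z_top - z_bottom) * (i - 29) / 28.0  # AR29 top, AR1 bottom
            ang = phase + 2.0 * np.pi * (29 - i) / 29.0
            first = ar_start + 33 * (i - 1)
            for k, dz in enumerate((-1.5, 0.0, 1.5)):
                add(
                    _CHAIN_IDS[c],
                    first + 16 * k,
                    "ALA",
                    "CA",
                    "C",
                    [helix_r * np.cos(ang), helix_r * np.sin(ang), zc + dz],
                )

    # --- interface residue clusters (heavy atoms only, per chain, C4-placed)
    # (residue, atom, element, local xyz); clusters spaced so only the
    # constructed partners fall within hydrogen-bonding range
    clusters = [
        # TRP-LH interface, near the intracellular face
        ("TRP", 1572, "NE1", "N", [24.0, 0.0, -8.0]),
        ("SER", 1421, "O", "O", [24.0, 2.9, -8.0]),  # backbone O: bonded (2.9 A)
        ("SER", 1421, "OG", "O", [24.0, 2.9, -13.0]),  # side chain: far from NE1
        ("GLN", 1253, "NE2", "N", [24.0, -12.0, -8.0]),
        ("SER", 1577, "OG", "O", [24.0, -16.5, -8.0]),  # 4.5 A: NOT bonded
        ("LYS", 1244, "NZ", "N", [33.0, 0.0, -8.0]),
        ("GLU", 1571, "OE1", "O", [33.0, 0.0, -10.8]),  # 2.8 A: bonded
        ("ASP", 1236, "OD1", "O", [33.0, 9.0, -8.0]),
        ("ARG", 1581, "NH1", "N", [33.0, 11.9, -8.0]),  # 2.9 A: bonded
        # AR29-LH interface, further down
        ("TRP", 1115, "NE1", "N", [22.0, 0.0, -24.0]),
        ("ASP", 1142, "OD1", "O", [22.0, 2.9, -24.0]),  # bonded
        ("ARG", 1127, "NH1", "N", [22.0, -9.0, -24.0]),
        ("GLU", 1163, "OE1", "O", [22.0, -11.8, -24.0]),  # bonded
    ]
    rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    for c in range(4):
        R = np.linalg.matrix_power(rot90, c)
        seen_ca = set()
        for rname, rid, aname, el, xyz in clusters:
            add(_CHAIN_IDS[c], rid, rname, aname, el, list(R @ np.asarray(xyz)))
            if rid not in seen_ca:
                # one CA per interface residue so residue-level selections work
                ca = R @ (np.asarray(xyz) + np.array([0.0, 0.0, 3.5]))
                add(_CHAIN_IDS[c], rid, rname, "CA", "C", list(ca))
                seen_ca.add(rid)

    n = len(coords)
    order = np.lexsort((np.asarray(res_id), np.asarray(chain_id)))
    return Structure(
        chain_id=np.asarray(chain_id)[order],
        res_id=np.asarray(res_id)[order],
        ins_code=np.full(n, ""),
        res_name=np.asarray(res_name)[order],
        atom_name=np.asarray(atom_name)[order],
        element=np.asarray(element)[order],
        occupancy=np.ones(n),
        coords=np.asarray(coords, dtype=float)[order],
    )


def channel_model_domain_map() -> DomainMap:
    """Domain map matching :func:`make_channel_model` (all chains)."""
    ar_start = 174
    regions = {
        "TM": [{"chain": "*", "start": 1539, "stop": 1569}],
        "S6": [{"chain": "*", "start": 1539, "stop": 1569}],
        "gate_residue": [{"chain": "*", "start": 1554, "stop": 1554}],
        "TRP": [{"chain": "*", "start": 1570, "stop": 1590}],
        "LH": [{"chain": "*", "start": 1131, "stop": 1360}],
        "S4S5_linker": [{"chain": "*", "start": 1415, "stop": 1430}],
        "AR": [{"chain": "*", "start": ar_start, "stop": ar_start + 33 * 29 - 1}],
    }
    for i in range(1, 30):
        first = ar_start + 33 * (i - 1)
        regions[f"AR{i}"] = [{"chain": "*", "start": first, "stop": first + 32}]
    return DomainMap.from_dict(regions)
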