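"""Synthetic-data generators with known ground truth.

Every analysis stage in this package can be exercised without external
downloads: these generators produce inputs with the statistical structure
each stage assumes and return the planted ground truth alongside the
data.  All generators are deterministic under a fixed seed.

Contents
--------
- metastable feature trajectories from a planted Markov chain
  (:func:`gen_metastable_trajectory`), emulating slow conformational
  exchange between a few basins with fast intra-basin mixing;
- minimal protein/ligand geometries at prescribed interaction geometry
  (:func:`gen_interaction_fixture`, :func:`gen_interaction_trajectory`);
- water-position ensembles with planted hydration sites
  (:func:`gen_water_ensemble`);
- 1-D well-tempered metadynamics on a double well
  (:func:`gen_metad_traces`) — a toy integrator for validating trace
  parsing, the WT height-damping rule and dissociation classification,
  not physics;
- CV traces with planted dissociation fractions
  (:func:`gen_dissociation_traces`);
- a backbone builder from phi/psi angles (:func:`build_peptide`) and a
  solvated-sidechain fixture (:func:`gen_exposure_fixture`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, Structure, Trajectory
from .metadynamics import CVTrace
from .msm import FeatureMatrix

__all__ = [
    "KineticEmissionSpec",
    "ToyMetadSpec",
    "sample_markov_chain",
    "gen_metastable_trajectory",
    "gen_interaction_fixture",
    "gen_interaction_trajectory",
    "gen_water_ensemble",
    "gen_metad_traces",
    "gen_dissociation_traces",
    "build_peptide",
    "gen_exposure_fixture",
]


# ---------------------------------------------------------------------------
# Planted metastable kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticEmissionSpec:
    """Planted Markov kinetics with Gaussian emissions.

    By default the macro chain is a reversible matrix built by detailed
    balance around ``stationary`` whose two relaxation timescales equal
    ``timescale_slow_frames`` and ``timescale_fast_frames`` exactly (the
    pair rates are solved for at construction), so the spectrum is
    non-degenerate and the slowest timescale is a well-posed recovery
    target.  A full ``transition_matrix`` may be planted instead.  Each
    basin holds ``microstates_per_basin`` microstates resampled every
    frame (fast intra-basin mixing), so macro lumping is exact.  Emission
    noise is chosen so basins overlap mildly (a few percent
    misassignment).
    """
    n_frames: int = 10000
    stationary: tuple = (0.43, 0.32, 0.25)
    timescale_slow_frames: float = 22.0
    timescale_fast_frames: float = 11.0
    transition_matrix: np.ndarray | None = None
    microstates_per_basin: int = 4
    basin_separation: float = 4.0
    emission_sigma: float = 0.8
    micro_offset_sigma: float = 0.3
    n_noise_features: int = 2
    seed: int = 0

    def __post_init__(self):
        pi = np.asarray(self.stationary, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi <= 0):
            raise ValueError("stationary must be a positive distribution")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("planted transition matrix rows must sum to 1")

    @property
    def n_metastable(self) -> int:
        return len(self.stationary)

    def _default_matrix(self) -> np.ndarray:
        from scipy.optimize import least_squares

        pi = np.asarray(self.stationary, dtype=float)
        if len(pi) != 3:
            raise ValueError("the default matrix construction covers 3 basins; "
                             "plant transition_matrix explicitly otherwise")
        targets = (np.exp(-1.0 / self.timescale_slow_frames),
                   np.exp(-1.0 / self.timescale_fast_frames))

        def build(rates):
            r01, r12, r02 = np.abs(rates)
            t = np.zeros((3, 3))
            t[0, 1], t[1, 0] = r01, r01 * pi[0] / pi[1]
            t[1, 2], t[2, 1] = r12, r12 * pi[1] / pi[2]
            t[0, 2], t[2, 0] = r02, r02 * pi[0] / pi[2]
            np.fill_diagonal(t, 0.0)
            np.fill_diagonal(t, 1.0 - t.sum(axis=1))
            return t

        def resid(rates):
            vals = np.sort(np.real(np.linalg.eigvals(build(rates))))
            return [vals[-2] - targets[0], vals[-3] - targets[1]]

        sol = least_squares(resid, [0.02, 0.005, 0.02], xtol=1e-14, ftol=1e-14)
        t = build(sol.x)
        if np.any(np.diag(t) <= 0) or np.max(np.abs(resid(sol.x))) > 1e-8:
            raise ValueError("requested relaxation timescales are unrealizable")
        return t

    @property
    def macro_transition_matrix(self) -> np.ndarray:
        if self.transition_matrix is not None:
            return np.asarray(self.transition_matrix, dtype=float)
        return self._default_matrix()

    @property
    def macro_stationary(self) -> np.ndarray:
        t = self.macro_transition_matrix
        vals, vecs = np.linalg.eig(t.T)
        mu = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1.0))]))
        return mu / mu.sum()

    @property
    def slowest_timescale_frames(self) -> float:
        vals = np.sort(np.real(np.linalg.eigvals(self.macro_transition_matrix)))
        lam2 = vals[-2]
        return -1.0 / np.log(lam2)


def sample_markov_chain(transition_matrix: np.ndarray, n_steps: int,
                        seed: int = 0, start: int = 0) -> np.ndarray:
    """Sample a state sequence from a row-stochastic matrix."""
    t = np.asarray(transition_matrix, dtype=float)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows must sum to 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(t, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = start
    u = rng.random(n_steps)
    for i in range(1, n_steps):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return states


def gen_metastable_trajectory(spec: KineticEmissionSpec) -> dict:
    """Sample the planted chain and emit Gaussian features.

    Returns a dict with ``features`` (:class:`FeatureMatrix`),
    ``macro_labels``, ``micro_labels``, ``true_pi``,
    ``true_transition_matrix`` and ``true_slowest_timescale_frames``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    pi = spec.macro_stationary
    m = spec.n_metastable
    t_macro = spec.macro_transition_matrix

    cum = np.cumsum(t_macro, axis=1)
    u = rng.random(n)
    macro = np.empty(n, dtype=np.int64)
    macro[0] = rng.choice(m, p=pi)
    for i in range(1, n):
        macro[i] = np.searchsorted(cum[macro[i - 1]], u[i])

    mpb = spec.microstates_per_basin
    micro = macro * mpb + rng.integers(0, mpb, size=n)

    # basin centers on an equilateral layout in 2-D
    theta = 2.0 * np.pi * np.arange(m) / m
    r = spec.basin_separation / (2.0 * np.sin(np.pi / m)) if m > 1 else 0.0
    basin_centers = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    micro_centers = (np.repeat(basin_centers, mpb, axis=0) +
                     rng.normal(0.0, spec.micro_offset_sigma, size=(m * mpb, 2)))

    informative = micro_centers[micro] + rng.normal(
        0.0, spec.emission_sigma, size=(n, 2))
    noise = rng.normal(0.0, 1.0, size=(n, spec.n_noise_features))
    data = np.hstack([informative, noise])
    labels = [("feature", i) for i in range(data.shape[1])]
    return {
        "features": FeatureMatrix(data, labels, stride_ns=1.0),
        "macro_labels": macro,
        "micro_labels": micro,
        "true_pi": pi,
        "true_transition_matrix": spec.transition_matrix,
        "true_slowest_timescale_frames": spec.slowest_timescale_frames,
        "micro_centers": micro_centers,
    }


# ---------------------------------------------------------------------------
# Interaction geometry fixtures
# ---------------------------------------------------------------------------

def _atom(serial, name, element, resname, resnum, chain, pos, roles=(),
          ring_id=None):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_number=resnum, chain=chain,
                      position=np.asarray(pos, dtype=float),
                      roles=set(roles), ring_id=ring_id)


def _benzene(first_serial, resname, resnum, chain, centroid, normal, ring_id,
             extra_roles=(), radius=1.39):
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = []
    for i in range(6):
        ang = np.pi / 3.0 * i
        pos = centroid + radius * (np.cos(ang) * u + np.sin(ang) * v)
        atoms.append(_atom(first_serial + i, f"C{i + 1}", "C", resname, resnum,
                           chain, pos,
                           roles={"aromatic_ring_member", *extra_roles},
                           ring_id=ring_id))
    return atoms


def gen_interaction_fixture(kind: str, **geometry) -> Structure:
    """Minimal atom sets realizing one interaction at a prescribed geometry.

    kinds and geometry keys (defaults satisfy the detection criteria):
      hbond:       distance (H-to-acceptor, 2.4), donor_angle (150),
                   acceptor_angle (100)
      pication:    distance (4.4) between charged center and ring centroid
      pipi:        centroid_distance (3.8), interplanar_angle (0)
      waterbridge: distance (2.7), donor_angle (150)
      saltbridge:  distance (3.9)
    """
    bonds = []
    if kind == "hbond":
        d = geometry.get("distance", 2.4)
        th_d = np.radians(geometry.get("donor_angle", 150.0))
        th_a = np.radians(geometry.get("acceptor_angle", 100.0))
        n_pos = np.array([0.0, 0.0, 0.0])
        h_pos = np.array([1.0, 0.0, 0.0])
        to_n = (n_pos - h_pos)  # unit -x
        acc_dir = np.array([-np.cos(th_d), np.sin(th_d), 0.0])
        a_pos = h_pos + d * acc_dir
        to_h = (h_pos - a_pos) / np.linalg.norm(h_pos - a_pos)
        perp = np.array([-to_h[1], to_h[0], 0.0])
        x_dir = np.cos(th_a) * to_h + np.sin(th_a) * perp
        x_pos = a_pos + 1.23 * x_dir
        atoms = [
            _atom(1, "N", "N", "ALA", 1, "A", n_pos,
                  {"hbond_donor_heavy", "polar", "backbone"}),
            _atom(2, "H", "H", "ALA", 1, "A", h_pos,
                  {"hbond_hydrogen", "polar", "backbone"}),
            _atom(3, "O1", "O", "LIG", 900, "L", a_pos,
                  {"hbond_acceptor", "polar", "ligand"}),
            _atom(4, "C1", "C", "LIG", 900, "L", x_pos, {"ligand"}),
        ]
        bonds = [(1, 2), (3, 4)]
    elif kind == "pication":
        d = geometry.get("distance", 4.4)
        atoms = _benzene(1, "LIG", 900, "L", np.zeros(3), [0, 0, 1], ring_id=0,
                         extra_roles={"ligand"})
        atoms.append(_atom(7, "NZ", "N", "LYS", 53, "A", [0.0, 0.0, d],
                           {"positive_center", "polar", "sidechain"}))
    elif kind == "pipi":
        d = geometry.get("centroid_distance", 3.8)
        ang = np.radians(geometry.get("interplanar_angle", 0.0))
        atoms = _benzene(1, "LIG", 900, "L", np.zeros(3), [0, 0, 1], ring_id=0,
                         extra_roles={"ligand"})
        normal_b = [np.sin(ang), 0.0, np.cos(ang)]
        atoms += _benzene(7, "PHE", 169, "A", np.array([0.0, 0.0, d]), normal_b,
                          ring_id=1, extra_roles={"sidechain"})
    elif kind == "waterbridge":
        d = geometry.get("distance", 2.7)
        th_d = np.radians(geometry.get("donor_angle", 150.0))
        # ligand carbonyl acceptor at origin; the water hydrogen donates to
        # it at distance d with the requested O_w-H...O_lig donor angle; a
        # protein N-H donates straight on to the water oxygen
        o_lig = np.array([0.0, 0.0, 0.0])
        c_lig = np.array([-1.23, 0.0, 0.0])
        hw1 = np.array([d, 0.0, 0.0])
        ow = hw1 + 0.96 * np.array([-np.cos(th_d), np.sin(th_d), 0.0])
        hw2 = ow + 0.96 * np.array([0.33, 0.94, 0.0])
        # protein donor N-H aimed at the water oxygen from below
        hp_dir = np.array([np.cos(np.radians(60.0)), -np.sin(np.radians(60.0)), 0.0])
        hp = ow + d * hp_dir
        n_p = hp + 1.0 * hp_dir  # straight-on donor angle of 180 degrees
        atoms = [
            _atom(1, "O1", "O", "LIG", 900, "L", o_lig,
                  {"hbond_acceptor", "polar", "ligand"}),
            _atom(2, "C1", "C", "LIG", 900, "L", c_lig, {"ligand"}),
            _atom(3, "O", "O", "HOH", 1000, "W", ow,
                  {"water_oxygen", "hbond_acceptor", "hbond_donor_heavy",
                   "polar"}),
            _atom(4, "H1", "H", "HOH", 1000, "W", hw1,
                  {"water_hydrogen", "hbond_hydrogen", "polar"}),
            _atom(5, "H2", "H", "HOH", 1000, "W", hw2,
                  {"water_hydrogen", "hbond_hydrogen", "polar"}),
            _atom(6, "H", "H", "GLY", 10, "A", hp,
                  {"hbond_hydrogen", "polar", "backbone"}),
            _atom(7, "N", "N", "GLY", 10, "A", n_p,
                  {"hbond_donor_heavy", "polar", "backbone"}),
        ]
        bonds = [(1, 2), (3, 4), (3, 5), (6, 7)]
    elif kind == "saltbridge":
        d = geometry.get("distance", 3.9)
        atoms = [
            _atom(1, "NZ", "N", "LYS", 53, "A", [0.0, 0.0, 0.0],
                  {"positive_center", "polar", "sidechain"}),
            _atom(2, "OE1", "O", "GLU", 71, "A", [d, 0.0, 0.0],
                  {"negative_center", "hbond_acceptor", "polar", "sidechain"}),
        ]
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")
    return Structure(atoms, bonds, title=f"{kind} fixture")


def gen_interaction_trajectory(kind: str, n_frames: int, on_fraction: float,
                               seed: int = 0, **geometry):
    """Trajectory toggling the interaction on exactly
    round(on_fraction * n_frames) frames (off frames displace the second
    partner by 10 A).  Returns (Trajectory, on_mask)."""
    base = gen_interaction_fixture(kind, **geometry)
    coords = base.coords
    rng = np.random.default_rng(seed)
    n_on = int(round(on_fraction * n_frames))
    on_mask = np.zeros(n_frames, dtype=bool)
    on_mask[rng.permutation(n_frames)[:n_on]] = True
    # displace every atom not in the first residue listed
    first_res = base.atoms[0].residue_key
    move = np.array([a.residue_key != first_res for a in base.atoms])
    xyz = np.repeat(coords[None, :, :], n_frames, axis=0)
    for i in np.where(~on_mask)[0]:
        xyz[i, move, 2] += 10.0
    return Trajectory(base, xyz, stride_ns=1.0), on_mask


# ---------------------------------------------------------------------------
# Water ensembles with planted hydration sites
# ---------------------------------------------------------------------------

def gen_water_ensemble(planted_sites, n_frames: int = 100,
                       bulk_noise_per_frame: int = 0,
                       box_half_width: float = 12.0, site_sigma: float = 0.3,
                       seed: int = 0) -> dict:
    """Water-oxygen observations around planted sites plus uniform bulk noise.

    ``planted_sites`` is a list of dicts with keys ``center``,
    ``occupancy`` (observation count over the whole ensemble, <= n_frames)
    and optional ``delta_g``.  Sites must be >= 1.0 A apart.  Returns a
    dict with ``positions_by_frame`` and the ground-truth ``sites`` table.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([np.asarray(s["center"], dtype=float)
                        for s in planted_sites])
    if len(centers) > 1:
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.0:
            raise ValueError("planted sites must be >= 1.0 A apart")
    frames = [[] for _ in range(n_frames)]
    for s, c in zip(planted_sites, centers):
        occ = int(s["occupancy"])
        if occ > n_frames:
            raise ValueError("site occupancy cannot exceed n_frames")
        present = rng.permutation(n_frames)[:occ]
        jitter = rng.normal(0.0, site_sigma, size=(occ, 3))
        for f, j in zip(present, jitter):
            frames[f].append(c + j)
    for f in range(n_frames):
        for _ in range(bulk_noise_per_frame):
            frames[f].append(rng.uniform(-box_half_width, box_half_width, 3))
    positions = [np.array(f).reshape(-1, 3) for f in frames]
    truth = [{"center": c, "occupancy": int(s["occupancy"]),
              "delta_g": s.get("delta_g")} for s, c in zip(planted_sites, centers)]
    return {"positions_by_frame": positions, "sites": truth,
            "n_frames": n_frames}


# ---------------------------------------------------------------------------
# Toy well-tempered metadynamics (1-D)
# ---------------------------------------------------------------------------

@dataclass
class ToyMetadSpec:
    """Overdamped Langevin on a 1-D double well with WT gaussian deposition.

    The CV is a distance-like coordinate with the bound well at
    ``well_bound`` and the unbound well at ``well_free`` (so reaching the
    dissociation threshold means crossing the barrier midway between
    them).  Bias parameters default to the production values (height 0.2
    kcal/mol, width 0.03 A, deposition every 1 ps, kTemp 3.4, wall 35 A).
    """
    barrier: float = 4.0            # kcal/mol
    well_bound: float = 2.0         # A
    well_free: float = 15.0
    temperature: float = 310.0      # K
    friction: float = 1.0           # 1/ps
    dt: float = 0.01                # ps
    n_steps: int = 30000
    gaussian_height: float = 0.2    # kcal/mol
    gaussian_width: float = 0.03    # A
    deposition_interval_steps: int = 10
    ktemp: float = 3.4              # kcal/mol WT damping scale
    wall: float = 35.0              # A
    seed: int = 0

    def __post_init__(self):
        if self.wall <= self.well_free - self.well_bound:
            raise ValueError("wall must exceed the well separation")
        for name in ("barrier", "temperature", "friction", "dt", "n_steps",
                     "gaussian_width", "deposition_interval_steps", "ktemp",
                     "wall"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kt(self) -> float:
        return 0.0019872041 * self.temperature  # kcal/mol


def _double_well_force(x, spec: ToyMetadSpec):
    c = 0.5 * (spec.well_bound + spec.well_free)
    w = 0.5 * (spec.well_free - spec.well_bound)
    f = -spec.barrier * 4.0 * ((x - c) ** 2 - w ** 2) * (x - c) / w ** 4
    if x > spec.wall:
        f -= 4.0 * 2.0 * (x - spec.wall) ** 3  # quartic wall
    return f


def _run_replica(spec: ToyMetadSpec, seed: int, bias: bool):
    rng = np.random.default_rng(seed)
    grid_lo, grid_hi = 0.0, spec.wall + 5.0
    dx = max(spec.gaussian_width / 2.0, 0.005)
    ngrid = int((grid_hi - grid_lo) / dx) + 1
    vbias = np.zeros(ngrid)
    sigma = spec.gaussian_width
    win = int(np.ceil(5.0 * sigma / dx))
    noise_scale = np.sqrt(2.0 * spec.kt * spec.dt / spec.friction)
    mob = spec.dt / spec.friction

    x = spec.well_bound
    record_every = max(spec.n_steps // 2000, 1)
    times, cvs = [], []
    deposits = []
    max_cv = x
    for step in range(spec.n_steps):
        f = _double_well_force(x, spec)
        if bias:
            gi = int((x - grid_lo) / dx)
            gi = min(max(gi, 1), ngrid - 2)
            f -= (vbias[gi + 1] - vbias[gi - 1]) / (2.0 * dx)
        x = x + mob * f + noise_scale * rng.standard_normal()
        if x < 0.0:
            x = -x  # reflective boundary at zero distance
        max_cv = max(max_cv, x)
        if bias and (step + 1) % spec.deposition_interval_steps == 0:
            gi = int(round((x - grid_lo) / dx))
            gi = min(max(gi, 0), ngrid - 1)
            h = spec.gaussian_height * np.exp(-vbias[gi] / spec.ktemp)
            lo_i = max(gi - win, 0)
            hi_i = min(gi + win + 1, ngrid)
            xs = grid_lo + dx * np.arange(lo_i, hi_i)
            vbias[lo_i:hi_i] += h * np.exp(-(xs - x) ** 2 / (2.0 * sigma ** 2))
            deposits.append((step + 1, float(x), float(h)))
        if step % record_every == 0:
            times.append(step * spec.dt * 1e-3)  # ps -> ns
            cvs.append(x)
    return np.array(times), np.array(cvs), max_cv, deposits


def gen_metad_traces(spec: ToyMetadSpec, n_replicas: int = 20,
                     bias: bool = True, start_state: str = "S1") -> dict:
    """Run replicas of the toy integrator.

    Returns a dict with ``traces`` (list of :class:`CVTrace`),
    ``max_cv`` per replica, ``deposits`` per replica (step, position,
    height triples) and ``escape_fraction`` (max CV >= well_free).
    Replica seeds derive deterministically from ``spec.seed`` so biased
    and unbiased runs can be paired.
    """
    traces, maxima, deposits = [], [], []
    params = {"gaussian_height_kcal": spec.gaussian_height if bias else 0.0,
              "deposition_interval_ps": spec.deposition_interval_steps * spec.dt,
              "width_angstrom": spec.gaussian_width, "wall_angstrom": spec.wall,
              "ktemp": spec.ktemp}
    for r in range(n_replicas):
        t, cv, mx, dep = _run_replica(spec, spec.seed * 100003 + r, bias)
        traces.append(CVTrace(replica_id=f"rep{r}", start_state=start_state,
                              times_ns=t, cv=cv, parameters=dict(params)))
        maxima.append(mx)
        deposits.append(dep)
    maxima = np.array(maxima)
    return {"traces": traces, "max_cv": maxima, "deposits": deposits,
            "escape_fraction": float(np.mean(maxima >= spec.well_free))}


def gen_dissociation_traces(per_state_counts: dict, n_points: int = 200,
                            threshold: float = 15.0, seed: int = 0) -> list:
    """CV traces with planted dissociation outcomes.

    ``per_state_counts`` maps start-state name -> (n_dissociated, n_total).
    Dissociating replicas ramp past the threshold; bound replicas stay in
    the well with their maximum strictly below it.
    """
    rng = np.random.default_rng(seed)
    traces = []
    times = np.linspace(0.0, 200.0, n_points)
    for state, (n_diss, n_total) in sorted(per_state_counts.items()):
        if n_diss > n_total:
            raise ValueError(f"{state}: dissociated count exceeds total")
        outcome = np.zeros(n_total, dtype=bool)
        outcome[:n_diss] = True
        for r, diss in enumerate(outcome):
            base = 3.0 + 0.8 * rng.standard_normal(n_points)
            base = np.clip(base, 0.5, 10.0)
            if diss:
                ramp_at = rng.integers(n_points // 4, n_points - 10)
                peak = threshold + 0.2 + 4.0 * rng.random()
                base[ramp_at:] = np.linspace(base[ramp_at], peak,
                                             n_points - ramp_at)
            traces.append(CVTrace(replica_id=f"{state}_rep{r}",
                                  start_state=state, times_ns=times,
                                  cv=base))
    return traces


# ---------------------------------------------------------------------------
# Backbone and exposure fixtures
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle, dihedral):
    """Place atom d given three predecessors and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(dihedral),
                   bond * np.sin(angle) * np.sin(dihedral)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide(phi_psi, chain: str = "A", resname: str = "ALA") -> Structure:
    """Poly-alanine-like backbone (N, CA, C per residue) with the given
    (phi, psi) per residue; terminal torsions that are undefined are
    ignored.  Standard bond geometry, omega fixed at 180 degrees."""
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    b_nca, b_cac, b_cn = 1.458, 1.525, 1.329
    a_ncac = np.radians(111.2)
    a_cacn = np.radians(116.6)
    a_cnca = np.radians(121.9)
    coords = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([b_nca, 0.0, 0.0])
    c0 = ca0 + b_cac * np.array([-np.cos(a_ncac), np.sin(a_ncac), 0.0])
    coords.append([n0, ca0, c0])
    for i in range(1, n_res):
        psi_prev = np.radians(phi_psi[i - 1][1])
        phi_i = np.radians(phi_psi[i][0])
        n_prev, ca_prev, c_prev = coords[-1]
        n_i = _nerf(n_prev, ca_prev, c_prev, b_cn, a_cacn, psi_prev)
        ca_i = _nerf(ca_prev, c_prev, n_i, b_nca, a_cnca, np.pi)
        c_i = _nerf(c_prev, n_i, ca_i, b_cac, a_ncac, phi_i)
        coords.append([n_i, ca_i, c_i])
    atoms, bonds = [], []
    serial = 1
    for i, (n_i, ca_i, c_i) in enumerate(coords, start=1):
        for name, pos in (("N", n_i), ("CA", ca_i), ("C", c_i)):
            el = name[0]
            atoms.append(_atom(serial, name, el, resname, i, chain, pos,
                               roles={"backbone"}))
            serial += 1
        base = serial - 3
        bonds += [(base, base + 1), (base + 1, base + 2)]
        if i > 1:
            bonds.append((base - 1, base))  # C(i-1)-N(i)
    return Structure(atoms, bonds, title="synthetic peptide backbone")


def gen_exposure_fixture(water_distances, resname: str = "LEU") -> Structure:
    """One residue with a branched sidechain plus water oxygens placed at
    the requested distances from the terminal sidechain atom."""
    atoms = [
        _atom(1, "N", "N", resname, 1, "A", [0.0, 0.0, 0.0], {"backbone"}),
        _atom(2, "CA", "C", resname, 1, "A", [1.46, 0.0, 0.0], {"backbone"}),
        _atom(3, "C", "C", resname, 1, "A", [2.0, 1.4, 0.0], {"backbone"}),
        _atom(4, "O", "O", resname, 1, "A", [1.4, 2.4, 0.0], {"backbone"}),
        _atom(5, "CB", "C", resname, 1, "A", [2.0, -1.2, 0.6], {"sidechain"}),
        _atom(6, "CG", "C", resname, 1, "A", [3.5, -1.3, 0.6], {"sidechain"}),
        _atom(7, "CD1", "C", resname, 1, "A", [4.1, -2.6, 1.1], {"sidechain"}),
        _atom(8, "CD2", "C", resname, 1, "A", [4.2, -0.1, 1.2], {"sidechain"}),
    ]
    tip = np.array([4.1, -2.6, 1.1])
    away = tip - np.array([3.0, -0.8, 0.7])  # outward from the sidechain bulk
    away /= np.linalg.norm(away)
    serial = 100
    for k, d in enumerate(water_distances):
        wobble = 0.15 * np.array([np.cos(2.1 * k), np.sin(2.1 * k), 0.0])
        direction = away + wobble
        direction /= np.linalg.norm(direction)
        pos = tip + d * direction
        atoms.append(_atom(serial, "O", "O", "HOH", 1000 + k, "W", pos,
                           {"water_oxygen", "polar"}))
        serial += 1
    return Structure(atoms, [], title="solvated sidechain fixture")
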