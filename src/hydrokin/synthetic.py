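"""Synthetic trajectories, state series, dwell times and height samples.

These generators emulate the statistical structure the analysis assumes, with
known ground truth: a rigid two-domain protein undergoing hinge motion about
a fixed axis, explicit 3-site waters whose pocket occupancy follows a
continuous-time Markov process with exponential dwell times, bulk waters at a
configured number density, and 1-D height samples from Gaussian mixtures.

All randomness is reproducible: every generator derives an independent RNG
stream from its single seed via fixed offsets, so identical configuration and
seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import MolecularSystem, Trajectory, classify_record
from .kinetics import StateSeries

__all__ = [
    "KineticScheme",
    "HingeConfig",
    "WaterSceneConfig",
    "SphereRegion",
    "BoxRegion",
    "gen_dwell_times",
    "simulate_markov_events",
    "gen_state_series",
    "build_two_domain_template",
    "gen_hinge_angles",
    "gen_hinge_trajectory",
    "gen_water_scene",
    "gen_height_samples",
]

# Fixed per-generator RNG stream offsets (spawned as default_rng([seed, off])).
_STREAM_DWELL = 11
_STREAM_MARKOV = 13
_STREAM_HINGE = 17
_STREAM_WATER = 19
_STREAM_HEIGHT = 23


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Kinetic scheme and Markov state dynamics

@dataclass(frozen=True)
class KineticScheme:
    """States with pairwise mean dwell times.

    ``tau[(A, B)]`` is the mean residence time (ps) in A before an A→B
    transition; the keys define the allowed-transition adjacency. With
    several successors, competing exponential clocks run in parallel, so the
    total escape rate from A is Σ_B 1/τ_AB.
    """

    states: tuple[str, ...]
    tau: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), t in self.tau.items():
            if a not in self.states or b not in self.states:
                raise ValueError(f"transition ({a}, {b}) uses undeclared state")
            if a == b:
                raise ValueError(f"self-transition ({a}, {a}) not allowed")
            if not t > 0:
                raise ValueError(f"tau[{a},{b}] must be > 0, got {t}")

    def successors(self, state: str) -> list[str]:
        return [b for (a, b) in self.tau if a == state]

    @staticmethod
    def two_state(a: str, b: str, tau_ab: float, tau_ba: float) -> "KineticScheme":
        return KineticScheme(states=(a, b), tau={(a, b): tau_ab, (b, a): tau_ba})


def gen_dwell_times(tau: float, n: int, t_min: float = 0.0, seed: int = 0) -> np.ndarray:
    """n samples of a shifted exponential: t_min + Exp(tau); mean t_min + tau."""
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if not n >= 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if t_min < 0:
        raise ValueError(f"t_min must be >= 0, got {t_min}")
    rng = _rng(seed, _STREAM_DWELL)
    return t_min + rng.exponential(tau, size=int(n))


def simulate_markov_events(
    scheme: KineticScheme,
    duration: float,
    seed: int = 0,
    initial: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Event-driven continuous-time Markov path.

    Returns (event_times, states): the path is in ``states[i]`` during
    [event_times[i], event_times[i+1]); the final event time exceeds
    ``duration``.
    """
    initial = scheme.states[0] if initial is None else initial
    if initial not in scheme.states:
        raise ValueError(f"initial state {initial!r} not in scheme")
    rng = _rng(seed, _STREAM_MARKOV)
    t = 0.0
    state = initial
    event_times = [0.0]
    states = [state]
    while t <= duration:
        succ = scheme.successors(state)
        if not succ:
            if len(scheme.states) > 1:
                raise ValueError(f"state {state!r} has no outgoing transitions")
            break  # single-state scheme: constant forever
        # Competing exponential clocks; smallest wins.
        draws = [rng.exponential(scheme.tau[(state, b)]) for b in succ]
        k = int(np.argmin(draws))
        t += draws[k]
        state = succ[k]
        event_times.append(t)
        states.append(state)
    return np.asarray(event_times), states


def gen_state_series(
    scheme: KineticScheme,
    duration: float,
    dt: float = 1.0,
    seed: int = 0,
    initial: str | None = None,
) -> StateSeries:
    """Markov path sampled on a uniform dt grid over [0, duration]."""
    if duration < dt:
        raise ValueError("duration must be >= dt")
    event_times, states = simulate_markov_events(scheme, duration, seed, initial)
    grid = np.arange(0.0, duration + 0.5 * dt, dt)
    # state active at time t: last event at or before t (right-continuous)
    idx = np.searchsorted(event_times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(states) - 1)
    labels = np.asarray(states, dtype="U32")[idx]
    return StateSeries(times=grid, labels=labels)


# ---------------------------------------------------------------------------
# Two-domain template protein

_HELIX_RADIUS = 2.3  # Å, Cα helix radius
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue


def _helix_atoms(resid_start: int, resid_stop: int, base: np.ndarray, resname="ALA"):
    """Ideal α-helix with N/CA/C/O/CB per residue, axis along +z from base."""
    atoms = []
    for i, resid in enumerate(range(resid_start, resid_stop + 1)):
        phi = np.deg2rad(_HELIX_TWIST * i)
        z = i * _HELIX_RISE

        def on_helix(t):
            a = np.deg2rad(_HELIX_TWIST) * t
            return base + np.array(
                [_HELIX_RADIUS * np.cos(a), _HELIX_RADIUS * np.sin(a), t * _HELIX_RISE]
            )

        ca = on_helix(i)
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        atoms.append(("N", "N", resid, resname, on_helix(i - 0.35)))
        atoms.append(("CA", "C", resid, resname, ca))
        atoms.append(("C", "C", resid, resname, on_helix(i + 0.35)))
        atoms.append(("O", "O", resid, resname, on_helix(i + 0.35) + 1.23 * radial))
        atoms.append(("CB", "C", resid, resname, ca + 1.53 * radial))
    return atoms


def build_two_domain_template() -> MolecularSystem:
    """Programmatically built two-domain dummy protein (synthetic stand-in).

    Two rigid groups of ideal α-helices around a hinge axis along z through
    the origin. Domain "C" (static) carries the pocket lower jaw — TRP 89
    (Cδ1) and TRP 92 (Cγ) — the crevice residue ALA 190, and the
    superposition helix spanning residues 87–96. Domain "N" (rotating)
    carries the upper jaw PHE 340 (Hδ1/Hε1), GLU 354 (Oε1), and a tip helix
    (residues 277–287) about 45 Å from the axis, so a 20° hinge rotation
    moves the tip by ≈16 Å. The jaw geometry is laid out so the hinge angle
    maps monotonically onto the jaw separation: ≈4.5 Å at 0° (closed) to
    ≈7.9 Å at 20° (open).
    """
    atoms: list[tuple] = []
    domains: list[str] = []

    def add(atom_list, domain):
        atoms.extend(atom_list)
        domains.extend([domain] * len(atom_list))

    # C-domain: pocket-jaw helix (incl. superposition anchor 87-96), crevice helix
    add(_helix_atoms(80, 100, np.array([8.0, 0.0, -15.0])), "C")
    add(_helix_atoms(185, 196, np.array([4.0, 8.0, -8.0])), "C")
    # N-domain: cleft helix with the upper jaw and crevice partner, tip helix
    add(_helix_atoms(335, 360, np.array([10.0, 6.0, -8.0])), "N")
    add(_helix_atoms(277, 287, np.array([45.0, 0.0, -7.0])), "N")

    extra = [
        # lower jaw (domain C)
        ("CD1", "C", 89, "TRP", np.array([10.0, -1.0, 0.0]), "C"),
        ("CG", "C", 92, "TRP", np.array([10.0, 1.0, 0.0]), "C"),
        # upper jaw (domain N): ring hydrogens of PHE 340
        ("HD1", "H", 340, "PHE", np.array([10.0, 4.5, 0.0]), "N"),
        ("HE1", "H", 340, "PHE", np.array([10.5, 5.3, 1.0]), "N"),
        # hydrophilic crevice partner (domain N); placed so the crevice
        # stretch runs ~9.5 Å (closed) to ~11.7 Å (open 20 deg)
        ("OE1", "O", 354, "GLU", np.array([-5.516, 4.310, 1.5]), "N"),
    ]
    special_resnames = {89: "TRP", 92: "TRP", 340: "PHE", 354: "GLU", 190: "ALA"}

    names, elements, resids, resnames, coords = [], [], [], [], []
    for name, element, resid, resname, xyz in atoms:
        names.append(name)
        elements.append(element)
        resids.append(resid)
        resnames.append(special_resnames.get(resid, resname))
        coords.append(xyz)
    for name, element, resid, resname, xyz, domain in extra:
        names.append(name)
        elements.append(element)
        resids.append(resid)
        resnames.append(resname)
        coords.append(xyz)
        domains.append(domain)

    n = len(names)
    return MolecularSystem(
        names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames),
        chains=np.array(["A"] * n),
        record=np.array(["protein"] * n),
        coords=np.array(coords, dtype=float),
        domains=np.array(domains),
    )


# ---------------------------------------------------------------------------
# Hinge trajectory

@dataclass
class HingeConfig:
    """Rigid two-domain hinge motion about a fixed axis.

    ``angle_process`` is ``two_state`` (telegraph switching between
    angle_open and angle_closed with exponential dwells) or ``ou_process``
    (Ornstein-Uhlenbeck fluctuation between the two angles, relaxation time
    ``ou_tau``).
    """

    n_frames: int = 200
    dt: float = 1.0  # ps
    hinge_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    hinge_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    angle_process: str = "two_state"
    angle_open: float = 20.0  # degrees
    angle_closed: float = 0.0
    dwell_tau_open: float = 57.0  # ps
    dwell_tau_closed: float = 81.0
    ou_tau: float = 50.0  # ps, OU relaxation time
    atom_noise_sigma: float = 0.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        axis = np.asarray(self.hinge_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"hinge_axis must be a unit vector, |axis| = {norm:.6g}")
        if self.dwell_tau_open <= 0 or self.dwell_tau_closed <= 0:
            raise ValueError("dwell taus must be > 0")
        if self.angle_process not in ("two_state", "ou_process"):
            raise ValueError(f"unknown angle_process {self.angle_process!r}")


def gen_hinge_angles(cfg: HingeConfig) -> tuple[np.ndarray, np.ndarray, StateSeries | None]:
    """Ground-truth hinge angle per frame: (times, angles_deg, state_series).

    state_series is None for the OU process. Deterministic in (cfg, seed).
    """
    times = np.arange(cfg.n_frames) * cfg.dt
    if cfg.angle_process == "two_state":
        scheme = KineticScheme.two_state(
            "open", "closed", cfg.dwell_tau_open, cfg.dwell_tau_closed
        )
        duration = (cfg.n_frames - 1) * cfg.dt
        series = gen_state_series(scheme, max(duration, cfg.dt), cfg.dt, seed=cfg.seed)
        labels = series.labels[: cfg.n_frames]
        angles = np.where(labels == "open", cfg.angle_open, cfg.angle_closed)
        return times, angles.astype(float), StateSeries(times, labels)
    # Ornstein-Uhlenbeck about the midpoint angle
    rng = _rng(cfg.seed, _STREAM_HINGE + 1)
    mu = 0.5 * (cfg.angle_open + cfg.angle_closed)
    sigma = 0.5 * abs(cfg.angle_open - cfg.angle_closed)
    decay = np.exp(-cfg.dt / cfg.ou_tau)
    kick = sigma * np.sqrt(1.0 - decay**2)
    angles = np.empty(cfg.n_frames)
    angles[0] = mu + sigma * rng.standard_normal()
    for k in range(1, cfg.n_frames):
        angles[k] = mu + (angles[k - 1] - mu) * decay + kick * rng.standard_normal()
    return times, angles, None


def gen_hinge_trajectory(
    cfg: HingeConfig,
    template: MolecularSystem,
    angles: np.ndarray | None = None,
) -> Trajectory:
    """Rigid hinge trajectory: domain C fixed, domain N rotated per frame.

    The rotation about (hinge_point, hinge_axis) by the frame's process angle
    is applied to all domain-"N" atoms; isotropic Gaussian noise of width
    atom_noise_sigma is then added to every atom. An explicit per-frame
    ``angles`` array (degrees) overrides the configured angle process, which
    lets a joint conformation/hydration state series drive the hinge.
    """
    if template.domains is None:
        raise ValueError("template must carry rigid-domain labels")
    moving = np.asarray(template.domains) == "N"
    if not moving.any() or not (~moving).any():
        raise ValueError("template must contain both domain 'N' and domain 'C' atoms")
    if angles is None:
        times, angles, _ = gen_hinge_angles(cfg)
    else:
        angles = np.asarray(angles, dtype=float)
        if len(angles) != cfg.n_frames:
            raise ValueError("angles must give one value per frame")
        times = np.arange(cfg.n_frames) * cfg.dt
    axis = np.asarray(cfg.hinge_axis, dtype=float)
    point = np.asarray(cfg.hinge_point, dtype=float)
    frames = np.empty((cfg.n_frames, template.n_atoms, 3))
    for k, angle in enumerate(angles):
        coords = template.coords.copy()
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        coords[moving] = rot.apply(coords[moving] - point) + point
        frames[k] = coords
    if cfg.atom_noise_sigma > 0:
        rng = _rng(cfg.seed, _STREAM_HINGE)
        frames += cfg.atom_noise_sigma * rng.standard_normal(frames.shape)
    return Trajectory(topology=template, frames=frames, times=times)


# ---------------------------------------------------------------------------
# Water scene

@dataclass(frozen=True)
class SphereRegion:
    center: tuple[float, float, float]
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.asarray(points) - np.asarray(self.center), axis=-1)
        return d <= self.radius

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        # rejection from the bounding cube
        out = np.empty((0, 3))
        while len(out) < n:
            cand = rng.uniform(-self.radius, self.radius, size=(4 * n + 8, 3))
            cand = cand[np.linalg.norm(cand, axis=1) <= self.radius]
            out = np.vstack([out, cand + np.asarray(self.center)])
        return out[:n]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c, r = np.asarray(self.center), self.radius
        return c - r, c + r


@dataclass(frozen=True)
class BoxRegion:
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=-1)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, 3))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lo, dtype=float), np.asarray(self.hi, dtype=float)


#: TIP3P-like rigid water geometry: O-H 0.9572 Å, H-O-H 104.52 deg.
_WATER_OH = 0.9572
_WATER_HOH = np.deg2rad(104.52)
_WATER_SITES = np.array(
    [
        [0.0, 0.0, 0.0],
        [_WATER_OH * np.sin(_WATER_HOH / 2), 0.0, _WATER_OH * np.cos(_WATER_HOH / 2)],
        [-_WATER_OH * np.sin(_WATER_HOH / 2), 0.0, _WATER_OH * np.cos(_WATER_HOH / 2)],
    ]
)


@dataclass
class WaterSceneConfig:
    """Explicit 3-site waters: uniform bulk plus Markov-switched pocket waters.

    The pocket region holds exactly ``n_pocket_waters_per_state[state]``
    water oxygens in every frame whose state demands them; bulk waters are
    resampled uniformly (outside the pocket region) each frame, which gives
    the correct stationary voxel density without simulating diffusion. The
    total water count is constant across frames (bulk + max pocket count);
    pocket waters not needed in a frame park in the bulk.
    """

    box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    box_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bulk_density: float = 0.0334  # waters per Å³ (≈ liquid water)
    pocket_region: SphereRegion | BoxRegion = SphereRegion((15.0, 15.0, 15.0), 3.0)
    exclusion_region: SphereRegion | BoxRegion | None = None  # bulk keep-out
    n_pocket_waters_per_state: dict[str, int] = field(default_factory=lambda: {"wet": 2, "dry": 0})
    scheme: KineticScheme = field(
        default_factory=lambda: KineticScheme.two_state("wet", "dry", 57.0, 81.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bulk_density < 0:
            raise ValueError("bulk_density must be >= 0")
        if any(v < 0 for v in self.n_pocket_waters_per_state.values()):
            raise ValueError("pocket water counts must be >= 0")
        origin = np.asarray(self.box_origin, dtype=float)
        lo, hi = self.pocket_region.bounds()
        if np.any(lo < origin) or np.any(hi > origin + np.asarray(self.box, dtype=float)):
            raise ValueError("pocket region does not fit inside the box")
        for s in self.scheme.states:
            if s not in self.n_pocket_waters_per_state:
                raise ValueError(f"no pocket water count for state {s!r}")


def _water_topology_arrays(n_waters: int, resid_start: int):
    names = np.tile(["O", "H1", "H2"], n_waters)
    elements = np.tile(["O", "H", "H"], n_waters)
    resids = np.repeat(np.arange(resid_start, resid_start + n_waters), 3)
    resnames = np.repeat(["HOH"], 3 * n_waters)
    return names, elements, resids, resnames


def gen_water_scene(
    cfg: WaterSceneConfig,
    protein: Trajectory | None = None,
    states: StateSeries | None = None,
) -> tuple[Trajectory, StateSeries]:
    """Merged protein + water trajectory realizing the pocket kinetic scheme.

    Returns the trajectory and the ground-truth pocket state series (pass an
    explicit ``states`` series to slave the pocket occupancy to an external
    process, e.g. a joint conformation/hydration scheme). With
    ``protein=None`` a pure solvent scene on a 50-frame 1-ps grid is
    produced. Bulk waters are kept out of ``exclusion_region`` (default: the
    pocket region) but may overlap protein atoms (no excluded volume) — the
    density analyses never depend on that.
    """
    rng = _rng(cfg.seed, _STREAM_WATER)
    box = np.asarray(cfg.box, dtype=float)
    origin = np.asarray(cfg.box_origin, dtype=float)
    keep_out = cfg.exclusion_region or cfg.pocket_region
    if protein is not None:
        times = protein.times
    else:
        times = np.arange(50, dtype=float)
    n_frames = len(times)
    dt = float(times[1] - times[0]) if n_frames > 1 else 1.0

    if states is None:
        duration = max(float(times[-1] - times[0]), dt)
        states = gen_state_series(cfg.scheme, duration, dt, seed=cfg.seed)
    elif len(states) < n_frames:
        raise ValueError("state series shorter than the protein trajectory")
    labels = states.labels[:n_frames]
    counts = np.array([cfg.n_pocket_waters_per_state[str(s)] for s in labels])
    max_pocket = int(max(cfg.n_pocket_waters_per_state.values(), default=0))

    n_bulk = int(round(cfg.bulk_density * np.prod(box)))
    n_waters = n_bulk + max_pocket

    def sample_bulk(n: int) -> np.ndarray:
        # uniform in box, rejected from the keep-out region
        out = np.empty((0, 3))
        while len(out) < n:
            cand = rng.uniform(origin, origin + box, size=(n + 16, 3))
            cand = cand[~keep_out.contains(cand)]
            out = np.vstack([out, cand])
        return out[:n]

    water_frames = np.empty((n_frames, 3 * n_waters, 3))
    for k in range(n_frames):
        n_pocket = int(counts[k])
        oxygens = np.empty((n_waters, 3))
        if n_pocket:
            oxygens[:n_pocket] = cfg.pocket_region.sample(rng, n_pocket)
        oxygens[n_pocket:] = sample_bulk(n_waters - n_pocket)
        # one random rigid orientation per water, applied to its 3 sites
        matrices = Rotation.random(n_waters, rng=rng).as_matrix()
        sites = np.einsum("wij,sj->wsi", matrices, _WATER_SITES).reshape(-1, 3)
        water_frames[k] = sites + np.repeat(oxygens, 3, axis=0)

    w_names, w_elements, w_resids, w_resnames = _water_topology_arrays(
        n_waters, resid_start=10000
    )
    if protein is not None:
        top = protein.topology
        topology = MolecularSystem(
            names=np.concatenate([top.names, w_names]),
            elements=np.concatenate([top.elements, w_elements]),
            resids=np.concatenate([top.resids, w_resids]),
            resnames=np.concatenate([top.resnames, w_resnames]),
            chains=np.concatenate([top.chains, np.repeat("W", 3 * n_waters)]),
            record=np.concatenate([top.record, np.repeat("water", 3 * n_waters)]),
            coords=np.vstack([protein.frames[0], water_frames[0]]),
            domains=None
            if top.domains is None
            else np.concatenate([top.domains, np.repeat("", 3 * n_waters)]),
        )
        frames = np.concatenate([protein.frames, water_frames], axis=1)
    else:
        topology = MolecularSystem(
            names=w_names,
            elements=w_elements,
            resids=w_resids,
            resnames=w_resnames,
            chains=np.repeat("W", 3 * n_waters),
            record=np.repeat("water", 3 * n_waters),
            coords=water_frames[0],
        )
        frames = water_frames
    traj = Trajectory(topology=topology, frames=frames, times=times)
    return traj, StateSeries(times=times, labels=labels)


# ---------------------------------------------------------------------------
# Height samples

def gen_height_samples(
    means, weights, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """n draws from a Gaussian mixture with common sigma (Å)."""
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if len(means) != len(weights):
        raise ValueError("means and weights must have equal length")
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    if n == 0:
        return np.empty(0)
    rng = _rng(seed, _STREAM_HEIGHT)
    component = rng.choice(len(means), size=int(n), p=weights)
    return means[component] + sigma * rng.standard_normal(int(n))
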