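"""Coarse-grained beads-on-a-string polymer model with spherical-well pairs.

Each bead represents a 20-kb chromatin segment. Consecutive beads are tied
by stiff harmonic bonds of rest length *a* (the unit of length throughout);
any two beads interact through a spherical-well pair potential:

    U(d) = +inf          d < 0.6 a    (hard core)
         = eps_ij        0.6 a <= d < 1.5 a
         = 0             d >= 1.5 a

with eps_ij <= 0 the well depth in units of kT (kT = 1). Conformations are
drawn from the Boltzmann distribution of the total energy by a Metropolis
Monte-Carlo sampler mixing single-bead Gaussian displacements with
crankshaft rotations of internal segments. Contact maps count bead pairs
closer than the interaction radius (strictly < 1.5 a).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "SamplingSchedule",
    "Ensemble",
    "pair_potential",
    "total_energy",
    "mc_sample",
    "ensemble_contact_map",
    "read_xyz",
    "write_xyz",
]


@dataclass(frozen=True)
class ModelParams:
    """Geometry and energetics of the chain; lengths in units of the bond length a."""

    n_beads: int
    bond_length: float = 1.0
    interaction_radius: float = 1.5
    hardcore_radius: float = 0.6
    bond_stiffness: float = 100.0  # kT / a^2

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("a chain needs at least 2 beads")
        if not (self.hardcore_radius < self.bond_length < self.interaction_radius):
            raise ValueError("require hardcore_radius < bond_length < interaction_radius")


@dataclass(frozen=True)
class SamplingSchedule:
    """How many Metropolis sweeps to burn and how far apart to snapshot.

    Sweeps are expressed per bead (one sweep = n_beads attempted moves);
    defaults are generous enough that the radius-of-gyration autocorrelation
    at one thinning interval is well below 0.2 for chains up to ~200 beads.
    """

    burnin_sweeps_per_bead: int = 200
    thin_sweeps_per_bead: int = 20

    def __post_init__(self) -> None:
        if self.burnin_sweeps_per_bead < 0 or self.thin_sweeps_per_bead < 1:
            raise ValueError("invalid schedule")


@dataclass
class Ensemble:
    """Ordered conformations (n_structures, n_beads, 3) plus provenance."""

    coords: np.ndarray
    params: ModelParams
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_structures, n_beads, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one conformation")
        if self.coords.shape[1] != self.params.n_beads:
            raise ValueError("bead count mismatch between coords and params")

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]


def _check_energy_matrix(eps: np.ndarray, n_beads: int) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (n_beads, n_beads):
        raise ValueError(f"energy matrix must be {n_beads}x{n_beads}")
    if not np.allclose(eps, eps.T):
        raise ValueError("energy matrix must be symmetric")
    if np.any(eps > 1e-12):
        raise ValueError("well depths must be <= 0 (attractive or neutral)")
    return eps


def pair_potential(d: float, eps_ij: float, params: ModelParams) -> float:
    """Spherical-well energy of a nonbonded pair at distance d (units of a)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d < params.hardcore_radius:
        return np.inf
    if d < params.interaction_radius:
        return eps_ij
    return 0.0


def total_energy(conf: np.ndarray, eps: np.ndarray, params: ModelParams) -> float:
    """Total energy: harmonic bonds plus spherical wells over pairs |i-j| >= 2.

    Any hard-core violation (including between bonded neighbours) returns
    +inf, never a finite value.
    """
    conf = np.asarray(conf, dtype=float)
    n = params.n_beads
    eps = _check_energy_matrix(eps, n)
    diff = conf[:, None, :] - conf[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu, ju = np.triu_indices(n, k=1)
    if np.any(dist[iu, ju] < params.hardcore_radius):
        return np.inf
    bond_d = dist[np.arange(n - 1), np.arange(1, n)]
    energy = params.bond_stiffness * ((bond_d - params.bond_length) ** 2).sum()
    far = np.abs(iu - ju) >= 2
    within = dist[iu, ju] < params.interaction_radius
    energy += eps[iu[far & within], ju[far & within]].sum()
    return float(energy)


# ---------------------------------------------------------------------------
# Metropolis kernel (numba)

@njit(cache=True)
def _bead_energy(coords, eps, bead, n, k_b, a, rc_hard, rc_well):
    """Energy terms involving one bead: its bonds and its nonbonded pairs."""
    e = 0.0
    x, y, z = coords[bead, 0], coords[bead, 1], coords[bead, 2]
    for j in range(n):
        if j == bead:
            continue
        dx = x - coords[j, 0]
        dy = y - coords[j, 1]
        dz = z - coords[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < rc_hard:
            return np.inf
        sep = bead - j
        if sep == 1 or sep == -1:
            e += k_b * (d - a) * (d - a)
        elif d < rc_well:
            e += eps[bead, j]
    return e


@njit(cache=True)
def _segment_cross_energy(coords, eps, lo, hi, n, k_b, a, rc_hard, rc_well):
    """Interaction of beads in [lo, hi] with beads outside, plus boundary bonds."""
    e = 0.0
    for i in range(lo, hi + 1):
        xi, yi, zi = coords[i, 0], coords[i, 1], coords[i, 2]
        for j in range(n):
            if lo <= j <= hi:
                continue
            dx = xi - coords[j, 0]
            dy = yi - coords[j, 1]
            dz = zi - coords[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < rc_hard:
                return np.inf
            sep = i - j
            if sep == 1 or sep == -1:
                e += k_b * (d - a) * (d - a)
            elif d < rc_well:
                e += eps[i, j]
    return e


@njit(cache=True)
def _rotate_segment(coords, lo, hi, axis_i, axis_j, angle, out):
    """Rotate beads lo..hi about the line through beads axis_i and axis_j."""
    px, py, pz = coords[axis_i, 0], coords[axis_i, 1], coords[axis_i, 2]
    ux = coords[axis_j, 0] - px
    uy = coords[axis_j, 1] - py
    uz = coords[axis_j, 2] - pz
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    if norm < 1e-12:
        return False
    ux /= norm
    uy /= norm
    uz /= norm
    c = np.cos(angle)
    s = np.sin(angle)
    for k in range(lo, hi + 1):
        vx = coords[k, 0] - px
        vy = coords[k, 1] - py
        vz = coords[k, 2] - pz
        dot = vx * ux + vy * uy + vz * uz
        # Rodrigues rotation
        rx = vx * c + (uy * vz - uz * vy) * s + ux * dot * (1.0 - c)
        ry = vy * c + (uz * vx - ux * vz) * s + uy * dot * (1.0 - c)
        rz = vz * c + (ux * vy - uy * vx) * s + uz * dot * (1.0 - c)
        out[k - lo, 0] = px + rx
        out[k - lo, 1] = py + ry
        out[k - lo, 2] = pz + rz
    return True


@njit(cache=True)
def _mc_run(eps, n, k_b, a, rc_hard, rc_well, n_snapshots, burnin_sweeps,
            thin_sweeps, seed, sigma0):
    """Metropolis chain; returns (snapshots, acceptance fraction, final sigma)."""
    np.random.seed(seed)
    coords = np.zeros((n, 3))
    # initial self-avoiding-ish zig-zag along x at bond length a
    for i in range(n):
        coords[i, 0] = a * i * 0.92
        coords[i, 1] = 0.3 * a * (i % 2)
        coords[i, 2] = 0.0
    snapshots = np.zeros((n_snapshots, n, 3))
    sigma = sigma0
    accepted = 0
    attempted = 0
    tune_acc = 0
    tune_att = 0
    total_sweeps = burnin_sweeps + thin_sweeps * n_snapshots
    taken = 0
    seg_buf = np.zeros((n, 3))
    for sweep in range(total_sweeps):
        for _ in range(n):
            if np.random.random() < 0.5 or n < 4:
                # single-bead Gaussian displacement
                bead = np.random.randint(0, n)
                e_old = _bead_energy(coords, eps, bead, n, k_b, a, rc_hard, rc_well)
                ox, oy, oz = coords[bead, 0], coords[bead, 1], coords[bead, 2]
                coords[bead, 0] = ox + sigma * np.random.normal()
                coords[bead, 1] = oy + sigma * np.random.normal()
                coords[bead, 2] = oz + sigma * np.random.normal()
                e_new = _bead_energy(coords, eps, bead, n, k_b, a, rc_hard, rc_well)
                de = e_new - e_old
                attempted += 1
                tune_att += 1
                if de <= 0.0 or (np.isfinite(de) and np.random.random() < np.exp(-de)):
                    accepted += 1
                    tune_acc += 1
                else:
                    coords[bead, 0] = ox
                    coords[bead, 1] = oy
                    coords[bead, 2] = oz
            else:
                # crankshaft: rotate an internal segment about the axis through
                # its flanking beads; distances to the flanks are preserved, so
                # only cross-segment nonbonded terms change
                i0 = np.random.randint(0, n - 2)
                j0 = i0 + 2 + np.random.randint(0, min(n - i0 - 2, n // 2))
                if j0 > n - 1:
                    j0 = n - 1
                lo, hi = i0 + 1, j0 - 1
                angle = (np.random.random() * 2.0 - 1.0) * np.pi
                ok = _rotate_segment(coords, lo, hi, i0, j0, angle, seg_buf)
                attempted += 1
                if not ok:
                    continue
                e_old = _segment_cross_energy(coords, eps, lo, hi, n, k_b, a,
                                              rc_hard, rc_well)
                old = coords[lo:hi + 1].copy()
                coords[lo:hi + 1] = seg_buf[:hi - lo + 1]
                e_new = _segment_cross_energy(coords, eps, lo, hi, n, k_b, a,
                                              rc_hard, rc_well)
                de = e_new - e_old
                if de <= 0.0 or (np.isfinite(de) and np.random.random() < np.exp(-de)):
                    accepted += 1
                else:
                    coords[lo:hi + 1] = old
        # tune displacement width toward ~40% acceptance during burn-in
        if sweep < burnin_sweeps and tune_att >= 50 * n:
            rate = tune_acc / tune_att
            if rate > 0.5:
                sigma *= 1.2
            elif rate < 0.3:
                sigma *= 0.85
            if sigma < 0.01:
                sigma = 0.01
            if sigma > 2.0:
                sigma = 2.0
            tune_acc = 0
            tune_att = 0
        if sweep >= burnin_sweeps and (sweep - burnin_sweeps + 1) % thin_sweeps == 0:
            if taken < n_snapshots:
                snapshots[taken] = coords
                taken += 1
    return snapshots, accepted / max(attempted, 1), sigma


def mc_sample(
    energies: np.ndarray,
    params: ModelParams,
    n_structures: int,
    seed: int,
    schedule: SamplingSchedule | None = None,
    initial_sigma: float = 0.35,
) -> Ensemble:
    """Draw an ensemble from the Boltzmann distribution at kT = 1.

    One Metropolis chain per call: burn-in, then evenly thinned snapshots.
    Identical (energies, params, seed, schedule) give bit-identical output.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    eps = _check_energy_matrix(energies, params.n_beads)
    schedule = schedule or SamplingSchedule()
    burnin = schedule.burnin_sweeps_per_bead * params.n_beads
    thin = schedule.thin_sweeps_per_bead * params.n_beads
    coords, acc, sigma = _mc_run(
        np.ascontiguousarray(eps),
        params.n_beads,
        params.bond_stiffness,
        params.bond_length,
        params.hardcore_radius,
        params.interaction_radius,
        n_structures,
        burnin,
        thin,
        int(seed) & 0x7FFFFFFF,
        initial_sigma,
    )
    if not 0.05 <= acc <= 0.95:
        logger.warning("Metropolis acceptance rate %.3f outside [0.05, 0.95]", acc)
    return Ensemble(
        coords,
        params,
        seed=int(seed),
        provenance={
            "acceptance_rate": float(acc),
            "displacement_sigma": float(sigma),
            "burnin_sweeps": int(burnin),
            "thin_sweeps": int(thin),
        },
    )


# ---------------------------------------------------------------------------
# Contact maps

def pairwise_distances(conf: np.ndarray) -> np.ndarray:
    diff = conf[:, None, :] - conf[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def ensemble_contact_map(ensemble: Ensemble, contact_radius: float = 1.5) -> np.ndarray:
    """Fraction of conformations with bead-bead distance strictly < contact_radius.

    Contact counting includes bonded neighbours; the diagonal is 1 by
    convention (a bead is always "in contact" with itself).
    """
    n = ensemble.n_beads
    counts = np.zeros((n, n), dtype=float)
    for conf in ensemble.coords:
        counts += pairwise_distances(conf) < contact_radius
    probs = counts / ensemble.n_structures
    np.fill_diagonal(probs, 1.0)
    return probs


# ---------------------------------------------------------------------------
# XYZ-style ensemble I/O

def write_xyz(ensemble: Ensemble, path) -> None:
    """Multi-frame text format: N, comment line, then N lines of "x y z"."""
    with open(path, "w") as fh:
        for k, conf in enumerate(ensemble.coords):
            fh.write(f"{ensemble.n_beads}\n")
            fh.write(f"frame {k} seed {ensemble.seed}\n")
            for x, y, z in conf:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path, params: ModelParams | None = None) -> Ensemble:
    frames = []
    seed = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().split()
            if "seed" in comment:
                tok = comment[comment.index("seed") + 1]
                seed = None if tok == "None" else int(tok)
            conf = np.empty((n, 3))
            for i in range(n):
                conf[i] = [float(t) for t in fh.readline().split()]
            frames.append(conf)
    coords = np.asarray(frames)
    if params is None:
        params = ModelParams(n_beads=coords.shape[1])
    return Ensemble(coords, params, seed=seed)
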