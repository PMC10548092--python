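"""Inverse optimization of spherical-well depths against a target contact map.

Given a balanced experimental (or synthetic) contact map, find a symmetric
matrix of well depths eps_ij <= 0 such that the simulated ensemble's contact
probabilities reproduce the target. The scheme is an iterative-Boltzmann-style
fixed point: at each iteration an ensemble is simulated under the current
energies, contact probabilities p_sim are estimated, and every eligible pair
(unmasked, |i - j| >= 2) is updated by a damped log-ratio step

    eps_ij <- clip(eps_ij + eta * log((p_sim_ij + delta) / (p_target_ij + delta)),
                   [eps_min, 0])

which deepens wells where the simulation under-contacts the target and
relaxes them where it over-contacts. When p_sim == p_target the update
vanishes, so a perfectly reproduced map is a fixed point.

The target is first rescaled onto the contact-probability scale by matching
its mean at genomic separation 2 to the homopolymer (all-eps-zero) reference
simulation: the overall scale of a balanced Hi-C map is arbitrary, and the
separation-2 contacts of a bonded chain are nearly model-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .polymer import Ensemble, ModelParams, SamplingSchedule, ensemble_contact_map, mc_sample

__all__ = [
    "FitConfig",
    "FitTrace",
    "TargetProbabilityMatrix",
    "prepare_target",
    "fit_energies",
    "goodness_of_fit",
]


@dataclass(frozen=True)
class FitConfig:
    n_iterations: int = 40
    ensemble_size_per_iter: int = 300
    learning_rate: float = 0.3       # kT per log-unit
    pseudocount: float | None = None  # default 1 / (2 * ensemble_size_per_iter)
    eps_min: float = -5.0
    convergence_r: float = 0.98
    seed: int = 0
    schedule: SamplingSchedule = field(
        default_factory=lambda: SamplingSchedule(burnin_sweeps_per_bead=100,
                                                 thin_sweeps_per_bead=5)
    )

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.eps_min >= 0:
            raise ValueError("eps_min must be negative")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def delta(self) -> float:
        return (
            self.pseudocount
            if self.pseudocount is not None
            else 1.0 / (2.0 * self.ensemble_size_per_iter)
        )


@dataclass
class FitTrace:
    """Per-iteration diagnostics of the inverse fit."""

    pearson_r: list[float] = field(default_factory=list)
    mean_abs_update: list[float] = field(default_factory=list)
    acceptance_rate: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pearson_r)


@dataclass
class TargetProbabilityMatrix:
    """Contact-probability target with an eligibility mask over bins."""

    probs: np.ndarray
    eligible: np.ndarray  # per-bin validity; pairs need both bins eligible
    scale_factor: float = 1.0


def _eligible_pairs(eligible: np.ndarray, n: int, min_sep: int = 2):
    iu, ju = np.triu_indices(n, k=min_sep)
    keep = eligible[iu] & eligible[ju]
    return iu[keep], ju[keep]


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] & 0x7FFFFFFF)


def homopolymer_reference_map(
    params: ModelParams, seed: int, n_structures: int = 400,
    schedule: SamplingSchedule | None = None,
) -> np.ndarray:
    """Contact map of the null (eps = 0) chain, used as the probability anchor."""
    eps0 = np.zeros((params.n_beads, params.n_beads))
    schedule = schedule or SamplingSchedule(burnin_sweeps_per_bead=100,
                                            thin_sweeps_per_bead=5)
    ens = mc_sample(eps0, params, n_structures, seed=seed, schedule=schedule)
    return ensemble_contact_map(ens, params.interaction_radius)


def prepare_target(matrix, params: ModelParams, seed: int,
                   reference_map: np.ndarray | None = None) -> TargetProbabilityMatrix:
    """Rescale a balanced contact matrix onto the contact-probability scale.

    ``matrix`` is a ContactMatrix (balanced) or a bare (values, mask) pair.
    The global scale is fixed by matching the mean of unmasked separation-2
    entries to the homopolymer simulation's mean at the same separation;
    scaled entries are clipped to <= 1. Masked bins are ineligible.
    """
    if hasattr(matrix, "values") and hasattr(matrix, "mask"):
        values, mask = matrix.values, matrix.mask
    else:
        values, mask = matrix
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = params.n_beads
    if values.shape != (n, n):
        raise ValueError("matrix size does not match params.n_beads")
    iu, ju = _eligible_pairs(mask, n)
    sep2 = ju - iu == 2
    if not sep2.any():
        raise ValueError("no unmasked separation-2 entries to anchor the scale")
    obs_mean = values[iu[sep2], ju[sep2]].mean()
    if obs_mean <= 0:
        raise ValueError("separation-2 entries sum to zero; cannot set scale")
    if reference_map is None:
        reference_map = homopolymer_reference_map(params, seed=_subseed(seed, 0xA11C))
    ri, rj = np.triu_indices(n, k=2)
    ref_mean = reference_map[ri[rj - ri == 2], rj[rj - ri == 2]].mean()
    scale = ref_mean / obs_mean
    probs = np.clip(values * scale, 0.0, 1.0)
    probs[~mask, :] = 0.0
    probs[:, ~mask] = 0.0
    return TargetProbabilityMatrix(probs, mask.copy(), scale_factor=float(scale))


def goodness_of_fit(sim_map: np.ndarray, target: TargetProbabilityMatrix,
                    min_sep: int = 2) -> float:
    """Pearson r over unmasked upper-triangle entries with |i - j| >= min_sep."""
    n = target.probs.shape[0]
    iu, ju = _eligible_pairs(target.eligible, n, min_sep)
    if iu.size < 3:
        raise ValueError("fewer than 3 eligible entries")
    x = np.asarray(sim_map)[iu, ju]
    y = target.probs[iu, ju]
    r, _ = stats.pearsonr(x, y)
    return float(r)


def fit_energies(
    target: TargetProbabilityMatrix,
    params: ModelParams,
    config: FitConfig | None = None,
) -> tuple[np.ndarray, FitTrace]:
    """Iteratively fit well depths so the simulated map reproduces the target.

    Each iteration simulates a fresh ensemble (sub-seed derived from
    config.seed and the iteration index), applies the damped log-ratio
    update to eligible pairs, and records Pearson r. Stops early at
    config.convergence_r; raises if r falls for 5 consecutive iterations.
    Masked-bead rows stay identically zero.
    """
    config = config or FitConfig()
    n = params.n_beads
    if target.probs.shape != (n, n):
        raise ValueError("target size does not match params")
    iu, ju = _eligible_pairs(target.eligible, n)
    if iu.size == 0:
        raise ValueError("no eligible pairs to fit")
    eps = np.zeros((n, n))
    trace = FitTrace()
    delta = config.delta
    n_worse = 0
    best_r = -np.inf
    prev_r = -np.inf
    for it in range(config.n_iterations):
        ens = mc_sample(
            eps, params, config.ensemble_size_per_iter,
            seed=_subseed(config.seed, it),
            schedule=config.schedule,
        )
        p_sim = ensemble_contact_map(ens, params.interaction_radius)
        r = goodness_of_fit(p_sim, target)
        update = config.learning_rate * np.log(
            (p_sim[iu, ju] + delta) / (target.probs[iu, ju] + delta)
        )
        new_vals = np.clip(eps[iu, ju] + update, config.eps_min, 0.0)
        trace.pearson_r.append(r)
        trace.mean_abs_update.append(float(np.abs(new_vals - eps[iu, ju]).mean()))
        trace.acceptance_rate.append(ens.provenance.get("acceptance_rate", np.nan))
        eps[iu, ju] = new_vals
        eps[ju, iu] = new_vals
        if r >= config.convergence_r:
            break
        # divergence guard: a sustained, material decline (not MC jitter)
        if r < prev_r:
            n_worse += 1
            if n_worse >= 5 and r < best_r - 0.05:
                raise RuntimeError(
                    f"fit diverging: Pearson r decreased for {n_worse} consecutive "
                    f"iterations (last r = {r:.4f}); trace attached", trace
                )
        else:
            n_worse = 0
        best_r = max(best_r, r)
        prev_r = r
    return eps, trace
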