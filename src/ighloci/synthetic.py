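"""Seeded synthetic-data generators for every pipeline stage.

These generators produce inputs with the statistical structure each analysis
stage assumes, so the full pipeline is exercisable without sequencing or
imaging data:

- energy "truths" emulating the pro-B Igh architecture (two anchor stripes
  from the CTCF superanchor / IGCR1, one distal attractive block);
- target contact-probability maps simulated from a known truth (ground
  truth for inverse-fit recovery);
- genome-wide 500-kb trans count tables with overdispersed
  negative-binomial background and spiked outlier bins;
- nuclei with fluorescent spot pairs/trios in a sphere of given volume at a
  controlled association frequency (focal locus at the centre, so the
  analytic random-association probability is exact);
- contact-pair records drawn from a probability map (to exercise binning
  and balancing end to end).

Every generator is deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_matrix import BinningScheme, ContactPair
from .polymer import Ensemble, ModelParams, SamplingSchedule, ensemble_contact_map, mc_sample
from .trans_network import TransCountTable

__all__ = [
    "synth_energy_truth",
    "synth_target_map",
    "synth_trans_counts",
    "synth_fish_nuclei",
    "synth_contact_pairs",
    "igh_bead_annotation",
]


def synth_energy_truth(
    n_beads: int,
    anchors: Sequence[int] = (),
    anchor_depth: float = -1.5,
    block: tuple[int, int, float] | None = None,
    background_depth: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Well-depth matrix with anchor stripes and an attractive distal block.

    ``anchors`` are 1-based bead indices whose full rows/columns are set to
    ``anchor_depth``; ``block`` = (start, end, depth) sets all pairs with
    both beads in the 1-based inclusive range [start, end]. Where specs
    overlap the deeper (more negative) value wins. The diagonal is zero and
    every entry is clipped to <= 0. ``seed`` is accepted for interface
    uniformity; the construction is deterministic.
    """
    eps = np.full((n_beads, n_beads), float(background_depth))
    for b in anchors:
        if not 1 <= b <= n_beads:
            raise ValueError(f"anchor bead {b} outside 1..{n_beads}")
        i = b - 1
        eps[i, :] = np.minimum(eps[i, :], anchor_depth)
        eps[:, i] = np.minimum(eps[:, i], anchor_depth)
    if block is not None:
        lo, hi, depth = block
        if not (1 <= lo <= hi <= n_beads):
            raise ValueError(f"block [{lo}, {hi}] outside 1..{n_beads}")
        eps[lo - 1:hi, lo - 1:hi] = np.minimum(eps[lo - 1:hi, lo - 1:hi], depth)
    eps = np.minimum(eps, 0.0)
    eps = np.minimum(eps, eps.T)
    np.fill_diagonal(eps, 0.0)
    return eps


def synth_target_map(
    truth: np.ndarray,
    params: ModelParams | None = None,
    n_structures: int = 400,
    seed: int = 0,
    schedule: SamplingSchedule | None = None,
) -> tuple[np.ndarray, Ensemble]:
    """Simulate an ensemble under a known truth and return its contact map.

    The returned (map, ensemble) pair is the ground truth for inverse-fit
    recovery experiments.
    """
    truth = np.asarray(truth, dtype=float)
    params = params or ModelParams(n_beads=truth.shape[0])
    schedule = schedule or SamplingSchedule(burnin_sweeps_per_bead=100,
                                            thin_sweeps_per_bead=5)
    ens = mc_sample(truth, params, n_structures, seed=seed, schedule=schedule)
    return ensemble_contact_map(ens, params.interaction_radius), ens


def synth_trans_counts(
    n_bins: int,
    background_mean: float = 100.0,
    dispersion: float = 10.0,
    spikes: Sequence[tuple[int, float]] = (),
    n_replicates: int = 2,
    seed: int = 0,
    chrom: str = "chrS",
    bin_size: int = 500_000,
) -> tuple[TransCountTable, np.ndarray]:
    """Negative-binomial trans count tables with spiked outlier bins.

    Background counts are NB with the given mean and size (``dispersion``)
    parameter (variance = mean + mean^2 / dispersion), drawn independently
    per replicate. Each (bin, fold) spike draws that bin with mean x fold in
    every replicate. Returns the table and the boolean ground-truth spike
    labels (0-based over bins).
    """
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    rng = np.random.default_rng(seed)
    means = np.full(n_bins, float(background_mean))
    labels = np.zeros(n_bins, dtype=bool)
    for b, fold in spikes:
        if not 0 <= b < n_bins:
            raise ValueError(f"spike bin {b} out of range")
        means[b] = background_mean * fold
        labels[b] = True
    size = float(dispersion)
    p = size / (size + means)
    tab = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n_bins, dtype=np.int64) * bin_size,
        "eligible": True,
    })
    for k in range(1, n_replicates + 1):
        tab[f"count_rep{k}"] = rng.negative_binomial(size, p)
    return TransCountTable(tab, bin_size, viewpoint="synthetic"), labels


def _uniform_in_sphere(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    """Uniform points in a ball via normalized Gaussians and a cube-root radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def synth_fish_nuclei(
    n_nuclei: int,
    nuclear_volume: float = 60.0,
    association_fraction: float = 0.0,
    association_radius: float = 1.0,
    channels: Sequence[str] = ("green", "red"),
    seed: int = 0,
):
    """Nuclei with two spots per channel inside a sphere of the given volume.

    The first channel's first spot (the focal locus) sits at the nucleus
    centre. Every other channel's first spot (the primary partner) is
    uniform in the sphere, except that with probability
    ``association_fraction`` it is placed uniformly within
    ``association_radius`` of the focal spot instead. Second-allele spots
    (one extra per channel) are uniform in the sphere. With the focal locus
    centred, the probability that an unassociated primary partner lies
    within r of it is exactly (4/3) pi r^3 / V.

    Returns a list of NucleusRecord.
    """
    from .fish_stats import NucleusRecord

    if not 0.0 <= association_fraction <= 1.0:
        raise ValueError("association_fraction must be in [0, 1]")
    R = (3.0 * nuclear_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    if association_radius >= R:
        raise ValueError(
            f"association radius {association_radius} um is not smaller than the "
            f"nuclear radius {R:.3f} um"
        )
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_nuclei):
        focal = np.zeros(3)
        spots = {channels[0]: [focal, _uniform_in_sphere(rng, R, 1)[0]]}
        for ch in channels[1:]:
            if rng.random() < association_fraction:
                partner = focal + _uniform_in_sphere(rng, association_radius, 1)[0]
            else:
                partner = _uniform_in_sphere(rng, R, 1)[0]
            spots[ch] = [partner, _uniform_in_sphere(rng, R, 1)[0]]
        records.append(
            NucleusRecord(f"nucleus_{i:06d}", {c: np.asarray(v) for c, v in spots.items()},
                          diameter=2.0 * R)
        )
    return records


def synth_contact_pairs(
    probability_map: np.ndarray,
    n_pairs: int,
    scheme: BinningScheme,
    seed: int = 0,
) -> list[ContactPair]:
    """Draw pair records with bin-pair frequencies proportional to a map.

    The (symmetric, non-negative) map is read on its upper triangle
    including the diagonal; positions are uniform within each bin. Rebinning
    the output with the same scheme recovers the map's relative frequencies
    up to multinomial noise.
    """
    P = np.asarray(probability_map, dtype=float)
    n = scheme.n_bins
    if P.shape != (n, n):
        raise ValueError("map shape does not match scheme")
    iu, ju = np.triu_indices(n)
    w = P[iu, ju].astype(float)
    if w.sum() <= 0:
        raise ValueError("probability map has no mass")
    rng = np.random.default_rng(seed)
    picks = rng.choice(iu.size, size=n_pairs, p=w / w.sum())
    pairs = []
    for k in picks:
        i, j = int(iu[k]), int(ju[k])
        pos = []
        for b in (i, j):
            lo = scheme.start + b * scheme.bin_size
            hi = min(lo + scheme.bin_size, scheme.end)
            pos.append(int(rng.integers(lo, hi)) + 1)  # 1-based
        pairs.append(ContactPair(scheme.chrom, pos[0], scheme.chrom, pos[1]))
    return pairs


def igh_bead_annotation(n_beads: int = 154) -> pd.DataFrame:
    """Synthetic stand-in annotation of the 20-kb Igh bead model.

    Follows the published bead indexing of the mouse Igh model region
    (3' CTCF-binding-element superanchor at bead 6, the constant/Emu block
    at beads 9-16, IGCR1 at bead 19, VH genes in beads 24-146). The exact
    DH bead set is not printed anywhere; beads 18-21 are used here (bead 19
    carries D genes in addition to IGCR1), flagged as inferred. CTCF levels
    and recombination scores are schematic placeholders (anchors high, VH
    region graded), not measured data.
    """
    rows = []
    dh = {18, 20, 21}  # bead 19 annotated as IGCR1; it also carries D genes
    for b in range(1, n_beads + 1):
        if b == 6:
            cls, ctcf = "CBE3prime", 10.0
        elif 9 <= b <= 16:
            cls, ctcf = "Emu" if b == 12 else "constant", 1.0
        elif b == 19:
            cls, ctcf = "IGCR1", 8.0
        elif b in dh:
            cls, ctcf = "DH", 2.0
        elif b in (22, 23):
            cls, ctcf = "JH", 1.0
        elif 24 <= b <= 146:
            cls, ctcf = "VH", 1.5
        else:
            cls, ctcf = "none", 0.5
        score = round(0.2 + 0.6 * (b - 24) / 122.0, 4) if cls == "VH" else np.nan
        rows.append((b, cls, ctcf, score))
    return pd.DataFrame(
        rows, columns=["bead_index", "element_class", "ctcf_level", "recombination_score"]
    )
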