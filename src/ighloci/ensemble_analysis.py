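"""Single-structure statistics over polymer ensembles of the Igh locus.

Quantities mirror the questions asked of V(D)J locus architecture: how many
partners each bead touches, how often VH beads contact DH beads, where beads
sit relative to the centre of mass of the whole locus (CM) and of the VH
region only (CMv), how those distances shift in the subset of structures
where a bead engages a given partner, and whether the locus folds into
discrete conformational subclasses (clustering by distance-matrix RMSD or by
contact-set overlap). Spearman rank correlation links per-bead geometry to
VDJ-seq recombination scores.

Bead indices are 1-based throughout, matching locus annotation conventions
(e.g. the 3' CTCF-binding-element superanchor at bead 6, IGCR1 at bead 19,
VH genes in beads 24-146 of the 20-kb model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .polymer import Ensemble, pairwise_distances

__all__ = [
    "ELEMENT_CLASSES",
    "BeadAnnotation",
    "read_annotation_tsv",
    "partners_per_bead",
    "vd_stats",
    "center_of_mass",
    "cm_distance_profiles",
    "conditional_cmv_distance",
    "vh_contact_fraction",
    "cluster_conformations",
    "spearman",
]

ELEMENT_CLASSES = frozenset(
    {"VH", "DH", "JH", "Emu", "CBE3prime", "IGCR1", "constant", "RR3prime", "none"}
)


@dataclass
class BeadAnnotation:
    """Per-bead element classes, CTCF level and recombination score (1-based)."""

    table: pd.DataFrame  # columns: bead_index, element_class, ctcf_level, recombination_score

    def __post_init__(self) -> None:
        required = {"bead_index", "element_class"}
        if not required <= set(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        idx = self.table["bead_index"]
        if idx.duplicated().any():
            raise ValueError("duplicate bead indices in annotation")
        if (idx < 1).any():
            raise ValueError("bead indices are 1-based")
        bad = set(self.table["element_class"]) - ELEMENT_CLASSES
        if bad:
            raise ValueError(f"unknown element classes: {sorted(bad)}")

    def beads_of_class(self, element_class: str) -> np.ndarray:
        """1-based bead indices of a class, sorted."""
        sel = self.table.loc[self.table["element_class"] == element_class, "bead_index"]
        return np.sort(sel.to_numpy(dtype=int))

    @property
    def vh_beads(self) -> np.ndarray:
        return self.beads_of_class("VH")

    @property
    def dh_beads(self) -> np.ndarray:
        return self.beads_of_class("DH")


def read_annotation_tsv(path) -> BeadAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    return BeadAnnotation(df)


def _contact_tensor(ensemble: Ensemble, contact_radius: float) -> np.ndarray:
    """(n_structures, n, n) boolean contact indicator, diagonal False."""
    out = np.empty((ensemble.n_structures, ensemble.n_beads, ensemble.n_beads), dtype=bool)
    for k, conf in enumerate(ensemble.coords):
        d = pairwise_distances(conf)
        np.fill_diagonal(d, np.inf)
        out[k] = d < contact_radius
    return out


def partners_per_bead(ensemble: Ensemble, contact_radius: float = 1.5) -> np.ndarray:
    """Mean number of interacting partners (distance < radius) per bead."""
    contacts = _contact_tensor(ensemble, contact_radius)
    return contacts.sum(axis=2).mean(axis=0)


def vd_stats(
    ensemble: Ensemble,
    annotation: BeadAnnotation,
    contact_radius: float = 1.5,
    vh_beads: np.ndarray | None = None,
    dh_beads: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.Series, pd.Series]:
    """V-D contact statistics per conformation and per bead.

    ``vh_beads`` / ``dh_beads`` (1-based) override the annotation's class
    sets — useful when a bead carries D genes in addition to another
    element (in the Igh model, the IGCR1 bead).

    Returns ``(vh_fraction, per_d, per_v)``:

    - ``vh_fraction[c]``: fraction of VH beads contacting >= 1 DH bead in
      conformation c;
    - ``per_d``: total V-D bead-pair contact events per DH bead (summed over
      conformations), indexed by 1-based bead;
    - ``per_v``: the same events tallied per VH bead.

    Events are bead pairs within the radius, one per conformation, so
    ``per_d.sum() == per_v.sum()``.
    """
    vh = annotation.vh_beads if vh_beads is None else np.asarray(vh_beads, dtype=int)
    dh = annotation.dh_beads if dh_beads is None else np.asarray(dh_beads, dtype=int)
    if vh.size == 0 or dh.size == 0:
        raise ValueError("annotation must contain at least one VH and one DH bead")
    contacts = _contact_tensor(ensemble, contact_radius)
    sub = contacts[:, vh - 1][:, :, dh - 1]  # (structures, nVH, nDH)
    vh_fraction = sub.any(axis=2).mean(axis=1)
    per_v = pd.Series(sub.sum(axis=(0, 2)), index=vh, name="vd_events")
    per_d = pd.Series(sub.sum(axis=(0, 1)), index=dh, name="vd_events")
    return vh_fraction, per_d, per_v


def center_of_mass(conf: np.ndarray, subset: Sequence[int] | str = "all") -> np.ndarray:
    """Mean coordinate of a bead subset (1-based indices) or of all beads."""
    conf = np.asarray(conf, dtype=float)
    if isinstance(subset, str):
        if subset != "all":
            raise ValueError("subset must be 1-based indices or 'all'")
        return conf.mean(axis=0)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty bead subset")
    return conf[subset - 1].mean(axis=0)


def cm_distance_profiles(
    ensemble: Ensemble, annotation: BeadAnnotation
) -> pd.DataFrame:
    """Per-bead mean distance (units of a) from CM and from CMv.

    CM is the centre of mass of all beads, CMv of the VH beads only;
    averages run over all conformations.
    """
    vh = annotation.vh_beads
    if vh.size == 0:
        raise ValueError("annotation has no VH beads")
    n = ensemble.n_beads
    d_cm = np.zeros(n)
    d_cmv = np.zeros(n)
    for conf in ensemble.coords:
        cm = conf.mean(axis=0)
        cmv = conf[vh - 1].mean(axis=0)
        d_cm += np.linalg.norm(conf - cm, axis=1)
        d_cmv += np.linalg.norm(conf - cmv, axis=1)
    m = ensemble.n_structures
    return pd.DataFrame(
        {
            "bead_index": np.arange(1, n + 1),
            "mean_dist_cm": d_cm / m,
            "mean_dist_cmv": d_cmv / m,
        }
    )


def conditional_cmv_distance(
    ensemble: Ensemble,
    annotation: BeadAnnotation,
    bead: int,
    partner: int,
    contact_radius: float = 1.5,
) -> tuple[float, int]:
    """Mean distance of ``bead`` from CMv over structures where it contacts ``partner``.

    Returns ``(mean_distance, subset_size)``; an empty conditioning subset
    yields ``(nan, 0)`` — never a silent zero. Beads are 1-based.
    """
    vh = annotation.vh_beads
    if vh.size == 0:
        raise ValueError("annotation has no VH beads")
    b, q = bead - 1, partner - 1
    dists = []
    for conf in ensemble.coords:
        if np.linalg.norm(conf[b] - conf[q]) < contact_radius:
            cmv = conf[vh - 1].mean(axis=0)
            dists.append(np.linalg.norm(conf[b] - cmv))
    if not dists:
        return float("nan"), 0
    return float(np.mean(dists)), len(dists)


def vh_contact_fraction(
    ensemble: Ensemble,
    annotation: BeadAnnotation,
    contact_radius: float = 1.5,
) -> np.ndarray:
    """Per-bead mean fraction of VH beads contacted across conformations.

    For bead b in conformation c the fraction is |{v in VH, v != b,
    dist(b, v) < radius}| / |VH \\ {b}|.
    """
    vh = annotation.vh_beads
    if vh.size == 0:
        raise ValueError("annotation has no VH beads")
    contacts = _contact_tensor(ensemble, contact_radius)
    n = ensemble.n_beads
    vh0 = vh - 1
    is_vh = np.zeros(n, dtype=bool)
    is_vh[vh0] = True
    denom = np.where(is_vh, max(vh.size - 1, 1), vh.size)
    counts = contacts[:, :, vh0].sum(axis=2)  # (structures, beads)
    return (counts / denom).mean(axis=0)


def _contact_fingerprints(ensemble: Ensemble, contact_radius: float) -> np.ndarray:
    """Boolean per-conformation vectors of contacts at |i-j| >= 2."""
    n = ensemble.n_beads
    iu, ju = np.triu_indices(n, k=2)
    out = np.empty((ensemble.n_structures, iu.size), dtype=bool)
    for k, conf in enumerate(ensemble.coords):
        d = pairwise_distances(conf)
        out[k] = d[iu, ju] < contact_radius
    return out


def cluster_conformations(
    ensemble: Ensemble,
    method: str = "rmsd",
    linkage_method: str = "average",
    k: int | None = 2,
    cut_height: float | None = None,
    contact_radius: float = 1.5,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Agglomerative clustering of conformations by structural dissimilarity.

    ``method='rmsd'``: sqrt of the mean squared difference of bead-bead
    distances over all pairs i < j (invariant to rigid motion).
    ``method='contact_overlap'``: 1 - Jaccard overlap of the contact sets
    (pairs < radius, |i - j| >= 2).

    Returns cluster labels (1-based, per conformation) and a dict of
    per-cluster mean contact maps keyed by label.
    """
    m = ensemble.n_structures
    if m < 2:
        raise ValueError("need at least 2 conformations to cluster")
    if k is not None and k > m:
        raise ValueError(f"k={k} exceeds the number of conformations ({m})")
    n = ensemble.n_beads
    iu, ju = np.triu_indices(n, k=1)
    if method == "rmsd":
        vecs = np.empty((m, iu.size))
        for i, conf in enumerate(ensemble.coords):
            vecs[i] = pairwise_distances(conf)[iu, ju]
        condensed = pdist(vecs, metric="euclidean") / np.sqrt(iu.size)
    elif method == "contact_overlap":
        fp = _contact_fingerprints(ensemble, contact_radius)
        condensed = pdist(fp, metric="jaccard")
    else:
        raise ValueError("method must be 'rmsd' or 'contact_overlap'")
    Z = linkage(condensed, method=linkage_method)
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(Z, t=k, criterion="maxclust")
    maps: dict[int, np.ndarray] = {}
    full = np.empty((m, n, n))
    for i, conf in enumerate(ensemble.coords):
        d = pairwise_distances(conf)
        full[i] = d < contact_radius
        np.fill_diagonal(full[i], 1.0)
    for lab in np.unique(labels):
        maps[int(lab)] = full[labels == lab].mean(axis=0)
    return labels, maps


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Returns (rho, two-sided p); constant input yields (nan, nan) rather than
    an arbitrary value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
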