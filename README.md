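# ighloci

Computational machinery for studying the 3D architecture of antigen-receptor
loci — above all the mouse immunoglobulin heavy-chain (*Igh*) locus — from
Capture Hi-C, polymer modeling and 3D DNA FISH. The package is aimed at
researchers analysing V(D)J recombination locus conformation: it covers the
full downstream path from deduplicated ligation-pair records to single-cell
conformational statistics, significant interchromosomal partner calling, and
microscopy-based validation statistics, with seeded synthetic generators so
every stage is testable without sequencing or imaging data.

## What it computes

**Contact maps** (`ighloci.contact_matrix`). Pair records are binned on a
fixed 20-kb grid (the *Igh* model region spans chr12:113,090,000–116,170,000),
low-coverage bins are masked, and the matrix is balanced by iterative
correction (Sinkhorn-style proportional fitting, so every unmasked bin ends
with the same marginal). An observed/expected transform divides each entry by
the mean at its genomic separation.

**Polymer model** (`ighloci.polymer`). A beads-on-a-string chain — one bead
per 20-kb bin, bond length *a* — in which any two beads interact through a
spherical-well potential: infinite below the hard-core radius 0.6 *a*, a
constant depth ε<sub>ij</sub> ≤ 0 (in kT) up to the interaction radius
1.5 *a*, zero beyond. A Metropolis Monte-Carlo sampler (single-bead moves +
crankshaft rotations, numba-compiled, bit-reproducible per seed) draws
conformational ensembles from the Boltzmann distribution; a contact map is
the fraction of conformations with bead–bead distance < 1.5 *a*.

**Inverse fitting** (`ighloci.energy_fit`). Well depths are optimized so the
simulated map reproduces a target map, by damped iterative-Boltzmann updates
ε<sub>ij</sub> ← clip(ε<sub>ij</sub> + η·log((p<sup>sim</sup><sub>ij</sub>+δ)/(p<sup>target</sup><sub>ij</sub>+δ)), [ε<sub>min</sub>, 0]).

**Ensemble statistics** (`ighloci.ensemble_analysis`). Per-bead partner
counts, V<sub>H</sub>–D<sub>H</sub> contact statistics, centre-of-mass
geometry (CM of the whole locus, CMv of the V<sub>H</sub> beads only),
conditional distances in the subset of structures where a bead engages a
partner, conformational clustering (distance-matrix RMSD or contact-set
Jaccard overlap), and Spearman correlation with recombination scores.

**Trans-interaction calling** (`ighloci.trans_network`). Virtual-4C counting
of viewpoint-anchored interchromosomal other-ends in 500-kb genome-wide bins
(first 3 Mb of each chromosome, blacklists and custom zones excluded), scored
with the Iglewicz–Hoaglin modified Z-score, z = 0.6745 (x − median)/MAD, and
called significant when z > 3.5 in **both** biological replicates; profiles
log2(avg z + 1) feed hierarchical clustering (Euclidean, complete linkage).

**FISH statistics** (`ighloci.fish_stats`). Closest cross-channel spot pairs
and trios per nucleus, nuclear-volume adjustment, distance brackets
(<0.5, 0.5–0.8, 0.8–1, >1 μm), and the analytic random-colocalization model
p = (4/3)πr³/V with Fisher-exact / binomial / Kruskal–Wallis + Dunn testing.

## Worked example

```python
import numpy as np
from ighloci.polymer import ModelParams, SamplingSchedule, mc_sample, ensemble_contact_map
from ighloci.synthetic import synth_energy_truth
from ighloci.fish_stats import random_association_probability, tripartite_probability
from ighloci.trans_network import modified_zscore

# a pro-B-like 40-bead architecture: anchor stripes at beads 6 and 19,
# a weakly attractive distal block over beads 24-40
params = ModelParams(n_beads=40)
truth = synth_energy_truth(40, anchors=(6, 19), anchor_depth=-1.5, block=(24, 40, -0.4))
ens = mc_sample(truth, params, 500, seed=1, schedule=SamplingSchedule(100, 5))
cmap = ensemble_contact_map(ens)
print(cmap[5, 18], cmap[9, 29])   # 1.0  0.116

p = random_association_probability(1.0, 60.0)
print(round(p, 4), round(tripartite_probability(p), 5))   # 0.0698  0.00487

print(np.round(modified_zscore(np.array([1, 2, 3, 4, 100])), 4))
# [-1.349  -0.6745  0.      0.6745 65.4265]
```

The two deep anchors are in contact in essentially every sampled structure
(probability 1.0) while a distal background pair touches in ~12% of
structures; the random two-locus colocalization chance within 1 μm in a
60 μm³ nucleus is ~7% and the three-locus chance its square (~0.5%); the
count 100 in an otherwise flat bin vector is an extreme outlier
(modified z ≈ 65), far above the 3.5 calling threshold.

A command-line interface mirrors the library
(`ighloci bin|balance|oe|simulate|fit|analyze|trans|fish|synth`); run
`ighloci --help` for the subcommands.

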