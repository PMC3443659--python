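"""Small bundled reference data.

``beta_globin_dmk_matrix`` returns published pairwise DMk distances
(k = 3) among the full β-globin gene sequences of 10 vertebrate
species — a classic benchmark set for alignment-free methods.  The
matrix is useful as a ready-made input for UPGMA tree building and as a
sanity check: the three primates (human, gorilla, chimpanzee) are
mutually closest, goat–bovine pair up, and gallus — the only
non-mammal — is the most distant from everything else.
"""

from __future__ import annotations

import numpy as np

from .distance import DistanceMatrix

BETA_GLOBIN_SPECIES = [
    "Human", "Goat", "Opossum", "Gallus", "Lemur",
    "Mouse", "Rat", "Gorilla", "Bovine", "Chimpanzee",
]

# upper triangle, row by row, in the species order above
_BETA_GLOBIN_UPPER = [
    [22.95, 37.65, 111.47, 14.02, 35.21, 20.68, 3.42, 25.07, 3.54],
    [41.22, 65.70, 18.80, 35.05, 33.93, 32.36, 6.04, 33.05],
    [42.54, 33.29, 64.03, 51.64, 46.35, 40.41, 49.73],
    [90.93, 80.07, 95.26, 121.09, 61.69, 122.65],
    [21.39, 18.50, 17.19, 18.12, 18.74],
    [16.04, 33.64, 27.60, 37.59],
    [17.69, 30.53, 20.58],
    [33.66, 0.80],
    [35.46],
]


def beta_globin_dmk_matrix() -> DistanceMatrix:
    """The 10-species β-globin DMk (k=3) distance matrix."""
    n = len(BETA_GLOBIN_SPECIES)
    values = np.zeros((n, n))
    for i, row in enumerate(_BETA_GLOBIN_UPPER):
        for offset, v in enumerate(row):
            j = i + 1 + offset
            values[i, j] = values[j, i] = v
    return DistanceMatrix(labels=list(BETA_GLOBIN_SPECIES), values=values)
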