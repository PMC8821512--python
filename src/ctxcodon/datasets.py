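"""Small built-in reference data.

``REFERENCE_CONTEXT_MATRICES`` holds three published representative
context-dependent substitution count matrices (contexts CC_CC, CC_AA and
AA_AA) estimated from pairwise comparisons of closely related angiosperm
chloroplast genomes with an outgroup orienting ancestral vs derived states.
Rows are the ancestral base (A, C, G, T), columns the derived base, and the
diagonal counts conserved sites. They serve as worked examples for the
stationary-vector machinery and as anchors for the ``table1_like``
simulation preset.

``REFERENCE_EQUILIBRIA`` gives the equilibrium base compositions (percent
A, C, G, T) published alongside those matrices.
"""

from __future__ import annotations

import numpy as np

REFERENCE_CONTEXT_MATRICES: dict[str, np.ndarray] = {
    "CC_CC": np.array(
        [
            [13766, 43, 134, 1],
            [24, 12031, 13, 132],
            [155, 27, 6424, 18],
            [3, 140, 23, 12530],
        ],
        dtype=np.int64,
    ),
    "CC_AA": np.array(
        [
            [16566, 62, 39, 27],
            [76, 6168, 6, 45],
            [68, 17, 5514, 30],
            [22, 33, 31, 13269],
        ],
        dtype=np.int64,
    ),
    "AA_AA": np.array(
        [
            [63064, 38, 56, 77],
            [48, 8949, 25, 40],
            [124, 21, 20755, 228],
            [151, 41, 174, 32101],
        ],
        dtype=np.int64,
    ),
}

REFERENCE_EQUILIBRIA: dict[str, tuple[float, float, float, float]] = {
    "CC_CC": (26.4, 32.7, 11.3, 29.6),
    "CC_AA": (43.4, 13.5, 9.4, 33.7),
    "AA_AA": (65.4, 5.9, 9.9, 18.8),
}
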