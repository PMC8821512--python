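"""Synthetic data: triplets evolved under known context-dependent mutation
models, and neutral coding sequences drawn from per-context equilibria.

The simulator mirrors the estimator's assumptions at low divergence: a root
sequence is drawn from a base composition, evolved along the unrooted
3-taxon tree ((ingroup1, ingroup2), outgroup) with a shared internal branch,
and each site substitutes according to the probability matrix of its
tetranucleotide context read from the pre-branch (parent) sequence. At the
sub-percent divergences emulated here (~0.7-1.5% of sites substituted
between the ingroups) this single-step approximation is essentially exact.
The terminal two bases of a sequence never substitute: they have no full
context, matching the estimator, which cannot score them. Gaps, when
requested, are independent single-base deletions per taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import AlignedTriplet
from .datasets import REFERENCE_CONTEXT_MATRICES
from .expectation import as_stationary_lookup, restricted_distribution
from .genetics import BASE_INDEX, BASES, FAMILIES, SIXFOLD_AAS, decode, translate
from .matrices import ALL_CONTEXTS, to_rate_matrix

PRESETS = ("null_uniform", "at_context", "table1_like")

#: branch order: ingroup1, ingroup2, outgroup, shared internal branch
DEFAULT_BRANCH_LENGTHS = (0.005, 0.005, 0.008, 0.002)


@dataclass
class SimulationModel:
    """A context-dependent mutation model for triplet simulation.

    ``context_probabilities`` maps each of the 256 contexts to a 4x4
    row-stochastic per-branch substitution probability matrix; its
    off-diagonal row mass sets the relative substitution rate of that
    context, and branch lengths (expected substituted-site fractions)
    rescale the off-diagonal mass uniformly, which leaves every context's
    stationary vector unchanged.
    """

    context_probabilities: dict[str, np.ndarray]
    root_composition: np.ndarray
    branch_lengths: tuple[float, float, float, float] = DEFAULT_BRANCH_LENGTHS
    indel_rate: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        for ctx, m in self.context_probabilities.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (4, 4) or np.abs(m.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError(f"matrix for context {ctx!r} is not row-stochastic")
            self.context_probabilities[ctx] = m
        rc = np.asarray(self.root_composition, dtype=float)
        if rc.shape != (4,) or abs(rc.sum() - 1) > 1e-9 or (rc < 0).any():
            raise ValueError("root_composition must be 4 frequencies summing to 1")
        self.root_composition = rc
        for b in self.branch_lengths:
            if not 0.0 <= b <= 0.1:
                raise ValueError("branch substituted-site fractions must be in [0, 0.1]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")

    @property
    def reference_divergence(self) -> float:
        """Mean off-diagonal row mass across contexts: the substituted-site
        fraction the stored matrices represent per branch of unit scale."""
        masses = [
            1.0 - np.diag(m).mean() for m in self.context_probabilities.values()
        ]
        return float(np.mean(masses))

    def branch_matrices(self, branch_length: float) -> np.ndarray:
        """(256, 4, 4) per-site substitution matrices for one branch."""
        alpha = branch_length / self.reference_divergence
        out = np.empty((256, 4, 4))
        eye = np.eye(4)
        for i, ctx in enumerate(ALL_CONTEXTS):
            pi = self.context_probabilities[ctx]
            out[i] = eye + alpha * (pi - eye)
        if (np.diagonal(out, axis1=1, axis2=2) < 0).any():
            raise ValueError(
                f"branch length {branch_length} too long for the stored matrices"
            )
        return out


def _direction_matrix(
    ts_tv: float, at_pull: float = 1.0, off_mass: float = 0.01
) -> np.ndarray:
    """Row-stochastic matrix with equal per-row off-diagonal mass, built from
    a transition:transversion ratio and a multiplier on rates into A/T."""
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    m = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = ts_tv if (i, j) in transitions else 1.0
            if BASES[j] in "AT":
                rate *= at_pull
            m[i, j] = rate
        m[i] *= off_mass / m[i].sum()
        m[i, i] = 1.0 - off_mass
    return m


def make_preset_model(
    preset_name: str,
    seed: int = 0,
    branch_lengths: tuple[float, float, float, float] = DEFAULT_BRANCH_LENGTHS,
    indel_rate: float = 0.0,
) -> SimulationModel:
    """Build one of the named study models.

    ``null_uniform``: one context-free matrix everywhere (uniform
    equilibrium). ``at_context``: transition bias falls and the pull towards
    A/T rises with the A+T count of the four context bases, the qualitative
    pattern seen in chloroplast intergenic data. ``table1_like``: the three
    published reference matrices anchor their own contexts (flanking A+T
    counts 0, 2 and 4) and other contexts interpolate linearly on flanking
    A+T count.
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; valid presets: {', '.join(PRESETS)}"
        )
    if preset_name == "null_uniform":
        base = _direction_matrix(ts_tv=2.0)
        probs = {ctx: base.copy() for ctx in ALL_CONTEXTS}
        root = np.full(4, 0.25)
    elif preset_name == "at_context":
        by_k = {
            k: _direction_matrix(ts_tv=4.0 / (1.0 + 0.75 * k), at_pull=1.0 + 0.75 * k)
            for k in range(5)
        }
        probs = {
            ctx: by_k[sum(b in "AT" for b in ctx.replace("_", ""))].copy()
            for ctx in ALL_CONTEXTS
        }
        root = np.array([0.33, 0.17, 0.17, 0.33])
    else:  # table1_like
        anchors = {
            0: to_rate_matrix(REFERENCE_CONTEXT_MATRICES["CC_CC"], pseudocount=True),
            2: to_rate_matrix(REFERENCE_CONTEXT_MATRICES["CC_AA"], pseudocount=True),
            4: to_rate_matrix(REFERENCE_CONTEXT_MATRICES["AA_AA"], pseudocount=True),
        }
        anchors[1] = 0.5 * (anchors[0] + anchors[2])
        anchors[3] = 0.5 * (anchors[2] + anchors[4])
        probs = {
            ctx: anchors[sum(b in "AT" for b in ctx.replace("_", ""))].copy()
            for ctx in ALL_CONTEXTS
        }
        root = np.array([0.35, 0.15, 0.15, 0.35])
    return SimulationModel(
        context_probabilities=probs,
        root_composition=root,
        branch_lengths=tuple(branch_lengths),
        indel_rate=indel_rate,
        seed=seed,
        name=preset_name,
    )


def _evolve(
    parent: np.ndarray, cum: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One branch: substitute interior sites using the context read from the
    pre-branch sequence. ``cum`` is (256, 4, 4) cumulative probabilities."""
    L = len(parent)
    child = parent.copy()
    if L < 5:
        return child
    p64 = parent.astype(np.int64)
    codes = p64[: L - 4] * 64 + p64[1 : L - 3] * 16 + p64[3 : L - 1] * 4 + p64[4:]
    rows = cum[codes, p64[2 : L - 2]]  # (L-4, 4)
    u = rng.random(L - 4)
    child[2 : L - 2] = np.minimum((rows < u[:, None]).sum(axis=1), 3)
    return child


def simulate_triplet(
    model: SimulationModel, length: int, seed: int | None = None
) -> AlignedTriplet:
    """Simulate an aligned triplet of ``length`` columns under ``model``."""
    if length < 5:
        raise ValueError("length must be at least 5 (two flanking bases each side)")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    b1, b2, b_out, b_int = model.branch_lengths
    cums = {
        b: np.cumsum(model.branch_matrices(b), axis=2)
        for b in sorted({b1, b2, b_out, b_int})
    }
    root = rng.choice(4, size=length, p=model.root_composition).astype(np.uint8)
    ingroup_anc = _evolve(root, cums[b_int], rng)
    in1 = _evolve(ingroup_anc, cums[b1], rng)
    in2 = _evolve(ingroup_anc, cums[b2], rng)
    out = _evolve(root, cums[b_out], rng)
    leaves = []
    for leaf in (in1, in2, out):
        if model.indel_rate > 0:
            gaps = rng.random(length) < model.indel_rate
            leaf = np.where(gaps, np.uint8(4), leaf)
        leaves.append(leaf)
    return AlignedTriplet(
        *(decode(leaf) for leaf in leaves),
        identifiers=("ingroup1", "ingroup2", "outgroup"),
    )


def simulate_neutral_gene(aa_sequence: str, matrix_set, seed: int | None = None) -> str:
    """A coding sequence for ``aa_sequence`` whose degenerate third positions
    are drawn from the per-context equilibrium vectors of ``matrix_set``.

    Sixfold amino acids are assigned to their fourfold or twofold subgroup
    uniformly at random; a trailing ``*`` appends a TAA stop codon, which
    then supplies the final sense codon's downstream context. The terminal
    codon of a stop-less sequence has no context and its third base is drawn
    uniformly over the synonymous bases.
    """
    aa_sequence = aa_sequence.upper()
    if not aa_sequence:
        raise ValueError("amino-acid sequence must be non-empty")
    stop = aa_sequence.endswith("*")
    aas = aa_sequence[:-1] if stop else aa_sequence
    if "*" in aas:
        raise ValueError("stop symbol only allowed at the terminal position")
    for a in aas:
        if a not in FAMILIES:
            raise ValueError(f"unknown amino-acid symbol {a!r}")
    rng = np.random.default_rng(seed)
    lookup = as_stationary_lookup(matrix_set)

    # scaffold: fix each codon's first two bases (sixfold subgroup drawn here)
    prefixes = []
    for a in aas:
        codons = FAMILIES[a]
        options = sorted({c[:2] for c in codons})
        prefixes.append(options[rng.integers(len(options))] if len(options) > 1 else options[0])
    downstream = prefixes[1:] + (["TA"] if stop else [None])

    seq = []
    for a, prefix, down in zip(aas, prefixes, downstream):
        syn = [c[2] for c in FAMILIES[a] if c.startswith(prefix)]
        if len(syn) == 1:
            seq.append(prefix + syn[0])
            continue
        if down is None:
            third = syn[rng.integers(len(syn))]
        else:
            ctx = f"{prefix}_{down}"
            p = restricted_distribution(
                lookup(ctx), [BASE_INDEX[b] for b in syn]
            )
            third = syn[rng.choice(len(p), p=p)]
        seq.append(prefix + third)
    if stop:
        seq.append("TAA")
    result = "".join(seq)
    assert translate(result) == aas
    return result
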