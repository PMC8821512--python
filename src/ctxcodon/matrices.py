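"""Per-context substitution count matrices and their equilibrium compositions.

A tetranucleotide context is written ``NN_NN``: the two bases immediately 5'
of a site, an underscore for the site itself, and the two bases immediately
3'. For every context a 4x4 count matrix is tallied (rows = ancestral base,
columns = derived base, diagonal = conserved sites). Complementary contexts
describe the same double-stranded neighbourhood read from the other strand
and can be combined; contexts sharing the immediate flanking pair and the
composition class of the two outer bases can be pooled into 48 generic
matrices to increase per-matrix sample size.

Row-normalizing a count matrix gives a stochastic matrix Pi whose stationary
vector Phi (Phi = Phi.Pi) is the base composition a neutrally evolving site
in that context drifts towards.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genetics import BASES, BASE_INDEX, COMPLEMENT, COMPLEMENT_INDEX

RAW256 = "raw256"
COMPLEMENT_COMBINED = "complement_combined"
POOLED48_AT = "pooled48_AT"
POOLED48_RY = "pooled48_RY"

#: all 256 context keys, lexicographic
ALL_CONTEXTS = tuple(
    f"{a}{b}_{c}{d}" for a, b, c, d in itertools.product(BASES, repeat=4)
)

_CONTEXT_CODE = {ctx: i for i, ctx in enumerate(ALL_CONTEXTS)}


def context_code(ctx: str) -> int:
    """Integer code 0..255 of an ``NN_NN`` context."""
    return _CONTEXT_CODE[ctx]


def context_from_code(code: int) -> str:
    return ALL_CONTEXTS[code]


def revcomp_context(ctx: str) -> str:
    """Reverse-complement partner: the same neighbourhood on the other strand."""
    five, three = ctx.split("_")
    rc = lambda s: "".join(COMPLEMENT[b] for b in reversed(s))
    return f"{rc(three)}_{rc(five)}"


def canonical_context(ctx: str) -> str:
    """Lexicographically smaller of a context and its reverse complement."""
    return min(ctx, revcomp_context(ctx))


def complement_matrix(counts: np.ndarray) -> np.ndarray:
    """Relabel both axes by base complement (A<->T, C<->G)."""
    return counts[np.ix_(COMPLEMENT_INDEX, COMPLEMENT_INDEX)]


def pooled_key(ctx: str, scheme: str) -> str:
    """48-matrix pooling key of an original context.

    The immediate 5' and 3' neighbours are kept verbatim; the two outer
    bases are reduced to a composition class: their A+T count (scheme
    ``"AT"``) or pyrimidine count (scheme ``"RY"``), each 0, 1 or 2.
    """
    if scheme not in ("AT", "RY"):
        raise ValueError(f"unknown pooling scheme {scheme!r}; use 'AT' or 'RY'")
    five, three = ctx.split("_")
    inner5, inner3 = five[1], three[0]
    outer = five[0] + three[1]
    group = "AT" if scheme == "AT" else "CT"
    k = sum(b in group for b in outer)
    return f"{inner5}_{inner3}|{scheme}={k}"


def pooled_keys(scheme: str) -> tuple[str, ...]:
    """The 48 pooling keys (16 immediate pairs x 3 outer classes)."""
    return tuple(
        f"{a}_{b}|{scheme}={k}"
        for a in BASES
        for b in BASES
        for k in (0, 1, 2)
    )


@dataclass
class SubstitutionCountMatrix:
    """4x4 ancestral-by-derived counts for one context (or pooled key)."""

    context: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_substitutions(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


@dataclass
class ContextMatrixSet:
    """A keyed collection of substitution count matrices at one level."""

    matrices: dict[str, np.ndarray]
    level: str = RAW256

    def __post_init__(self) -> None:
        for k, m in self.matrices.items():
            m = np.asarray(m, dtype=np.int64)
            if m.shape != (4, 4) or (m < 0).any():
                raise ValueError(f"matrix for {k!r} must be a non-negative 4x4")
            self.matrices[k] = m
        if self.level.startswith("pooled48") and len(self.matrices) != 48:
            raise ValueError("pooled sets must have exactly 48 keys")
        if self.level == RAW256 and len(self.matrices) > 256:
            raise ValueError("raw256 sets have at most 256 keys")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.matrices[key]

    def __contains__(self, key: str) -> bool:
        return key in self.matrices

    def keys(self):
        return self.matrices.keys()

    def items(self):
        return self.matrices.items()

    def total_counts(self) -> int:
        return int(sum(m.sum() for m in self.matrices.values()))

    def total_substitutions(self) -> int:
        return int(sum(m.sum() - np.trace(m) for m in self.matrices.values()))

    def substitutions(self, key: str) -> int:
        m = self.matrices[key]
        return int(m.sum() - np.trace(m))


def count_contexts(observations) -> ContextMatrixSet:
    """Tally site observations into the full raw256 matrix set.

    ``observations`` is either an iterable of
    :class:`~ctxcodon.scoring.SiteObservation` or a
    :class:`~ctxcodon.scoring.SiteObservations` batch (fast path). Contexts
    without observations are present with all-zero matrices.
    """
    tally = np.zeros((256, 4, 4), dtype=np.int64)
    codes = getattr(observations, "context_codes", None)
    if codes is not None:
        np.add.at(
            tally,
            (codes, observations.ancestral_idx, observations.derived_idx),
            1,
        )
    else:
        for obs in observations:
            tally[
                context_code(obs.context),
                BASE_INDEX[obs.ancestral],
                BASE_INDEX[obs.derived],
            ] += 1
    return ContextMatrixSet(
        {ctx: tally[i] for i, ctx in enumerate(ALL_CONTEXTS)}, level=RAW256
    )


def complement_combine(raw: ContextMatrixSet) -> ContextMatrixSet:
    """Fold each context with its reverse-complement partner.

    The kept key is the lexicographically smaller of the pair; the partner's
    counts enter with both axes complement-relabelled. Self-complementary
    contexts pass through unchanged. Idempotent in the sense that combining a
    set whose keys are already canonical is the identity.
    """
    if raw.level == COMPLEMENT_COMBINED:
        # already canonical: combining again is the identity (projection)
        return ContextMatrixSet(
            {k: m.copy() for k, m in raw.items()}, level=COMPLEMENT_COMBINED
        )
    if raw.level != RAW256:
        raise ValueError("complement_combine expects a raw256 set")
    out: dict[str, np.ndarray] = {}
    for ctx, m in raw.items():
        canon = canonical_context(ctx)
        if ctx == canon:
            out[canon] = out.get(canon, np.zeros((4, 4), dtype=np.int64)) + m
        else:
            out[canon] = out.get(canon, np.zeros((4, 4), dtype=np.int64)) + (
                complement_matrix(m)
            )
    return ContextMatrixSet(out, level=COMPLEMENT_COMBINED)


def pool_matrices(mset: ContextMatrixSet, scheme: str = "AT") -> ContextMatrixSet:
    """Pool into the 48 generic matrices.

    From a ``raw256`` set each pooled matrix is the plain sum of its 4 or 8
    original member contexts, so total counts are conserved. From a
    ``complement_combined`` set each canonical matrix is folded into both
    strand orientations (its own key as-is, its partner's key complemented),
    which makes complementary pooled keys exact mirrors of one another but
    represents every observation once per strand.
    """
    keys = pooled_keys(scheme)
    out = {k: np.zeros((4, 4), dtype=np.int64) for k in keys}
    if mset.level == RAW256:
        for ctx, m in mset.items():
            out[pooled_key(ctx, scheme)] += m
    elif mset.level == COMPLEMENT_COMBINED:
        for ctx, m in mset.items():
            partner = revcomp_context(ctx)
            out[pooled_key(ctx, scheme)] += m
            out[pooled_key(partner, scheme)] += complement_matrix(m)
    else:
        raise ValueError(f"cannot pool a set at level {mset.level!r}")
    level = POOLED48_AT if scheme == "AT" else POOLED48_RY
    return ContextMatrixSet(out, level=level)


def to_rate_matrix(counts: np.ndarray, pseudocount: bool = True) -> np.ndarray:
    """Row-normalize counts into a stochastic matrix Pi.

    With ``pseudocount`` on, off-diagonal zero cells receive a single count
    before normalization (so the chain is irreducible). A row that is wholly
    empty *before* pseudocounting becomes an identity (absorbing) row.
    """
    m = np.asarray(counts, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("counts must be 4x4")
    if m.sum() == 0:
        raise ValueError("cannot normalize an all-zero count matrix")
    empty = m.sum(axis=1) == 0
    if pseudocount:
        off = ~np.eye(4, dtype=bool)
        m = m.copy()
        m[off & (m == 0) & ~empty[:, None]] = 1.0
    pi = np.zeros((4, 4))
    pi[empty] = np.eye(4)[empty]
    rows = ~empty
    pi[rows] = m[rows] / m[rows].sum(axis=1, keepdims=True)
    return pi


@dataclass
class StationaryVector:
    """Equilibrium base frequencies Phi of a row-stochastic matrix."""

    frequencies: np.ndarray  # A, C, G, T, sums to 1
    context: str | None = None
    gc_percent: float = field(init=False)
    pr_at: float = field(init=False)  # 100 * A / (A + T)
    pr_gc: float = field(init=False)  # 100 * G / (G + C)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("frequencies must be a length-4 probability vector")
        self.frequencies = f
        a, c, g, t = f
        self.gc_percent = 100.0 * (g + c)
        self.pr_at = 100.0 * a / (a + t) if a + t > 0 else float("nan")
        self.pr_gc = 100.0 * g / (g + c) if g + c > 0 else float("nan")

    def __getitem__(self, base: str) -> float:
        return float(self.frequencies[BASE_INDEX[base]])


def stationary_vector(
    pi: np.ndarray,
    context: str | None = None,
    tol: float = 1e-12,
    max_doublings: int = 200,
) -> StationaryVector:
    """Stationary vector by repeated squaring of Pi.

    Pi^t for large t has identical rows, each equal to Phi. Squaring doubles
    t each step, so the cap of 200 doublings corresponds to t = 2^200 and is
    never reached for an irreducible aperiodic 4-state chain.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4, 4) or np.abs(pi.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("pi must be a 4x4 row-stochastic matrix")
    m = pi.copy()
    for _ in range(max_doublings):
        nxt = m @ m
        nxt /= nxt.sum(axis=1, keepdims=True)  # guard drift
        if np.abs(nxt - nxt[0]).max() < tol and np.abs(nxt - m).max() < tol:
            phi = nxt.mean(axis=0)
            phi /= phi.sum()
            if np.abs(phi @ pi - phi).max() > 1e-8:
                break
            return StationaryVector(phi, context=context)
        m = nxt
    where = f" for context {context}" if context else ""
    raise RuntimeError(f"stationary vector did not converge{where}")


def stationary_set(
    mset: ContextMatrixSet, pseudocount: bool = True
) -> dict[str, StationaryVector]:
    """Stationary vector of every matrix in a set (keys preserved)."""
    return {
        key: stationary_vector(to_rate_matrix(m, pseudocount=pseudocount), key)
        for key, m in mset.items()
        if m.sum() > 0
    }


def stationary_lookup(mset: ContextMatrixSet, pseudocount: bool = True):
    """Return ``ctx -> frequency vector`` resolving any set level.

    For complement-combined sets a non-canonical context is served by the
    complement-permuted stationary of its canonical partner; for pooled sets
    the context is reduced to its pooling key first.
    """
    stat = {k: sv.frequencies for k, sv in stationary_set(mset, pseudocount).items()}
    level = mset.level

    def lookup(ctx: str) -> np.ndarray:
        if level == RAW256:
            key, flip = ctx, False
        elif level == COMPLEMENT_COMBINED:
            key = canonical_context(ctx)
            flip = key != ctx
        elif level in (POOLED48_AT, POOLED48_RY):
            scheme = "AT" if level == POOLED48_AT else "RY"
            key, flip = pooled_key(ctx, scheme), False
        else:
            raise ValueError(f"unknown set level {level!r}")
        try:
            phi = stat[key]
        except KeyError:
            raise KeyError(
                f"no stationary vector available for context {ctx!r} (key {key!r})"
            ) from None
        return phi[COMPLEMENT_INDEX] if flip else phi

    return lookup
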