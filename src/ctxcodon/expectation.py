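"""Context-dependent neutral expectations of codon usage for a gene.

The tetranucleotide context of a third codon position is the first two
bases of that codon and the first two bases of the downstream codon, so it
is fixed by the amino-acid sequence (and, for sixfold amino acids, by the
subgroup the observed codon sits in). Given per-context equilibrium base
frequencies, each degenerate third position gets the stationary vector of
its context restricted and renormalized to the synonymous bases; summing
those positional vectors yields a real-valued expected codon usage from
which the context-dependent expectations ENC_CD, PR-AT_CD, PR-GC_CD,
C2_CD and CAI_CD are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codonstats import (
    CodonFitnessTable,
    N_CODONS,
    c2_batch,
    cai_batch,
    enc_batch,
    gc3,
    pr_at_batch,
    pr_gc_batch,
)
from .genetics import (
    BASE_INDEX,
    BASES,
    CODON_INDEX,
    COMPLEMENT_INDEX,
    STOP_CODONS,
    synonymous_third_bases,
    translate,
)
from .matrices import (
    ContextMatrixSet,
    StationaryVector,
    canonical_context,
    pooled_key,
    stationary_lookup,
)


def third_position_context(gene: str, codon_index: int) -> str:
    """Context of a third codon position, read off the nucleotide sequence:
    the codon's first two bases, then the downstream codon's first two."""
    gene = gene.upper()
    n_codons = len(gene) // 3
    if len(gene) % 3:
        raise ValueError("gene length must be a multiple of 3")
    if not 0 <= codon_index < n_codons:
        raise IndexError(f"codon index {codon_index} out of range")
    if codon_index == n_codons - 1:
        raise ValueError(
            f"terminal codon {codon_index} has no downstream context; skip it"
        )
    i = 3 * codon_index
    return f"{gene[i]}{gene[i + 1]}_{gene[i + 3]}{gene[i + 4]}"


@dataclass(frozen=True)
class DegenerateSite:
    codon_index: int
    context: str
    third_bases: str  # synonymous third bases, subset of ACGT
    codon_ids: tuple[int, ...]  # codon index of prefix+base, same order
    base_ids: tuple[int, ...]


@dataclass
class GeneSiteStructure:
    """Decomposition of a CDS into fixed codons and degenerate third positions.

    Degenerate positions whose downstream codon exists in the nucleotide
    sequence (a stop codon counts: its first two bases are observed) carry a
    context; the final codon when nothing follows it, and all nondegenerate
    codons, are fixed and contribute point counts.
    """

    gene_id: str
    codons: tuple[str, ...]  # sense codons in order
    fixed_counts: np.ndarray
    sites: tuple[DegenerateSite, ...]

    @property
    def n_codons(self) -> int:
        return len(self.codons)


def build_site_structure(gene: str, gene_id: str = "gene") -> GeneSiteStructure:
    gene = gene.upper()
    translate(gene)  # validates frame and internal stops
    all_codons = [gene[i : i + 3] for i in range(0, len(gene), 3)]
    stop = all_codons[-1] if all_codons and all_codons[-1] in STOP_CODONS else None
    sense = all_codons[:-1] if stop else all_codons
    fixed = np.zeros(N_CODONS)
    sites = []
    for i, codon in enumerate(sense):
        syn = synonymous_third_bases(codon)
        if i < len(sense) - 1:
            downstream = sense[i + 1][:2]
        elif stop is not None:
            downstream = stop[:2]
        else:
            downstream = None
        if len(syn) == 1 or downstream is None:
            fixed[CODON_INDEX[codon]] += 1
            continue
        prefix = codon[:2]
        sites.append(
            DegenerateSite(
                codon_index=i,
                context=f"{prefix}_{downstream}",
                third_bases=syn,
                codon_ids=tuple(CODON_INDEX[prefix + b] for b in syn),
                base_ids=tuple(BASE_INDEX[b] for b in syn),
            )
        )
    return GeneSiteStructure(gene_id, tuple(sense), fixed, tuple(sites))


def as_stationary_lookup(stationaries):
    """Normalize the accepted forms of a stationary-vector source into a
    ``ctx -> length-4 frequency array`` callable."""
    if isinstance(stationaries, ContextMatrixSet):
        return stationary_lookup(stationaries)
    if callable(stationaries):
        return stationaries

    def _freq(phi) -> np.ndarray:
        if isinstance(phi, StationaryVector):
            return phi.frequencies
        return np.asarray(phi, dtype=float)

    def lookup(ctx: str) -> np.ndarray:
        # direct key, then pooled key, then the complement-combined canonical
        # partner (whose vector is served complement-permuted)
        if ctx in stationaries:
            return _freq(stationaries[ctx])
        for scheme in ("AT", "RY"):
            key = pooled_key(ctx, scheme)
            if key in stationaries:
                return _freq(stationaries[key])
        canon = canonical_context(ctx)
        if canon != ctx and canon in stationaries:
            return _freq(stationaries[canon])[COMPLEMENT_INDEX]
        raise KeyError(f"no stationary vector for context {ctx!r}")

    return lookup


def restricted_distribution(phi: np.ndarray, base_ids) -> np.ndarray:
    """Stationary frequencies restricted to the synonymous bases, renormalized."""
    p = np.asarray(phi, dtype=float)[list(base_ids)]
    total = p.sum()
    if total <= 0:
        raise ValueError("stationary vector puts zero mass on all synonymous bases")
    return p / total


@dataclass
class GeneNeutralExpectation:
    gene_id: str
    expected_counts: np.ndarray  # real-valued expected codon usage, length 61
    positional: tuple  # (codon_index, context, {base: prob})
    enc_cd: float
    pr_at_cd: float
    pr_gc_cd: float
    c2_cd: float
    expected_gc3: float
    cai_cd: float = field(default=float("nan"))


def expected_codon_usage(
    gene: str,
    stationaries,
    fitness: CodonFitnessTable | None = None,
    gene_id: str = "gene",
) -> GeneNeutralExpectation:
    """Deterministic context-dependent expectation of a gene's codon usage."""
    struct = build_site_structure(gene, gene_id)
    lookup = as_stationary_lookup(stationaries)
    counts = struct.fixed_counts.copy()
    positional = []
    for site in struct.sites:
        p = restricted_distribution(lookup(site.context), site.base_ids)
        counts[list(site.codon_ids)] += p
        positional.append(
            (site.codon_index, site.context, dict(zip(site.third_bases, p)))
        )
    row = counts[None, :]
    return GeneNeutralExpectation(
        gene_id=gene_id,
        expected_counts=counts,
        positional=tuple(positional),
        enc_cd=float(enc_batch(row, finite_n=False)[0]),
        pr_at_cd=float(pr_at_batch(row)[0]),
        pr_gc_cd=float(pr_gc_batch(row)[0]),
        c2_cd=float(c2_batch(row)[0]),
        expected_gc3=gc3(counts),
        cai_cd=(
            float(cai_batch(row, fitness)[0]) if fitness is not None else float("nan")
        ),
    )
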