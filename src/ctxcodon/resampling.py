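"""Nested matrix-and-codon resampling test of observed codon usage.

The null hypothesis is that a gene's codon usage arises from context-
dependent mutation bias plus drift alone. The outer loop resamples every
pooled substitution matrix (per-row multinomial redraw of the off-diagonal
counts, diagonals fixed) to propagate matrix sampling error, recomputes the
per-context equilibrium vectors, and the inner loop draws synonymous
sequences for the gene's amino-acid scaffold from those equilibria. Four
statistics -- ENC, CAI, PR-AT at fourfold degenerate sites and C2 -- are
computed on every draw with the same code paths used for the observed gene,
and the observed values are placed on the pooled null distribution as
z-scores. |z| above the threshold (default 3.5, a Bonferroni-style 5%
cutoff) flags a significant departure from the neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codonstats import (
    CodonFitnessTable,
    CodonUsageTable,
    c2_batch,
    cai_batch,
    enc_batch,
    pr_at_batch,
)
from .expectation import (
    as_stationary_lookup,
    build_site_structure,
    restricted_distribution,
)
from .matrices import (
    POOLED48_AT,
    POOLED48_RY,
    ContextMatrixSet,
    pooled_key,
    stationary_vector,
    to_rate_matrix,
)

STATISTICS = ("ENC", "CAI", "PR_AT", "C2")


def resample_matrix(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Redraw each row's off-diagonal counts from a multinomial with the
    row's original off-diagonal total and relative probabilities; the
    diagonal (conserved sites) is kept fixed."""
    counts = np.asarray(counts, dtype=np.int64)
    out = np.diag(np.diag(counts)).astype(np.int64)
    for i in range(4):
        row = counts[i].astype(float)
        row[i] = 0.0
        total = int(row.sum())
        if total == 0:
            continue
        out[i] += rng.multinomial(total, row / row.sum())
    return out


def sample_neutral_sequence(gene: str, stationaries, rng: np.random.Generator) -> str:
    """One synonymous resample of ``gene``: every degenerate third position is
    drawn independently from its context's restricted equilibrium vector;
    nondegenerate codons, the terminal codon and any stop are copied."""
    gene = gene.upper()
    struct = build_site_structure(gene)
    lookup = as_stationary_lookup(stationaries)
    seq = list(gene)
    for site in struct.sites:
        p = restricted_distribution(lookup(site.context), site.base_ids)
        choice = rng.choice(len(p), p=p)
        seq[3 * site.codon_index + 2] = site.third_bases[choice]
    return "".join(seq)


@dataclass
class ResamplingDistribution:
    statistic: str
    draws: np.ndarray
    observed: float
    mean: float
    sd: float
    z: float
    threshold: float
    significant: bool

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _scheme_of(matrix_set: ContextMatrixSet) -> str:
    if matrix_set.level == POOLED48_AT:
        return "AT"
    if matrix_set.level == POOLED48_RY:
        return "RY"
    raise ValueError(
        f"nested resampling expects a pooled 48-matrix set, got {matrix_set.level!r}"
    )


def nested_resampling_test(
    gene: str,
    matrix_set: ContextMatrixSet,
    fitness: CodonFitnessTable,
    n_outer: int = 100,
    n_inner: int = 100,
    threshold: float = 3.5,
    seed: int | np.random.Generator | None = None,
    gene_id: str = "gene",
) -> dict[str, ResamplingDistribution]:
    """Full nested test of one gene against a pooled 48-matrix set."""
    scheme = _scheme_of(matrix_set)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    struct = build_site_structure(gene, gene_id)
    observed_counts = CodonUsageTable.from_sequence(gene, gene_id).counts

    sites = struct.sites
    n_sites = len(sites)
    site_keys = [pooled_key(s.context, scheme) for s in sites]
    needed = sorted(set(site_keys))
    key_index = {k: i for i, k in enumerate(needed)}
    site_key_idx = np.array([key_index[k] for k in site_keys], dtype=np.int64)
    base_counts = np.array([len(s.base_ids) for s in sites])
    max_b = int(base_counts.max()) if n_sites else 1
    site_base_ids = np.zeros((n_sites, max_b), dtype=np.int64)
    site_codon_ids = np.zeros((n_sites, max_b), dtype=np.int64)
    for j, s in enumerate(sites):
        site_base_ids[j, : len(s.base_ids)] = s.base_ids
        site_codon_ids[j, : len(s.codon_ids)] = s.codon_ids
        site_codon_ids[j, len(s.codon_ids) :] = s.codon_ids[-1]
    pad = np.arange(max_b)[None, :] >= base_counts[:, None]

    needed_counts = [np.asarray(matrix_set[k]) for k in needed]

    draws = {name: [] for name in STATISTICS}
    for _ in range(n_outer):
        # outer: resample matrices, recompute equilibria (pseudocounts on)
        phis = np.empty((len(needed), 4))
        for m_i, counts in enumerate(needed_counts):
            res = resample_matrix(counts, rng)
            phis[m_i] = stationary_vector(to_rate_matrix(res, pseudocount=True)).frequencies
        if n_sites:
            p = phis[site_key_idx[:, None], site_base_ids]  # (n_sites, max_b)
            p[pad] = 0.0
            p /= p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            cum[:, -1] = 1.0
            u = rng.random((n_inner, n_sites))
            choice = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
            cids = site_codon_ids[np.arange(n_sites)[None, :], choice]
            flat = (np.arange(n_inner)[:, None] * 61 + cids).ravel()
            counts_mat = np.bincount(flat, minlength=n_inner * 61).reshape(
                n_inner, 61
            ) + struct.fixed_counts[None, :]
        else:
            counts_mat = np.repeat(struct.fixed_counts[None, :], n_inner, axis=0)
        draws["ENC"].append(enc_batch(counts_mat, finite_n=True))
        draws["CAI"].append(cai_batch(counts_mat, fitness))
        draws["PR_AT"].append(pr_at_batch(counts_mat))
        draws["C2"].append(c2_batch(counts_mat))

    obs_row = observed_counts[None, :]
    observed = {
        "ENC": float(enc_batch(obs_row, finite_n=True)[0]),
        "CAI": float(cai_batch(obs_row, fitness)[0]),
        "PR_AT": float(pr_at_batch(obs_row)[0]),
        "C2": float(c2_batch(obs_row)[0]),
    }

    results = {}
    for name in STATISTICS:
        values = np.concatenate(draws[name])
        finite = values[~np.isnan(values)]
        mean = float(finite.mean()) if finite.size else float("nan")
        sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        obs = observed[name]
        z = (obs - mean) / sd if sd > 0 else float("nan")
        results[name] = ResamplingDistribution(
            statistic=name,
            draws=values,
            observed=obs,
            mean=mean,
            sd=sd,
            z=float(z),
            threshold=threshold,
            significant=bool(sd > 0 and abs(z) > threshold),
        )
    return results
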