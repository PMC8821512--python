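"""Context matrix aggregation, complement combination, pooling, equilibria."""

import itertools

import numpy as np
import pytest
import scipy.linalg

import ctxcodon as cc
from ctxcodon.matrices import (
    ALL_CONTEXTS,
    canonical_context,
    complement_matrix,
    pooled_key,
    pooled_keys,
    revcomp_context,
    stationary_lookup,
)
from ctxcodon.scoring import SiteObservation


def test_revcomp_context_partner():
    assert revcomp_context("AG_GA") == "TC_CT"
    assert revcomp_context("TC_CT") == "AG_GA"
    assert canonical_context("TC_CT") == "AG_GA"
    # self-complementary contexts are their own partner
    assert revcomp_context("AG_CT") == "AG_CT"
    n_self = sum(revcomp_context(c) == c for c in ALL_CONTEXTS)
    assert n_self == 16


def test_count_contexts_empty_and_single():
    empty = cc.count_contexts([])
    assert len(list(empty.keys())) == 256
    assert empty.total_counts() == 0
    one = cc.count_contexts(
        [SiteObservation(10, "AG_GA", "A", "G")]
    )
    m = one["AG_GA"]
    assert m[0, 2] == 1 and m.sum() == 1
    assert one.total_substitutions() == 1


def test_scored_context_totals_match_sequence_composition():
    """Under a uniform context-free model, every context is equally likely
    among scored sites."""
    model = cc.make_preset_model("null_uniform", seed=3)
    obs = cc.extract_site_observations(cc.simulate_triplet(model, 400_000, seed=9))
    totals = np.array([cc.count_contexts(obs)[c].sum() for c in ALL_CONTEXTS])
    expected = totals.sum() / 256
    assert np.abs(totals / expected - 1).max() < 0.12


def test_complement_combine_forced_example():
    raw = cc.count_contexts(
        [
            SiteObservation(0, "AG_GA", "A", "G"),
            SiteObservation(1, "TC_CT", "T", "C"),
        ]
    )
    combined = cc.complement_combine(raw)
    assert "TC_CT" not in combined
    assert combined["AG_GA"][0, 2] == 2  # T->C complements to A->G


def test_complement_combine_conserves_and_projects(simulated_raw256):
    combined = cc.complement_combine(simulated_raw256)
    assert len(list(combined.keys())) == 136  # 120 pairs + 16 self-complementary
    assert combined.total_counts() == simulated_raw256.total_counts()
    twice = cc.complement_combine(combined)
    for k in combined.keys():
        assert np.array_equal(twice[k], combined[k])


def test_complement_combine_strand_symmetry():
    """Pre-complementing every raw matrix and swapping keys leaves the
    combined set unchanged."""
    rng = np.random.default_rng(5)
    raw = cc.ContextMatrixSet(
        {c: rng.integers(0, 20, size=(4, 4)) for c in ALL_CONTEXTS}, level="raw256"
    )
    mirrored = cc.ContextMatrixSet(
        {revcomp_context(c): complement_matrix(raw[c]) for c in ALL_CONTEXTS},
        level="raw256",
    )
    a = cc.complement_combine(raw)
    b = cc.complement_combine(mirrored)
    for k in a.keys():
        if revcomp_context(k) == k:
            # self-complementary contexts pass through unchanged, so the
            # mirrored set carries their complement-transformed counts
            assert np.array_equal(complement_matrix(a[k]), b[k])
        else:
            assert np.array_equal(a[k], b[k])


def _brute_force_members(key: str, scheme: str):
    return {c for c in ALL_CONTEXTS if pooled_key(c, scheme) == key}


def test_pooling_member_lists_by_enumeration():
    assert _brute_force_members("G_G|AT=2", "AT") == {
        "AG_GA",
        "TG_GA",
        "TG_GT",
        "AG_GT",
    }
    for scheme in ("AT", "RY"):
        sizes = sorted(
            len(_brute_force_members(k, scheme)) for k in pooled_keys(scheme)
        )
        assert sizes == [4] * 32 + [8] * 16
        # every context belongs to exactly one key
        assert sum(sizes) == 256


def test_pooling_conserves_counts(simulated_raw256):
    for scheme in ("AT", "RY"):
        pooled = cc.pool_matrices(simulated_raw256, scheme=scheme)
        assert len(list(pooled.keys())) == 48
        assert pooled.total_counts() == simulated_raw256.total_counts()
        assert pooled.total_substitutions() == simulated_raw256.total_substitutions()
        # pooled matrix equals the brute-force sum of its members
        for key in itertools.islice(pooled.keys(), 6):
            members = _brute_force_members(key, scheme)
            expected = sum(simulated_raw256[c] for c in members)
            assert np.array_equal(pooled[key], expected)


def test_pooling_combined_input_gives_mirrored_keys(simulated_raw256):
    pooled = cc.pool_matrices(cc.complement_combine(simulated_raw256), scheme="AT")
    for key in pooled.keys():
        a, rest = key.split("_", 1)
        b, cls = rest.split("|")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mirror = f"{comp[b]}_{comp[a]}|{cls}"
        assert np.array_equal(pooled[key], complement_matrix(pooled[mirror]))


def test_unknown_pooling_scheme():
    with pytest.raises(ValueError, match="scheme"):
        pooled_key("AG_GA", "XY")


def test_to_rate_matrix_pseudocount():
    counts = np.zeros((4, 4), dtype=int)
    counts[0] = [98, 1, 1, 0]
    counts[1, 1] = counts[2, 2] = counts[3, 3] = 10
    pi = cc.to_rate_matrix(counts, pseudocount=True)
    np.testing.assert_allclose(pi[0], np.array([98, 1, 1, 1]) / 101, atol=1e-12)
    assert np.allclose(pi.sum(axis=1), 1, atol=1e-12)


def test_to_rate_matrix_diagonal_only_identity():
    pi = cc.to_rate_matrix(np.diag([5, 5, 5, 5]), pseudocount=False)
    np.testing.assert_array_equal(pi, np.eye(4))


def test_to_rate_matrix_all_zero_errors():
    with pytest.raises(ValueError, match="all-zero"):
        cc.to_rate_matrix(np.zeros((4, 4)))


@pytest.mark.parametrize("ctx", ["CC_CC", "CC_AA", "AA_AA"])
def test_reference_stationary_vectors(ctx, reference_matrices, reference_equilibria):
    sv = cc.stationary_vector(cc.to_rate_matrix(reference_matrices[ctx]), ctx)
    np.testing.assert_allclose(
        sv.frequencies * 100, reference_equilibria[ctx], atol=0.1
    )


def test_stationary_uniform_offdiagonals():
    pi = np.full((4, 4), 0.02)
    np.fill_diagonal(pi, 0.94)
    sv = cc.stationary_vector(pi)
    np.testing.assert_allclose(sv.frequencies, 0.25, atol=1e-10)


def test_stationary_detailed_balance_closed_form():
    """P(i->j) = 0.1*pi_j has stationary exactly pi; cross-checked against a
    brute-force eigen decomposition."""
    target = np.array([0.4, 0.3, 0.2, 0.1])
    pi = 0.1 * np.tile(target, (4, 1))
    np.fill_diagonal(pi, 0)
    np.fill_diagonal(pi, 1 - pi.sum(axis=1))
    sv = cc.stationary_vector(pi)
    np.testing.assert_allclose(sv.frequencies, target, atol=1e-10)
    w, vl = scipy.linalg.eig(pi, left=True, right=False)
    lead = np.argmin(np.abs(w - 1))
    eig_phi = np.real(vl[:, lead])
    eig_phi /= eig_phi.sum()
    np.testing.assert_allclose(sv.frequencies, eig_phi, atol=1e-9)


def test_stationary_fixed_point_on_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(25):
        m = rng.random((4, 4)) + 0.01
        pi = m / m.sum(axis=1, keepdims=True)
        phi = cc.stationary_vector(pi).frequencies
        assert np.abs(phi @ pi - phi).max() < 1e-8


def test_stationary_vector_derived_quantities():
    sv = cc.StationaryVector(np.array([0.3, 0.2, 0.2, 0.3]))
    assert sv.pr_at == 50.0 and sv.pr_gc == 50.0
    assert sv.gc_percent == pytest.approx(40.0)
    rng = np.random.default_rng(4)
    for _ in range(50):
        f = rng.dirichlet(np.ones(4))
        sv = cc.StationaryVector(f)
        assert 0 <= sv.pr_at <= 100 and 0 <= sv.pr_gc <= 100
        flipped = cc.StationaryVector(f[[3, 2, 1, 0]])
        assert sv.pr_at + flipped.pr_at == pytest.approx(100.0)
        assert sv.pr_gc + flipped.pr_gc == pytest.approx(100.0)


def test_stationary_lookup_resolves_all_levels(simulated_raw256):
    combined = cc.complement_combine(simulated_raw256)
    pooled = cc.pool_matrices(simulated_raw256, scheme="AT")
    for mset in (simulated_raw256, combined, pooled):
        lookup = stationary_lookup(mset)
        phi = lookup("TC_CT")
        assert phi.shape == (4,) and abs(phi.sum() - 1) < 1e-9
    # the combined set serves a non-canonical context with the complemented
    # stationary of its partner
    lookup = stationary_lookup(combined)
    np.testing.assert_allclose(
        lookup("TC_CT"), lookup("AG_GA")[[3, 2, 1, 0]], atol=1e-12
    )
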