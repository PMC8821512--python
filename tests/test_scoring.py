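"""Site classification, window filters and triplet scoring."""

import numpy as np
import pytest

import ctxcodon as cc
from ctxcodon.scoring import FOURFOLD_ONLY, SiteFilterConfig, classify_site


@pytest.mark.parametrize(
    "in1,in2,out,kind,anc,der",
    [
        ("A", "A", "A", "conserved", "A", "A"),
        ("A", "A", "G", "conserved", "A", "A"),  # outgroup state irrelevant
        ("A", "G", "A", "substitution", "A", "G"),
        ("G", "A", "A", "substitution", "A", "G"),
        ("A", "G", "C", "ignored", None, None),  # all three differ
        ("A", "-", "A", "ignored", None, None),
        ("-", "A", "A", "ignored", None, None),
        ("A", "A", "-", "ignored", None, None),
    ],
)
def test_classify_site(in1, in2, out, kind, anc, der):
    call = classify_site(in1, in2, out)
    assert call.kind == kind
    assert call.ancestral == anc and call.derived == der


def _triplet(s1, s2, s3):
    return cc.AlignedTriplet(s1, s2, s3)


def test_window_filter_perfect_window():
    seq = "ACGTACGTACGTACGTACGT"
    trip = _triplet(seq, seq, seq)
    assert cc.site_passes_filters(trip, 10, SiteFilterConfig())


def test_window_filter_too_few_ungapped_pairs():
    # 7 ungapped-pair columns in the 10-column window around position 10
    s1 = list("ACGTACGTACGTACGTACGT")
    s2 = list("ACGTACGTACGTACGTACGT")
    for i in (5, 7, 12):
        s2[i] = "-"
    trip = _triplet("".join(s1), "".join(s2), "ACGTACGTACGTACGTACGT")
    assert not cc.site_passes_filters(trip, 10, SiteFilterConfig())


def test_window_filter_similarity_below_threshold():
    # 8 ungapped pairs of which 5 identical: 62.5% < 70%
    s1 = list("AAAAAAAAAAAAAAAAAAAA")
    s2 = list(s1)
    s2[5] = s2[6] = "-"  # 8 ungapped pairs remain in the window around 10
    for i in (7, 8, 9):
        s2[i] = "C"  # 3 mismatches -> 5/8 identical
    trip = _triplet("".join(s1), "".join(s2), "".join(s1))
    assert not cc.site_passes_filters(trip, 10, SiteFilterConfig())


def test_window_filter_similarity_at_threshold_passes():
    s1 = list("A" * 21)
    s2 = list(s1)
    for i in (7, 8, 9):
        s2[i] = "C"  # 10 ungapped, 7 identical = 70% exactly
    trip = _triplet("".join(s1), "".join(s2), "".join(s1))
    assert cc.site_passes_filters(trip, 10, SiteFilterConfig())


def test_position_out_of_range():
    trip = _triplet("ACGT", "ACGT", "ACGT")
    with pytest.raises(IndexError):
        cc.site_passes_filters(trip, 4, SiteFilterConfig())


def test_identical_triplet_yields_interior_conserved_sites():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 100))
    trip = _triplet(seq, seq, seq)
    obs = cc.extract_site_observations(trip)
    # brute-force expectation: a column needs a full 2+2 context (so columns
    # 2..97) and at least 8 flanking columns in its end-truncated window,
    # which drops columns 2 and 97 (windows of size 7)
    expected = [
        i
        for i in range(2, 98)
        if min(i, 5) + min(99 - i, 5) >= 8
    ]
    assert len(obs) == len(expected) == 94
    assert list(obs.positions) == expected
    assert obs.n_substitutions == 0
    for o in obs:
        assert o.ancestral == o.derived == seq[o.alignment_position]


def test_short_alignment_is_skipped_entirely():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 70))
    trip = _triplet(seq, seq, seq)
    assert len(cc.extract_site_observations(trip)) == 0
    seq = "".join(rng.choice(list("ACGT"), 71))
    trip = _triplet(seq, seq, seq)
    assert len(cc.extract_site_observations(trip)) > 0


def test_substitution_next_to_unconserved_context_not_scored():
    base = "ACGT" * 30
    s1 = list(base)
    s2 = list(base)
    s2[50] = "G" if s1[50] != "G" else "A"  # ingroup difference
    s2[51] = "C" if s1[51] != "C" else "T"  # context column not conserved
    trip = _triplet("".join(s1), "".join(s2), base)
    obs = cc.extract_site_observations(trip)
    assert obs.n_substitutions == 0


def test_substitution_scored_with_outgroup_polarity():
    base = "ACGT" * 30
    s2 = list(base)
    s2[50] = "A"  # base[50] == 'G'
    trip = _triplet(base, "".join(s2), base)
    obs = cc.extract_site_observations(trip)
    subs = [o for o in obs if o.ancestral != o.derived]
    assert len(subs) == 1
    assert subs[0].ancestral == "G" and subs[0].derived == "A"
    assert subs[0].alignment_position == 50
    assert subs[0].context == "AC_TA"


def test_ingroup_swap_leaves_observations_unchanged():
    model = cc.make_preset_model("table1_like", seed=4, indel_rate=0.001)
    trip = cc.simulate_triplet(model, 5000, seed=21)
    swapped = cc.AlignedTriplet(trip.ingroup2, trip.ingroup1, trip.outgroup)
    a = cc.extract_site_observations(trip)
    b = cc.extract_site_observations(swapped)
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.context_codes, b.context_codes)
    np.testing.assert_array_equal(a.ancestral_idx, b.ancestral_idx)
    np.testing.assert_array_equal(a.derived_idx, b.derived_idx)


def test_emitted_context_matches_alignment():
    model = cc.make_preset_model("at_context", seed=6, indel_rate=0.002)
    trip = cc.simulate_triplet(model, 20000, seed=13)
    obs = cc.extract_site_observations(trip)
    seqs = trip.sequences
    for o in list(obs)[::37]:
        i = o.alignment_position
        for s in seqs:
            assert s[i - 2] + s[i - 1] + "_" + s[i + 1] + s[i + 2] == o.context


def test_null_substitution_fraction_matches_branch_lengths():
    """Scored substitution fraction approximates the summed ingroup branch
    lengths under the context-free model."""
    model = cc.make_preset_model(
        "null_uniform", seed=1, branch_lengths=(0.004, 0.004, 0.006, 0.002)
    )
    trip = cc.simulate_triplet(model, 1_000_000, seed=3)
    obs = cc.extract_site_observations(trip)
    frac = obs.n_substitutions / len(obs)
    assert 0.006 <= frac <= 0.010


def test_fourfold_mode_requires_frame_and_scores_only_fourfold_thirds():
    # Ala-Ala-Ala... CDS: every third position fourfold degenerate
    seq = "GCA" * 50
    trip = _triplet(seq, seq, seq)
    config = SiteFilterConfig(site_class=FOURFOLD_ONLY)
    with pytest.raises(ValueError, match="frame"):
        cc.extract_site_observations(trip, config)
    obs = cc.extract_site_observations(trip, config, frame_annotation="cds")
    assert len(obs) > 0
    assert all(o.alignment_position % 3 == 2 for o in obs)
    # Lys (AAA) codons: third position is not fourfold degenerate
    seq2 = "AAA" * 50
    trip2 = _triplet(seq2, seq2, seq2)
    assert len(cc.extract_site_observations(trip2, config, frame_annotation="cds")) == 0
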