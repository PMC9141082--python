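"""Signal profiles, dissimilarity pseudometric and similarity dendrogram."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import karyofish as kf
from karyofish.errors import MeasurementError
from karyofish.profiles import SignalProfile
from karyofish.signals import CATEGORIES


def _profile(draw_tuple):
    n_pairs, cats, hetero = draw_tuple
    counts = {c: v for c, v in zip(CATEGORIES, cats) if v}
    total = sum(counts.values())
    return SignalProfile("p", min(n_pairs, total), counts, hetero)


profile_strategy = st.builds(
    _profile,
    st.tuples(
        st.integers(min_value=0, max_value=6),
        st.tuples(*[st.integers(min_value=0, max_value=6)] * 4),
        st.integers(min_value=0, max_value=3),
    ),
)


def test_profiles_from_fixtures_match_reported_pair_counts(fixtures_by_id):
    expected = {
        "robinia_pseudoacacia": 4,
        "robinia_pseudoacacia_idaho": 3,
        "robinia_pseudoacacia_decaisneana": 4,
        "styphnolobium_japonicum": 1,
        "amorpha_fruticosa": 2,
    }
    for sid, fixture in fixtures_by_id.items():
        profile = kf.profile_from_fixture(fixture)
        assert profile.n_pairs_5s == expected[sid], sid
    idaho = kf.profile_from_fixture(
        fixtures_by_id["robinia_pseudoacacia_idaho"])
    assert idaho.heteromorphic_pairs == 1


def test_profile_from_measured_spread_matches_fixture_profile(rp_run,
                                                              rp_masks):
    det = kf.detect_signals(rp_run.image, rp_masks)
    measured = kf.measure_spread(rp_masks, rp_run.image.pixel_size_um,
                                 "robinia_pseudoacacia")
    paired = kf.pair_homologs(measured, det.sites)
    profile = kf.encode_signal_profile(paired, det.sites)
    assert profile.n_pairs_5s == 4
    assert profile.heteromorphic_pairs == 0
    assert sum(profile.category_counts.values()) == 8


def test_profile_without_sites_is_empty():
    profile = SignalProfile("empty", 0, {}, 0)
    assert profile.n_pairs_5s == 0
    assert profile.category_counts == {}


def test_profile_site_deficit_is_rejected():
    with pytest.raises(MeasurementError):
        SignalProfile("bad", 3, {"centromeric": 2}, 0)


def test_encode_rejects_unknown_chromosome(noise_free_tables):
    table = kf.pair_homologs(noise_free_tables["amorpha_fruticosa"])
    ghost = kf.SignalSite("nonexistent", "TAMRA", "long", 0.5, "strong",
                          1.0, 0.0, 0.0)
    with pytest.raises(MeasurementError, match="unknown chromosome"):
        kf.encode_signal_profile(table, [ghost])


def test_dissimilarity_identity_and_symmetry_on_packaged_profiles(
        fixtures_by_id):
    profiles = [kf.profile_from_fixture(f) for f in fixtures_by_id.values()]
    for p in profiles:
        assert kf.profile_dissimilarity(p, p) == 0.0
        for q in profiles:
            assert kf.profile_dissimilarity(p, q) == kf.profile_dissimilarity(
                q, p)


def test_negative_weights_are_rejected(fixtures_by_id):
    profiles = [kf.profile_from_fixture(f) for f in fixtures_by_id.values()]
    with pytest.raises(MeasurementError):
        kf.profile_dissimilarity(profiles[0], profiles[1],
                                 weights={"n_pairs": -1.0})


@given(p=profile_strategy, q=profile_strategy, r=profile_strategy)
def test_dissimilarity_is_a_pseudometric(p, q, r):
    dpq = kf.profile_dissimilarity(p, q)
    assert dpq >= 0
    assert dpq == kf.profile_dissimilarity(q, p)
    assert kf.profile_dissimilarity(p, p) == 0
    assert dpq <= kf.profile_dissimilarity(p, r) + kf.profile_dissimilarity(
        r, q) + 1e-9


def test_robinia_taxa_are_mutually_closer_than_outgroups(fixtures_by_id):
    by_id = {f.species_id: kf.profile_from_fixture(f)
             for f in fixtures_by_id.values()}
    rp = by_id["robinia_pseudoacacia"]
    dec = by_id["robinia_pseudoacacia_decaisneana"]
    af = by_id["amorpha_fruticosa"]
    assert kf.profile_dissimilarity(rp, dec) < kf.profile_dissimilarity(rp, af)


def test_dendrogram_first_merge_and_robinia_grouping(fixtures_by_id):
    profiles = [kf.profile_from_fixture(f) for f in fixtures_by_id.values()]
    tree = kf.cluster_profiles(profiles, "average")
    merges = tree.merges()
    assert merges[0][0] | merges[0][1] == frozenset(
        {"robinia_pseudoacacia", "robinia_pseudoacacia_decaisneana"}
    )
    robinia = frozenset(s for s in tree.labels if s.startswith("robinia"))
    # monophyly in the merge order: every merged cluster is inside the
    # Robinia trio, disjoint from it, or contains it whole
    clusters = tree.join_order()
    assert robinia in clusters
    for merged in clusters:
        assert (merged <= robinia or not (merged & robinia)
                or robinia <= merged)


def test_two_identical_profiles_merge_at_height_zero():
    p = SignalProfile("a", 2, {"centromeric": 4}, 0)
    q = SignalProfile("b", 2, {"centromeric": 4}, 0)
    tree = kf.cluster_profiles([p, q])
    assert tree.merge_heights() == pytest.approx([0.0])


def test_dendrogram_leaves_are_exactly_the_input_species(fixtures_by_id):
    profiles = [kf.profile_from_fixture(f) for f in fixtures_by_id.values()]
    tree = kf.cluster_profiles(profiles, "single")
    assert set(tree.labels) == set(fixtures_by_id)
    last = tree.merges()[-1]
    assert last[0] | last[1] == frozenset(fixtures_by_id)


def test_newick_round_trips_through_dendropy(fixtures_by_id):
    import dendropy

    profiles = [kf.profile_from_fixture(f) for f in fixtures_by_id.values()]
    tree = kf.cluster_profiles(profiles)
    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    taxa = {leaf.taxon.label.replace(" ", "_")
            for leaf in parsed.leaf_node_iter()}
    assert taxa == set(tree.labels)


def test_clustering_fewer_than_two_profiles_raises():
    with pytest.raises(MeasurementError):
        kf.cluster_profiles([SignalProfile("only", 0, {}, 0)])
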