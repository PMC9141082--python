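"""Karyotype analytics: arm ratios, Levan classes, Stebbins cytotypes,
ordering, pairing and their invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import karyofish as kf
from karyofish.errors import MeasurementError
from karyofish.measurements import ChromosomeMeasurement, MeasurementTable

CLASS_ORDER = ("m", "sm", "st", "t")


def _table(arm_pairs, species="toy"):
    rows = tuple(
        ChromosomeMeasurement(f"{i:02d}", long_arm, short_arm)
        for i, (long_arm, short_arm) in enumerate(arm_pairs, 1)
    )
    return MeasurementTable(species_id=species, rows=rows)


@pytest.mark.parametrize(
    "long_arm, short_arm, expected",
    [(2.0, 2.0, 1.0), (3.0, 1.0, 3.0), (1.0, 3.0, 3.0)],
)
def test_arm_ratio_is_orientation_free(long_arm, short_arm, expected):
    assert kf.arm_ratio(long_arm, short_arm) == pytest.approx(expected)


def test_arm_ratio_rejects_non_positive_arms():
    with pytest.raises(MeasurementError):
        kf.arm_ratio(0.0, 1.0)


@pytest.mark.parametrize(
    "ratio, cls",
    [(1.0, "m"), (1.3, "m"), (1.70, "m"), (1.71, "sm"), (2.2, "sm"),
     (3.00, "sm"), (3.01, "st"), (4.0, "st"), (7.00, "st"), (7.01, "t")],
)
def test_levan_classification_bands(ratio, cls):
    assert kf.classify_levan(ratio) == cls


@given(
    r1=st.floats(min_value=1.0, max_value=20.0),
    r2=st.floats(min_value=1.0, max_value=20.0),
)
def test_levan_classification_is_monotone(r1, r2):
    lo, hi = sorted((r1, r2))
    assert CLASS_ORDER.index(kf.classify_levan(lo)) <= CLASS_ORDER.index(
        kf.classify_levan(hi)
    )


def test_relative_lengths_examples_and_normalization():
    assert kf.relative_lengths(_table([(1.5, 1.5), (1.5, 1.5)])) == pytest.approx(
        [50.0, 50.0]
    )
    assert kf.relative_lengths(_table([(2.0, 1.0), (0.6, 0.4)])) == pytest.approx(
        [75.0, 25.0]
    )
    rng = np.random.default_rng(0)
    arms = [(a + b, a) for a, b in rng.uniform(0.2, 3.0, size=(30, 2))]
    assert kf.relative_lengths(_table(arms)).sum() == pytest.approx(100.0, abs=1e-6)


def test_relative_lengths_empty_table_raises():
    with pytest.raises(MeasurementError):
        kf.relative_lengths(_table([]))


def test_order_by_length_is_idempotent_with_deterministic_ties():
    table = _table([(0.6, 0.4), (2.0, 1.0), (1.2, 0.8)])
    ordered = kf.order_by_length(table)
    assert [r.total_length for r in ordered] == [3.0, 2.0, 1.0]
    assert kf.order_by_length(ordered).rows == ordered.rows
    # all-equal lengths: tie-break by arm ratio, then id
    tied = _table([(1.8, 1.2), (2.0, 1.0), (1.5, 1.5)])
    assert [r.arm_ratio for r in kf.order_by_length(tied)] == sorted(
        r.arm_ratio for r in tied
    )


def test_pair_homologs_recovers_generator_pairs(fixtures_by_id,
                                                noise_free_tables):
    for sid, table in noise_free_tables.items():
        truth = {r.chromosome_id: r.pair_index for r in table}
        shuffled = table.with_rows(
            [ChromosomeMeasurement(r.chromosome_id, r.long_arm, r.short_arm)
             for r in table.rows[::-1]]
        )
        paired = kf.pair_homologs(shuffled)
        groups = {}
        for r in paired:
            groups.setdefault(r.pair_index, []).append(truth[r.chromosome_id])
        assert all(a == b for a, b in groups.values()), sid


def test_pair_homologs_rejects_odd_complements():
    with pytest.raises(MeasurementError, match="diploid"):
        kf.pair_homologs(_table([(1, 1), (1, 1), (1, 1)]))


def test_karyotype_formula_single_metacentric_pair():
    assert kf.karyotype_formula(_table([(1.0, 1.0), (1.0, 1.0)])) == "2n = 2x = 2m"


def test_formulas_for_generated_species_tables(noise_free_tables):
    assert (kf.karyotype_formula(noise_free_tables["amorpha_fruticosa"])
            == "2n = 2x = 38m + 2sm")
    assert (kf.karyotype_formula(noise_free_tables["styphnolobium_japonicum"])
            == "2n = 2x = 14m + 12sm + 2st")


def test_interchromosomal_ratio_examples(noise_free_tables):
    assert kf.interchromosomal_ratio(_table([(1, 1), (1, 1)])) == 1.0
    assert kf.interchromosomal_ratio(
        noise_free_tables["robinia_pseudoacacia"]
    ) == pytest.approx(3.4821, abs=1e-9)


def test_stebbins_cytotype_species_and_boundaries(noise_free_tables):
    assert kf.stebbins_cytotype(
        noise_free_tables["robinia_pseudoacacia_idaho"])[2] == "1A"
    assert kf.stebbins_cytotype(
        noise_free_tables["styphnolobium_japonicum"])[2] == "2B"
    # single metacentric pair is forced to 1A
    assert kf.stebbins_cytotype(_table([(1, 1), (1, 1)]))[2] == "1A"
    # longest/shortest exactly 2 stays in column B
    assert kf.stebbins_cytotype(_table([(1.0, 1.0), (0.5, 0.5)]))[1] == "B"
    # proportion exactly 0.5 stays in row 2 (S. japonicum's borderline)
    half = _table([(1.5, 1.5), (2.2, 0.8)])
    assert kf.stebbins_cytotype(half)[0] == 2


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_descriptors_are_scale_invariant(scale):
    arms = [(2.0, 1.0), (1.2, 0.9), (0.8, 0.25), (0.5, 0.45)]
    base = _table(arms)
    scaled = _table([(a * scale, b * scale) for a, b in arms])
    assert [r.levan_class for r in scaled] == [r.levan_class for r in base]
    assert kf.relative_lengths(scaled) == pytest.approx(
        kf.relative_lengths(base))
    assert kf.interchromosomal_ratio(scaled) == pytest.approx(
        kf.interchromosomal_ratio(base))
    assert kf.stebbins_cytotype(scaled) == kf.stebbins_cytotype(base)


def test_formula_and_cytotype_survive_moderate_noise(fixtures_by_id):
    """Round trip under 2% measurement noise holds in >= 8/10 replicates."""
    for sid, fixture in fixtures_by_id.items():
        ref = kf.analyze_karyotype(kf.generate_measurement_table(fixture))
        hits = 0
        for seed in range(10):
            noisy = kf.generate_measurement_table(fixture, seed=seed,
                                                  noise_cv=0.02)
            res = kf.analyze_karyotype(noisy)
            hits += (res.formula_string == ref.formula_string
                     and res.cytotype == ref.cytotype)
        assert hits >= 8, f"{sid}: only {hits}/10 replicates matched"
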