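import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nullmark.cohort_io import PopulationRecord, ReferencePanel, load_reference_panel
from nullmark.freq_estimation import locus_frequency_from_counts
from nullmark.genetic_distance import (
    DistanceMatrix,
    LocusAlleleProfile,
    average_distance,
    build_matrix,
    nei_distance,
    nei_identity,
    pairwise_entry,
    profiles_from_null_freqs,
)


def profile(q, locus="GSTM1"):
    return LocusAlleleProfile(locus=locus, p=1.0 - q, q=q)


class TestNeiIdentity:
    def test_self_identity_is_one(self):
        a = profile(0.6218)
        assert nei_identity(a, a) == pytest.approx(1.0, abs=1e-15)
        assert nei_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_against_fixed_functional_population(self):
        a = LocusAlleleProfile("GSTM1", p=0.3782, q=0.6218)
        b = profile(0.0)
        expected = 0.3782 / math.sqrt(0.3782**2 + 0.6218**2)
        assert nei_identity(a, b) == pytest.approx(expected, rel=1e-12)
        assert nei_identity(a, b) == pytest.approx(0.5197, abs=5e-5)

    def test_portugal_anchor(self):
        """HWE-derived GSTM1 profiles at f_null 0.3867 vs 0.372 -> D rounds to 0.0003."""
        a = LocusAlleleProfile.from_null_genotype_freq("GSTM1", 0.3867)
        b = LocusAlleleProfile.from_null_genotype_freq("GSTM1", 0.372)
        assert nei_identity(a, b) == pytest.approx(0.99974, abs=5e-6)
        assert round(nei_distance(a, b), 4) == 0.0003

    def test_opposite_fixation_is_infinite(self):
        assert nei_identity(profile(0.0), profile(1.0)) == 0.0
        assert nei_distance(profile(0.0), profile(1.0)) == math.inf

    @given(
        st.floats(0.0, 1.0, allow_nan=False), st.floats(0.0, 1.0, allow_nan=False)
    )
    def test_identity_bounds_and_symmetry(self, qa, qb):
        a, b = profile(qa), profile(qb)
        i_ab, i_ba = nei_identity(a, b), nei_identity(b, a)
        assert i_ab == pytest.approx(i_ba, abs=1e-15)
        assert 0.0 <= i_ab <= 1.0
        d = nei_distance(a, b)
        assert d >= 0.0

    def test_monotone_in_frequency_gap(self):
        """With q_a fixed, D grows as q_b moves away on one side of q_a."""
        a = profile(0.4)
        grid = np.linspace(0.4, 1.0, 61)
        distances = [nei_distance(a, profile(q)) for q in grid]
        assert all(x < y for x, y in zip(distances, distances[1:]) if math.isfinite(y))
        grid_low = np.linspace(0.4, 0.0, 41)
        distances_low = [nei_distance(a, profile(q)) for q in grid_low]
        assert all(x < y for x, y in zip(distances_low, distances_low[1:]))


class TestAverageDistance:
    def test_two_locus_mean(self):
        assert average_distance({"GSTM1": 0.0003, "GSTT1": 0.0452}) == pytest.approx(0.02275)

    def test_single_locus_passthrough(self):
        assert average_distance({"GSTT1": 0.0614}) == 0.0614

    def test_infinite_locus_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            avg = average_distance({"GSTM1": 0.01, "GSTT1": math.inf})
        assert avg == 0.01
        assert "infinite" in caplog.text

    def test_no_finite_loci_errors(self):
        with pytest.raises(ValueError, match="finite"):
            average_distance({"GSTT1": math.inf})


class TestPairwiseEntry:
    def test_missing_locus_is_skipped_and_recorded(self):
        a = profiles_from_null_freqs({"GSTM1": 0.3867, "GSTT1": 0.3267})
        b = profiles_from_null_freqs({"GSTT1": 0.179})  # no GSTM1 published
        entry = pairwise_entry("current", a, "Murcia", b)
        assert entry.loci_skipped == ["GSTM1"]
        assert set(entry.d_per_locus) == {"GSTT1"}
        assert entry.d_average == entry.d_per_locus["GSTT1"]

    def test_no_shared_loci_errors(self):
        a = profiles_from_null_freqs({"GSTM1": 0.4})
        b = profiles_from_null_freqs({"GSTT1": 0.2})
        with pytest.raises(ValueError, match="no shared loci"):
            pairwise_entry("A", a, "B", b)


class TestDistanceMatrix:
    def test_single_population_matrix_is_zero(self):
        panel = ReferencePanel([PopulationRecord("Solo", 10, {"GSTM1": 0.4})])
        m = build_matrix(panel, loci=["GSTM1"])
        assert m.labels == ["Solo"] and m.values.shape == (1, 1) and m.values[0, 0] == 0.0

    def test_equal_frequencies_give_zero_matrix(self):
        panel = ReferencePanel(
            [PopulationRecord(p, 10, {"GSTM1": 0.4, "GSTT1": 0.2}) for p in "ABC"]
        )
        m = build_matrix(panel)
        assert np.allclose(m.values, 0.0, atol=1e-12)

    def test_entries_match_elementwise_recomputation(self, rng):
        panel = ReferencePanel(
            [
                PopulationRecord(f"P{i}", 50, {"GSTM1": f1, "GSTT1": f2})
                for i, (f1, f2) in enumerate(rng.random((6, 2)))
            ]
        )
        m = build_matrix(panel)
        for i, a in enumerate(panel):
            for j, b in enumerate(panel):
                if i == j:
                    continue
                entry = pairwise_entry(
                    a.population,
                    profiles_from_null_freqs(a.null_freq),
                    b.population,
                    profiles_from_null_freqs(b.null_freq),
                )
                assert m.values[i, j] == pytest.approx(entry.d_average, abs=1e-14)

    def test_symmetry_and_zero_diagonal_over_random_panels(self, rng):
        for _ in range(100):
            k = rng.integers(2, 7)
            panel = ReferencePanel(
                [
                    PopulationRecord(f"P{i}", 30, {"L1": f1, "L2": f2})
                    for i, (f1, f2) in enumerate(rng.random((k, 2)))
                ]
            )
            m = build_matrix(panel)
            assert np.allclose(m.values, m.values.T, atol=1e-12)
            assert np.allclose(np.diag(m.values), 0.0)
            assert (m.values >= 0).all()

    def test_populations_missing_a_locus_are_excluded(self, tiny_panel, caplog):
        with caplog.at_level("INFO"):
            m = build_matrix(tiny_panel, loci=["GSTM1", "GSTT1"])
        assert "NoLocus" not in m.labels
        assert set(m.labels) == {"Alpha", "Beta", "NoSize"}

    def test_focal_cohort_joins_matrix(self, tiny_panel):
        focal = [
            locus_frequency_from_counts("GSTM1", 300, 116),
            locus_frequency_from_counts("GSTT1", 300, 98),
        ]
        m = build_matrix(tiny_panel, focal, ["GSTM1", "GSTT1"], focal_label="current")
        assert m.labels[0] == "current"

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_write_read_round_trip(self, tmp_path, tiny_panel):
        import pandas as pd

        m = build_matrix(tiny_panel, loci=["GSTT1"])
        path = tmp_path / "dist.tsv"
        m.write_tsv(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        assert list(frame.index) == m.labels
        assert np.allclose(frame.to_numpy(), m.values)

    def test_phylip_emission(self, tmp_path, tiny_panel):
        m = build_matrix(tiny_panel, loci=["GSTT1"])
        path = tmp_path / "dist.phy"
        m.write_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0] == str(len(m))
        assert len(lines) == len(m) + 1


def test_reference_panel_distance_reproduces_published_portugal_cell():
    """GSTM1 distance between the study cohort and the Portuguese reference."""
    panel = load_reference_panel()
    current = profiles_from_null_freqs(panel.get("Current study (Venezuela)").null_freq)
    portugal = profiles_from_null_freqs(panel.get("Portuguese").null_freq)
    entry = pairwise_entry("current", current, "Portugal", portugal, loci=["GSTM1"])
    assert round(entry.d_per_locus["GSTM1"], 4) == 0.0003
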