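import math

import numpy as np
import pytest

from arisakit.arisa import (
    BinnedProfile,
    BinningScheme,
    DEFAULT_SCHEME,
    FilterParams,
    assign_bins,
    clip_to_window,
    filter_min_rfu,
    merge_technical_replicates,
    process_peak_table,
    profiles_to_otu_table,
    relative_intensity_filter,
)
from arisakit.errors import EmptyInputError, ValidationError
from arisakit.io import PeakRecord, PeakTable

from conftest import random_peaks


def peaks(*size_intensity, sample="S1", rep="rep1"):
    return PeakTable([PeakRecord(sample, rep, s, i) for s, i in size_intensity])


class TestRfuFilter:
    def test_threshold_is_strict(self):
        table = peaks((300, 9), (300, 10), (300, 10.5))
        out = filter_min_rfu(table, FilterParams())
        assert [r.intensity_rfu for r in out] == [10.5]

    def test_zero_floor_is_identity(self):
        table = peaks((300, 1), (400, 2))
        out = filter_min_rfu(table, FilterParams(min_rfu=0.0))
        assert len(out) == 2

    def test_matches_brute_force_on_random_peaks(self):
        rng = np.random.default_rng(11)
        table = random_peaks(rng, n=1000)
        out = filter_min_rfu(table, FilterParams())
        expected = [r for r in table.records if r.intensity_rfu > 10.0]
        assert out.records == expected


class TestClipToWindow:
    def test_window_endpoints_included(self):
        table = peaks((150, 50), (200.0, 50), (1150.0, 50), (1200, 50))
        out = clip_to_window(table, DEFAULT_SCHEME)
        assert [r.size_bp for r in out] == [200.0, 1150.0]

    def test_inside_window_is_identity(self):
        table = peaks((250, 50), (900, 50))
        assert len(clip_to_window(table, DEFAULT_SCHEME)) == 2

    def test_empty_table_passes_through(self):
        assert len(clip_to_window(PeakTable([]), DEFAULT_SCHEME)) == 0


class TestBinningScheme:
    def test_default_bin_count(self):
        # 167 x 3bp (last truncated [698,700)) + 60 x 5bp + 15 x 10bp
        assert DEFAULT_SCHEME.n_bins == 167 + 60 + 15

    def test_regimes_tile_window_without_overlap(self):
        edges = DEFAULT_SCHEME.bin_edges()
        assert edges[0][0] == DEFAULT_SCHEME.min_bp
        assert edges[-1][1] == DEFAULT_SCHEME.max_bp
        for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
            assert hi1 == lo2
            assert hi1 > lo1

    @pytest.mark.parametrize(
        "size,expected",
        [
            (250.4, (248.0, 251.0)),
            (251.0, (251.0, 254.0)),
            (699.9, (698.0, 700.0)),  # truncated last 3-bp bin
            (700.2, (700.0, 705.0)),  # regime boundary goes to higher regime
            (700.0, (700.0, 705.0)),
            (1000.0, (1000.0, 1010.0)),
            (200.0, (200.0, 203.0)),
            (1150.0, (1140.0, 1150.0)),  # closed top bin
        ],
    )
    def test_grid_arithmetic(self, size, expected):
        assert DEFAULT_SCHEME.bin_of(size) == expected

    def test_outside_window_raises(self):
        with pytest.raises(ValueError):
            DEFAULT_SCHEME.bin_of(199.9)


class TestAssignBins:
    def test_hand_enumerated_grid(self):
        table = peaks((250.4, 500), (251.0, 300))
        (profile,) = assign_bins(table, DEFAULT_SCHEME)
        assert profile.intensity == {
            "bin_0248.00_0251.00": 500.0,
            "bin_0251.00_0254.00": 300.0,
        }

    def test_regime_boundary_respected(self):
        table = peaks((699.9, 50), (700.2, 50))
        (profile,) = assign_bins(table, DEFAULT_SCHEME)
        assert set(profile.intensity) == {
            "bin_0698.00_0700.00",
            "bin_0700.00_0705.00",
        }

    def test_single_peak_conserved(self):
        (profile,) = assign_bins(peaks((432.1, 77.7)), DEFAULT_SCHEME)
        assert profile.total_intensity == 77.7

    def test_intensity_conservation_random(self):
        rng = np.random.default_rng(5)
        table = clip_to_window(random_peaks(rng, n=500), DEFAULT_SCHEME)
        (profile,) = assign_bins(table, DEFAULT_SCHEME)
        total_in = sum(r.intensity_rfu for r in table)
        assert math.isclose(profile.total_intensity, total_in, abs_tol=1e-9)

    def test_profiles_split_by_sample_and_replicate(self):
        table = PeakTable(
            [
                PeakRecord("S1", "rep1", 300, 20),
                PeakRecord("S1", "rep2", 300, 30),
                PeakRecord("S2", "rep1", 300, 40),
            ]
        )
        profiles = assign_bins(table, DEFAULT_SCHEME)
        assert {(p.sample_id, p.replicate_id) for p in profiles} == {
            ("S1", "rep1"),
            ("S1", "rep2"),
            ("S2", "rep1"),
        }


class TestRelativeIntensityFilter:
    def test_bin_below_threshold_dropped(self):
        # 920 RFU total; the 0.9 RFU bin is 0.098% < 0.1%
        profile = BinnedProfile(
            "S1", "rep1", intensity={"a": 900.0, "b": 19.1, "c": 0.9}
        )
        out = relative_intensity_filter(profile, FilterParams())
        assert set(out.intensity) == {"a", "b"}
        assert math.isclose(sum(out.relative.values()), 1.0, abs_tol=1e-9)

    def test_equal_bins_all_kept(self):
        profile = BinnedProfile("S1", "rep1", intensity={f"b{i}": 5.0 for i in range(40)})
        out = relative_intensity_filter(profile, FilterParams())
        assert len(out.intensity) == 40

    def test_matches_brute_force_single_pass(self):
        rng = np.random.default_rng(7)
        vals = rng.exponential(100.0, size=50)
        vals[rng.choice(50, 5, replace=False)] *= 1e-4
        profile = BinnedProfile(
            "S1", "rep1", intensity={f"b{i}": float(v) for i, v in enumerate(vals)}
        )
        out = relative_intensity_filter(profile, FilterParams())
        total = vals.sum()
        expected = {f"b{i}" for i, v in enumerate(vals) if v / total >= 0.001}
        assert set(out.intensity) == expected

    def test_zero_total_raises(self):
        profile = BinnedProfile("S1", "rep1", intensity={})
        with pytest.raises(EmptyInputError):
            relative_intensity_filter(profile, FilterParams())

    def test_every_retained_bin_above_floor(self):
        rng = np.random.default_rng(9)
        vals = rng.exponential(10.0, size=200)
        profile = BinnedProfile(
            "S1", "rep1", intensity={f"b{i}": float(v) for i, v in enumerate(vals)}
        )
        out = relative_intensity_filter(profile, FilterParams())
        total = vals.sum()
        assert all(v / total >= 0.001 for v in out.intensity.values())


def _profile(sample, rep, rel):
    return BinnedProfile(sample, rep, intensity=dict(rel), relative=dict(rel))


class TestReplicateMerge:
    def test_identical_replicates(self):
        rel = {"a": 0.6, "b": 0.4}
        qc = merge_technical_replicates(
            _profile("S1", "rep1", rel), _profile("S1", "rep2", rel)
        )
        assert qc.passed
        assert math.isclose(qc.similarity, 1.0, abs_tol=1e-12)
        assert qc.merged_profile.relative == pytest.approx(rel)

    def test_disjoint_bins_fail(self):
        qc = merge_technical_replicates(
            _profile("S1", "rep1", {"a": 1.0}), _profile("S1", "rep2", {"b": 1.0})
        )
        assert not qc.passed
        assert qc.similarity == 0.0
        assert qc.merged_profile is None

    def test_hand_computed_three_bin_example(self):
        # sim = 2*(min(.5,.35)+min(.3,.4)+min(.2,.25)) / 2 = 0.85
        p1 = _profile("S1", "rep1", {"a": 0.5, "b": 0.3, "c": 0.2})
        p2 = _profile("S1", "rep2", {"a": 0.35, "b": 0.4, "c": 0.25})
        qc = merge_technical_replicates(p1, p2, min_similarity=0.8)
        assert math.isclose(qc.similarity, 0.85, abs_tol=1e-12)
        assert qc.passed
        assert math.isclose(sum(qc.merged_profile.relative.values()), 1.0, abs_tol=1e-9)

    def test_different_samples_rejected(self):
        with pytest.raises(ValidationError):
            merge_technical_replicates(
                _profile("S1", "rep1", {"a": 1.0}), _profile("S2", "rep2", {"a": 1.0})
            )


class TestProfilesToOtuTable:
    def test_shared_bin_layout(self):
        p1 = _profile("S1", "merged", {"a": 0.7, "b": 0.3})
        p2 = _profile("S2", "merged", {"b": 0.4, "c": 0.6})
        table = profiles_to_otu_table([p1, p2])
        assert table.otu_ids == ["a", "b", "c"]
        assert table.data.loc["S1", "c"] == 0.0
        assert table.data.loc["S2", "a"] == 0.0

    def test_single_sample_sums_to_one(self):
        table = profiles_to_otu_table([_profile("S1", "merged", {"a": 0.25, "b": 0.75})])
        assert table.n_samples == 1
        assert math.isclose(table.data.sum(axis=1).iloc[0], 1.0, abs_tol=1e-9)

    def test_empty_collection_raises(self):
        with pytest.raises(EmptyInputError):
            profiles_to_otu_table([])

    def test_duplicate_sample_raises(self):
        p = _profile("S1", "merged", {"a": 1.0})
        with pytest.raises(ValidationError):
            profiles_to_otu_table([p, p])


def brute_force_pipeline(table, min_rfu=10.0, min_rel=0.001):
    """Independent re-implementation of the composed processing order.

    Works per (sample, replicate) with explicit loops and its own bin-edge
    arithmetic; used as the oracle for the library pipeline.
    """
    edges = []
    x = 200.0
    while x < 700.0:
        edges.append((x, min(x + 3.0, 700.0)))
        x = min(x + 3.0, 700.0)
    while x < 1000.0:
        edges.append((x, x + 5.0))
        x += 5.0
    while x < 1150.0:
        edges.append((x, x + 10.0))
        x += 10.0

    out = {}
    for rec in table.records:
        if rec.intensity_rfu <= min_rfu:
            continue
        if rec.size_bp < 200.0 or rec.size_bp > 1150.0:
            continue
        for lo, hi in edges:
            if lo <= rec.size_bp < hi or (hi == 1150.0 and rec.size_bp == 1150.0):
                key = (rec.sample_id, rec.replicate_id)
                bins = out.setdefault(key, {})
                bins[(lo, hi)] = bins.get((lo, hi), 0.0) + rec.intensity_rfu
                break
    result = {}
    for key, bins in out.items():
        total = sum(bins.values())
        result[key] = {
            b: v for b, v in bins.items() if v / total >= min_rel
        }
    return result


class TestComposedPipeline:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(123)
        table = random_peaks(rng, n=1000)
        expected = brute_force_pipeline(table)

        params = FilterParams()
        staged = assign_bins(
            clip_to_window(filter_min_rfu(table, params), DEFAULT_SCHEME),
            DEFAULT_SCHEME,
        )
        got = {}
        for profile in staged:
            out = relative_intensity_filter(profile, params)
            got[(profile.sample_id, profile.replicate_id)] = out.intensity

        for key in expected:
            exp = {
                DEFAULT_SCHEME.bin_label(lo, hi): v for (lo, hi), v in expected[key].items()
            }
            assert set(got[key]) == set(exp)
            for b in exp:
                assert math.isclose(got[key][b], exp[b], abs_tol=1e-9)


class TestProcessPeakTable:
    def test_qc_report_and_table(self):
        rng = np.random.default_rng(42)
        recs = []
        for rep in ("rep1", "rep2"):
            for _ in range(200):
                recs.append(
                    PeakRecord(
                        "S1",
                        rep,
                        float(rng.uniform(200, 1150)),
                        float(rng.exponential(200) + 11),
                    )
                )
        table, qc = process_peak_table(PeakTable(recs), replicate_threshold=0.0)
        assert qc.shape[0] == 1
        assert table.n_samples == 1
        assert math.isclose(table.data.sum(axis=1).iloc[0], 1.0, abs_tol=1e-9)

    def test_sample_otu_count_bounded_by_scheme(self):
        rng = np.random.default_rng(43)
        table = random_peaks(rng, n=5000)
        otus, _ = process_peak_table(table)
        assert otus.n_otus <= DEFAULT_SCHEME.n_bins
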