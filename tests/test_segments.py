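import numpy as np
import pandas as pd
import pytest

from introtrace.coverage import DeviationProfile
from introtrace.segments import (
    CallParams,
    IntrogressionSegment,
    assign_zygosity,
    call_blocks,
    core_region,
    segment_report,
)
from introtrace.windows import WindowGrid

MB = 1_000_000


def _grid(n_windows=20, chrom="chr1"):
    return WindowGrid.from_chrom_lengths({chrom: n_windows * MB}, MB)


def _profile(d, low, grid, line="L0"):
    n = len(d)
    flag = np.array(["low" if i in low else "none" for i in range(n)], dtype=object)
    d = np.asarray(d, dtype=float)
    return DeviationProfile(
        line=line, c=d.copy(), m=np.ones(n), epsilon=1.0, d=d,
        masked=np.zeros(n, dtype=bool), z=np.zeros(n), flag=flag, grid=grid,
    )


def _ratio(n, retained=(), counts=None):
    counts = counts or {}
    return pd.DataFrame(
        {
            "line": "L0",
            "window": range(n),
            "count": [counts.get(i, 0) for i in range(n)],
            "het_count": 0,
            "panel_mean": 1.0,
            "ratio": [2.0 if i in retained else 0.0 for i in range(n)],
            "retained": [i in retained for i in range(n)],
        }
    )


def _snps(windows, chrom="chr1", gt="hom", line="L0", donor="d"):
    return pd.DataFrame(
        [
            {"line": line, "chrom": chrom, "pos": w * MB + 1 + k, "ref": "A",
             "alt": "T", "gt": gt, "donor": donor}
            for w, k_n in windows.items()
            for k in range(k_n)
        ],
        columns=["line", "chrom", "pos", "ref", "alt", "gt", "donor"],
    )


class TestCallBlocks:
    def test_no_evidence_no_blocks(self):
        grid = _grid()
        prof = _profile(np.ones(20), set(), grid)
        assert call_blocks(prof, _ratio(20), grid) == []

    def test_bridged_gap_spans_single_block(self):
        """Low flags at windows 3-12 except 7; 7 carries donor SNPs."""
        grid = _grid()
        low = set(range(3, 13)) - {7}
        d = np.array([1.0] * 20)
        d[list(low)] = 0.5
        d[7] = 0.95
        prof = _profile(d, low, grid)
        snps = _snps({7: 2})
        blocks = call_blocks(prof, _ratio(20, counts={7: 2}), grid, matched_snps=snps)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (3 * MB, 13 * MB)

    def test_unbridgeable_gap_splits_blocks(self):
        grid = _grid()
        low = {2, 3, 4, 8, 9, 10}
        d = np.ones(20)
        d[list(low)] = 0.5
        prof = _profile(d, low, grid)
        blocks = call_blocks(prof, _ratio(20), grid)  # gap 5-7 has no SNPs
        assert [(b.start // MB, b.end // MB) for b in blocks] == [(2, 5), (8, 11)]

    def test_small_blocks_discarded(self):
        grid = _grid()
        low = {5, 6}
        d = np.ones(20)
        d[[5, 6]] = 0.5
        prof = _profile(d, low, grid)
        assert call_blocks(prof, _ratio(20), grid, CallParams(min_windows=3)) == []

    def test_snp_only_windows_do_not_bound_blocks(self):
        grid = _grid()
        low = {5, 6, 7, 8}
        d = np.ones(20)
        d[[5, 6, 7, 8]] = 0.5
        prof = _profile(d, low, grid)
        blocks = call_blocks(
            prof, _ratio(20, retained={3, 10}, counts={3: 1, 4: 1, 9: 1, 10: 1}),
            grid,
        )
        assert [(b.start // MB, b.end // MB) for b in blocks] == [(5, 9)]

    def test_majority_low_rule_discards_snp_dominated_runs(self):
        grid = _grid()
        low = {5, 10}
        d = np.ones(20)
        d[[5, 10]] = 0.5
        prof = _profile(d, low, grid)
        counts = {i: 1 for i in range(5, 11)}
        blocks = call_blocks(
            prof, _ratio(20, retained=set(range(5, 11)), counts=counts), grid
        )
        assert blocks == []

    def test_mismatched_grid_rejected(self):
        grid = _grid(20)
        prof = _profile(np.ones(10), set(), _grid(10))
        with pytest.raises(ValueError, match="grid"):
            call_blocks(prof, _ratio(10), grid)

    def test_matches_exhaustive_run_oracle(self):
        """Calls equal an independent run-enumeration under the stated rule."""
        rng = np.random.default_rng(11)
        grid = _grid(40)
        params = CallParams(gap_windows=2, min_windows=3)
        for _ in range(50):
            low = set(np.flatnonzero(rng.random(40) < 0.25))
            retained = set(np.flatnonzero(rng.random(40) < 0.2))
            snp_windows = {int(w): 1 for w in np.flatnonzero(rng.random(40) < 0.4)}
            for w in retained:
                snp_windows[int(w)] = snp_windows.get(int(w), 0) + 1
            d = np.ones(40)
            d[list(low)] = 0.5
            prof = _profile(d, low, grid)
            blocks = call_blocks(
                prof, _ratio(40, retained=retained, counts=snp_windows), grid,
                params, matched_snps=_snps(snp_windows),
            )
            got = [(b.start // MB, b.end // MB) for b in blocks]
            assert got == self._oracle(low, retained, snp_windows, 40, params)

    @staticmethod
    def _oracle(low, retained, snp_windows, n, params):
        """Independent pairwise-linkage re-implementation of the block rule."""
        evidence = sorted(low | retained)
        # link consecutive evidence windows when the gap is bridgeable
        groups = []
        for w in evidence:
            if groups:
                prev = groups[-1][-1]
                gap = list(range(prev + 1, w))
                if len(gap) <= params.gap_windows and all(
                    snp_windows.get(g, 0) >= 1 for g in gap
                ):
                    groups[-1].append(w)
                    continue
            groups.append([w])
        out = []
        for g in groups:
            lo_list = [w for w in g if w in low]
            if not lo_list:
                continue
            s, e = min(lo_list), max(lo_list) + 1  # boundaries must be low
            n_evidence = sum(1 for w in g if s <= w < e)
            if n_evidence < params.min_windows:
                continue
            n_low = sum(1 for w in range(s, e) if w in low)
            if n_low <= (e - s) / 2:
                continue
            out.append((s, e))
        return out


class TestZygosity:
    def _segment(self, start_w=5, end_w=10):
        return IntrogressionSegment(
            line="L0", chrom="chr1", start=start_w * MB, end=end_w * MB,
            donor="d", mean_d=0.5,
        )

    def test_both_criteria_fail_gives_hom(self):
        grid = _grid()
        seg = self._segment()
        seg.mean_d = 0.45
        snps = _snps({6: 20})
        snps.loc[0, "gt"] = "het"  # 5% het
        zyg = assign_zygosity(seg, _profile(np.ones(20), set(), grid), snps, grid)
        assert zyg == "hom"

    def test_dual_evidence_gives_het(self):
        grid = _grid()
        seg = self._segment()
        seg.mean_d = 0.75
        snps = _snps({6: 10}, gt="het")
        snps.loc[0, "gt"] = "hom"  # 90% het
        assert assign_zygosity(seg, _profile(np.ones(20), set(), grid), snps, grid) == "het"

    def test_intermediate_coverage_alone_is_not_het(self):
        grid = _grid()
        seg = self._segment()
        seg.mean_d = 0.75
        snps = _snps({6: 10}, gt="hom")
        assert assign_zygosity(seg, _profile(np.ones(20), set(), grid), snps, grid) == "hom"

    def test_no_snps_falls_back_to_coverage_with_warning(self):
        grid = _grid()
        seg = self._segment()
        seg.mean_d = 0.75
        with pytest.warns(UserWarning, match="coverage alone"):
            zyg = assign_zygosity(seg, _profile(np.ones(20), set(), grid), None, grid)
        assert zyg == "het"


def _seg(line, start_w, end_w, chrom="chr1", zyg="hom"):
    return IntrogressionSegment(
        line=line, chrom=chrom, start=start_w * MB, end=end_w * MB,
        donor="d", zygosity=zyg,
    )


class TestCoreRegion:
    def test_single_carrier_returns_its_segment(self):
        core = core_region({"A": [_seg("A", 2, 9)]}, ["A"], [], "chr1")
        assert (core.start, core.end) == (2 * MB, 9 * MB)

    def test_worked_interval_algebra_example(self):
        by_line = {
            "A": [_seg("A", 0, 10)],
            "B": [_seg("B", 5, 20)],
            "C": [_seg("C", 5, 12)],
            "X": [_seg("X", 0, 5)],
        }
        core = core_region(by_line, ["A", "B", "C"], ["X"], "chr1")
        assert (core.start, core.end) == (5 * MB, 10 * MB)

    def test_disjoint_carriers_empty_core(self):
        by_line = {"A": [_seg("A", 0, 5)], "B": [_seg("B", 10, 15)]}
        assert core_region(by_line, ["A", "B"], [], "chr1") is None

    def test_carrier_without_segment_is_an_error(self):
        with pytest.raises(ValueError, match="B"):
            core_region({"A": [_seg("A", 0, 5)]}, ["A", "B"], [], "chr1")

    def test_matches_brute_force_on_random_configurations(self):
        """200 random carrier/excluded layouts vs positional brute force."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n_car = rng.integers(1, 5)
            n_exc = rng.integers(0, 4)
            by_line = {}
            for i in range(n_car + n_exc):
                segs = []
                for _ in range(rng.integers(1, 4)):
                    s = int(rng.integers(0, 55))
                    e = s + int(rng.integers(1, 12))
                    segs.append(_seg(f"L{i}", s, e))
                by_line[f"L{i}"] = segs
            carriers = [f"L{i}" for i in range(n_car)]
            excluded = [f"L{i}" for i in range(n_car, n_car + n_exc)]
            core = core_region(by_line, carriers, excluded, "chr1")
            # brute force on 1 Mb positions
            cover = np.ones(70, dtype=bool)
            for line in carriers:
                line_cov = np.zeros(70, dtype=bool)
                for s in by_line[line]:
                    line_cov[s.start // MB : s.end // MB] = True
                cover &= line_cov
            for line in excluded:
                for s in by_line[line]:
                    cover[s.start // MB : s.end // MB] = False
            runs = []
            start = None
            for i, b in enumerate(list(cover) + [False]):
                if b and start is None:
                    start = i
                if not b and start is not None:
                    runs.append((start, i))
                    start = None
            if not runs:
                assert core is None
            else:
                best = max(runs, key=lambda t: t[1] - t[0])
                assert (core.start // MB, core.end // MB) == best

    def test_monotone_under_adding_carriers_and_exclusions(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            by_line = {
                f"L{i}": [_seg(f"L{i}", int(s), int(s) + int(w))]
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 20, 6), rng.integers(5, 30, 6))
                )
            }
            lines = list(by_line)
            base = core_region(by_line, lines[:2], [], "chr1")
            more_car = core_region(by_line, lines[:3], [], "chr1")
            more_exc = core_region(by_line, lines[:2], [lines[3]], "chr1")
            base_len = base.length if base else 0
            assert (more_car.length if more_car else 0) <= base_len
            assert (more_exc.length if more_exc else 0) <= base_len


class TestSegmentReport:
    def test_identity_calls_perfect_metrics(self):
        truth = [_seg("A", 2, 9), _seg("B", 5, 20)]
        rep = segment_report(list(truth), truth)
        assert rep["recall"] == 1 and rep["precision"] == 1
        assert rep["max_boundary_error"] == 0

    def test_one_window_shift_boundary_error(self):
        truth = [_seg("A", 2, 9)]
        calls = [_seg("A", 3, 10)]
        rep = segment_report(calls, truth)
        assert rep["boundary_errors"] == [1.0]

    def test_matches_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            truth = [
                _seg(f"L{i}", int(s), int(s) + int(w))
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 40, 5), rng.integers(2, 15, 5))
                )
            ]
            calls = [
                _seg(f"L{int(i)}", int(s), int(s) + int(w))
                for i, s, w in zip(
                    rng.integers(0, 5, 6), rng.integers(0, 40, 6), rng.integers(2, 15, 6)
                )
            ]
            rep = segment_report(calls, truth)
            exp_rec = sum(
                1 for t in truth
                if any(c.line == t.line and c.start < t.end and c.end > t.start
                       for c in calls)
            ) / len(truth)
            exp_prec = sum(
                1 for c in calls
                if any(c.line == t.line and c.start < t.end and c.end > t.start
                       for t in truth)
            ) / len(calls)
            assert rep["recall"] == pytest.approx(exp_rec)
            assert rep["precision"] == pytest.approx(exp_prec)
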