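"""Chi-square, effect sizes, neighbourhood association and run reports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnbaudit import (
    RunConfig,
    build_report,
    chi2_2x2,
    neighbor_association,
    odds_ratio,
    rate_ratio,
    scan_run,
    simulate_pairs,
)
from dnbaudit.artifact_report import format_p_value
from dnbaudit.errors import ConfigError, InputError


def _chi2_direct(table):
    """Independent oracle: textbook sum of (O-E)^2 / E."""
    o = np.asarray(table, dtype=float)
    row, col, n = o.sum(axis=1), o.sum(axis=0), o.sum()
    e = np.outer(row, col) / n
    return float(((o - e) ** 2 / e).sum())


class TestChi2:
    def test_identical_rows_statistic_zero(self):
        stat, p = chi2_2x2([[10, 90], [10, 90]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # O = 30,70,10,90; E = 20,80,20,80 -> 100/20+100/80+100/20+100/80 = 12.5
        stat, _p = chi2_2x2([[30, 70], [10, 90]])
        assert stat == pytest.approx(12.5)

    def test_transposition_invariance(self):
        t = [[13, 7], [28, 41]]
        assert chi2_2x2(t)[0] == pytest.approx(chi2_2x2(np.transpose(t))[0])

    def test_zero_margin_is_error(self):
        with pytest.raises(InputError):
            chi2_2x2([[0, 0], [5, 9]])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(1, 500), min_size=4, max_size=4))
    def test_matches_direct_summation(self, cells):
        table = [cells[:2], cells[2:]]
        stat, _ = chi2_2x2(table)
        assert stat == pytest.approx(_chi2_direct(table), rel=1e-9)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (23.91, 2.516, 9.50),
            (23.99, 2.516, 9.53),
            (26.09, 7.51, 3.47),
        ],
    )
    def test_rate_ratio_on_reported_proportions(self, p1, p2, expected):
        """Proportion ratios reproduce the reported effect sizes at
        2-decimal rounding."""
        ratio = rate_ratio(round(p1 * 1000), 100_000, round(p2 * 1000), 100_000)
        assert round(ratio, 2) == expected

    def test_equal_proportions_ratio_one(self):
        assert rate_ratio(13, 100, 13, 100) == 1.0
        assert rate_ratio(5, 50, 10, 100) == 1.0

    def test_zero_baseline_is_infinite(self):
        assert math.isinf(rate_ratio(5, 100, 0, 100))

    def test_odds_ratio_differs_from_rate_ratio(self):
        """On the same proportions the cross-product odds ratio is larger
        than the proportion ratio (both are reported, labelled apart)."""
        rr = rate_ratio(2391, 10_000, 252, 10_016)
        orr = odds_ratio(2391, 10_000, 252, 10_016)
        assert orr > rr > 1.0

    def test_invalid_group_sizes(self):
        with pytest.raises(InputError):
            rate_ratio(1, 0, 1, 10)


class TestFormatP:
    def test_tiny_p_clamped(self):
        assert format_p_value(0.0) == "< 1e-300"
        assert format_p_value(1e-320) == "< 1e-300"

    def test_normal_p_rendered(self):
        assert format_p_value(0.0321) == "0.0321"


@pytest.fixture(scope="module")
def biased_run():
    config = RunConfig(
        n_pairs=20_000, n_fovs=10, seed=3,
        duplicate_rate=0.03, duplicate_artifact_bias=10.0,
    )
    pairs, truth = simulate_pairs(config)
    _report, hits = scan_run([p.reverse for p in pairs], method="fast")
    return pairs, truth, hits


class TestNeighborAssociation:
    def test_whole_pool_selection_gives_ratio_one(self, biased_run):
        pairs, _truth, hits = biased_run
        assoc = neighbor_association(pairs, pairs, mode="case13", hits=hits)
        assert assoc.rate_ratio == 1.0
        assert assoc.chi2_statistic == pytest.approx(0.0)

    def test_scan_association_equals_truth_oracle(self, biased_run):
        """Dual route: the scan-based association must agree exactly with
        the association computed from the planted truth table."""
        pairs, truth, hits = biased_run
        sel_mask = truth.planted_class.isin(["improper_pair", "misdemux"]).to_numpy()
        selected = [p for p, m in zip(pairs, sel_mask) if m]
        assoc = neighbor_association(selected, pairs, mode="case13", hits=hits)

        dup = truth[truth.planted_class.str.startswith("duplicate_of:")]
        src = dup.planted_class.str.extract(r":(\d+)$")[0].astype(int)
        flagged = set(zip(dup.lane, dup.fov_col, dup.fov_row, dup.ordinal))
        flagged |= set(zip(dup.lane, dup.fov_col, dup.fov_row, src))
        keys = list(zip(truth.lane, truth.fov_col, truth.fov_row, truth.ordinal))
        ind = np.array([k in flagged for k in keys])
        assert assoc.k_selected == int(ind[sel_mask].sum())
        assert assoc.k_baseline == int(ind.sum())

    def test_biased_planting_detected(self, biased_run):
        """Duplicates planted preferentially on artifact pairs produce a
        strong, significant enrichment."""
        pairs, truth, hits = biased_run
        sel_mask = truth.planted_class.isin(["improper_pair", "misdemux"]).to_numpy()
        selected = [p for p, m in zip(pairs, sel_mask) if m]
        assoc = neighbor_association(selected, pairs, mode="case13", hits=hits)
        assert assoc.rate_ratio > 2.0
        assert assoc.p_value < 1e-10
        assert assoc.odds_ratio > assoc.rate_ratio  # both reported

    def test_case2_neighbor_mode(self, biased_run):
        """In the offset-neighbour mode a pair whose reverse read has an
        in-pool neighbour at a mode offset counts as flagged."""
        pairs, _truth, _hits = biased_run
        # thin the pool randomly so the offset-neighbour indicator is
        # neither all-true (dense pool) nor all-false
        rng = np.random.default_rng(7)
        pool = [p for p in pairs if rng.random() < 0.02]
        assoc = neighbor_association(pool, pool, mode="case2")
        assert assoc.rate_ratio == 1.0
        assert 0 < assoc.k_baseline < len(pool)

    def test_empty_selection_is_error(self, biased_run):
        pairs, _truth, hits = biased_run
        with pytest.raises(InputError):
            neighbor_association([], pairs, mode="case13", hits=hits)

    def test_unknown_mode_is_config_error(self, biased_run):
        pairs, _truth, hits = biased_run
        with pytest.raises(ConfigError):
            neighbor_association(pairs, pairs, mode="case99", hits=hits)


class TestRunReport:
    def test_full_report_sections_present(self, small_run):
        from dnbaudit import ADAPTER_F, misdemux_rate, tabulate_barcodes

        config, pairs, _truth, panel, _refs = small_run
        rep_f = misdemux_rate(
            tabulate_barcodes([p.forward for p in pairs], ADAPTER_F), panel,
            config.target_barcode_id,
        )
        scan, _hits = scan_run([p.forward for p in pairs], method="fast")
        report = build_report(
            misdemux_forward=rep_f,
            scan=scan,
            pair_classes={"proper": 10, "case1_improper_pair_short": 2},
            filter_summary={"kept": 8, "removed": 4},
        )
        d = report.to_dict()
        assert d["misdemux_forward"]["n_exact_panel_match"] > 0
        assert d["scan"]["method"] == "fast"
        assert d["misdemux_reverse"] is None  # omitted stage stays null
        text = report.render_text()
        assert "Optical duplicates" in text

    def test_json_round_trip(self):
        report = build_report(pair_classes={"proper": 3})
        from dnbaudit import RunReport

        back = RunReport.from_json(report.to_json())
        assert back == report
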