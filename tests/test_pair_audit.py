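"""Overlap merging, lightweight mapping, four-case classification, filter."""

import random

import numpy as np
import pytest

from dnbaudit import (
    ADAPTER_F,
    InsertModel,
    MgiReadName,
    PairClass,
    ReadPair,
    ReadRecord,
    ReferenceIndex,
    RunConfig,
    ca_group_stats,
    classify_pair,
    contains_adapter,
    estimate_insert,
    filter_short_inserts,
    map_read,
    resolve_inputs,
    simulate_pairs,
)
from dnbaudit.errors import ConfigError
from dnbaudit.mgi_io import revcomp

VIS_THRESHOLD = 300 - 32  # adapter + barcode footprint at PE300


def _pair(fwd, rev, ordinal=1):
    name = MgiReadName("S", 1, 1, 1, ordinal)
    return ReadPair(
        ReadRecord(name.with_mate(1), fwd, "I" * len(fwd)),
        ReadRecord(name.with_mate(2), rev, "I" * len(rev)),
    )


@pytest.fixture(scope="module")
def fixed_insert_run():
    config = RunConfig(
        n_pairs=20, n_fovs=1, seed=3, read_length=300,
        insert_model=InsertModel(name="fixed", mean=200),
        misdemux_rate=0.0, improper_pair_rate=0.0, duplicate_rate=0.0,
        chimera_rate=0.0, substitution_error_rate=0.0,
    )
    pairs, truth = simulate_pairs(config)
    panel, refs = resolve_inputs(config)
    return config, pairs, truth, panel, refs


@pytest.fixture(scope="module")
def small_reference_index():
    rng = random.Random(3)
    ref = "".join(rng.choice("ACGT") for _ in range(10_000))
    return ReferenceIndex({"target": ref})


@pytest.fixture(scope="module")
def classified_run(noise_free_run):
    config, pairs, truth, panel, refs = noise_free_run
    index = ReferenceIndex(refs)
    classes = [
        classify_pair(p, panel, config.target_barcode_id, index) for p in pairs
    ]
    # a planted duplicate copies its source's reads, so its *content*
    # class (what a classifier can see) is the source pair's class
    src_class = {
        (lane, col, row, o): c
        for lane, col, row, o, c in zip(
            truth.lane, truth.fov_col, truth.fov_row, truth.ordinal,
            truth.planted_class,
        )
    }
    effective = []
    for lane, col, row, o, c in zip(
        truth.lane, truth.fov_col, truth.fov_row, truth.ordinal, truth.planted_class
    ):
        if c.startswith("duplicate_of:"):
            effective.append(src_class[(lane, col, row, int(c.split(":")[1]))])
        else:
            effective.append(c)
    return config, truth.assign(cls=[c.value for c in classes], content=effective)


class TestEstimateInsert:
    def test_innie_overlap_arithmetic(self):
        """l=450 at PE300: mates share 150 bases; insert = 300+300-150."""
        rng = random.Random(1)
        frag = "".join(rng.choice("ACGT") for _ in range(450))
        pair = _pair(frag[:300], revcomp(frag)[:300])
        est = estimate_insert(pair)
        assert est.merged
        assert est.overlap_length == 150
        assert est.insert_length == 450
        assert est.mismatches_in_overlap == 0

    def test_engulfed_read_through(self, clean_short_run):
        """Error-free clean pairs recover the true insert exactly, both
        in the innie and the engulfed (insert < read length) regime."""
        config, pairs, truth, _panel, _refs = clean_short_run
        mergeable_max = 2 * config.read_length - 10  # below min_overlap beyond this
        checked = 0
        for pair, ell in zip(pairs, truth.true_insert_length):
            if ell > mergeable_max or checked >= 150:
                continue
            est = estimate_insert(pair)
            assert est.merged
            assert est.insert_length == ell
            checked += 1
        assert checked == 150

    def test_improper_pairs_rarely_merge(self):
        """Unrelated mates stay unmerged at default thresholds
        (>= 99% of 1000 planted improper pairs)."""
        config = RunConfig(
            n_pairs=1050, n_fovs=2, seed=41, misdemux_rate=0.0,
            improper_pair_rate=1.0, duplicate_rate=0.0, chimera_rate=0.0,
            substitution_error_rate=0.0,
        )
        pairs, truth = simulate_pairs(config)
        improper = [p for p, c in zip(pairs, truth.planted_class) if c == "improper_pair"]
        assert len(improper) >= 1000
        unmerged = sum(1 for p in improper if not estimate_insert(p).merged)
        assert unmerged / len(improper) >= 0.99

    def test_noise_tolerant_recovery(self):
        """At substitution rate 0.005 at least 99% of clean pairs still
        merge to the true insert."""
        config = RunConfig(
            n_pairs=800, n_fovs=2, seed=43, misdemux_rate=0.0,
            improper_pair_rate=0.0, duplicate_rate=0.0, chimera_rate=0.0,
            substitution_error_rate=0.005,
        )
        pairs, truth = simulate_pairs(config)
        mergeable = [
            (p, ell) for p, ell in zip(pairs, truth.true_insert_length)
            if ell <= 2 * config.read_length - 10  # true overlap >= min_overlap
        ]
        exact = sum(
            1 for p, ell in mergeable if estimate_insert(p).insert_length == ell
        )
        assert exact / len(mergeable) >= 0.99


class TestContainsAdapter:
    def test_adapter_iff_insert_below_read_minus_22(self, clean_short_run):
        """On error-free clean pairs the adapter predicate equals the
        insert-length rule l <= read_length - 22."""
        config, pairs, truth, _panel, _refs = clean_short_run
        cutoff = config.read_length - len(ADAPTER_F)
        for pair, ell in zip(pairs, truth.true_insert_length):
            assert contains_adapter(pair.forward) == (ell <= cutoff)

    def test_adapter_at_read_end(self):
        seq = "A" * (300 - 22) + ADAPTER_F
        assert contains_adapter(seq)


class TestMapRead:
    def test_verbatim_copy_maps(self, small_reference_index):
        read = small_reference_index.references["target"][1000:1300]
        res = map_read(read, small_reference_index)
        assert res.mapped
        assert res.reference_label == "target"
        assert res.position == 1000
        assert res.strand == "+"
        assert res.identity == 1.0

    def test_revcomp_copy_maps_minus_strand(self, small_reference_index):
        read = revcomp(small_reference_index.references["target"][2000:2300])
        res = map_read(read, small_reference_index)
        assert res.mapped
        assert res.strand == "-"
        assert res.position == 2000

    def test_random_reads_unmapped(self, small_reference_index):
        for seed in range(100):
            rng = random.Random(10_000 + seed)
            read = "".join(rng.choice("ACGT") for _ in range(300))
            assert not map_read(read, small_reference_index).mapped

    def test_reference_shorter_than_k_rejected(self):
        with pytest.raises(ConfigError):
            ReferenceIndex({"tiny": "ACGT"})


class TestClassifyPair:
    def test_case1_recall_and_precision(self, classified_run):
        _config, truth = classified_run
        detectable = truth[
            (truth.planted_class == "improper_pair")
            & (truth.true_insert_length <= VIS_THRESHOLD)
        ]
        called = truth[truth.cls == PairClass.CASE1_IMPROPER_PAIR_SHORT.value]
        assert len(detectable) > 0 and len(called) > 0
        recall = (detectable.cls == PairClass.CASE1_IMPROPER_PAIR_SHORT.value).mean()
        precision = (called.content == "improper_pair").mean()
        assert recall >= 0.9
        assert precision >= 0.9

    def test_case2_recall_and_precision(self, classified_run):
        _config, truth = classified_run
        detectable = truth[
            (truth.planted_class == "misdemux")
            & (truth.true_insert_length <= VIS_THRESHOLD)
            & (truth.true_barcode_id_rev != 104)
        ]
        called = truth[truth.cls == PairClass.CASE2_MISDEMUX_SHORT.value]
        assert len(detectable) > 0 and len(called) > 0
        recall = (detectable.cls == PairClass.CASE2_MISDEMUX_SHORT.value).mean()
        precision = (called.content == "misdemux").mean()
        assert recall >= 0.9
        assert precision >= 0.9

    def test_clean_long_pairs_proper(self, classified_run):
        _config, truth = classified_run
        clean_long = truth[
            (truth.planted_class == "none") & (truth.true_insert_length >= 350)
        ]
        assert (clean_long.cls == PairClass.PROPER.value).mean() >= 0.99

    def test_case4_never_for_target_source(self, classified_run):
        """case4 (excluded) requires both mates consistent with a
        non-target source; clean target pairs never land there."""
        _config, truth = classified_run
        clean = truth[truth.planted_class == "none"]
        assert (clean.cls != PairClass.CASE4_EXCLUDED.value).all()


class TestFilterShortInserts:
    def test_removes_exactly_adapter_pairs(self, small_run):
        _config, pairs, _truth, _panel, _refs = small_run
        kept, removed = filter_short_inserts(pairs)
        assert removed == sum(1 for p in pairs if contains_adapter(p.forward))
        assert all(not contains_adapter(p.forward) for p in kept)
        assert len(kept) + removed == len(pairs)
        # order preserved
        kept_stems = [p.name.stem for p in kept]
        expected = [p.name.stem for p in pairs if not contains_adapter(p.forward)]
        assert kept_stems == expected

    def test_idempotent(self, small_run):
        _config, pairs, _truth, _panel, _refs = small_run
        kept, _ = filter_short_inserts(pairs)
        kept2, removed2 = filter_short_inserts(kept)
        assert removed2 == 0
        assert kept2 == kept

    def test_empty_input(self):
        assert filter_short_inserts([]) == ([], 0)


class TestCaGroupStats:
    def test_contaminant_enrichment_direction(self):
        """When improper pairs (contaminant-source forwards) are enriched
        among short inserts, the CA group shows a higher contaminant
        percentage than the total set."""
        config = RunConfig(
            n_pairs=8000, n_fovs=4, seed=47, misdemux_rate=0.0,
            improper_pair_rate=0.02, improper_short_enrichment=2.0,
            duplicate_rate=0.0, chimera_rate=0.0, substitution_error_rate=0.0,
        )
        pairs, _truth = simulate_pairs(config)
        _panel, refs = resolve_inputs(config)
        index = ReferenceIndex(refs)
        table = ca_group_stats(
            pairs, index, contaminant_reference_label="contaminant"
        ).set_index("group")
        assert table.loc["CA", "pct_contaminant"] > table.loc["total", "pct_contaminant"]
        assert table.loc["CA", "pct_unmapped"] > table.loc["total", "pct_unmapped"]

    def test_no_contaminant_reference_gives_nan(self, clean_short_run):
        _config, pairs, _truth, _panel, refs = clean_short_run
        index = ReferenceIndex(refs)
        table = ca_group_stats(pairs[:200], index).set_index("group")
        assert np.isnan(table.loc["CA", "pct_contaminant"])

    def test_all_long_clean_pairs(self):
        config = RunConfig(
            n_pairs=300, n_fovs=1, seed=53,
            insert_model=InsertModel(name="uniform", low=400, high=550),
            misdemux_rate=0.0, improper_pair_rate=0.0, duplicate_rate=0.0,
            chimera_rate=0.0, substitution_error_rate=0.0,
        )
        pairs, _truth = simulate_pairs(config)
        _panel, refs = resolve_inputs(config)
        table = ca_group_stats(pairs, ReferenceIndex(refs)).set_index("group")
        assert table.loc["CA", "n"] == 0
        assert np.isnan(table.loc["CA", "pct_unmapped"])
        assert table.loc["total", "pct_unmapped"] <= 1.0
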