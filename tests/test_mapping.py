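"""Quality filtering, cross-pool exclusion, SNP-index tracks and peak calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutpool.genome import Variant
from mutpool.mapping import (
    FilterConfig,
    IntegrityError,
    SNPIndexTrack,
    VariantRecord,
    call_peak_regions,
    compute_snp_index,
    exclude_shared,
    fit_index_decay,
    map_pipeline,
    quality_filter,
    scan_genome,
)
from mutpool.simulate import simulate_cross_scenario


def rec(chrom="chr1", pos=100, ref="G", alt="A", ad=10, dp=20, mq=60.0, bq=35.0, **kw):
    return VariantRecord(chrom, pos, ref, alt, ad, dp, mq, bq, **kw)


record_strategy = st.builds(
    rec,
    pos=st.integers(1, 10_000),
    ad=st.integers(0, 30),
    dp=st.just(30),
    mq=st.floats(0, 60),
    bq=st.floats(0, 45),
)


class TestVariantRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            rec(ad=21, dp=20)
        with pytest.raises(ValueError):
            rec(pos=0)
        with pytest.raises(ValueError):
            rec(ref="G", alt="G")


class TestQualityFilter:
    def test_thresholds_are_inclusive(self):
        kept = quality_filter([rec(mq=30.0, bq=20.0, dp=10, ad=5)], FilterConfig())
        assert len(kept) == 1

    def test_below_threshold_removed(self):
        assert quality_filter([rec(mq=29.0)], FilterConfig()) == []
        assert quality_filter([rec(bq=19.9)], FilterConfig()) == []
        assert quality_filter([rec(dp=4, ad=2)], FilterConfig()) == []

    @given(st.lists(record_strategy, max_size=200))
    def test_matches_predicate_oracle(self, records):
        cfg = FilterConfig(min_mapping_quality=30, min_base_quality=20, min_total_depth=5)
        expected = []
        for r in records:  # independently re-stated predicates
            if r.mapping_quality < 30:
                continue
            if r.base_quality < 20:
                continue
            if r.total_depth < 5:
                continue
            expected.append(r)
        assert quality_filter(records, cfg) == expected


class TestExcludeShared:
    def test_exact_key_subtraction(self):
        v1 = rec(pos=100)
        v2 = rec(pos=200)
        out = exclude_shared([v1, v2], wild_type=[rec(pos=200)])
        assert out == [v1]

    def test_different_alt_not_removed(self):
        target = rec(pos=100, ref="G", alt="A")
        other = rec(pos=100, ref="G", alt="T")
        assert exclude_shared([target], other_pools=[[other]]) == [target]

    def test_presence_requires_min_alt_reads(self):
        target = rec(pos=100)
        weak = rec(pos=100, ad=1, dp=20)  # 1 alt read: not "present"
        assert exclude_shared([target], wild_type=[weak]) == [target]
        strong = rec(pos=100, ad=2, dp=20)
        assert exclude_shared([target], wild_type=[strong]) == []

    def test_conflicting_ref_raises(self):
        with pytest.raises(IntegrityError):
            exclude_shared([rec(pos=100, ref="G", alt="A")],
                           wild_type=[rec(pos=100, ref="C", alt="A")])

    def test_causal_survives_cross_exclusion(self):
        """The causal SNP is private to its pool, so cross-exclusion against
        the wild type and the other mutant pool never removes it."""
        for seed in range(10):
            sc = simulate_cross_scenario(n_background=200, seed=seed)
            for name, line in sc.lines.items():
                others = [sc.pools[o] for o in sc.pools if o != name]
                out = exclude_shared(sc.pools[name], sc.wildtype, others)
                keys = {r.key for r in out}
                assert tuple(line.causal) in keys

    def test_exclusion_removes_false_candidates(self):
        """Shared parental SNPs are fixed in every pool (index ~1); dropping
        the cross-exclusion step strictly increases false candidates."""
        sc = simulate_cross_scenario(n_background=200, n_shared=20, seed=1)
        pool = sc.pools["s140"]
        with_excl = exclude_shared(pool, sc.wildtype, [sc.pools["s76"]])
        without = exclude_shared(pool, [], [])
        shared_keys = {tuple(v) for v in sc.shared_variants}
        assert not shared_keys & {r.key for r in with_excl}
        assert shared_keys <= {r.key for r in without}
        assert len(without) > len(with_excl)


class TestSNPIndex:
    @pytest.mark.parametrize(
        "ad,dp,expected", [(20, 20, 1.0), (10, 20, 0.5), (7, 20, 0.35)]
    )
    def test_direct_ratio(self, ad, dp, expected):
        assert compute_snp_index(rec(ad=ad, dp=dp)) == pytest.approx(expected)

    def test_low_depth_flagged_not_raised(self):
        track = SNPIndexTrack.from_records([rec(dp=3, ad=1), rec(dp=10, ad=5)], min_total_depth=5)
        assert len(track) == 1
        assert len(track.excluded) == 1

    @given(st.lists(record_strategy, max_size=100))
    def test_index_bounded(self, records):
        track = SNPIndexTrack.from_records(records, min_total_depth=1)
        assert ((track.sites["snp_index"] >= 0) & (track.sites["snp_index"] <= 1)).all()


class TestScanGenome:
    def test_constant_input(self):
        records = [rec(pos=p, ad=10, dp=20) for p in range(100, 2001, 100)]
        scan = scan_genome(SNPIndexTrack.from_records(records), window_size=500, step=250)
        means = scan.windows["mean_index"].dropna()
        assert (means == 0.5).all()

    def test_window_mean_small_case(self):
        records = [
            rec(pos=10, ad=20, dp=20),
            rec(pos=20, ad=16, dp=20),
            rec(pos=30, ad=18, dp=20),
        ]
        scan = scan_genome(SNPIndexTrack.from_records(records), window_size=100, step=100)
        assert scan.windows.iloc[0]["mean_index"] == pytest.approx(0.9)

    def test_matches_bruteforce_windows(self):
        rng = np.random.default_rng(5)
        records = [
            rec(pos=int(p), ad=int(a), dp=20)
            for p, a in zip(rng.integers(1, 50_000, 300), rng.integers(0, 21, 300))
        ]
        track = SNPIndexTrack.from_records(records)
        scan = scan_genome(track, window_size=7_000, step=3_000)
        sites = track.sites
        for _, w in scan.windows.iterrows():
            sub = sites[(sites["pos"] >= w["start"]) & (sites["pos"] < w["start"] + 7_000)]
            if len(sub):
                assert w["mean_index"] == pytest.approx(sub["snp_index"].mean())
            else:
                assert np.isnan(w["mean_index"])

    def test_bad_window_params(self):
        track = SNPIndexTrack.from_records([rec()])
        with pytest.raises(ValueError):
            scan_genome(track, window_size=0)
        with pytest.raises(ValueError):
            scan_genome(track, step=0)


class TestPeakCalling:
    def test_flat_track_has_no_peaks(self):
        records = [rec(pos=p, ad=10, dp=20) for p in range(1000, 100_000, 1000)]
        scan = scan_genome(SNPIndexTrack.from_records(records), 10_000, 5_000)
        assert call_peak_regions(scan) == []

    def test_single_peak_contains_high_run(self):
        records = [rec(pos=p, ad=10, dp=20) for p in range(1000, 100_000, 1000)]
        records += [rec(pos=p, ad=20, dp=20, chrom="chr2") for p in range(1000, 20_000, 1000)]
        records += [rec(pos=p, ad=10, dp=20, chrom="chr2") for p in range(20_000, 100_000, 1000)]
        scan = scan_genome(SNPIndexTrack.from_records(records), 10_000, 5_000)
        peaks = call_peak_regions(scan, index_threshold=0.9, min_sites=3)
        assert len(peaks) == 1
        assert peaks[0].chrom == "chr2"
        assert peaks[0].contains("chr2", 10_000)
        assert peaks[0].top_site[1] == 1.0

    def test_two_mutants_map_to_their_own_chromosomes(self):
        """Paired simulation: each pool's top region sits on its own causal
        chromosome."""
        sc = simulate_cross_scenario(
            causal_positions={
                "mutA": ("chr3", 5_000_000, "G", "A"),
                "mutB": ("chr7", 5_000_000, "C", "T"),
            },
            pool_sizes={"mutA": 40, "mutB": 40},
            n_background=1000,
            seed=2,
        )
        tops = {}
        for name in ("mutA", "mutB"):
            others = [sc.pools[o] for o in sc.pools if o != name]
            peaks, _ = map_pipeline(
                sc.pools[name], sc.wildtype, others, chrom_lengths=sc.genome.lengths
            )
            tops[name] = peaks[0].chrom
        assert tops == {"mutA": "chr3", "mutB": "chr7"}

    def test_pipeline_deterministic(self):
        sc = simulate_cross_scenario(n_background=300, seed=3)
        args = (sc.pools["s140"], sc.wildtype, [sc.pools["s76"]])
        p1, _ = map_pipeline(*args, chrom_lengths=sc.genome.lengths)
        p2, _ = map_pipeline(*args, chrom_lengths=sc.genome.lengths)
        assert p1 == p2


class TestIndexDecayFit:
    def test_recovers_rate_from_exact_curve(self):
        d = np.linspace(0, 8e6, 50)
        y = 0.5 + 0.5 * np.exp(-2 * 4.0 * d / 1e6 / 100)
        assert fit_index_decay(d, y) == pytest.approx(4.0, rel=1e-6)
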