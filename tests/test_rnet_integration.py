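import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from termtk.io_formats import ThreePrimeEnd
from termtk.pipeline import call_strand_ends, score_nusg_pausing, screen_terminators
from termtk.rnet_integration import (
    RNETPeak,
    assign_rnet_peak,
    fisher_exact_2x2,
    filter_by_cohort,
    nusg_dependency,
    revise_terminator,
    weak_pair_enrichment,
)
from termtk.synthetic_data import (
    SimulationConfig,
    generate_genome_with_truth,
    rnet_offsets,
    simulate_rnet,
    simulate_tracks,
)
from termtk.termination_metrics import STRAINS

from conftest import make_track


def _rnet_track(length=400, bg=4.0, peaks=(), strand="+"):
    vals = np.full(length, float(bg))
    for pos, count in peaks:
        vals[pos - 1] = count
    return make_track(vals, strand=strand, kind="rnet_ends")


class TestAssignRnetPeak:
    def test_peak_and_normalisation(self):
        x = 300
        track = _rnet_track(bg=4.0, peaks=[(x + 2, 30.0)])
        peak = assign_rnet_peak(x, track)
        assert (peak.x_nascent, peak.offset, peak.raw) == (x + 2, 2, 30.0)
        assert peak.upstream_p75 == 4.0
        assert peak.norm == 7.5

    def test_zero_upstream_percentile_rejected(self):
        x = 300
        track = _rnet_track(bg=0.0, peaks=[(x + 1, 30.0)])
        assert assign_rnet_peak(x, track) is None

    def test_no_proximal_count_rejected(self):
        x = 300
        track = _rnet_track(bg=4.0, peaks=[(x + 9, 30.0)])
        # upstream is uniformly 4 but the proximal window holds no peak;
        # the most abundant proximal position is background-level
        vals = np.zeros(400)
        vals[x - 151 : x - 1] = 4.0  # upstream only, nothing in [x, x+4]
        track = make_track(vals, kind="rnet_ends")
        assert assign_rnet_peak(x, track) is None

    def test_tie_goes_downstream(self):
        x = 300
        track = _rnet_track(bg=1.0, peaks=[(x + 1, 30.0), (x + 3, 30.0)])
        assert assign_rnet_peak(x, track).x_nascent == x + 3

    def test_minus_strand_windows_mirrored(self):
        x = 100
        vals = np.full(400, 4.0)
        vals[x - 1 - 2] = 30.0  # x-2 on the forward axis = offset +2 on minus
        track = make_track(vals, strand="-", kind="rnet_ends")
        peak = assign_rnet_peak(x, track)
        assert (peak.x_nascent, peak.offset) == (x - 2, 2)

    def test_out_of_bounds_windows_error(self):
        track = _rnet_track(length=100)
        with pytest.raises(IndexError):
            assign_rnet_peak(50, track)


class TestCohortFilter:
    def _peaks(self, norms):
        return [
            RNETPeak(
                terminator_id=f"t{i}",
                x_nascent=100 + 10 * i,
                offset=0,
                raw=n * 4,
                upstream_p75=4.0,
                norm=n,
            )
            for i, n in enumerate(norms)
        ]

    def test_interpolated_p25_strict_cut(self):
        # norms {1,2,3,4}: interpolated p25 = 1.75, strict > keeps {2,3,4}
        kept = filter_by_cohort(self._peaks([1.0, 2.0, 3.0, 4.0]))
        assert sorted(p.norm for p in kept) == [2.0, 3.0, 4.0]

    def test_identical_norms_all_removed(self):
        assert filter_by_cohort(self._peaks([2.0] * 6)) == []

    def test_max_always_survives_distinct_cohort(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            norms = rng.permutation(np.arange(1, 13, dtype=float)).tolist()
            kept = filter_by_cohort(self._peaks(norms))
            assert max(norms) in {p.norm for p in kept}

    def test_removes_about_a_quarter_of_distinct_norms(self):
        for n in (8, 9, 12, 17, 40):
            norms = list(np.arange(1.0, n + 1.0))
            kept = filter_by_cohort(self._peaks(norms))
            removed = n - len(kept)
            assert math.floor(0.25 * n) <= removed <= math.floor(0.25 * n) + 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            filter_by_cohort([])


class TestNusgDependency:
    def test_log2_ratio(self):
        assert nusg_dependency(8.0, 2.0) == 2.0
        assert nusg_dependency(3.0, 3.0) == 0.0

    def test_absent_dnusg_floored_at_001(self):
        assert nusg_dependency(5.0, None) == pytest.approx(math.log2(5 / 0.01))
        assert nusg_dependency(5.0, None) == pytest.approx(8.9658, abs=1e-4)

    def test_floor_not_applied_to_observed_values(self):
        # an observed tiny abundance is used as-is, not floored
        assert nusg_dependency(5.0, 0.005) == pytest.approx(math.log2(1000))

    def test_nonpositive_wt_rejected(self):
        with pytest.raises(ValueError):
            nusg_dependency(0.0, 1.0)


class TestFisherExact:
    def test_uninformative_table(self):
        _, orr, p = fisher_exact_2x2(np.array([[1, 1], [1, 1]]))
        assert p == 1.0 and orr == 1.0

    def test_perfect_separation_five_five(self):
        _, orr, p = fisher_exact_2x2(np.array([[5, 0], [0, 5]]))
        assert p == pytest.approx(2 / 252)
        assert orr is None  # zero cells

    def test_odds_ratio_definition(self):
        _, orr, _ = fisher_exact_2x2(np.array([[10, 5], [2, 8]]))
        assert orr == 8.0

    def test_degenerate_margin_p_one(self):
        _, orr, p = fisher_exact_2x2(np.array([[0, 0], [3, 4]]))
        assert p == 1.0 and orr is None

    def test_matches_hypergeometric_enumeration_to_1e10(self):
        # oracle: enumerate the hypergeometric distribution directly for
        # every 2x2 table with N <= 50 (margins fixed)
        rng = np.random.default_rng(7)
        tables = []
        for _ in range(300):
            n = int(rng.integers(2, 51))
            a_plus_b = int(rng.integers(1, n))
            a_plus_c = int(rng.integers(1, n))
            lo = max(0, a_plus_b + a_plus_c - n)
            hi = min(a_plus_b, a_plus_c)
            a = int(rng.integers(lo, hi + 1))
            tables.append(
                (a, a_plus_b - a, a_plus_c - a, n - a_plus_b - a_plus_c + a)
            )
        for a, b, c, d in tables:
            n = a + b + c + d
            _, _, p = fisher_exact_2x2(np.array([[a, b], [c, d]]))
            rv = hypergeom(n, a + b, a + c)
            support = np.arange(max(0, (a + b) + (a + c) - n), min(a + b, a + c) + 1)
            probs = rv.pmf(support)
            p_oracle = probs[probs <= rv.pmf(a) * (1 + 1e-12)].sum()
            assert abs(p - p_oracle) < 1e-10, (a, b, c, d)


class TestWeakPairEnrichment:
    def test_tabulation_rule(self):
        table, orr, p = weak_pair_enrichment([1, 2, 0, 3], [0, 0, 1, 0])
        assert table.tolist() == [[3, 1], [1, 3]]
        assert orr == 9.0
        assert 0 < p <= 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            weak_pair_enrichment([], [1])


class TestSyntheticIntegration:
    def test_dependency_exact_on_noiseless_pause_mass(self, clean_world):
        genome = clean_world["genome"]
        truth = clean_world["truth"]
        tracks = clean_world["tracks"]
        terms = screen_terminators(
            genome,
            [
                e
                for strand in "+-"
                for e in call_strand_ends(tracks["WT"].termseq_ends[strand])
            ],
            {s: tracks[s].rnaseq for s in STRAINS},
        )
        df = score_nusg_pausing(
            genome,
            terms,
            clean_world["rnet"]["WT"],
            clean_world["rnet"]["dnusG"],
            apply_cohort_filter=False,
        )
        motif_x = {t.x_true for t in truth if t.has_pause_motif}
        for _, row in df.iterrows():
            expected = 2.0 if row.coordinate in motif_x else 0.0
            assert row.nusg_dependency == expected

    def test_offset_distribution_matches_planted_deltas(self, clean_world):
        genome = clean_world["genome"]
        truth = clean_world["truth"]
        cfg = clean_world["config"]
        wt = clean_world["rnet"]["WT"]
        planted = rnet_offsets(truth, cfg)
        for rec, delta in zip(truth, planted):
            peak = assign_rnet_peak(rec.x_true, wt[rec.strand])
            assert peak is not None and peak.offset == delta

    def test_zero_background_track_is_rejected_downstream(self):
        cfg = SimulationConfig(
            genome_length=8000, n_terminators=2, noise="none", seed=5, rnet_bg_lambda=0.0
        )
        genome, truth = generate_genome_with_truth(cfg)
        rnet = simulate_rnet(genome, truth, "WT", cfg)
        for rec in truth:
            assert assign_rnet_peak(rec.x_true, rnet[rec.strand]) is None

    def test_revised_hairpin_regains_weak_pairs_at_motif_terminators(self, clean_world):
        genome = clean_world["genome"]
        truth = clean_world["truth"]
        tracks = clean_world["tracks"]
        wt = clean_world["rnet"]["WT"]
        terms = screen_terminators(
            genome,
            [
                e
                for strand in "+-"
                for e in call_strand_ends(tracks["WT"].termseq_ends[strand])
            ],
            {s: tracks[s].rnaseq for s in STRAINS},
        )
        by_x = {t.call.end.x: t for t in terms}
        planted = dict(zip([r.x_true for r in truth], rnet_offsets(truth, clean_world["config"])))
        checked = 0
        for rec in truth:
            if not rec.has_pause_motif:
                continue
            term = by_x[rec.x_true]
            peak = assign_rnet_peak(rec.x_true, wt[rec.strand])
            hairpin, utract = revise_terminator(term.call, peak, genome)
            assert hairpin is not None and utract is not None
            # small trimming offsets keep the anchor on the planted
            # register, where the revised stem must expose its A-U bottom
            if planted[rec.x_true] <= 2:
                assert hairpin.terminal_weak_run >= 1
                assert hairpin.stem_bp > term.call.hairpin.stem_bp
                checked += 1
        assert checked >= 1
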