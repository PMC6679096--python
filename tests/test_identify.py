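"""Decision core: dedup, filters, screening, ranking, pipeline, stability."""

import itertools

import numpy as np
import pytest

from ancid import (
    FilterConfig,
    SequenceRecord,
    TaxonomyMap,
    deamination_screen,
    dedupe_hits,
    filter_hits,
    identify_pipeline,
    species_ranking,
    stability_analysis,
)
from ancid.align import query_coverage
from ancid.identify import UNIDENTIFIED
from ancid.presets import toy_study_config
from ancid.damage import simulate_reads

from conftest import make_hit

TAX = TaxonomyMap(
    {"MT001": "species_A", "MT002": "species_B", "MT003": "species_C"}
)


def aligned_hit(qid, sid, read, ref, pident=99.0, qstart=1, qlen=None):
    qlen = qlen or len(read)
    qend = qstart + len(read) - 1
    return make_hit(
        qid=qid, sid=sid, pident=pident, qstart=qstart, qend=qend, qlen=qlen,
        sstart=1, send=len(read), qaln=read, saln=ref,
    )


class TestDedupe:
    def test_unique_maximum_kept(self):
        hits = [
            make_hit(qid="r1", sid="MT001", pident=97.0),
            make_hit(qid="r1", sid="MT001", pident=99.0),
        ]
        (kept,) = dedupe_hits(hits, seed=0)
        assert kept.pident == 99.0

    def test_tie_reproducible_under_seed(self):
        hits = [
            make_hit(qid="r1", sid="MT001", pident=98.0, sstart=1, send=50),
            make_hit(qid="r1", sid="MT001", pident=98.0, sstart=500, send=549),
        ]
        picks = {dedupe_hits(hits, seed=7)[0].sstart for _ in range(5)}
        assert len(picks) == 1
        assert len(dedupe_hits(hits, seed=7)) == 1

    def test_distinct_subjects_all_retained(self):
        hits = [make_hit(qid="r1", sid=s) for s in ("MT001", "MT002", "MT003")]
        assert len(dedupe_hits(hits, seed=0)) == 3

    def test_matches_grouping_oracle(self, rng):
        hits = []
        for _ in range(500):
            hits.append(
                make_hit(
                    qid=f"r{int(rng.integers(0, 40))}",
                    sid=f"MT{int(rng.integers(1, 7)):03d}",
                    pident=float(rng.choice([96.0, 98.0, 98.0, 99.5, 100.0])),
                    sstart=int(rng.integers(1, 1000)),
                    send=int(rng.integers(1, 1000)) + 50,
                )
            )
        out = dedupe_hits(hits, seed=3)
        groups = {}
        for h in hits:
            groups.setdefault((h.qid, h.sid), []).append(h)
        assert len(out) == len(groups)
        for h in out:
            assert h.pident == max(g.pident for g in groups[(h.qid, h.sid)])


class TestFilterHits:
    def test_perfect_identity_removed_by_default(self):
        hit = make_hit(pident=100.0, mismatches=0)
        assert filter_hits([hit], FilterConfig()) == []

    def test_boundary_values_inclusive(self):
        # L exactly 98 and C exactly 96 both survive
        hit = make_hit(pident=98.0, qstart=1, qend=48, qlen=50, sstart=1, send=48)
        assert filter_hits([hit], FilterConfig()) == [hit]

    def test_keep_perfect_mode(self):
        hit = make_hit(pident=100.0, mismatches=0)
        assert filter_hits([hit], FilterConfig(exclude_perfect=False)) == [hit]

    def test_matches_predicate_oracle_and_monotone(self, rng):
        hits = []
        for i in range(1000):
            qlen = int(rng.integers(30, 101))
            qstart = int(rng.integers(1, 6))
            qend = int(rng.integers(qstart + 20, qlen + 1))
            hits.append(
                make_hit(
                    qid=f"r{i}", pident=float(round(rng.uniform(94, 100), 2)),
                    qstart=qstart, qend=qend, qlen=qlen,
                    sstart=1, send=qend - qstart + 1,
                )
            )
        cfg = FilterConfig()
        out = filter_hits(hits, cfg)
        expected = [
            h
            for h in hits
            if h.pident >= 98.0 and h.pident < 100.0 and query_coverage(h) >= 96.0
        ]
        assert out == expected
        stricter = filter_hits(hits, FilterConfig(L_min=99.0))
        assert set(id(h) for h in stricter) <= set(id(h) for h in out)


class TestDeaminationScreen:
    def test_terminal_ct_change_kept(self):
        read = "T" + "ACGT" * 12 + "A"  # 50 bp
        ref = "C" + "ACGT" * 12 + "A"
        hit = aligned_hit("r1", "MT001", read, ref)
        assert deamination_screen([hit], X=5) == [hit]

    def test_identical_alignment_removed_for_all_windows(self):
        read = "ACGT" * 12
        hit = aligned_hit("r1", "MT001", read, read)
        for X in (5, 6, 7, 8, 9, 10):
            assert deamination_screen([hit], X=X) == []

    def test_interior_change_outside_window_removed(self):
        read = list("ACGT" * 15)  # 60 bp
        ref = list(read)
        ref[29] = "C"
        read[29] = "T"  # C->T at position 30, far from both ends
        hit = aligned_hit("r1", "MT001", "".join(read), "".join(ref))
        assert deamination_screen([hit], X=10) == []
        assert deamination_screen([hit], X=30) == [hit]

    def test_ga_change_at_3prime_end_kept(self):
        read = "ACGT" * 12 + "GA"
        ref = "ACGT" * 12 + "GG"  # G->A at last position
        hit = aligned_hit("r1", "MT001", read, ref)
        assert deamination_screen([hit], X=5) == [hit]

    def test_reverse_substitution_does_not_qualify(self):
        read = "C" + "ACGT" * 12  # T->C is not deamination
        ref = "T" + "ACGT" * 12
        hit = aligned_hit("r1", "MT001", read, ref)
        assert deamination_screen([hit], X=10) == []

    def test_positions_count_over_full_read_with_trimmed_prefix(self):
        # alignment starts at read position 8; a C->T in column 1 sits at
        # read position 8, inside X=10 but outside X=5
        read = "T" + "ACGT" * 10
        ref = "C" + "ACGT" * 10
        hit = aligned_hit("r1", "MT001", read, ref, qstart=8, qlen=60)
        assert deamination_screen([hit], X=10) == [hit]
        assert deamination_screen([hit], X=5) == []

    def test_gap_columns_never_qualify(self):
        read = "ACGTA-CGTACGTACGTACGTACGTACGTA"
        ref = "ACGTATCGTACGTACGTACGTACGTACGTA"
        hit = make_hit(
            qid="r1", qstart=1, qend=29, qlen=29, sstart=1, send=30,
            qaln=read, saln=ref, alen=30, gapopens=1,
        )
        assert deamination_screen([hit], X=10) == []

    def test_missing_alignment_strings_error(self):
        with pytest.raises(ValueError, match="r1"):
            deamination_screen([make_hit(qid="r1")], X=5)

    def test_column_scan_matches_brute_force_oracle(self, rng):
        hits = []
        for i in range(300):
            n = int(rng.integers(30, 80))
            read = "".join(rng.choice(list("ACGT"), size=n))
            ref = list(read)
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, n))
                ref[p] = "ACGT"[int(rng.integers(0, 4))]
            hits.append(aligned_hit(f"r{i}", "MT001", read, "".join(ref)))
        X = 8
        kept = deamination_screen(hits, X=X)
        oracle = []
        for h in hits:
            qual = False
            for p, (qc, sc) in enumerate(zip(h.qaln, h.saln), start=1):
                if (p <= X or p > h.qlen - X) and (
                    (sc == "C" and qc == "T") or (sc == "G" and qc == "A")
                ):
                    qual = True
            if qual:
                oracle.append(h)
        assert kept == oracle


class TestSpeciesRanking:
    def test_povmh_and_ratio_arithmetic(self):
        hits = [make_hit(qid=f"r{i}", sid="MT001") for i in range(3)]
        hits.append(make_hit(qid="r9", sid="MT002"))
        r = species_ranking(hits, TAX, FilterConfig(min_vmh=4))
        assert r.rows[0] == ("species_A", 3, 75.0)
        assert r.rows[1] == ("species_B", 1, 25.0)
        assert r.R == pytest.approx(3.0)
        assert r.call == "species_A"
        assert sum(p for _, _, p in r.rows) == pytest.approx(100.0)

    def test_low_vmh_gives_unidentified(self):
        hits = [make_hit(qid="r1", sid="MT001"), make_hit(qid="r2", sid="MT001")]
        r = species_ranking(hits, TAX, FilterConfig(min_vmh=10))
        assert r.call == UNIDENTIFIED
        assert "low_vmh" in r.flags

    def test_zero_hits(self):
        r = species_ranking([], TAX, FilterConfig())
        assert r.total_vmh == 0 and r.call == UNIDENTIFIED

    def test_unresolvable_sid_named(self):
        with pytest.raises(KeyError, match="MT999"):
            species_ranking([make_hit(sid="MT999")], TAX, FilterConfig(min_vmh=1))

    def test_equal_counts_ordered_lexicographically(self):
        hits = [make_hit(qid="r1", sid="MT002"), make_hit(qid="r2", sid="MT001")]
        r = species_ranking(hits, TAX, FilterConfig(min_vmh=1))
        assert [row[0] for row in r.rows] == ["species_A", "species_B"]

    def test_mixture_fractions_recovered(self, toy_refs):
        from ancid.damage import SimConfig, SimSource

        refs, taxmap = toy_refs
        fracs = {"species_A": 0.6, "species_B": 0.3, "species_C": 0.1}
        cfg = SimConfig(
            sources=tuple(
                SimSource(tuple(refs[i : i + 1]), sp, f, None)
                for i, (sp, f) in enumerate(fracs.items())
            ),
            n_reads=3000,
            seq_error=0.0,
            seed=17,
        )
        reads, truth = simulate_reads(cfg)
        hits = [
            make_hit(qid=r.id, sid=truth.reads[r.id].sid, pident=99.0,
                     qstart=1, qend=len(r.seq), qlen=len(r.seq),
                     sstart=1, send=len(r.seq))
            for r in reads
        ]
        r = species_ranking(hits, taxmap, FilterConfig())
        assert [row[0] for row in r.rows] == ["species_A", "species_B", "species_C"]
        for row in r.rows:
            f = fracs[row[0]]
            se = 100 * np.sqrt(f * (1 - f) / 3000)
            assert abs(row[2] - 100 * f) < 3 * se


class TestPipeline:
    def test_pure_undamaged_sample_screen_off(self, toy_refs):
        refs, taxmap = toy_refs
        from ancid.damage import SimConfig, SimSource

        sim = SimConfig(
            sources=(SimSource(tuple(refs[0:1]), "species_A", 1.0, None),),
            n_reads=400, seed=2,
        )
        reads, _ = simulate_reads(sim)
        res = identify_pipeline(
            reads, refs, taxmap, FilterConfig(X=0, exclude_perfect=False)
        )
        assert res.post is None
        assert res.final.call == "species_A"
        assert res.final.rows[0][2] > 95.0

    def test_degenerate_config_never_crashes(self, toy_refs):
        refs, taxmap = toy_refs
        from ancid.damage import SimConfig, SimSource

        sim = SimConfig(
            sources=(SimSource(tuple(refs[0:1]), "species_A", 1.0, None),),
            n_reads=50, seq_error=0.0, seed=3,
        )
        reads, _ = simulate_reads(sim)
        # error-free reads all align at 100% identity; excluding perfect
        # hits at L_min=100 leaves nothing
        res = identify_pipeline(
            reads, refs, taxmap, FilterConfig(L_min=100.0, exclude_perfect=True)
        )
        assert res.final.call == UNIDENTIFIED
        assert res.final.total_vmh == 0

    def test_screening_raises_ratio_in_contaminated_sample(self, toy_refs):
        refs, taxmap = toy_refs
        _, _, sim = toy_study_config(
            0.3, n_reads=2500, seed=5, contaminant_fraction=0.5
        )
        reads, _ = simulate_reads(sim)
        res = identify_pipeline(reads, refs, taxmap, FilterConfig())
        assert res.pre.total_vmh >= res.post.total_vmh
        assert res.final.call == "species_A"
        pre_r = res.pre.R if res.pre.R is not None else np.inf
        post_r = res.post.R if res.post.R is not None else np.inf
        assert post_r > pre_r

    def test_monotone_stage_counts(self, toy_refs):
        refs, taxmap = toy_refs
        _, _, sim = toy_study_config(0.5, n_reads=1000, seed=9)
        reads, _ = simulate_reads(sim)
        res = identify_pipeline(reads, refs, taxmap, FilterConfig())
        assert res.n_dedup <= res.n_raw_hits
        assert res.n_filtered <= res.n_dedup
        assert res.n_screened <= res.n_filtered


class TestStability:
    def test_single_species_database_stable_from_first_depth(self, toy_refs):
        from ancid.damage import SimConfig, SimSource
        from ancid.presets import ENDOGENOUS_DAMAGE

        refs, taxmap = toy_refs
        sim = SimConfig(
            sources=(SimSource(tuple(refs[0:1]), "species_A", 1.0, ENDOGENOUS_DAMAGE),),
            n_reads=500, seed=4,
        )
        reads, _ = simulate_reads(sim)
        table, depth = stability_analysis(
            reads, refs[0:1], taxmap, FilterConfig(X=0),
            depths=(100, 500), k=1, reps=2, seed=0,
        )
        assert depth == 100

    def test_full_depth_subsample_equals_full_ranking(self, mixture):
        refs, taxmap, reads, hits = mixture
        cfg = FilterConfig(X=0)
        table, _ = stability_analysis(
            reads, refs, taxmap, cfg, depths=(len(reads),), k=5, reps=1,
            seed=0, hits=hits,
        )
        full = identify_pipeline(reads, refs, taxmap, cfg, hits=hits)
        assert table.iloc[0]["top_k"] == full.final.top(5)

    def test_reproducible_and_depth_skipping(self, mixture):
        refs, taxmap, reads, hits = mixture
        cfg = FilterConfig(X=0)
        kw = dict(depths=(100, 300, 1000, 3000), k=5, reps=2, seed=11, hits=hits)
        t1, d1 = stability_analysis(reads, refs, taxmap, cfg, **kw)
        t2, d2 = stability_analysis(reads, refs, taxmap, cfg, **kw)
        assert d1 == d2
        assert t1.drop(columns=["top_k"]).equals(t2.drop(columns=["top_k"]))
        with pytest.warns(UserWarning, match="exceeds"):
            _, d3 = stability_analysis(
                reads, refs, taxmap, cfg,
                depths=(100, 10**6), k=5, reps=1, seed=1, hits=hits,
            )
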