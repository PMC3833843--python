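"""Hit-table parsing, screening, curation with synteny, category assignment."""

import numpy as np
import pytest

from noveltx.homology import (
    AMENDED_GENE, LNC_CONSERVED, NO_HOMOLOGY, POTENTIAL_NOVEL,
    POTENTIAL_PSEUDOGENE, PSEUDOGENE, UTR_OF_KNOWN,
    CurateThresholds, HomologyHit, LocusContext, ScreenThresholds,
    assign_homology_category, curate_hits, read_hit_table,
    read_context_table, screen_hits,
)


def _hit(qid="q1", sid="s1", pident=95.0, covered=200, qlen=200,
         species="human", db="refseq", kind="coding_gene", gene=""):
    return HomologyHit(
        query_id=qid, subject_id=sid, subject_db=db, subject_species=species,
        percent_identity=pident, aligned_length=covered, query_length=qlen,
        covered_region=covered, subject_locus_kind=kind,
        subject_gene=gene or sid,
    )


def _ctx(eid, up=("GA",), down=("GB",), kind="unknown", gene=""):
    return LocusContext(eid, "chr1", tuple(up), tuple(down), kind, gene)


QCTX = _ctx("q1", up=("GA",), down=("GB",))


class TestReadHitTable:
    def _row(self, **kw):
        base = dict(q="q1", s="s1", pident=95.0, length=150, mm=5, go=0,
                    qs=1, qe=150, ss=1, se=150, ev=1e-30, bs=250.0,
                    db="refseq", sp="human")
        base.update(kw)
        return "\t".join(str(v) for v in base.values())

    def test_well_formed_row(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._row() + "\n")
        (h,) = read_hit_table(p, {"q1": 200})
        assert h.covered_region == 150
        assert h.total_identity == pytest.approx(95.0 * 150 / 200)
        assert h.mode == "interspecies"

    def test_column_count_mismatch_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._row() + "\textra_column\n")
        with pytest.raises(ValueError, match=":1"):
            read_hit_table(p, {"q1": 200})

    def test_covered_exceeding_query_length_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._row(qe=400) + "\n")
        with pytest.raises(ValueError, match="covered region"):
            read_hit_table(p, {"q1": 200})

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_hit_table(p, {}) == []

    def test_evalue_rechecked(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._row(ev=1e-3) + "\n")
        assert read_hit_table(p, {"q1": 200}) == []

    def test_context_table_round_trip(self, tmp_path):
        p = tmp_path / "ctx.tsv"
        p.write_text(
            "entity_id\tchrom\tupstream_gene\tdownstream_gene\tlocus_kind\tgene_symbol\n"
            "e1\tchr5\tGA,GB\t-\tcoding_gene\tGX\n"
        )
        ctx = read_context_table(p)["e1"]
        assert ctx.upstream_genes == ("GA", "GB")
        assert ctx.downstream_genes == ()
        assert ctx.locus_kind == "coding_gene" and ctx.gene_symbol == "GX"


class TestScreen:
    def test_interspecies_all_cuts_met(self):
        assert screen_hits([_hit(pident=92.0, covered=250, qlen=250)])

    def test_covered_region_cut(self):
        assert not screen_hits([_hit(pident=80.0, covered=90, qlen=90)])

    def test_intraspecies_needs_90(self):
        h = _hit(pident=85.0, covered=200, qlen=200, species="bovine")
        assert not screen_hits([h])
        assert screen_hits([_hit(pident=92.0, covered=200, qlen=200,
                                 species="bovine")])

    def test_total_identity_includes_coverage_fraction(self):
        # high mapping identity over half the query fails the total cut
        assert not screen_hits([_hit(pident=98.0, covered=120, qlen=400)])

    def test_monotone_in_thresholds(self, rng):
        hits = [
            _hit(qid=f"q{i}", pident=float(rng.uniform(60, 100)),
                 covered=int(rng.integers(50, 300)), qlen=300)
            for i in range(200)
        ]
        loose = {h.subject_id for h in screen_hits(hits, ScreenThresholds())}
        for tight in (
            ScreenThresholds(min_covered=150),
            ScreenThresholds(inter_mapping=85.0),
            ScreenThresholds(inter_total=95.0),
        ):
            assert {h.subject_id for h in screen_hits(hits, tight)} <= loose


class TestCurate:
    subject_ctx = {"s1": _ctx("s1", up=("GA",), down=("GZ",))}

    def test_long_covered_low_identity_accepted(self):
        (r,) = curate_hits([_hit(pident=78.0, covered=200, qlen=200)],
                           QCTX, self.subject_ctx)
        assert r.similarity_pass and r.syntenic and r.accepted and not r.rescued

    def test_rescue_short_covered_high_identity(self):
        (r,) = curate_hits([_hit(pident=91.0, covered=120, qlen=120)],
                           QCTX, self.subject_ctx)
        assert r.accepted and r.rescued

    def test_low_identity_short_covered_rejected(self):
        (r,) = curate_hits([_hit(pident=80.0, covered=120, qlen=120)],
                           QCTX, self.subject_ctx)
        assert not r.similarity_pass and not r.accepted

    def test_missing_context_marked_uncurated(self):
        (r,) = curate_hits([_hit(sid="unknown_subject")], QCTX, self.subject_ctx)
        assert r.similarity_pass and not r.has_context and not r.accepted

    def test_intraspecies_needs_identical_adjacent_loci(self):
        h = _hit(pident=96.0, covered=200, qlen=200, species="bovine")
        same = {"s1": _ctx("s1", up=("GA",), down=("GB",))}
        shifted = {"s1": _ctx("s1", up=("GA",), down=("GZ",))}
        (r1,) = curate_hits([h], QCTX, same)
        (r2,) = curate_hits([h], QCTX, shifted)
        assert r1.accepted
        assert r2.similarity_pass and not r2.syntenic

    def test_rescue_metric_switchable_to_total_identity(self):
        h = _hit(pident=95.0, covered=120, qlen=140)  # total = 81.4
        (on_mapping,) = curate_hits([h], QCTX, self.subject_ctx)
        (on_total,) = curate_hits(
            [h], QCTX, self.subject_ctx, CurateThresholds(rescue_on="total")
        )
        assert on_mapping.rescued and not on_total.similarity_pass

    def test_curated_subset_of_screened(self, rng):
        hits = [
            _hit(qid="q1", sid=f"s{i}", pident=float(rng.uniform(70, 100)),
                 covered=int(rng.integers(80, 300)), qlen=300)
            for i in range(100)
        ]
        screened = screen_hits(hits)
        assert set(h.subject_id for h in screened) <= {h.subject_id for h in hits}
        ctx = {h.subject_id: _ctx(h.subject_id) for h in hits}
        curated = [r for r in curate_hits(screened, QCTX, ctx) if r.accepted]
        assert {r.hit.subject_id for r in curated} <= {
            h.subject_id for h in screened
        }


class TestAssignCategory:
    def _cur(self, hits, subject_ctx):
        return curate_hits(hits, QCTX, subject_ctx)

    def test_lnc_subject_syntenic(self):
        ctx = {"s1": _ctx("s1", kind="noncoding_gene")}
        cur = self._cur([_hit(db="noncode", kind="noncoding_gene")], ctx)
        assert assign_homology_category("q1", cur, QCTX) == LNC_CONSERVED

    def test_coding_subject_discordant_context_is_potential_pseudogene(self):
        ctx = {"s1": _ctx("s1", up=("GX",), down=("GY",), kind="coding_gene")}
        cur = self._cur([_hit(kind="coding_gene")], ctx)
        assert assign_homology_category("q1", cur, QCTX) == POTENTIAL_PSEUDOGENE

    def test_no_hits_is_species_specific_candidate(self):
        assert assign_homology_category("q1", [], QCTX) == NO_HOMOLOGY

    def test_coding_syntenic_within_1kb_is_utr(self):
        cur = self._cur([_hit(kind="coding_gene")],
                        {"s1": _ctx("s1", kind="coding_gene")})
        assert assign_homology_category(
            "q1", cur, QCTX, neighbour_distance=800
        ) == UTR_OF_KNOWN

    def test_coding_syntenic_flanking_ortholog_is_amended(self):
        cur = self._cur([_hit(kind="coding_gene", gene="GA")],
                        {"s1": _ctx("s1", kind="coding_gene")})
        assert assign_homology_category(
            "q1", cur, QCTX, neighbour_distance=5000
        ) == AMENDED_GENE

    def test_coding_syntenic_no_local_annotation_is_novel_gene(self):
        cur = self._cur([_hit(kind="coding_gene", gene="GQ")],
                        {"s1": _ctx("s1", kind="coding_gene")})
        assert assign_homology_category(
            "q1", cur, QCTX, neighbour_distance=5000
        ) == POTENTIAL_NOVEL

    def test_annotated_pseudogene_subject(self):
        cur = self._cur([_hit(kind="pseudogene", db="noncode")],
                        {"s1": _ctx("s1", kind="pseudogene")})
        assert assign_homology_category("q1", cur, QCTX) == PSEUDOGENE

    def test_best_hit_wins_on_disagreement(self):
        ctx = {
            "lnc": _ctx("lnc", kind="noncoding_gene"),
            "cod": _ctx("cod", up=("GX",), down=("GY",), kind="coding_gene"),
        }
        strong_lnc = _hit(sid="lnc", pident=98.0, db="noncode",
                          kind="noncoding_gene")
        weak_coding = _hit(sid="cod", pident=80.0, kind="coding_gene")
        cur = self._cur([weak_coding, strong_lnc], ctx)
        assert assign_homology_category("q1", cur, QCTX) == LNC_CONSERVED

    def test_planted_pseudogene_recall_is_total(self, pipeline_result, sim):
        _, classified, _, _ = pipeline_result
        planted = {r.transcript_id for r in sim.truth
                   if r.category == "pseudogene_copy"}
        got = {c.transcript_id for c in classified
               if c.homology_category == POTENTIAL_PSEUDOGENE}
        assert planted <= got

    def test_conserved_fraction_tracks_conservation_rate(self, tmp_path):
        # generator planted at rate 0.7; recovered conserved fraction must
        # sit inside the binomial 95% band around it
        from noveltx.simulate import SimulationConfig, simulate

        cfg = SimulationConfig.noiseless(seed=17, conservation_rate=0.7)
        s = simulate(cfg)
        flags = [r.conserved for r in s.truth if r.category == "conserved_lncRNA"]
        rate = np.mean(flags)
        half = 1.96 * np.sqrt(0.7 * 0.3 / len(flags))
        assert abs(rate - 0.7) <= half + 1e-9
        # and every conserved plant carries a screen-passing hit
        with_hits = {r["qseqid"] for r in s.inter_hits}
        for rec in s.truth:
            if rec.category == "conserved_lncRNA":
                assert (rec.transcript_id in with_hits) == rec.conserved
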