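"""The driver-prioritization ladder: band estimation, SNP removal, branches."""

import numpy as np
import pytest

import mutopt as m
from mutopt.driver_filter import FilterConfig, aa_position
from mutopt.synthetic_data import recurrence_catalog_from_frame

from conftest import snv_records


def snv(sample="T1", chrom="chr1", pos=1000, ref="C", alt="A", tri="ACA",
        gene="Kras", effect="missense", aa="Q61L", vaf=0.4, group="G1"):
    return m.SNVRecord(sample, chrom, pos, ref, alt, tri, gene, effect, aa, vaf, group)


def catalog(*entries):
    return m.RecurrenceCatalog(
        m.RecurrenceEntry(g, g.upper(), p, c, n) for g, p, c, n in entries
    )


KRAS_CAT = catalog(("Kras", 61, "Q61L", 300), ("Kras", 12, "G12D", 5000))


class TestVafThresholds:
    def test_hand_computed_band(self):
        low, high = m.vaf_thresholds([0.3, 0.4, 0.5])  # sample SD exactly 0.1
        assert (low, high) == (pytest.approx(0.1), pytest.approx(0.7))

    def test_degenerate_band_warns(self):
        with pytest.warns(UserWarning):
            assert m.vaf_thresholds([0.4, 0.4, 0.4]) == (0.4, 0.4)

    def test_clipping_and_minimum_n(self):
        low, high = m.vaf_thresholds([0.1, 0.9])
        assert low == 0.0 and high == 1.0
        with pytest.raises(ValueError):
            m.vaf_thresholds([0.4])


class TestRemoveSnps:
    def test_group_shared_snv_flagged(self):
        a = snv(sample="T1", group="ex3op")
        b = snv(sample="T2", group="ex3op")
        kept, flagged = m.remove_snps([a, b], FilterConfig())
        assert kept == [] and len(flagged) == 2

    def test_same_snv_in_different_groups_kept(self):
        a = snv(sample="T1", group="g1")
        b = snv(sample="T2", group="g2")
        kept, _ = m.remove_snps([a, b], FilterConfig())
        assert kept == [a, b]

    def test_coordinate_cluster_flagged(self):
        a = snv(pos=1000)
        b = snv(pos=1040, alt="G", aa="Q61R")
        kept, flagged = m.remove_snps([a, b], FilterConfig())
        assert kept == [] and {r for _, r in flagged} == {
            "clustered by genomic coordinates"
        }

    def test_full_vaf_and_known_positions_flagged(self):
        full = snv(vaf=1.0)
        known = snv(pos=99, vaf=0.4)
        clean = snv(pos=500_000, vaf=0.42)
        kept, flagged = m.remove_snps(
            [full, known, clean], FilterConfig(), known_snps={("chr1", 99)}
        )
        assert kept == [clean]
        assert [r for _, r in flagged] == ["VAF 100%", "known SNP position"]

    def test_too_many_samples_flagged(self):
        rows = [snv(sample=f"T{i}", group=f"g{i}") for i in range(9)]
        kept, flagged = m.remove_snps(rows, FilterConfig())
        assert kept == [] and all("samples" in r for _, r in flagged)


class TestCancerGeneBranch:
    GENES = ["Kras", "Braf", "Trp53"]

    @pytest.mark.parametrize(
        "effect,vaf,expect",
        [
            ("missense", 0.30, "cancer_gene_hit"),
            ("missense", 0.10, "rejected"),  # below the 15.7%-style floor
            ("synonymous", 0.30, "rejected"),
        ],
    )
    def test_floor_and_effect(self, effect, vaf, expect):
        [c] = m.cancer_gene_branch([snv(effect=effect, vaf=vaf)], self.GENES, 0.157)
        assert c.tier == expect
        assert all(isinstance(t, tuple) and len(t) == 3 for t in c.trail)

    def test_unlisted_gene_rejected_and_empty_list_error(self):
        [c] = m.cancer_gene_branch([snv(gene="Nope")], self.GENES, 0.157)
        assert c.tier == "rejected"
        with pytest.raises(ValueError):
            m.cancer_gene_branch([snv()], [], 0.157)


class TestAllGeneBranch:
    def run_one(self, record, ref_vaf=None, cat=KRAS_CAT, config=None,
                band=(0.157, 0.722)):
        refs = {} if ref_vaf is None else {record.sample_id: ref_vaf}
        [c] = m.all_gene_branch([record], cat, band, refs, config or FilterConfig())
        return c

    def test_clean_candidate_passes_all_stages(self):
        c = self.run_one(snv(vaf=0.45), ref_vaf=0.45)
        assert c.tier == "putative_driver"
        assert len(c.trail) == 7 and all(ok for _, ok, _ in c.trail)

    def test_relative_band_rejection(self):
        # 0.80 > 1.5 x 0.40 = 0.60 -> rejected at the relative-VAF stage
        c = self.run_one(snv(vaf=0.80), ref_vaf=0.40, band=(0.157, 0.9))
        assert c.tier == "rejected"
        assert c.trail[-1][0] == "all_gene:relative_vaf_band"

    def test_same_gene_clustering_rejects_both(self):
        a = snv(pos=1000, vaf=0.4)
        b = snv(pos=500_000, alt="G", aa="Q61R", vaf=0.45)
        out = m.all_gene_branch(
            [a, b], KRAS_CAT, (0.157, 0.722), {}, FilterConfig()
        )
        assert [c.tier for c in out] == ["rejected", "rejected"]
        assert all(c.trail[-1][0] == "all_gene:single_snv_per_gene" for c in out)

    def test_gene_recurrence_and_position_stages(self):
        c = self.run_one(snv(gene="Unknown"))
        assert c.trail[-1][0] == "all_gene:gene_recurrence"
        # catalogued gene but novel position
        c = self.run_one(snv(aa="A999A".replace("A999A", "M7T")))
        assert c.trail[-1][0] == "all_gene:human_position"
        # same position, different change: conserved-position rule admits it
        c = self.run_one(snv(aa="Q61P"))
        assert c.tier == "putative_driver"


class TestFinalize:
    def test_relative_floor_drops_low_vaf(self):
        keep = snv(vaf=0.40, aa="Q61L")
        drop = snv(pos=700_000, gene="Gpn1", aa="M7T", vaf=0.20)
        cat = catalog(("Kras", 61, "Q61L", 300), ("Gpn1", 7, "M7T", 20))
        cands = m.all_gene_branch(
            [keep, drop], cat, (0.1, 0.722), {"T1": 0.40}, FilterConfig()
        )
        final = m.finalize_drivers(cands, {"T1": 0.40}, cat, FilterConfig())
        assert [c.snv.aa_change for c in final] == ["Q61L"]  # 0.20 < 0.65*0.40

    def test_initiating_promotion_needs_more_than_ten_patients(self):
        ten = catalog(("Kras", 61, "Q61L", 10))
        eleven = catalog(("Kras", 61, "Q61L", 11))
        for cat, tier in [(ten, "putative_driver"), (eleven, "initiating_driver")]:
            cands = m.all_gene_branch(
                [snv(vaf=0.4)], cat, (0.1, 0.722), {"T1": 0.4}, FilterConfig()
            )
            [c] = m.finalize_drivers(cands, {"T1": 0.4}, cat, FilterConfig())
            assert c.tier == tier

    def test_driver_negative_tumor_self_reference(self):
        only = snv(gene="Gpn1", aa="M7T", vaf=0.50, pos=900_000)
        cat = catalog(("Gpn1", 7, "M7T", 8))  # below the initiating threshold
        cands = m.all_gene_branch([only], cat, (0.1, 0.722), {}, FilterConfig())
        [c] = m.finalize_drivers(cands, {}, cat, FilterConfig())
        assert c.snv.vaf == 0.50 and c.tier == "putative_driver"

    def test_cancer_branch_needs_catalogued_position(self):
        hit = snv(gene="Trp53", aa="R270H", vaf=0.4, pos=800_000)
        cands = m.cancer_gene_branch([hit], ["Trp53"], 0.157)
        final = m.finalize_drivers(cands, {"T1": 0.4}, KRAS_CAT, FilterConfig())
        assert final == []  # position not mutated in human
        cat = catalog(("Trp53", 270, "R270H", 8))
        final = m.finalize_drivers(
            m.cancer_gene_branch([hit], ["Trp53"], 0.157),
            {"T1": 0.4}, cat, FilterConfig(),
        )
        assert [c.tier for c in final] == ["cancer_gene_hit"]


class TestLadder:
    def test_degenerate_config_reduces_to_nonsyn_non_snp(self, tumor_bundle):
        config = FilterConfig(
            min_vaf_call=0.0,
            vaf_band=(0.0, 1.0),
            rel_band=(0.0, np.inf),
            rel_floor=0.0,
            gene_recurrence_min=0,
            initiating_recurrence_min=10**9,
        )
        snvs = snv_records(tumor_bundle.snvs)
        cat = recurrence_catalog_from_frame(tumor_bundle.recurrence)
        res = m.run_driver_ladder(snvs, tumor_bundle.gene_list, cat, config)
        kept, _ = m.remove_snps(snvs, config)
        expected = {
            (s.sample_id, *s.key)
            for s in kept
            if s.effect in ("missense", "nonsense")
            # the same-gene-per-sample clustering stage still applies
            and sum(
                1 for t in kept
                if t.sample_id == s.sample_id and t.gene == s.gene
            ) == 1
        }
        got = {(c.snv.sample_id, *c.snv.key) for c in res.final}
        assert got == expected

    def test_trail_completeness_and_idempotence(self, tumor_bundle):
        snvs = snv_records(tumor_bundle.snvs)
        cat = recurrence_catalog_from_frame(tumor_bundle.recurrence)
        res = m.run_driver_ladder(snvs, tumor_bundle.gene_list, cat)
        assert len(res.all_candidates) == len(snvs)
        for c in res.all_candidates:
            assert c.tier in ("initiating_driver", "putative_driver",
                              "cancer_gene_hit", "rejected")
            assert c.trail, "every SNV must carry a non-empty trail"
            if c.tier == "rejected":
                assert any(not ok for _, ok, _ in c.trail)
        # running the ladder on its own survivors keeps them all
        survivors = [c.snv for c in res.final]
        res2 = m.run_driver_ladder(
            survivors, tumor_bundle.gene_list, cat,
            FilterConfig(vaf_band=res.vaf_band),
        )
        assert {(c.snv.sample_id, *c.snv.key) for c in res2.final} == {
            (c.snv.sample_id, *c.snv.key) for c in res.final
        }

    def test_recovers_planted_drivers(self, tumor_bundle):
        snvs = snv_records(tumor_bundle.snvs)
        cat = recurrence_catalog_from_frame(tumor_bundle.recurrence)
        res = m.run_driver_ladder(snvs, tumor_bundle.gene_list, cat)
        truth = {
            (r.sample, r.chrom, int(r.pos), r.ref, r.alt)
            for r in tumor_bundle.ground_truth.drivers.itertuples(index=False)
        }
        got = {(c.snv.sample_id, *c.snv.key) for c in res.final}
        assert truth <= got
        assert all(c.tier == "initiating_driver" for c in res.final
                   if (c.snv.sample_id, *c.snv.key) in truth)

    def test_aa_position_parsing(self):
        assert aa_position("Q61L") == 61
        assert aa_position("V637E") == 637
        assert aa_position("p.?") is None and aa_position("") is None
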