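"""Hit filtering, RPKM, per-cell copy number, roll-ups, MAG rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habspec.gene_profiles import (
    GeneProfileError,
    HIT_COLUMNS,
    ThresholdConfig,
    copy_number,
    filter_hits,
    gene_profile,
    mag_occurrence,
    mag_quality_tier,
    pathway_presence,
    process_rollup,
    rpkm,
)


def hits_df(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def hit(query, family, identity, coverage=95.0, bitscore=100.0, length=900):
    return (query, f"{family}_t1", family, identity, coverage, bitscore, length)


class TestFilterHits:
    def test_identity_boundary_default_family(self):
        h = hits_df([hit("r1", "DsrA", 49.9), hit("r2", "DsrA", 50.0)])
        kept, removed = filter_hits(h, ThresholdConfig())
        assert kept["query_id"].tolist() == ["r2"]
        assert removed["low_identity"] == 1

    def test_family_override_coxl(self):
        cfg = ThresholdConfig(identity_overrides={"CoxL": 60.0})
        h = hits_df([hit("r1", "CoxL", 55.0), hit("r2", "CoxL", 61.0)])
        kept, _ = filter_hits(h, cfg)
        assert kept["query_id"].tolist() == ["r2"]

    def test_coverage_strictly_greater(self):
        h = hits_df(
            [hit("r1", "DsrA", 80.0, coverage=80.0), hit("r2", "DsrA", 80.0, coverage=80.1)]
        )
        kept, removed = filter_hits(h, ThresholdConfig())
        assert kept["query_id"].tolist() == ["r2"]
        assert removed["low_coverage"] == 1

    def test_best_hit_by_bitscore_then_identity(self):
        h = hits_df(
            [
                hit("r1", "Sqr", 70.0, bitscore=90.0),
                hit("r1", "DsrA", 60.0, bitscore=100.0),
                hit("r2", "Sqr", 75.0, bitscore=50.0),
                hit("r2", "FCC", 80.0, bitscore=50.0),
            ]
        )
        kept, removed = filter_hits(h, ThresholdConfig())
        by_query = kept.set_index("query_id")
        assert by_query.loc["r1", "gene_family"] == "DsrA"  # higher bitscore
        assert by_query.loc["r2", "gene_family"] == "FCC"  # tie -> higher identity
        assert removed["not_best_hit"] == 2

    def test_conservation_of_rows(self):
        rng = np.random.default_rng(0)
        h = hits_df(
            [
                hit(f"r{i % 40}", "Sqr", rng.uniform(30, 100), rng.uniform(60, 100))
                for i in range(120)
            ]
        )
        kept, removed = filter_hits(h, ThresholdConfig())
        assert len(kept) + sum(removed.values()) == len(h)

    def test_unknown_override_family_rejected(self):
        with pytest.raises(GeneProfileError, match="unknown gene families"):
            ThresholdConfig(
                identity_overrides={"NotAGene": 60.0}, known_families={"Sqr"}
            )

    def test_threshold_config_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "default_identity: 50\ncoverage: 80\nmin_read_length_bp: 140\n"
            "identity_overrides:\n  CoxL: 60\n  PsbA: 70\n  PsaA: 80\n"
        )
        cfg = ThresholdConfig.from_yaml(p)
        assert cfg.identity_for("PsaA") == 80
        assert cfg.identity_for("Sqr") == 50


class TestRpkm:
    def test_hand_arithmetic(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_reads(self):
        assert rpkm(0, 500, 10_000) == 0.0

    def test_linearity_in_total(self):
        assert rpkm(7, 300, 2_000_000) == pytest.approx(rpkm(7, 300, 1_000_000) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(GeneProfileError):
            rpkm(1, 0, 100)
        with pytest.raises(GeneProfileError):
            rpkm(1, 100, 0)


class TestCopyNumber:
    def test_half_community(self):
        assert copy_number(10.0, [20.0] * 14) == pytest.approx(0.5)

    def test_three_marker_toy_geomean(self):
        assert copy_number(20.0, [10.0, 20.0, 40.0]) == pytest.approx(1.0)
        assert stats.gmean([10.0, 20.0, 40.0]) == pytest.approx(8000 ** (1 / 3))

    def test_zero_marker_errors_unless_floored(self):
        markers = [10.0] * 13 + [0.0]
        with pytest.raises(GeneProfileError, match="zero RPKM"):
            copy_number(5.0, markers)
        floored = copy_number(5.0, markers, pseudo_floor=True)
        assert floored > 0

    def test_scale_invariance_to_read_duplication(self):
        """Doubling every read count and the total leaves RPKM ratios, and
        hence copy numbers, unchanged."""
        gene = rpkm(50, 900, 1_000_000)
        markers = [rpkm(c, 600, 1_000_000) for c in (30, 40, 50)]
        gene2 = rpkm(100, 900, 2_000_000)
        markers2 = [rpkm(2 * c, 600, 2_000_000) for c in (30, 40, 50)]
        assert copy_number(gene, markers) == pytest.approx(copy_number(gene2, markers2))


class TestProcessRollup:
    def _profile(self, percents):
        df = pd.DataFrame({"community_percent": percents})
        df.index.name = "gene_family"
        return df

    def test_sulfide_oxidation_sum(self):
        prof = self._profile({"Sqr": 54.0, "FCC": 12.0})
        out = process_rollup(prof, {"sulfide_oxidation": ["Sqr", "FCC"]})
        assert out.loc["sulfide_oxidation", "community_percent"] == pytest.approx(66.0)
        assert not out.loc["sulfide_oxidation", "capped"]

    def test_cap_at_100(self):
        prof = self._profile({"g1": 60.0, "g2": 70.0})
        out = process_rollup(prof, {"p": ["g1", "g2"]})
        assert out.loc["p", "community_percent"] == 100.0
        assert out.loc["p", "capped"]

    def test_photosynthesis_averaged(self):
        prof = self._profile({"PsaA": 10.0, "PsbA": 20.0})
        out = process_rollup(prof, {"oxygenic_photosynthesis": ["PsaA", "PsbA"]})
        assert out.loc["oxygenic_photosynthesis", "community_percent"] == pytest.approx(15.0)

    def test_monotone_below_cap(self):
        low = process_rollup(self._profile({"g1": 10.0, "g2": 20.0}), {"p": ["g1", "g2"]})
        high = process_rollup(self._profile({"g1": 15.0, "g2": 20.0}), {"p": ["g1", "g2"]})
        assert high.loc["p", "community_percent"] > low.loc["p", "community_percent"]

    def test_empty_process_errors(self):
        with pytest.raises(GeneProfileError, match="no member genes"):
            process_rollup(self._profile({"g": 1.0}), {"p": []})


class TestMagRules:
    def mags(self):
        return pd.DataFrame(
            {
                "order": ["Woeseiales", "Woeseiales", "Desulfobacterales"] + ["Flavobacteriales"] * 4,
                "completeness": [50.0, 50.0, 95.0, 100.0, 100.0, 100.0, 100.0],
                "contamination": [1.0] * 7,
                "genes_present": [
                    frozenset({"Sqr"}),
                    frozenset(),
                    frozenset({"DsrA"}),
                    frozenset({"Sqr"}),
                    frozenset({"Sqr"}),
                    frozenset({"Sqr"}),
                    frozenset(),
                ],
            },
            index=pd.Index([f"mag{i}" for i in range(7)], name="mag_id"),
        )

    def test_completeness_normalization(self):
        occ = mag_occurrence(self.mags(), "Sqr")
        woe = occ.loc["Woeseiales"]
        assert woe["raw_percent"] == pytest.approx(50.0)
        assert woe["normalized_percent"] == pytest.approx(100.0)

    def test_full_completeness_identity(self):
        occ = mag_occurrence(self.mags(), "Sqr")
        flavo = occ.loc["Flavobacteriales"]
        assert flavo["raw_percent"] == pytest.approx(75.0)
        assert flavo["normalized_percent"] == pytest.approx(75.0)

    def test_cap_flagged_with_uncapped_value(self):
        mags = self.mags()
        mags.loc["mag0", "genes_present"] = frozenset({"Sqr"})
        mags.loc["mag1", "genes_present"] = frozenset({"Sqr"})
        occ = mag_occurrence(mags, "Sqr")
        woe = occ.loc["Woeseiales"]
        assert woe["normalized_percent_uncapped"] == pytest.approx(200.0)
        assert woe["normalized_percent"] == 100.0
        assert woe["capped"]

    @pytest.mark.parametrize(
        "completeness,contamination,tier",
        [(95, 3, "high"), (80, 4, "medium"), (45, 2, "fail"),
         (90, 3, "medium"), (95, 5, "medium"), (50, 9, "fail"), (51, 10, "fail")],
    )
    def test_quality_tiers(self, completeness, contamination, tier):
        assert mag_quality_tier(completeness, contamination) == tier

    def test_tier_range_validation(self):
        with pytest.raises(GeneProfileError):
            mag_quality_tier(101, 0)

    @pytest.mark.parametrize(
        "detected,required,present",
        [(8, 10, True), (7, 10, False), (0, 5, False), (5, 5, True)],
    )
    def test_pathway_presence_strict(self, detected, required, present):
        genes = {f"g{i}" for i in range(detected)}
        pathway = {f"g{i}" for i in range(required)}
        ok, frac = pathway_presence(genes, pathway)
        assert ok is present
        assert frac == pytest.approx(detected / required)

    def test_empty_pathway_errors(self):
        with pytest.raises(GeneProfileError):
            pathway_presence({"g"}, set())


class TestGeneProfile:
    def test_end_to_end_copy_number(self):
        """3 markers at equal RPKM and a gene at half their RPKM: copy number
        0.5, community percent 50."""
        rows = []
        for fam, n in (("m1", 40), ("m2", 40), ("m3", 40), ("gene", 20)):
            rows += [hit(f"{fam}_r{i}", fam, 80.0, length=600) for i in range(n)]
        profile = gene_profile(
            hits_df(rows), ThresholdConfig(), total_reads=1_000_000, marker_families=["m1", "m2", "m3"]
        )
        assert profile.loc["gene", "copy_number_per_cell"] == pytest.approx(0.5)
        assert profile.loc["gene", "community_percent"] == pytest.approx(50.0)
        assert profile.loc["m1", "copy_number_per_cell"] == pytest.approx(1.0)

    def test_missing_marker_errors(self):
        rows = [hit("r1", "m1", 80.0)]
        with pytest.raises(GeneProfileError, match="zero RPKM"):
            gene_profile(hits_df(rows), ThresholdConfig(), 1000, ["m1", "m2"])
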