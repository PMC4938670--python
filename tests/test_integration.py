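"""Physical placement by exact flank match, multi-hit resolution, contig
anchoring, Marey correlation and discordance detection."""

import numpy as np
import pandas as pd
import pytest

from salmap.integration import (
    AnchorReport,
    _longest_monotone_idx,
    anchor_contigs,
    collate_placements,
    detect_discordance,
    integrate,
    linkage_group_chromosomes,
    per_chrom_correlation,
    place_markers_by_flank,
    resolve_multihit,
)
from salmap.simulate.genome import decode, encode, reverse_complement


def _flank_df(flanks):
    return pd.DataFrame(
        {"flank": flanks, "snp_offset": 35},
        index=pd.Index([f"m{k}" for k in range(len(flanks))], name="marker_id"),
    )


@pytest.fixture(scope="module")
def toy_genome(rng=np.random.default_rng(77)):
    return {
        "chr1": rng.integers(0, 4, 50_000, dtype=np.uint8),
        "chr2": rng.integers(0, 4, 50_000, dtype=np.uint8),
        "contig_01": rng.integers(0, 4, 5_000, dtype=np.uint8),
    }


class TestPlacement:
    def test_lifted_flank_found_at_true_position(self, toy_genome):
        pos = 1_000
        fl = decode(toy_genome["chr2"][pos - 35 : pos + 36])
        hits = place_markers_by_flank(_flank_df([fl]), toy_genome)
        h = hits[hits["status"] == "hit"]
        assert len(h) == 1
        assert tuple(h.iloc[0][["target", "pos", "strand"]]) == ("chr2", pos, "+")

    def test_reverse_complement_same_coordinate_minus_strand(self, toy_genome):
        pos = 2_345
        fl = decode(reverse_complement(toy_genome["chr1"][pos - 35 : pos + 36]))
        hits = place_markers_by_flank(_flank_df([fl]), toy_genome)
        h = hits[hits["status"] == "hit"]
        assert len(h) == 1
        assert tuple(h.iloc[0][["target", "pos", "strand"]]) == ("chr1", pos, "-")

    def test_snp_site_is_wildcard(self, toy_genome):
        pos = 4_321
        fl = list(decode(toy_genome["chr1"][pos - 35 : pos + 36]))
        fl[35] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fl[35]]  # other allele
        hits = place_markers_by_flank(_flank_df(["".join(fl)]), toy_genome)
        h = hits[hits["status"] == "hit"]
        assert len(h) == 1 and h.iloc[0]["pos"] == pos

    def test_multi_hit_recorded(self, toy_genome):
        g = {k: v.copy() for k, v in toy_genome.items()}
        g["chr2"][10_000:10_071] = g["chr1"][5_000 - 35 : 5_000 + 36]  # duplicate
        fl = decode(g["chr1"][5_000 - 35 : 5_000 + 36])
        hits = place_markers_by_flank(_flank_df([fl]), g)
        plc = collate_placements(hits)
        assert plc.iloc[0]["n_exact_hits"] == 2
        assert plc.iloc[0]["status"] == "multi"

    def test_bad_flank_skipped(self, toy_genome):
        fl = "N" * 71
        hits = place_markers_by_flank(_flank_df([fl]), toy_genome)
        assert list(hits["status"]) == ["bad_flank"]

    def test_no_hit_reported(self, toy_genome):
        rng = np.random.default_rng(123)
        fl = decode(rng.integers(0, 4, 71, dtype=np.uint8))
        hits = place_markers_by_flank(_flank_df([fl]), toy_genome)
        assert list(hits["status"]) == ["no_hit"]

    def test_strand_consistency_under_genome_reversal(self, toy_genome):
        pos = 3_000
        fl = decode(toy_genome["chr1"][pos - 35 : pos + 36])
        flipped = {"chr1": reverse_complement(toy_genome["chr1"])}
        hits = place_markers_by_flank(_flank_df([fl]), flipped)
        h = hits[hits["status"] == "hit"].iloc[0]
        assert h["pos"] == len(toy_genome["chr1"]) - 1 - pos
        assert h["strand"] == "-"


class TestResolution:
    def _setup(self):
        gmap = pd.DataFrame(
            {
                "linkage_group": ["LG1", "LG1", "LG2"],
                "order_index": [0, 1, 0],
                "male_cM": [0.0, 1.0, 0.0],
                "female_cM": [0.0, 2.0, 0.0],
            },
            index=pd.Index(["m0", "m1", "m2"], name="marker_id"),
        )
        hits = pd.DataFrame(
            {
                "marker_id": ["m0", "m1", "m1", "m2"],
                "target": ["chr3", "chr1", "chr3", "chr1"],
                "pos": [100, 200, 300, 400],
                "strand": ["+"] * 4,
                "status": ["hit"] * 4,
            }
        )
        return gmap, hits

    def test_hit_on_linkage_chromosome_retained(self):
        gmap, hits = self._setup()
        plc = collate_placements(hits)
        lg2c = {"LG1": "chr3", "LG2": "chr1"}
        out = resolve_multihit(plc, hits, gmap, lg2c)
        assert out.loc["m1", "status"] == "resolved_by_linkage"
        assert out.loc["m1", "target"] == "chr3"
        assert out.loc["m1", "pos"] == 300

    def test_two_hits_same_chromosome_unresolved(self):
        gmap, hits = self._setup()
        hits.loc[1, "target"] = "chr3"  # both m1 hits now on chr3
        plc = collate_placements(hits)
        out = resolve_multihit(plc, hits, gmap, {"LG1": "chr3"})
        assert out.loc["m1", "status"] == "unresolved"

    def test_unmapped_marker_unresolved(self):
        gmap, hits = self._setup()
        gmap = gmap.drop("m1")
        plc = collate_placements(hits)
        out = resolve_multihit(plc, hits, gmap, {"LG1": "chr3"})
        assert out.loc["m1", "status"] == "unresolved"

    def test_majority_vote_lg_assignment(self):
        gmap, hits = self._setup()
        plc = collate_placements(hits)
        lg2c = linkage_group_chromosomes(plc, gmap, {"chr1", "chr3"})
        assert lg2c == {"LG1": "chr3", "LG2": "chr1"}


class TestCorrelation:
    def test_hand_computed_pearson(self):
        gmap = pd.DataFrame(
            {
                "linkage_group": ["LG1"] * 5,
                "order_index": range(5),
                "male_cM": [0.0, 1, 2, 3, 4],
                "female_cM": [0.0, 1, 2, 3, 4],
            },
            index=pd.Index([f"m{k}" for k in range(5)], name="marker_id"),
        )
        plc = pd.DataFrame(
            {
                "target": ["chr1"] * 5,
                "pos": [0, 10, 20, 40, 30],
                "strand": ["+"] * 5,
                "n_exact_hits": [1] * 5,
                "status": ["unique"] * 5,
            },
            index=gmap.index,
        )
        out = per_chrom_correlation(gmap, plc, {"LG1": "chr1"})
        assert out.loc["chr1", "male_r"] == pytest.approx(0.9)

    def test_reversed_order_gives_abs_one(self):
        gmap = pd.DataFrame(
            {
                "linkage_group": ["LG1"] * 4,
                "order_index": range(4),
                "male_cM": [0.0, 1, 2, 3],
                "female_cM": [0.0, 1, 2, 3],
            },
            index=pd.Index([f"m{k}" for k in range(4)], name="marker_id"),
        )
        plc = pd.DataFrame(
            {
                "target": ["chr1"] * 4,
                "pos": [300, 200, 100, 0],
                "strand": ["+"] * 4,
                "n_exact_hits": [1] * 4,
                "status": ["unique"] * 4,
            },
            index=gmap.index,
        )
        out = per_chrom_correlation(gmap, plc, {"LG1": "chr1"})
        assert out.loc["chr1", "male_r"] == pytest.approx(1.0)

    def test_too_few_markers_flagged(self):
        gmap = pd.DataFrame(
            {
                "linkage_group": ["LG1"] * 2,
                "order_index": range(2),
                "male_cM": [0.0, 1],
                "female_cM": [0.0, 1],
            },
            index=pd.Index(["m0", "m1"], name="marker_id"),
        )
        plc = pd.DataFrame(
            {
                "target": ["chr1"] * 2,
                "pos": [0, 10],
                "strand": ["+"] * 2,
                "n_exact_hits": [1] * 2,
                "status": ["unique"] * 2,
            },
            index=gmap.index,
        )
        out = per_chrom_correlation(gmap, plc, {"LG1": "chr1"})
        assert out.loc["chr1", "undefined"]


class TestAnchoring:
    def _placements(self, targets, groups):
        n = len(targets)
        plc = pd.DataFrame(
            {
                "target": targets,
                "pos": range(n),
                "strand": ["+"] * n,
                "n_exact_hits": [1] * n,
                "status": ["unique"] * n,
            },
            index=pd.Index([f"m{k}" for k in range(n)], name="marker_id"),
        )
        gmap = pd.DataFrame(
            {
                "linkage_group": groups,
                "order_index": range(n),
                "male_cM": [0.0] * n,
                "female_cM": [0.0] * n,
            },
            index=plc.index,
        )
        return plc, gmap

    def test_unanimous_support_anchors(self):
        plc, gmap = self._placements(["ctgA"] * 3, ["LG1"] * 3)
        rep = anchor_contigs(plc, gmap, {"LG1": "chr5"}, {"ctgA": 1000, "ctgB": 500})
        assert rep.table.loc["ctgA", "chrom"] == "chr5"
        assert rep.table.loc["ctgB", "chrom"] == ""
        assert rep.anchored_bp == 1000
        assert rep.anchored_bp == rep.table[rep.table["chrom"] != ""]["length"].sum()

    def test_tie_is_unassigned(self):
        plc, gmap = self._placements(["ctgA"] * 4, ["LG1", "LG1", "LG2", "LG2"])
        rep = anchor_contigs(
            plc, gmap, {"LG1": "chr5", "LG2": "chr7"}, {"ctgA": 1000}
        )
        assert rep.table.loc["ctgA", "chrom"] == ""
        assert rep.n_anchored == 0

    def test_min_support_gate(self):
        plc, gmap = self._placements(["ctgA"], ["LG1"])
        rep = anchor_contigs(plc, gmap, {"LG1": "chr5"}, {"ctgA": 800}, min_support=2)
        assert rep.n_anchored == 0


class TestDiscordance:
    def test_longest_monotone_subsequence(self):
        assert list(_longest_monotone_idx(np.array([1, 2, 3, 4]))) == [0, 1, 2, 3]
        assert list(_longest_monotone_idx(np.array([4, 3, 2, 1]))) == [0, 1, 2, 3]
        got = _longest_monotone_idx(np.array([1, 5, 2, 3, 4]))
        assert list(got) == [0, 2, 3, 4]

    def _case(self, order_by_pos):
        n = len(order_by_pos)
        ids = [f"m{k}" for k in range(n)]
        gmap = pd.DataFrame(
            {
                "linkage_group": ["LG1"] * n,
                "order_index": order_by_pos,
                "male_cM": np.asarray(order_by_pos, float),
                "female_cM": np.asarray(order_by_pos, float),
            },
            index=pd.Index(ids, name="marker_id"),
        )
        plc = pd.DataFrame(
            {
                "target": ["chr1"] * n,
                "pos": np.arange(n) * 1000,
                "strand": ["+"] * n,
                "n_exact_hits": [1] * n,
                "status": ["unique"] * n,
            },
            index=gmap.index,
        )
        return gmap, plc

    def test_concordant_chromosome_has_no_segments(self):
        gmap, plc = self._case(list(range(10)))
        segs, conc = detect_discordance(gmap, plc, {"LG1": "chr1"})
        assert segs == []
        assert len(conc["chr1"]) == 10

    def test_translocated_block_flagged(self):
        # physical order: 0..4, then markers with genetic order 10..14
        # displaced, then 5..9
        order = list(range(5)) + list(range(10, 15)) + list(range(5, 10))
        gmap, plc = self._case(order)
        segs, conc = detect_discordance(gmap, plc, {"LG1": "chr1"}, min_run=3)
        assert len(segs) == 1
        assert len(segs[0].marker_ids) == 5
        assert segs[0].start_bp == 5000 and segs[0].end_bp == 9000

    def test_short_runs_below_gate_ignored(self):
        order = [0, 1, 3, 2, 4, 5, 7, 6, 8, 9]  # two isolated swaps
        gmap, plc = self._case(order)
        segs, _ = detect_discordance(gmap, plc, {"LG1": "chr1"}, min_run=3)
        assert segs == []


class TestEndToEnd:
    def test_clean_fixture_places_uniquely_and_anchors_truthfully(
        self, clean_fixture
    ):
        from salmap.linkage import build_genetic_map

        fx = clean_fixture
        res = build_genetic_map(fx.gm, error_rate=0.0, seed=2)
        out = integrate(
            fx.flanks, dict(fx.genome.records()), res.genetic_map,
            chromosomes=set(fx.genome.chromosomes),
        )
        plc = out.placements
        # all flanks are genuine substrings: everything places
        assert (plc["status"] == "unique").all()
        # placements match generation-time truth
        truth = fx.truth.markers
        for mid, row in plc.iterrows():
            assert row["target"] == truth.loc[mid, "record"]
            assert row["pos"] == truth.loc[mid, "record_pos"]
        # linkage-group -> chromosome map is a bijection onto the 3 chromosomes
        assert sorted(out.lg_to_chrom.values()) == sorted(fx.genome.chromosomes)
        # contigs with mapped markers anchor to their true source chromosome
        by_name = {c.name: c for c in fx.genome.contigs}
        anchored = out.anchors.table[out.anchors.table["chrom"] != ""]
        for contig, row in anchored.iterrows():
            assert row["chrom"] == by_name[contig].source_chromosome
        # Marey correlations are high on the error-free fixture (male
        # informative meioses are sparse at this scale, so female only)
        ok = out.correlations[~out.correlations["undefined"]]
        assert (ok["female_r"] > 0.85).all()
        # conservation: anchored bp equals the sum of assigned contig lengths
        assert out.anchors.anchored_bp == int(anchored["length"].sum())
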