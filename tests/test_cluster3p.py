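"""Overlap clustering, polyA detection, replicate validation, counting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tagseq3p.annot import GeneIndex, GeneModel
from tagseq3p.cluster3p import (
    MetaCluster,
    PolyAPolicy,
    TagCluster,
    assign_and_count,
    build_clusters,
    detect_polya,
    group_replicates,
    quantify,
    validate_metacluster,
)
from tagseq3p.simdata import SimConfig, simulate_annotation, simulate_tag_reads

from conftest import make_record


def brute_force_components(intervals):
    """Union-find over all pairwise overlaps; the clustering oracle."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(intervals)), 2):
        (s1, e1), (s2, e2) = intervals[i], intervals[j]
        if s1 < e2 and s2 < e1:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g), len(g))
        for g in groups.values()
    )


def record_at(start, end, strand="+", **kw):
    m = end - start
    return make_record(start=start, cigar=(("M", m),), strand=strand, **kw)


class TestBuildClusters:
    def test_transitive_overlap_merges(self):
        recs = [record_at(100, 175), record_at(150, 225), record_at(300, 375)]
        clusters = build_clusters(recs, "s1")
        spans = [(c.start, c.end, c.n_reads) for c in clusters]
        assert spans == [(100, 225, 2), (300, 375, 1)]

    def test_strand_separation(self):
        recs = [
            record_at(100, 175),
            record_at(150, 225, strand="-"),
            record_at(300, 375),
        ]
        clusters = build_clusters(recs, "s1")
        assert len(clusters) == 3

    def test_touching_intervals_do_not_overlap(self):
        clusters = build_clusters(
            [record_at(100, 175), record_at(175, 250)], "s1"
        )
        assert len(clusters) == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        recs = [
            record_at(int(s), int(s) + int(rng.integers(20, 120)))
            for s in rng.integers(0, 2000, size=80)
        ]
        a = build_clusters(recs, "s")
        order = rng.permutation(len(recs))
        b = build_clusters([recs[i] for i in order], "s")
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        intervals = []
        for s in rng.integers(0, 3000, size=n):
            intervals.append((int(s), int(s) + int(rng.integers(1, 150))))
        recs = [record_at(s, e) for s, e in intervals]
        got = [
            (c.start, c.end, c.n_reads) for c in build_clusters(recs, "s")
        ]
        assert sorted(got) == brute_force_components(intervals)


class TestDetectPolyA:
    def test_plus_strand_trailing_clip(self):
        rec = make_record(
            cigar=(("M", 69), ("S", 6)), sequence="C" * 69 + "AAAAAA"
        )
        assert detect_polya(rec) == (True, 6)

    def test_purity_below_threshold(self):
        rec = make_record(
            cigar=(("M", 69), ("S", 6)), sequence="C" * 69 + "AAGAAA"
        )
        assert detect_polya(rec) == (False, 6)  # 5/6 < 0.9

    def test_minus_strand_uses_leading_t_clip(self):
        rec = make_record(
            cigar=(("S", 6), ("M", 69)),
            strand="-",
            sequence="TTTTTT" + "C" * 69,
        )
        assert detect_polya(rec) == (True, 6)
        # same bases but clip on the wrong (trailing) end: no 3' clip
        rec2 = make_record(
            cigar=(("M", 69), ("S", 6)),
            strand="-",
            sequence="C" * 69 + "TTTTTT",
        )
        assert detect_polya(rec2) == (False, 0)

    def test_short_clip_rejected(self):
        rec = make_record(cigar=(("M", 71), ("S", 4)),
                          sequence="C" * 71 + "AAAA")
        assert detect_polya(rec) == (False, 4)

    def test_min_tail_configurable(self):
        rec = make_record(cigar=(("M", 71), ("S", 4)),
                          sequence="C" * 71 + "AAAA")
        assert detect_polya(rec, PolyAPolicy(min_tail=3)) == (True, 4)


def tc(sample, start, end, n=1, polya=0, ref="c", strand="+"):
    return TagCluster(sample, ref, strand, start, end, n, polya)


class TestGroupReplicates:
    def test_overlap_merge_across_replicates(self):
        clusters = {
            "rep1": [tc("rep1", 100, 200)],
            "rep2": [tc("rep2", 150, 250)],
            "rep3": [tc("rep3", 400, 500)],
        }
        metas = group_replicates(clusters, {"g": ["rep1", "rep2", "rep3"]})["g"]
        spans = [(m.start, m.end, len(m.members)) for m in metas]
        assert spans == [(100, 250, 2), (400, 500, 1)]

    def test_identical_clusters_merge_to_one(self):
        clusters = {
            f"rep{i}": [tc(f"rep{i}", 10, 90)] for i in (1, 2, 3)
        }
        metas = group_replicates(clusters, {"g": list(clusters)})["g"]
        assert len(metas) == 1 and len(metas[0].members) == 3

    def test_unknown_sample_fatal(self):
        with pytest.raises(ValueError, match="replicate group"):
            group_replicates({"s1": [tc("s1", 0, 10)]}, {"g": ["s2"]})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_cross_sample_brute_force(self, seed):
        rng = np.random.default_rng(seed + 10)
        clusters, all_iv = {}, []
        for r in range(3):
            sid = f"rep{r}"
            ivs = []
            pos = 0
            for _ in range(int(rng.integers(5, 40))):
                pos += int(rng.integers(1, 200))
                end = pos + int(rng.integers(1, 120))
                ivs.append((pos, end))
                pos = end  # per-sample clusters stay disjoint
            clusters[sid] = [tc(sid, s, e) for s, e in ivs]
            all_iv.extend(ivs)
        metas = group_replicates(clusters, {"g": list(clusters)})["g"]
        got = sorted((m.start, m.end, len(m.members)) for m in metas)
        assert got == brute_force_components(all_iv)


class TestValidateMetacluster:
    def meta(self, polya_counts):
        members = [
            tc(f"rep{i}", 0, 100, n=max(5, c), polya=c)
            for i, c in enumerate(polya_counts)
        ]
        return MetaCluster("c", "+", 0, 100, members)

    @pytest.mark.parametrize(
        "counts,expected",
        [((2, 0, 0), True), ((1, 1, 1), False), ((0, 0, 0), False)],
    )
    def test_per_replicate_rule(self, counts, expected):
        assert validate_metacluster(self.meta(counts)) is expected

    def test_truth_table_per_replicate_vs_pooled(self):
        for counts in itertools.product((0, 1, 2), repeat=3):
            per = validate_metacluster(self.meta(counts),
                                       mode="per_replicate")
            pooled = validate_metacluster(self.meta(counts), mode="pooled")
            assert per == (max(counts) >= 2)
            assert pooled == (sum(counts) >= 2)
            assert (per != pooled) == (sum(counts) >= 2 > max(counts))

    def test_empty_meta_fatal(self):
        with pytest.raises(ValueError):
            validate_metacluster(MetaCluster("c", "+", 0, 1, []))


class TestAssignAndCount:
    @pytest.fixture
    def index(self):
        return GeneIndex(
            [
                GeneModel("g1", "c", 1000, 2000, "+"),
                GeneModel("g2", "c", 2050, 3000, "+"),
            ]
        )

    @pytest.fixture
    def samples(self):
        return pd.DataFrame(
            {
                "genotype": ["G"] * 3,
                "time_point": ["T"] * 3,
                "replicate": ["1", "2", "3"],
            },
            index=pd.Index(["rep1", "rep2", "rep3"], name="sample_id"),
        )

    def validated_meta(self, start, end, reads):
        members = [
            tc(sid, start, end, n=n, polya=2) for sid, n in reads.items()
        ]
        m = MetaCluster("c", "+", start, end, members)
        m.validated = True
        return m

    def test_counts_per_sample(self, index, samples):
        meta = self.validated_meta(1500, 1700,
                                   {"rep1": 10, "rep2": 7, "rep3": 12})
        matrix, inter = assign_and_count([meta], index, samples)
        assert list(matrix.counts.loc["g1"]) == [10, 7, 12]
        assert matrix.counts.loc["g2"].sum() == 0
        assert inter == []

    def test_maximal_overlap_wins(self, index, samples):
        # spans g1 by 300 and g2 by 40
        meta = self.validated_meta(1700, 2090, {"rep1": 5})
        matrix, _ = assign_and_count([meta], index, samples)
        assert matrix.counts.at["g1", "rep1"] == 5
        assert matrix.counts.at["g2", "rep1"] == 0

    def test_intergenic_reported_not_counted(self, index, samples):
        meta = self.validated_meta(5000, 5100, {"rep1": 4})
        matrix, inter = assign_and_count([meta], index, samples)
        assert matrix.counts.to_numpy().sum() == 0
        assert len(inter) == 1 and inter[0]["score"] == 4

    def test_unvalidated_meta_ignored(self, index, samples):
        meta = self.validated_meta(1500, 1700, {"rep1": 9})
        meta.validated = False
        matrix, inter = assign_and_count([meta], index, samples)
        assert matrix.counts.to_numpy().sum() == 0 and inter == []

    def test_unknown_reference_fatal(self, samples):
        idx = GeneIndex([GeneModel("g1", "c", 0, 10, "+")])
        meta = self.validated_meta(0, 5, {"rep1": 3})
        meta.reference = "other"
        with pytest.raises(ValueError, match="other"):
            assign_and_count([meta], idx, samples)


class TestQuantify:
    def test_noise_free_recovery_is_exact(self, sim_fixture):
        result = quantify(sim_fixture["sheet"], sim_fixture["gff"])
        truth = sim_fixture["truth"].true_counts
        pd.testing.assert_frame_equal(
            result.matrix.counts.loc[truth.index, truth.columns], truth
        )
        assert result.stage_counts["reads_intergenic"] == 0

    def test_without_polya_matrix_is_all_zero(self, tmp_path):
        cfg = SimConfig(n_genes=10, seed=9, polya_fraction=0.0)
        ann = simulate_annotation(cfg)
        gff = tmp_path / "a.gff3"
        ann.write_gff3(gff)
        sheet, _ = simulate_tag_reads(cfg, ann, tmp_path / "reads")
        result = quantify(sheet, gff)
        assert result.matrix.counts.to_numpy().sum() == 0
        assert result.stage_counts["metaclusters_validated"] == 0

    def test_read_conservation(self, sim_fixture):
        result = quantify(sim_fixture["sheet"], sim_fixture["gff"])
        s = result.stage_counts
        assert (
            s["reads_assigned"] + s["reads_intergenic"] + s["reads_rejected"]
            == s["reads_filtered"]
        )

    def test_empty_alignment_files(self, tmp_path, caplog):
        from conftest import write_sam

        rows = []
        for i in (1, 2, 3):
            sam = write_sam(tmp_path / f"s{i}.sam", "")
            rows.append(
                {"sample_id": f"s{i}", "path": str(sam), "genotype": "G",
                 "time_point": "T", "replicate": str(i)}
            )
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\nchr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        )
        with caplog.at_level("WARNING"):
            result = quantify(pd.DataFrame(rows), gff)
        assert result.matrix.counts.to_numpy().sum() == 0
        assert "no clusters" in caplog.text
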