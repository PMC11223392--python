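"""Panel joining, coverage accounting, and exon-block transcript coverage."""

import numpy as np
import pandas as pd
import pytest

from xplatcord.containers import ExpressionMatrix, InputError
from xplatcord.gtfio import read_gtf, write_gtf
from xplatcord.panels import (
    ProbeAlignment,
    ProbeRecord,
    TranscriptModel,
    coverage_summary,
    map_probe_pairs,
    probe_covers_transcript,
    read_panel_tsv,
    strip_version,
    summarize_to_genes,
    transcript_coverage,
    write_panel_tsv,
)


def probe(pid, platform, tx, label="Coding", gene="g1"):
    return ProbeRecord(pid, platform, label, gene, frozenset(tx))


class TestMapProbePairs:
    def test_small_worked_example(self):
        # brute-force over the 4-pair cross product: only (a1, b1) share t1
        panel_a = [probe("a1", "A", {"t1", "t2"}), probe("a2", "A", {"t3"})]
        panel_b = [probe("b1", "B", {"t1"}), probe("b2", "B", {"t4"})]
        join = map_probe_pairs(panel_a, panel_b)
        assert join.pairs == [("a1", "b1", frozenset({"t1"}))]
        assert join.mapped_probe_count == 2
        assert join.covered_transcript_count == 1

    def test_disjoint_universes_empty_join(self):
        join = map_probe_pairs([probe("a1", "A", {"t1"})], [probe("b1", "B", {"t2"})])
        assert join.pairs == []
        assert join.mapped_probe_count == 0

    def test_duplicate_probe_id_rejected(self):
        dup = [probe("a1", "A", {"t1"}), probe("a1", "A", {"t2"})]
        with pytest.raises(InputError, match="duplicate"):
            map_probe_pairs(dup, [probe("b1", "B", {"t1"})])

    def test_version_suffix_stripped_by_default(self):
        # version drift (.4 -> .5) must not break the join
        a = [probe("a1", "A", {"ENST00000615680.4"})]
        b = [probe("b1", "B", {"ENST00000615680.5"})]
        assert len(map_probe_pairs(a, b).pairs) == 1
        assert map_probe_pairs(a, b, strip_versions=False).pairs == []

    def test_join_symmetry(self, rng):
        panels = []
        for plat in ("A", "B"):
            panels.append(
                [
                    probe(
                        f"{plat}{i}",
                        plat,
                        {f"t{j}" for j in rng.choice(30, size=rng.integers(1, 4), replace=False)},
                    )
                    for i in range(25)
                ]
            )
        fwd = map_probe_pairs(panels[0], panels[1])
        rev = map_probe_pairs(panels[1], panels[0])
        assert {(a, b, ts) for a, b, ts in fwd.pairs} == {
            (b, a, ts) for a, b, ts in rev.pairs
        }
        assert fwd.mapped_probe_count <= len(panels[0]) + len(panels[1])

    def test_one_to_one_filter(self):
        a = [probe("a1", "A", {"t1"}), probe("a2", "A", {"t2"})]
        b = [probe("b1", "B", {"t1"}), probe("b2", "B", {"t2"}), probe("b3", "B", {"t2"})]
        nn = map_probe_pairs(a, b)
        assert len(nn.pairs) == 3
        # a2 pairs with two B probes, so every pair involving it is dropped
        oo = map_probe_pairs(a, b, one_to_one=True)
        assert oo.pairs == [("a1", "b1", frozenset({"t1"}))]

    def test_strip_version_helper(self):
        assert strip_version("ENST0001.4") == "ENST0001"
        assert strip_version("ENST0001") == "ENST0001"
        assert strip_version("no.digits.x") == "no.digits.x"


class TestCoverageSummary:
    def test_recount_oracle_on_synthetic_panels(self, small_truth, small_config):
        from xplatcord.synthdata import generate_panels

        pa, pb, _, _ = generate_panels(small_truth, small_config)
        join = map_probe_pairs(pa, pb)
        table = coverage_summary(pa, pb, join)
        in_pair = {x for a, b, _ in join.pairs for x in (a, b)}
        for label in table.index.drop("Total"):
            assert table.loc[label, "probes_A"] == sum(1 for p in pa if p.label == label)
            assert table.loc[label, "mapped_A"] == sum(
                1 for p in pa if p.label == label and p.transcript_ids
            )
            assert table.loc[label, "overlapping"] == sum(
                1 for p in pa + pb if p.label == label and p.probe_id in in_pair
            )
        # Total row equals column sums; total overlap = mapped probe count
        assert (
            table.loc["Total"] == table.drop(index="Total").sum(axis=0)
        ).all()
        assert table.loc["Total", "overlapping"] == join.mapped_probe_count

    def test_single_label_toy_panel(self):
        a = [probe("a1", "A", {"t1"}), probe("a2", "A", {"t9"}), probe("a3", "A", set())]
        b = [probe("b1", "B", {"t1"})]
        join = map_probe_pairs(a, b)
        table = coverage_summary(a, b, join)
        assert table.loc["Coding", "probes_A"] == 3
        assert table.loc["Coding", "mapped_A"] == 2
        assert table.loc["Coding", "overlapping"] == 2  # a1 and b1

    def test_unknown_label_rejected(self, tmp_path):
        df = pd.DataFrame(
            [{"probe_id": "x", "platform": "A", "label": "Bogus", "gene_id": "g",
              "transcript_ids": "t1"}]
        )
        path = tmp_path / "panel.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(InputError, match="Bogus"):
            read_panel_tsv(path)


def spliced_projection_oracle(aln, model):
    """Per-base oracle: project every exonic base to transcript coordinates
    and require the probe's bases to be exonic and contiguous."""
    if aln.chrom != model.chrom or aln.strand != model.strand:
        return False
    tx_coord = {}
    t = 0
    for s, e in model.exons:
        for g in range(s, e):
            tx_coord[g] = t
            t += 1
    probe_bases = [g for s, e in aln.blocks for g in range(s, e)]
    if any(g not in tx_coord for g in probe_bases):
        return False
    ts = sorted(tx_coord[g] for g in probe_bases)
    return all(b - a == 1 for a, b in zip(ts, ts[1:])) and len(ts) == len(set(ts))


class TestTranscriptCoverage:
    one_exon = TranscriptModel("t1", "g1", "chr1", "+", [(100, 200)])
    three_exon = TranscriptModel(
        "t3", "g1", "chr1", "+", [(100, 200), (300, 400), (500, 600)]
    )

    def test_block_inside_single_exon_covered(self):
        aln = ProbeAlignment("p", "chr1", "+", [(120, 170)])
        assert probe_covers_transcript(aln, self.one_exon)

    def test_one_base_overhang_not_covered(self):
        aln = ProbeAlignment("p", "chr1", "+", [(150, 201)])
        assert not probe_covers_transcript(aln, self.one_exon)

    def test_junction_spanning_blocks_must_abut(self):
        covered = ProbeAlignment("p", "chr1", "+", [(380, 400), (500, 530)])
        assert probe_covers_transcript(covered, self.three_exon)
        gap_in_tx = ProbeAlignment("p", "chr1", "+", [(380, 399), (500, 530)])
        assert not probe_covers_transcript(gap_in_tx, self.three_exon)
        not_at_junction = ProbeAlignment("p", "chr1", "+", [(380, 395), (395, 400)])
        # blocks abut genomically inside one exon: contiguous, covered
        assert probe_covers_transcript(not_at_junction, self.three_exon)

    def test_strand_mismatch(self):
        aln = ProbeAlignment("p", "chr1", "-", [(120, 170)])
        assert not probe_covers_transcript(aln, self.one_exon)
        assert probe_covers_transcript(aln, self.one_exon, match_strand=False)

    def test_malformed_block_rejected(self):
        with pytest.raises(InputError):
            ProbeAlignment("p", "chr1", "+", [(10, 10)])
        with pytest.raises(InputError):
            TranscriptModel("t", "g", "chr1", "+", [(5, 2)])

    def test_agrees_with_per_base_oracle_on_random_models(self, rng):
        n_agree = 0
        for case in range(1000):
            n_exons = int(rng.integers(1, 4))
            exons = []
            pos = int(rng.integers(0, 50))
            for _ in range(n_exons):
                length = int(rng.integers(5, 60))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(1, 40))
            strand = "+" if rng.random() < 0.5 else "-"
            model = TranscriptModel(f"t{case}", "g", "chr1", strand, exons)
            span = exons[-1][1] - exons[0][0]
            n_blocks = int(rng.integers(1, 4))
            starts = np.sort(rng.integers(exons[0][0] - 5, exons[-1][1] + 5, size=n_blocks))
            blocks = []
            prev_end = -(10**9)
            for s in starts:
                s = max(int(s), prev_end + 1)
                e = s + int(rng.integers(3, 25))
                blocks.append((s, e))
                prev_end = e
            aln = ProbeAlignment(f"p{case}", "chr1", strand, blocks)
            got = probe_covers_transcript(aln, model)
            want = spliced_projection_oracle(aln, model)
            assert got == want, f"case {case}: {blocks} vs {exons}"
            n_agree += got
        # sanity: the random battery exercises both outcomes
        assert 0 < n_agree < 1000

    def test_transcript_coverage_mapping(self):
        aln = [ProbeAlignment("p1", "chr1", "+", [(120, 150)])]
        cov = transcript_coverage(aln, [self.one_exon, self.three_exon])
        assert cov == {"p1": {"t1", "t3"}}


class TestSummarizeToGenes:
    def _panel(self):
        return [
            ProbeRecord("p1", "B", "Coding", "gA", frozenset({"t1"})),
            ProbeRecord("p2", "B", "Coding", "gA", frozenset({"t2"})),
            ProbeRecord("p3", "B", "Coding", "gB", frozenset({"t3"})),
            ProbeRecord("p4", "B", "Unassigned", None, frozenset()),
        ]

    def test_counts_sum_within_gene(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [10, 5, 7, 3]}, index=["p1", "p2", "p3", "p4"]),
            kind="counts",
        )
        out, dropped = summarize_to_genes(mat, self._panel())
        assert out.values.loc["gA", "s1"] == 15
        assert out.values.loc["gB", "s1"] == 7
        assert dropped == ["p4"]

    def test_log2_intensities_averaged(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [8.0, 10.0, 7.0, 1.0]}, index=["p1", "p2", "p3", "p4"]),
            kind="log2_intensity",
        )
        out, _ = summarize_to_genes(mat, self._panel())
        assert out.values.loc["gA", "s1"] == pytest.approx(9.0)

    def test_missing_feature_named_in_error(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [1]}, index=["mystery"]), kind="counts"
        )
        with pytest.raises(InputError, match="mystery"):
            summarize_to_genes(mat, self._panel())

    def test_matches_groupby_oracle_on_random_fixture(self, rng):
        genes = [f"g{i}" for i in range(50)]
        probes = []
        rows = []
        for i, g in enumerate(genes):
            for j in range(int(rng.integers(1, 4))):
                pid = f"p{i}_{j}"
                probes.append(ProbeRecord(pid, "B", "Coding", g, frozenset({f"t{i}"})))
                rows.append(pid)
        vals = pd.DataFrame(
            rng.integers(0, 100, size=(len(rows), 4)),
            index=rows,
            columns=[f"s{k}" for k in range(4)],
        )
        out, _ = summarize_to_genes(ExpressionMatrix(vals, "counts"), probes)
        gene_of = {p.probe_id: p.gene_id for p in probes}
        expected = vals.groupby(vals.index.map(gene_of)).sum()
        pd.testing.assert_frame_equal(
            out.values.sort_index(), expected.sort_index(), check_names=False
        )


class TestIO:
    def test_panel_tsv_round_trip(self, tmp_path):
        panel = [
            ProbeRecord("p1", "A", "Coding", "g1", frozenset({"t1", "t2"})),
            ProbeRecord("p2", "A", "Non-coding", None, frozenset()),
        ]
        path = tmp_path / "panel.tsv"
        write_panel_tsv(panel, path)
        back = read_panel_tsv(path)
        assert sorted(p.probe_id for p in back) == ["p1", "p2"]
        assert {p.probe_id: p.transcript_ids for p in back}["p1"] == frozenset({"t1", "t2"})
        assert {p.probe_id: p.gene_id for p in back}["p2"] is None

    def test_gtf_round_trip(self, tmp_path):
        models = [
            TranscriptModel("t1.2", "g1", "chr1", "+", [(0, 100), (200, 250)]),
            TranscriptModel("t2", "g1", "chr1", "-", [(300, 420)]),
        ]
        path = tmp_path / "models.gtf"
        write_gtf(models, path)
        # 1-based inclusive on disk
        line = path.read_text().splitlines()[0].split("\t")
        assert (line[3], line[4]) == ("1", "100")
        back = {m.transcript_id: m for m in read_gtf(path)}
        assert back["t1.2"].exons == [(0, 100), (200, 250)]
        assert back["t2"].strand == "-"
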