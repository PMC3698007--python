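"""Streaming k-way merge vs. brute force, class summaries, matrix files."""

import random

import pytest

from wgspipe.errors import ConsistencyError, ValidationError
from wgspipe.fixtures import SoapsnpFixtureSpec, generate_soapsnp_file
from wgspipe.manifest import parse_master_manifest
from wgspipe.merge import (
    ClassCounts,
    MergeConfig,
    merge_sorted_streams,
    merge_subjects,
    read_genotype_file,
    summarize_class_counts,
    write_genotype_files,
    write_plink_transposed,
)
from wgspipe.soapsnp import (
    FilterCriteria,
    SnpRecord,
    parse_snp_line,
    read_sorted_snp_stream,
)


def _rec(pos, consensus="R", ref="A", quality=30, best_unique=5, second_unique=5,
         chrom="chr1"):
    return SnpRecord(
        chrom=chrom, pos=pos, ref_base=ref, consensus=consensus,
        quality=quality, best_base="G", best_unique_count=best_unique,
        best_all_count=best_unique, second_base="A",
        second_unique_count=second_unique, second_all_count=second_unique,
        depth=best_unique + second_unique,
    )


def _fixture_streams(n_samples, seed, max_records=2000):
    rng = random.Random(seed)
    specs = [
        SoapsnpFixtureSpec(
            chrom="chr1",
            n_records=rng.randint(0, max_records),
            class_mix=(0.5, 0.45, 0.05),
            pass_fraction=rng.choice([1.0, 0.9, 0.6]),
            position_step=rng.choice([1, 3, 17]),
            seed=rng.randrange(2**31),
        )
        for _ in range(n_samples)
    ]
    texts = [generate_soapsnp_file(s)[0] for s in specs]
    record_lists = [
        [parse_snp_line(line) for line in text.splitlines()] for text in texts
    ]
    return texts, record_lists


class TestMergeSortedStreams:
    def test_union_pattern_with_missing_cells(self):
        s1 = [_rec(100), _rec(200)]
        s2 = [_rec(200), _rec(300)]
        rows = list(merge_sorted_streams([s1, s2], ["a", "b"]))
        assert [r.pos for r in rows] == [100, 200, 300]
        assert rows[0].genotype_codes == ("AG", "NN")
        assert rows[1].genotype_codes == ("AG", "AG")
        assert rows[2].genotype_codes == ("NN", "AG")

    def test_all_streams_empty_gives_empty_output(self):
        assert list(merge_sorted_streams([[], []], ["a", "b"])) == []

    def test_single_stream_degenerates_to_its_passing_records(self):
        stream = [_rec(10, "M"), _rec(20, quality=13), _rec(30, "C", ref="A")]
        rows = list(merge_sorted_streams([stream], ["only"]))
        assert [(r.pos, r.genotype_codes[0]) for r in rows] == [
            (10, "AC"), (30, "CC"),
        ]

    def test_failing_record_leaves_missing_cell_not_row_suppression(self):
        s1 = [_rec(100)]
        s2 = [_rec(100, quality=13)]  # fails the filter at the shared site
        rows = list(merge_sorted_streams([s1, s2], ["a", "b"]))
        assert rows[0].genotype_codes == ("AG", "NN")

    def test_conflicting_reference_bases_raise(self):
        s1 = [_rec(100, ref="A")]
        s2 = [_rec(100, "Y", ref="C")]
        with pytest.raises(ConsistencyError, match="100"):
            list(merge_sorted_streams([s1, s2], ["a", "b"]))

    def test_rows_strictly_increasing(self, merge_oracle):
        _, record_lists = _fixture_streams(4, seed=11)
        rows = list(
            merge_sorted_streams(record_lists, list("abcd"))
        )
        positions = [r.pos for r in rows]
        assert positions == sorted(set(positions))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_oracle(self, merge_oracle, seed):
        _, record_lists = _fixture_streams(5, seed=seed, max_records=800)
        ids = [f"s{i}" for i in range(5)]
        config = MergeConfig()
        streaming = list(merge_sorted_streams(record_lists, ids, config))
        expected = merge_oracle(record_lists, config.criteria, config.missing_code)
        assert streaming == expected

    def test_column_order_follows_stream_order(self):
        s1 = [_rec(100)]
        s2 = [_rec(300, "M")]
        forward = list(merge_sorted_streams([s1, s2], ["a", "b"]))
        reverse = list(merge_sorted_streams([s2, s1], ["b", "a"]))
        assert [r.pos for r in forward] == [r.pos for r in reverse]
        for f, r in zip(forward, reverse):
            assert f.genotype_codes == tuple(reversed(r.genotype_codes))

    def test_memory_contract_one_buffered_record_per_stream(self):
        """The merge may hold at most one un-emitted record per input stream."""
        n_streams, n_records = 6, 500
        outstanding = [0] * n_streams
        peak = 0

        def instrumented(i, records):
            nonlocal peak
            for rec in records:
                outstanding[i] += 1
                peak = max(peak, sum(outstanding))
                yield rec
                outstanding[i] -= 1

        _, record_lists = _fixture_streams(n_streams, seed=13, max_records=n_records)
        streams = [instrumented(i, records) for i, records in enumerate(record_lists)]
        for _ in merge_sorted_streams(streams, [f"s{i}" for i in range(n_streams)]):
            pass
        assert peak <= n_streams


class TestSummarize:
    def test_counts_recover_generator_composition(self):
        spec = SoapsnpFixtureSpec(
            n_records=85, class_mix=(50 / 85, 30 / 85, 5 / 85),
            pass_fraction=1.0, seed=21,
        )
        text, truth = generate_soapsnp_file(spec)
        counts = summarize_class_counts(read_sorted_snp_stream(text.splitlines()))
        assert counts == ClassCounts(50, 30, 5)
        assert counts.total == 85
        assert counts == truth.expected_counts

    def test_zero_passing_records(self):
        spec = SoapsnpFixtureSpec(n_records=40, pass_fraction=0.0, seed=22)
        text, _ = generate_soapsnp_file(spec)
        counts = summarize_class_counts(read_sorted_snp_stream(text.splitlines()))
        assert counts == ClassCounts(0, 0, 0)
        assert counts.total == 0

    def test_total_is_class_sum_on_random_fixtures(self):
        for seed in range(5):
            spec = SoapsnpFixtureSpec(n_records=200, pass_fraction=0.8, seed=seed)
            text, _ = generate_soapsnp_file(spec)
            c = summarize_class_counts(read_sorted_snp_stream(text.splitlines()))
            assert c.total == c.homozygous + c.heterozygous + c.het2

    def test_reference_consensus_not_counted_as_snp(self):
        stream = [_rec(10, consensus="A", ref="A"), _rec(20, consensus="G", ref="A")]
        counts = summarize_class_counts(stream)
        assert counts == ClassCounts(homozygous=1)


class TestGenotypeFiles:
    def _rows(self):
        return list(
            merge_sorted_streams(
                [[_rec(100), _rec(200)], [_rec(200, "M")]], ["s1", "s2"]
            )
        )

    def test_one_file_per_chromosome(self, tmp_path):
        chr1_rows = self._rows()
        chr2_rows = list(
            merge_sorted_streams([[_rec(50, chrom="chr2")], []], ["s1", "s2"])
        )
        files = write_genotype_files(chr1_rows + chr2_rows, ["s1", "s2"], tmp_path)
        assert files == ["chr1.genotype.txt", "chr2.genotype.txt"]

    def test_header_lists_samples_in_manifest_order(self, tmp_path):
        write_genotype_files(self._rows(), ["s1", "s2"], tmp_path)
        header = (tmp_path / "chr1.genotype.txt").read_text().splitlines()[0]
        assert header == "#chrom\tpos\tref\ts1\ts2"

    def test_written_file_round_trips(self, tmp_path):
        rows = self._rows()
        write_genotype_files(rows, ["s1", "s2"], tmp_path)
        ids, reread = read_genotype_file(tmp_path / "chr1.genotype.txt")
        assert ids == ["s1", "s2"]
        assert reread == rows

    def test_plink_transposed_export(self, tmp_path):
        rows = self._rows()
        n = write_plink_transposed(rows, ["s1", "s2"], tmp_path / "out.tped")
        lines = (tmp_path / "out.tped").read_text().strip().split("\n")
        assert n == len(rows) == len(lines)
        first = lines[0].split("\t")
        assert first[0] == "chr1" and first[3] == "100"
        assert first[4] == "A G"
        assert first[5] == "0 0"  # missing cell


class TestMergeSubjects:
    def _setup(self, tmp_path, chroms=("chr1", "chr2"), drop=None):
        manifest = parse_master_manifest(
            "S1\t/d/s1.bam\t/out\nS2\t/d/s2.bam\t/out\n"
        )
        truths = {}
        for si, subject in enumerate(manifest.subject_ids):
            snp_dir = tmp_path / subject / "snp"
            snp_dir.mkdir(parents=True)
            for ci, chrom in enumerate(chroms):
                if drop == (subject, chrom):
                    continue
                text, truth = generate_soapsnp_file(
                    SoapsnpFixtureSpec(
                        chrom=chrom, n_records=60, seed=100 + 10 * si + ci
                    )
                )
                (snp_dir / f"{chrom}.txt").write_text(text)
                truths[(subject, chrom)] = truth
        def resolver(subject, chrom):
            path = tmp_path / subject / "snp" / f"{chrom}.txt"
            return path if path.exists() else None
        return manifest, resolver, truths

    def test_two_subjects_two_chromosomes(self, tmp_path):
        manifest, resolver, truths = self._setup(tmp_path)
        out = merge_subjects(
            manifest, resolver, ["chr1", "chr2"], output_dir=tmp_path / "g"
        )
        assert out.genotype_files == ["chr1.genotype.txt", "chr2.genotype.txt"]
        assert set(out.class_counts) == {"S1", "S2"}
        for subject in ("S1", "S2"):
            expected = (
                truths[(subject, "chr1")].expected_counts
                + truths[(subject, "chr2")].expected_counts
            )
            assert out.class_counts[subject] == expected

    def test_missing_chromosome_file_yields_missing_column(self, tmp_path):
        manifest, resolver, _ = self._setup(tmp_path, drop=("S2", "chr2"))
        out = merge_subjects(
            manifest, resolver, ["chr1", "chr2"], output_dir=tmp_path / "g"
        )
        _, rows = read_genotype_file(tmp_path / "g" / "chr2.genotype.txt")
        assert rows  # S1 still contributes
        assert all(r.genotype_codes[1] == "NN" for r in rows)

    def test_missing_source_error_policy(self, tmp_path):
        manifest, resolver, _ = self._setup(tmp_path, drop=("S2", "chr2"))
        with pytest.raises(ValidationError, match="S2"):
            merge_subjects(
                manifest, resolver, ["chr1", "chr2"],
                output_dir=tmp_path / "g2", missing_source="error",
            )

    def test_full_pipeline_matches_oracle_files_byte_for_byte(
        self, tmp_path, merge_oracle
    ):
        manifest, resolver, _ = self._setup(tmp_path, chroms=("chr1",))
        merge_subjects(manifest, resolver, ["chr1"], output_dir=tmp_path / "got")
        record_lists = [
            [parse_snp_line(l) for l in resolver(s, "chr1").read_text().splitlines()]
            for s in manifest.subject_ids
        ]
        oracle_rows = merge_oracle(record_lists, FilterCriteria())
        write_genotype_files(oracle_rows, manifest.subject_ids, tmp_path / "want")
        got = (tmp_path / "got" / "chr1.genotype.txt").read_bytes()
        want = (tmp_path / "want" / "chr1.genotype.txt").read_bytes()
        assert got == want
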