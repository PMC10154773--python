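"""Split extraction, splice exclusion and ligation-junction calling."""

import pytest
from hypothesis import given, settings, strategies as st

from proxilig.io_formats import ChimericJunctionRecord, IntronRecord, SplitAlignmentRecord
from proxilig.junctions import (
    KnownJunctionSet,
    RegionMask,
    build_known_set,
    chimeric_to_ligation,
    classify_split,
    extract_splits_from_cigar,
    mapping_summary,
    neo_junctions_from_alignments,
    parse_cigar,
    read_junction_table,
    write_junction_table,
    SplitInterval,
)


def _aln(read_id, chrom, pos, cigar, unique=True):
    return SplitAlignmentRecord(
        read_id=read_id, chrom=chrom, strand="+", pos=pos, cigar=cigar,
        is_unique=unique, is_primary=True,
    )


def _intron(chrom, start, end, annotated=1):
    return IntronRecord(chrom, start, end, 1, 1, annotated, 5)


class TestCigarSplits:
    @pytest.mark.parametrize(
        "pos,cigar,expected",
        [
            (1001, "20M100N30M", [(1021, 1120)]),
            (1, "50M", []),
            (1, "10M5N10M5N10M", [(11, 15), (26, 30)]),
            (100, "5S10M3D5N10M", [(113, 117)]),  # D consumes ref, not a split
        ],
    )
    def test_reference_walk_examples(self, pos, cigar, expected):
        assert extract_splits_from_cigar(pos, cigar) == [
            SplitInterval(*e) for e in expected
        ]

    @pytest.mark.parametrize("cigar", ["", "*", "10Q", "M10", "10M5", "0M10N5M"])
    def test_invalid_cigars_rejected(self, cigar):
        with pytest.raises(ValueError):
            parse_cigar(cigar)

    # base-by-base oracle: expand the CIGAR to one op letter per base and
    # scan for runs of N on the reference
    @staticmethod
    def _oracle(pos, cigar):
        expanded = []
        for length, op in parse_cigar(cigar):
            expanded.extend(op * length)
        splits, ref, run_start = [], pos, None
        for op in expanded:
            if op in "M=XDN":
                if op == "N":
                    if run_start is None:
                        run_start = ref
                else:
                    if run_start is not None:
                        splits.append((run_start, ref - 1))
                        run_start = None
                ref += 1
        if run_start is not None:
            splits.append((run_start, ref - 1))
        return splits

    # aligners never emit two N ops separated only by ops that do not
    # consume reference; rewrite such runs so the CIGAR stays realistic
    @staticmethod
    def _alignerlike(ops):
        out, n_open = [], False
        for length, op in ops:
            if op == "N":
                if n_open:
                    op = "M"
                else:
                    n_open = True
            elif op in "MD=X":
                n_open = False
            out.append((length, op))
        return out

    @given(
        pos=st.integers(min_value=1, max_value=10_000),
        ops=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=80),
                st.sampled_from("MIDNS=XHP"),
            ),
            min_size=1,
            max_size=10,
        ),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_base_walk_oracle(self, pos, ops):
        cigar = "".join(f"{l}{o}" for l, o in self._alignerlike(ops))
        assert [
            tuple(s) for s in extract_splits_from_cigar(pos, cigar)
        ] == self._oracle(pos, cigar)


class TestKnownSet:
    def test_union_of_control_and_annotation(self):
        known = build_known_set(
            [_intron("chr1", 1021, 1120)],
            [_intron("chr1", 1021, 1120), _intron("chr2", 500, 700)],
        )
        assert len(known) == 2

    def test_empty_set_classifies_everything_neo(self):
        known = build_known_set()
        assert len(known) == 0
        assert classify_split(SplitInterval(10, 20), "chr1", known) == "neo"

    def test_replicate_lists_flattened(self):
        known = build_known_set(
            [[_intron("chr1", 1, 10)], [_intron("chr1", 20, 30)]]
        )
        assert len(known) == 2

    @pytest.mark.parametrize(
        "query,tol,expected",
        [
            ((1021, 1120), 0, "splice"),
            ((1022, 1120), 0, "neo"),
            ((1023, 1121), 3, "splice"),
            ((1025, 1120), 3, "neo"),
        ],
    )
    def test_tolerance_matching(self, query, tol, expected):
        known = KnownJunctionSet([("chr1", 1021, 1120)], tolerance=tol)
        assert classify_split(SplitInterval(*query), "chr1", known) == expected


class TestNeoJunctions:
    def test_reads_aggregated_on_shared_split(self):
        known = build_known_set()
        # both reads skip exactly (2001, 4999): points (2000, 5000)
        alns = [
            _aln("r1", "chr1", 1971, "30M2999N30M"),
            _aln("r2", "chr1", 1951, "50M2999N30M"),
        ]
        (j,) = neo_junctions_from_alignments(alns, known)
        assert j.read_ids == {"r1", "r2"}
        assert (j.point_a.chrom, j.point_a.pos, j.point_a.side) == (
            "chr1", 2000, "donor",
        )
        assert (j.point_b.pos, j.point_b.side) == (5000, "acceptor")

    def test_splice_split_excluded_neo_kept_in_same_read(self):
        # one read carrying a canonical splice split and a ligation split
        known = build_known_set([_intron("chr1", 1021, 1120)])
        aln = _aln("r1", "chr1", 1001, "20M100N30M4849N30M")
        (j,) = neo_junctions_from_alignments([aln], known)
        assert j.point_a.pos == 1150  # only the non-splice split emitted
        assert j.n_reads == 1

    def test_non_unique_read_contributes_nothing(self):
        known = build_known_set()
        aln = _aln("r1", "chr1", 100, "20M50N20M", unique=False)
        assert neo_junctions_from_alignments([aln], known, unique_only=True) == []

    def test_masked_read_dropped(self):
        known = build_known_set()
        mask = RegionMask([("chr1", 0, 200)])
        aln = _aln("r1", "chr1", 100, "20M50N20M")
        assert neo_junctions_from_alignments([aln], known, mask=mask) == []

    def test_no_emitted_junction_matches_known_set(self, fixture_data):
        from proxilig import io_formats
        paths, _ = fixture_data
        known = build_known_set(
            [io_formats.read_sj_table(paths["control_sj"])],
            io_formats.read_sj_table(paths["annotation_sj"]),
        )
        junctions = neo_junctions_from_alignments(
            io_formats.read_sam_splits(paths["sam"]), known
        )
        assert junctions  # fixture plants co-linear ligation junctions
        for j in junctions:
            assert not known.matches(
                j.point_a.chrom, j.point_a.pos + 1, j.point_b.pos - 1
            )

    def test_order_independent(self):
        known = build_known_set()
        alns = [
            _aln("r1", "chr1", 100, "20M50N20M"),
            _aln("r2", "chr2", 900, "20M70N20M"),
            _aln("r3", "chr1", 100, "20M50N20M"),
        ]
        fwd = neo_junctions_from_alignments(alns, known)
        rev = neo_junctions_from_alignments(list(reversed(alns)), known)
        assert fwd == rev


def _chim(read_id, cd="chr1", pd=301, sd="+", ca="chr7", pa=8999, sa="-",
          jtype=0):
    return ChimericJunctionRecord(
        chrom_donor=cd, pos_donor=pd, strand_donor=sd, chrom_acceptor=ca,
        pos_acceptor=pa, strand_acceptor=sa, junction_type=jtype,
        repeat_left=0, repeat_right=0, read_id=read_id, seg1_start=266,
        cigar1="35M", seg2_start=9000, cigar2="40M",
    )


class TestChimericJunctions:
    def test_records_aggregated_on_shared_breakpoints(self):
        (j,) = chimeric_to_ligation([_chim("r1"), _chim("r2")])
        assert j.read_ids == {"r1", "r2"}
        assert j.kind == "chimeric"
        # donor '+' at breakpoint 301 -> last aligned base 300
        # acceptor '-' at breakpoint 8999 -> first aligned base 8998
        # (breakpoints are strand-directed: one step back along the strand)
        points = {(p.chrom, p.pos) for p in (j.point_a, j.point_b)}
        assert points == {("chr1", 300), ("chr7", 8998)}

    def test_mate_encompassing_excluded_by_default(self):
        assert chimeric_to_ligation([_chim("r1", jtype=-1)]) == []
        assert len(
            chimeric_to_ligation(
                [_chim("r1", jtype=-1)], include_mate_encompassing=True
            )
        ) == 1

    def test_backward_orientation_retained(self):
        # same chromosome, donor downstream of acceptor: circRNA-like
        (j,) = chimeric_to_ligation(
            [_chim("r1", cd="chr1", pd=5001, sd="+", ca="chr1", pa=1999,
                   sa="+")]
        )
        assert j.span == 3000

    def test_masked_point_dropped(self):
        mask = RegionMask([("chr7", 8990, 9010)])
        assert chimeric_to_ligation([_chim("r1")], mask=mask) == []


class TestMappingSummary:
    def test_ligation_fraction(self):
        alns = [_aln(f"r{i}", "chr1", 100, "50M") for i in range(10)]
        known = build_known_set()
        carried = [
            _aln(f"r{i}", "chr1", 100, "20M50N20M") for i in range(4)
        ]
        junctions = neo_junctions_from_alignments(carried, known)
        summary = mapping_summary(alns, junctions, n_total_reads=10)
        assert summary["frac_ligation_of_unique"] == pytest.approx(0.4)

    def test_no_alignments_warns_and_reports_zero(self):
        with pytest.warns(UserWarning):
            summary = mapping_summary([], [])
        assert summary["frac_mapped"] == 0.0
        assert summary["frac_unique_of_mapped"] == 0.0

    def test_splice_only_reads_have_zero_ligation_fraction(self):
        alns = [_aln("r1", "chr1", 991, "30M100N30M")]
        summary = mapping_summary(alns, [], n_total_reads=1)
        assert summary["frac_ligation_of_unique"] == 0.0
        assert summary["frac_mapped"] == 1.0


def test_junction_table_round_trip(tmp_path, fixture_data):
    from proxilig import io_formats
    paths, _ = fixture_data
    known = build_known_set([io_formats.read_sj_table(paths["control_sj"])])
    junctions = neo_junctions_from_alignments(
        io_formats.read_sam_splits(paths["sam"]), known
    )
    p = tmp_path / "junctions.tsv"
    write_junction_table(junctions, p)
    assert read_junction_table(p) == junctions
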