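"""Alignment ingestion, the exhaustive aligner vs a quadratic DP oracle,
edit-distance filtering and best-hit tie sets."""

import numpy as np
import pytest

from sedaprof.align import (
    AlignmentHit,
    best_hits,
    edit_distance_filter,
    exhaustive_align,
    read_sam,
    write_sam,
)
from sedaprof.preprocess import Read
from sedaprof.simulate import revcomp

SAM_TEXT = (
    "@HD\tVN:1.6\n"
    "@SQ\tSN:refA\tLN:100\n"
    "r1\t0\trefA\t11\t255\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tNM:i:3\n"
    "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
)


def hw_edit_distance(query, ref):
    """Unbanded infix edit distance: full quadratic DP, free ref gaps."""
    m, w = len(query), len(ref)
    prev = [0] * (w + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * w
        for j in range(1, w + 1):
            cur[j] = min(
                prev[j - 1] + (query[i - 1] != ref[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)


class TestReadSam:
    def test_unmapped_skipped(self):
        hits = read_sam(SAM_TEXT)
        assert set(hits) == {"r1"}

    def test_fields_copied(self):
        h = read_sam(SAM_TEXT)["r1"][0]
        assert h.edit_distance == 3
        assert h.read_len == 50
        assert h.ref_start == 11
        assert h.strand == "+"

    def test_missing_nm_is_error(self):
        bad = (
            "@HD\tVN:1.6\n@SQ\tSN:refA\tLN:100\n"
            "r1\t0\trefA\t1\t255\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(ValueError, match="r1"):
            read_sam(bad)

    def test_sam_round_trip(self, panel_bundle):
        _, _, panel = panel_bundle
        rng = np.random.default_rng(5)
        reads = {}
        hits = {}
        accs = sorted(panel)
        for i in range(30):
            acc = accs[int(rng.integers(0, len(accs)))]
            start = int(rng.integers(0, 900))
            frag = panel[acc][start : start + 60]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            read = Read(f"r{i}", frag)
            reads[read.read_id] = read
            hits[read.read_id] = exhaustive_align(read, panel, max_edit=2)
        hits = {k: v for k, v in hits.items() if v}
        sam = write_sam(hits, reads, panel)
        again = read_sam(sam)
        assert {k: set(v) for k, v in again.items()} == {
            k: set(v) for k, v in hits.items()
        }


class TestExhaustiveAlign:
    def test_planted_exact_substring(self, panel_bundle):
        _, _, panel = panel_bundle
        acc = sorted(panel)[0]
        read = Read("r", panel[acc][100:150])
        hits = exhaustive_align(read, panel, max_edit=0)
        mine = [h for h in hits if h.ref_accession == acc and h.strand == "+"]
        assert mine and mine[0].ref_start == 101
        assert mine[0].edit_distance == 0

    def test_single_substitution(self, panel_bundle):
        _, _, panel = panel_bundle
        acc = sorted(panel)[0]
        frag = list(panel[acc][200:250])
        frag[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[10]]
        hits = exhaustive_align(Read("r", "".join(frag)), panel, max_edit=3)
        mine = [h for h in hits if h.ref_accession == acc and h.strand == "+"]
        assert mine[0].edit_distance == 1

    def test_distances_match_quadratic_dp_oracle(self, panel_bundle):
        _, _, panel = panel_bundle
        rng = np.random.default_rng(11)
        accs = sorted(panel)[:4]
        small = {a: panel[a] for a in accs}
        for _ in range(25):
            read_seq = "".join(rng.choice(list("ACGT"), size=40))
            hits = exhaustive_align(Read("q", read_seq), small, max_edit=6)
            by_key = {}
            for h in hits:
                key = (h.ref_accession, h.strand)
                by_key.setdefault(key, h)
            for acc in accs:
                for strand, q in (("+", read_seq), ("-", revcomp(read_seq))):
                    oracle = hw_edit_distance(q, small[acc])
                    got = by_key.get((acc, strand))
                    if oracle <= 6:
                        assert got is not None and got.edit_distance == oracle
                    else:
                        assert got is None

    def test_max_edit_zero_equals_substring_scan(self, panel_bundle):
        _, _, panel = panel_bundle
        acc = sorted(panel)[2]
        read_seq = panel[acc][500:540]
        hits = exhaustive_align(Read("r", read_seq), panel, max_edit=0)
        for h in hits:
            ref = panel[h.ref_accession]
            window = ref[h.ref_start - 1 : h.ref_start - 1 + 40]
            expected = read_seq if h.strand == "+" else revcomp(read_seq)
            assert window == expected

    def test_cigar_consumes_read(self, panel_bundle):
        _, _, panel = panel_bundle
        acc = sorted(panel)[1]
        read = Read("r", panel[acc][300:350])
        for h in exhaustive_align(read, panel, max_edit=2):
            assert h.read_len == 50  # enforced by AlignmentHit itself


def _hit(read_id="r", nm=0, read_len=50, acc="A", start=1):
    return AlignmentHit(read_id, acc, nm, start, "+", f"{read_len}M", read_len)


class TestEditDistanceFilter:
    @pytest.mark.parametrize(
        "read_len,nm,kept",
        [(100, 5, True), (100, 6, False), (40, 2, True), (40, 3, False)],
    )
    def test_boundary(self, read_len, nm, kept):
        hits = [_hit(nm=nm, read_len=read_len)]
        assert bool(edit_distance_filter(hits)) is kept

    def test_random_sets_match_oracle(self):
        rng = np.random.default_rng(3)
        hits = [
            _hit(read_id="r", nm=int(rng.integers(0, 8)),
                 read_len=int(rng.integers(25, 101)), acc=f"a{i}")
            for i in range(200)
        ]
        out = edit_distance_filter(hits, frac=0.05)
        assert out == [h for h in hits if h.edit_distance <= 0.05 * h.read_len]


class TestBestHits:
    def test_tie_set(self):
        hits = [_hit(nm=2, acc="A"), _hit(nm=2, acc="B"), _hit(nm=4, acc="C")]
        assert {h.ref_accession for h in best_hits(hits)} == {"A", "B"}

    def test_single_hit_identity(self):
        hits = [_hit(nm=1)]
        assert best_hits(hits) == hits

    def test_same_reference_counts_once(self):
        hits = [_hit(nm=1, acc="A", start=1), _hit(nm=1, acc="A", start=90)]
        assert len(best_hits(hits)) == 1

    def test_empty(self):
        assert best_hits([]) == []

    def test_filter_commutes_with_best_when_best_passes(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            hits = [
                _hit(nm=int(rng.integers(0, 3)), read_len=100, acc=f"a{i}")
                for i in range(6)
            ]
            a = best_hits(edit_distance_filter(hits))
            b = edit_distance_filter(best_hits(hits))
            assert set(a) == set(b)
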