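"""Specificity engine against an exhaustive position-scan oracle, the
four antisense orientation cases, and the external BLAST+ backend.

The oracle slides the oriented oligo across *every* placement on every
database sequence (numpy prefilter on total matches, then an O(L^2)
enumeration of all candidate segments), applying the same hit
definition as the engine — ≤2 internal mismatches, match at both ends,
an exact k-mer run inside, ≥ min_matched matching columns — through a
completely separate code path.
"""

import numpy as np
import pytest

from probecraft.fixtures import FixtureSpec, PlantedDuplication, generate_fixture
from probecraft.scanner import OligoCandidate
from probecraft.sequence_io import reverse_complement
from probecraft.specificity import (AlignmentHit, antisense_filter, blast_available,
                                    build_index, exon_avoidance_filter, find_hits,
                                    find_hits_blast, genome_uniqueness_filter,
                                    isoform_specificity_filter, merge_hits)

K = 12
MIN_MATCHED = 18
MAX_MM = 2


# ---------------------------------------------------------------------------
# exhaustive oracle

def _segment_score(mask: list[bool]) -> tuple[int, int, int] | None:
    """All-pairs enumeration of candidate segments of one placement."""
    L = len(mask)
    best = None
    for s in range(L):
        if not mask[s]:
            continue
        mm = 0
        run = 0
        longest = 0
        matched = 0
        for e in range(s, L):
            if mask[e]:
                matched += 1
                run += 1
                longest = max(longest, run)
            else:
                mm += 1
                run = 0
                if mm > MAX_MM:
                    break
                continue
            # segment [s, e] ends on a match here
            if longest >= K and matched >= MIN_MATCHED:
                cand = (matched, s, e + 1)
                if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
    return best


def oracle_hits(oligo: str, db: dict[str, str]) -> list[AlignmentHit]:
    raw = []
    for orientation, q in (("plus/plus", oligo),
                           ("plus/minus", reverse_complement(oligo))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        L = len(q)
        for sid, seq in db.items():
            pad = L - 1
            padded = ("\0" * pad) + seq + ("\0" * pad)
            da = np.frombuffer(padded.encode(), dtype=np.uint8)
            N = len(padded)
            counts = np.zeros(N - L + 1, dtype=np.int32)
            for j in range(L):
                counts += (da[j:N - L + 1 + j] == qa[j])
            for off in np.nonzero(counts >= MIN_MATCHED)[0]:
                mask = [padded[off + j] == q[j] for j in range(L)]
                seg = _segment_score(mask)
                if seg is not None:
                    matched, s, e = seg
                    raw.append(AlignmentHit(sid, orientation,
                                            start=int(off) - pad + s,
                                            matched=matched,
                                            end=int(off) - pad + e))
    # independent interval merge (repeated-pass)
    merged: list[AlignmentHit] = []
    for h in sorted(raw, key=lambda h: (h.sequence_id, h.start, h.end)):
        placed = False
        for i, m in enumerate(merged):
            if m.sequence_id == h.sequence_id and h.start < m.end and m.start < h.end:
                better = min([m, h], key=lambda x: (-x.matched, x.start,
                                                    x.orientation != "plus/plus"))
                lo, hi = min(m.start, h.start), max(m.end, h.end)
                merged[i] = AlignmentHit(better.sequence_id, better.orientation,
                                         better.start, better.matched, better.end)
                placed = True
                break
        if not placed:
            merged.append(h)
    return sorted(merged, key=lambda h: (h.sequence_id, h.start))


@pytest.fixture(scope="module")
def small_db():
    fx = generate_fixture(FixtureSpec(seed=77, n_contigs=2, contig_length=10000,
                                      gc_target=50.0))
    return fx.assembly.contigs


class TestIndex:
    def test_seed_counts(self):
        idx = build_index({"s": "ACGTACGTACGT"}, k=8)
        assert sum(len(v) for v in idx.seed_map.values()) == 5  # 12-8+1

    def test_empty_db(self):
        idx = build_index({}, k=8)
        assert idx.seed_map == {}

    def test_duplicate_kmer_lists_both_positions(self):
        idx = build_index({"s": "AAAACGTTCCGG" + "AAAACGTTCCGG"}, k=12)
        assert len(idx.seed_map["AAAACGTTCCGG"]) == 2

    def test_short_sequence_warns(self):
        with pytest.warns(UserWarning, match="shorter than k"):
            build_index({"tiny": "ACGT"}, k=12)

    def test_k_lower_bound(self):
        with pytest.raises(ValueError):
            build_index({"s": "ACGTACGTACGT"}, k=4)


class TestFindHits:
    def test_planted_forward_hit(self, small_db):
        idx = build_index(small_db, k=K)
        oligo = small_db["ctg1"][4000:4030]
        hits = find_hits(oligo, idx, MIN_MATCHED)
        exact = [h for h in hits if h.matched == 30]
        assert any(h.sequence_id == "ctg1" and h.start == 4000 and
                   h.orientation == "plus/plus" for h in exact)

    def test_planted_reverse_hit(self, small_db):
        idx = build_index(small_db, k=K)
        oligo = reverse_complement(small_db["ctg2"][1234:1264])
        hits = find_hits(oligo, idx, MIN_MATCHED)
        assert any(h.sequence_id == "ctg2" and h.start == 1234 and
                   h.orientation == "plus/minus" for h in hits)

    def test_matches_exhaustive_oracle(self, small_db):
        """500 random/planted/mutated oligos on a 20-kb database."""
        idx = build_index(small_db, k=K)
        rng = np.random.default_rng(1234)
        bases = np.array(list("ACGT"))
        sids = list(small_db)
        oligos = []
        for i in range(500):
            kind = i % 4
            if kind == 0:       # pure random
                oligos.append("".join(bases[rng.integers(0, 4, 30)]))
                continue
            sid = sids[int(rng.integers(0, len(sids)))]
            p = int(rng.integers(0, len(small_db[sid]) - 30))
            seq = small_db[sid][p:p + 30]
            if kind == 2:       # mutated copy (1-3 point changes)
                s = list(seq)
                for _ in range(int(rng.integers(1, 4))):
                    q = int(rng.integers(0, 30))
                    s[q] = "ACGT"[(("ACGT".index(s[q])) + 1 + int(rng.integers(0, 3))) % 4]
                seq = "".join(s)
            elif kind == 3:     # reverse complement of a db segment
                seq = reverse_complement(seq)
            oligos.append(seq)
        for oligo in oligos:
            assert find_hits(oligo, idx, MIN_MATCHED) == oracle_hits(oligo, small_db)


class TestGenomeUniqueness:
    def _mk(self, seq, label="t", offset=0):
        return OligoCandidate(label, offset, seq, 70.0, 50.0)

    def test_unique_retained_duplicate_rejected(self):
        fx = generate_fixture(FixtureSpec(
            seed=5, n_contigs=2, contig_length=8000, gc_target=50.0,
            planted_duplications=(PlantedDuplication("ctg1", 3000, 3200,
                                                     "ctg2", 5000),)))
        db = fx.assembly.contigs
        idx = build_index(db, k=K)
        unique = self._mk(db["ctg1"][1000:1030])
        dup = self._mk(db["ctg1"][3050:3080])
        out = genome_uniqueness_filter([unique, dup], idx, MIN_MATCHED)
        assert out == [unique]

    def test_reverse_complement_elsewhere_rejected(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 500)])
        b = "".join(bases[rng.integers(0, 4, 500)])
        oligo = a[100:130]
        db = {"c1": a, "c2": b[:200] + reverse_complement(oligo) + b[200:]}
        idx = build_index(db, k=K)
        # oracle confirms two loci (one per orientation)
        assert len(oracle_hits(oligo, db)) == 2
        assert genome_uniqueness_filter([self._mk(oligo)], idx, MIN_MATCHED) == []

    def test_zero_hits_is_an_error(self, small_db):
        idx = build_index(small_db, k=K)
        foreign = "TTTTTTTTTTGGGGGGGGGGTTTTTTTTTT"
        with pytest.raises(ValueError, match="no genome hits"):
            genome_uniqueness_filter([self._mk(foreign)], idx, MIN_MATCHED)

    def test_retained_oligos_requery_to_one_hit(self, small_db):
        idx = build_index(small_db, k=K)
        oligos = [self._mk(small_db["ctg1"][p:p + 30], offset=p)
                  for p in range(2000, 2600, 60)]
        out = genome_uniqueness_filter(oligos, idx, MIN_MATCHED)
        assert set(out) <= set(oligos)
        for o in out:
            assert len(find_hits(o.sequence, idx, MIN_MATCHED)) == 1


class TestAntisenseOrientationCases:
    """The four cases: no hits → keep; plus/plus only → reverse-complement;
    plus/minus only → keep; both → reject."""

    def _db_and_oligo(self):
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        oligo = "".join(bases[rng.integers(0, 4, 30)])
        pad = lambda: "".join(bases[rng.integers(0, 4, 150)])
        return oligo, pad

    def _mk(self, seq):
        return OligoCandidate("t", 0, seq, 70.0, 50.0)

    def test_case_no_hits_retained_unchanged(self):
        oligo, pad = self._db_and_oligo()
        idx = build_index({"u1": pad()}, k=K)
        out = antisense_filter([self._mk(oligo)], idx, MIN_MATCHED)
        assert [o.sequence for o in out] == [oligo]

    def test_case_plus_plus_reverse_complemented(self):
        oligo, pad = self._db_and_oligo()
        idx = build_index({"u1": pad() + oligo + pad()}, k=K)
        out = antisense_filter([self._mk(oligo)], idx, MIN_MATCHED)
        assert [o.sequence for o in out] == [reverse_complement(oligo)]

    def test_case_plus_minus_retained_unchanged(self):
        oligo, pad = self._db_and_oligo()
        idx = build_index({"u1": pad() + reverse_complement(oligo) + pad()}, k=K)
        out = antisense_filter([self._mk(oligo)], idx, MIN_MATCHED)
        assert [o.sequence for o in out] == [oligo]

    def test_case_both_orientations_rejected(self):
        oligo, pad = self._db_and_oligo()
        db = {"u1": pad() + oligo + pad(),
              "u2": pad() + reverse_complement(oligo) + pad()}
        idx = build_index(db, k=K)
        assert antisense_filter([self._mk(oligo)], idx, MIN_MATCHED) == []

    def test_outputs_have_no_plus_plus_complementarity(self, chromatin_fixture):
        """Re-query check: surviving probes cannot bind unspliced RNA."""
        fx = chromatin_fixture
        unspliced = {t.transcript_id: t.sequence for t in fx.unspliced}
        idx = build_index(unspliced, k=K)
        genome = fx.assembly.contigs["ctg1"]
        oligos = [OligoCandidate("t", p, genome[p:p + 30], 70.0, 50.0)
                  for p in range(2400, 4000, 40)]  # spans both planted genes
        out = antisense_filter(oligos, idx, MIN_MATCHED)
        assert out, "some oligos must survive"
        changed = [o for o in out
                   if o.sequence != genome[o.offset:o.offset + 30]]
        assert changed, "sense-strand oligos over G1 must be flipped"
        for o in out:
            hits = find_hits(o.sequence, idx, MIN_MATCHED)
            assert not [h for h in hits if h.orientation == "plus/plus"]


class TestExonAvoidance:
    def test_intron_kept_exon_rejected(self, chromatin_fixture):
        fx = chromatin_fixture
        spliced = {t.transcript_id: t.sequence for t in fx.spliced}
        idx = build_index(spliced, k=K)
        genome = fx.assembly.contigs["ctg1"]
        exon_oligo = OligoCandidate("t", 2560, genome[2560:2590], 70.0, 50.0)
        intron_oligo = OligoCandidate("t", 2710, genome[2710:2740], 70.0, 50.0)
        out = exon_avoidance_filter([exon_oligo, intron_oligo], idx, MIN_MATCHED)
        assert out == [intron_oligo]

    def test_boundary_overlap_rejected(self, chromatin_fixture):
        """An oligo straddling the exon edge with ≥18 nt of exonic overlap
        still hits the spliced transcript."""
        fx = chromatin_fixture
        spliced = {t.transcript_id: t.sequence for t in fx.spliced}
        idx = build_index(spliced, k=K)
        genome = fx.assembly.contigs["ctg1"]
        # exon is [2550, 2700); 20 exonic + 10 intronic nt
        straddle = OligoCandidate("t", 2680, genome[2680:2710], 70.0, 50.0)
        assert oracle_hits(straddle.sequence, spliced)  # oracle agrees it hits
        assert exon_avoidance_filter([straddle], idx, MIN_MATCHED) == []


class TestIsoformSpecificity:
    def _setup(self):
        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        shared = "".join(bases[rng.integers(0, 4, 120)])
        uniq1 = "".join(bases[rng.integers(0, 4, 120)])
        other = "".join(bases[rng.integers(0, 4, 240)])
        db = {
            "TXA1": uniq1 + shared,            # gene GA isoform 1
            "TXA2": shared,                    # gene GA isoform 2
            "TXB": other[:100] + uniq1[40:70] + other[100:],  # gene GB
        }
        gm = {"TXA1": "GA", "TXA2": "GA", "TXB": "GB"}
        return db, gm, shared, uniq1

    def _mk(self, seq):
        return OligoCandidate("TXA1", 0, seq, 70.0, 50.0)

    def test_isoform_shared_oligo_retained(self):
        db, gm, shared, _ = self._setup()
        idx = build_index(db, k=K, gene_map=gm)
        out = isoform_specificity_filter([self._mk(shared[10:40])], idx, "GA",
                                         MIN_MATCHED)
        assert len(out) == 1

    def test_cross_gene_oligo_rejected(self):
        db, gm, _, uniq1 = self._setup()
        idx = build_index(db, k=K, gene_map=gm)
        # this oligo sits in TXA1 but also matches TXB
        out = isoform_specificity_filter([self._mk(uniq1[40:70])], idx, "GA",
                                         MIN_MATCHED)
        assert out == []

    def test_plus_minus_hit_to_other_gene_ignored(self):
        db, gm, _, uniq1 = self._setup()
        oligo = uniq1[80:110]
        db["TXB"] = db["TXB"] + reverse_complement(oligo)
        idx = build_index(db, k=K, gene_map=gm)
        out = isoform_specificity_filter([self._mk(oligo)], idx, "GA",
                                         MIN_MATCHED)
        assert len(out) == 1  # probe binds RNA only where hits are plus/plus

    def test_zero_hits_is_an_error(self):
        db, gm, _, _ = self._setup()
        idx = build_index(db, k=K, gene_map=gm)
        foreign = "TTTTTTTTTTGGGGGGGGGGTTTTTTTTTT"
        with pytest.raises(ValueError, match="plus/plus"):
            isoform_specificity_filter([self._mk(foreign)], idx, "GA", MIN_MATCHED)


class TestBlastBackend:
    """Backend contract: swapping the built-in engine for BLAST+ changes
    no retain/reject decision on fixture data."""

    def test_blast_present(self):
        assert blast_available(), "blastn ships with the environment"

    def test_uniqueness_decisions_match(self, chromatin_fixture):
        fx = chromatin_fixture
        db = fx.assembly.contigs
        idx = build_index(db, k=K)
        genome = db["ctg1"]
        oligos = [OligoCandidate("t", p, genome[p:p + 30], 70.0, 50.0)
                  for p in list(range(1000, 1800, 40))]  # spans the dup source
        builtin = {o.sequence: find_hits(o.sequence, idx, MIN_MATCHED)
                   for o in oligos}
        queries = {f"q{i}": o.sequence for i, o in enumerate(oligos)}
        blast = find_hits_blast(queries, db, MIN_MATCHED)
        blast_by_seq = {queries[n]: h for n, h in blast.items()}
        kept_builtin = genome_uniqueness_filter(oligos, idx, MIN_MATCHED,
                                                hits_by_oligo=builtin)
        kept_blast = genome_uniqueness_filter(oligos, idx, MIN_MATCHED,
                                              hits_by_oligo=blast_by_seq)
        assert [o.offset for o in kept_builtin] == [o.offset for o in kept_blast]
        # the duplicated segment must actually reject some oligos
        assert len(kept_builtin) < len(oligos)


class TestMergeHits:
    def test_overlapping_hits_collapse_to_best(self):
        hits = [AlignmentHit("s", "plus/plus", 10, 25, 40),
                AlignmentHit("s", "plus/minus", 30, 30, 60),
                AlignmentHit("s", "plus/plus", 100, 20, 130)]
        out = merge_hits(hits)
        assert len(out) == 2
        assert out[0].matched == 30 and out[1].start == 100
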