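"""Fragment space: windows, exclusivity, provenance, labels, lookup build."""

import random

import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from trfspace import (TRNALocus, TRNASpace, assess_exclusivity, build_lookup,
                      enumerate_windows, genome_occurrences, make_label,
                      parse_label, resolve_provenance)
from trfspace.fragments import FragmentRecord, LabelError, Placement
from trfspace.reference import MatureTRNA

from conftest import naive_exclusive, naive_window_set


def _random_seq(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mature(locus, templated):
    return MatureTRNA(locus, templated + "CCA", len(templated))


class TestEnumerateWindows:
    def test_closed_form_counts(self):
        """Sum over k of (n-k+1) windows: L=72 mature (75 nt) gives 1505."""
        m = _mature(TRNALocus("trna1", "AspGTC", "chr1", "+", 1, 72), _random_seq(72))
        assert len(enumerate_windows(m)) == sum(75 - k + 1 for k in range(16, 51))
        assert len(enumerate_windows(m)) == 1505

    def test_short_mature_truncates_range(self):
        m = _mature(TRNALocus("trna1", "GlyGCC", "chr1", "+", 1, 16), _random_seq(16))
        # 19 nt mature: 4 + 3 + 2 + 1 windows of lengths 16..19
        assert len(enumerate_windows(m)) == 10

    def test_single_window_when_range_pins_full_length(self):
        m = _mature(TRNALocus("trna1", "GlyGCC", "chr1", "+", 1, 30), _random_seq(30))
        wins = enumerate_windows(m, min_len=33, max_len=33)
        assert wins == [(m.seq, 1, 33)]

    def test_coordinates_match_slices(self):
        m = _mature(TRNALocus("trna1", "GlyGCC", "chr1", "+", 1, 59), _random_seq(59))
        for seq, fs, fe in enumerate_windows(m, 16, 20):
            assert m.seq[fs - 1 : fe] == seq
            assert fe - fs + 1 == len(seq)


class TestGenomeOccurrences:
    def test_planted_minus_strand_singleton(self):
        frag = _random_seq(25, seed=42)
        genome = {"chr1": _random_seq(500, 1) + reverse_complement(frag) + _random_seq(500, 2)}
        occ = genome_occurrences(frag, genome)
        assert occ == [("chr1", "-", 501, 525)]

    def test_eleven_planted_copies_found(self):
        """A 72 nt sequence planted at 11 loci yields exactly 11 placements."""
        frag = _random_seq(72, seed=7)
        parts = {
            "chr1": 5, "chr6": 2, "chr12": 3, "chr17": 1,
        }
        genome = {
            c: "".join(_random_seq(200, seed=hash(c) % 1000 + i) + frag for i in range(n))
            + _random_seq(200, 99)
            for c, n in parts.items()
        }
        occ = genome_occurrences(frag, genome)
        assert len(occ) == 11
        assert all(s == "+" for _, s, _, _ in occ)

    def test_absent_sequence_and_bad_bases(self):
        genome = {"chr1": _random_seq(100, 3)}
        assert genome_occurrences("T" * 30, genome) == []
        with pytest.raises(ValueError):
            genome_occurrences("ACGTN", genome)

    def test_cap_marks_saturation(self):
        genome = {"chr1": "A" * 200}
        occ = genome_occurrences("A" * 16, genome, cap=50)
        assert len(occ) == 51  # cap + 1 signals saturation


class TestExclusivity:
    def _genome_with(self, frag, n_inside, decoy=False):
        """Plant `frag` inside n_inside tRNA loci, optionally once outside."""
        chunks, loci = [], []
        pos = 1
        for i in range(n_inside):
            pad = _random_seq(50, seed=100 + i)
            chunks.append(pad)
            pos += len(pad)
            start = pos
            chunks.append(frag)
            pos += len(frag)
            loci.append(TRNALocus(f"trna{i + 1}", "AlaAGC", "chr1", "+",
                                  start, start + len(frag) - 1))
        if decoy:
            chunks.append(_random_seq(50, 200) + frag)
        chunks.append(_random_seq(50, 201))
        return {"chr1": "".join(chunks)}, TRNASpace(loci)

    def test_all_placements_inside_space_is_exclusive(self):
        frag = _random_seq(32, seed=1)
        genome, space = self._genome_with(frag, 5)
        occ = genome_occurrences(frag, genome)
        assert len(occ) == 5
        assert assess_exclusivity(frag, occ, space)

    def test_partial_trna_decoy_breaks_exclusivity(self):
        """One extra occurrence outside tRNA space forces exclusion."""
        frag = _random_seq(24, seed=2)
        genome, space = self._genome_with(frag, 5, decoy=True)
        occ = genome_occurrences(frag, genome)
        assert len(occ) == 6
        assert not assess_exclusivity(frag, occ, space)

    def test_junction_spanning_sequence_with_zero_hits_is_exclusive(self):
        assert assess_exclusivity("ACGT" * 5, [], TRNASpace([]), junction_hit=True)
        assert not assess_exclusivity("ACGT" * 5, [], TRNASpace([]), junction_hit=False)

    def test_reverse_complement_occurrence_outside_space_counts_against(self):
        frag = _random_seq(26, seed=3)
        genome, space = self._genome_with(frag, 2)
        genome["chr2"] = _random_seq(40, 4) + reverse_complement(frag) + _random_seq(40, 5)
        occ = genome_occurrences(frag, genome)
        assert not assess_exclusivity(frag, occ, space)


class TestProvenance:
    def _matures_with_core(self, core, spec):
        """spec: list of (anticodon, n_loci, is_pseudo) sharing `core`."""
        out, n = [], 0
        for anticodon, count, pseudo in spec:
            for _ in range(count):
                n += 1
                pad5 = _random_seq(20, seed=n)
                pad3 = _random_seq(20, seed=1000 + n)
                locus = TRNALocus(f"trna{n}", anticodon, "chr1", "+",
                                  1000 * n, 1000 * n + 59 + len(core),
                                  is_pseudo=pseudo)
                out.append(_mature(locus, pad5 + core + pad3))
        return out

    def test_single_anticodon_eight_loci(self):
        core = _random_seq(30, seed=55)
        matures = self._matures_with_core(core, [("GluCTC", 8, False)])
        placements, n_ac, n_ps, n_loci, proxy = resolve_provenance(core, matures)
        assert (n_ac, n_ps, n_loci) == (1, 0, 8)
        assert len(placements) == 8
        assert proxy.locus.id == "trna1"  # smallest start on the same chromosome

    def test_pseudo_singleton(self):
        core = _random_seq(22, seed=56)
        matures = self._matures_with_core(core, [("GlyGCC", 1, True)])
        _, n_ac, n_ps, n_loci, _ = resolve_provenance(core, matures)
        assert (n_ac, n_ps, n_loci) == (1, 1, 1)

    def test_fourteen_loci_five_anticodons(self):
        """Shared segment across Ala/Cys/Val anticodons counts 5 anticodons."""
        core = _random_seq(21, seed=57)
        matures = self._matures_with_core(
            core,
            [("AlaAGC", 5, False), ("AlaCGC", 3, False), ("AlaTGC", 3, False),
             ("CysGCA", 1, False), ("ValAAC", 2, False)],
        )
        _, n_ac, n_ps, n_loci, _ = resolve_provenance(core, matures)
        assert (n_ac, n_ps, n_loci) == (5, 0, 14)

    def test_unknown_sequence_raises(self):
        matures = self._matures_with_core(_random_seq(30, 58), [("GlyGCC", 2, False)])
        with pytest.raises(ValueError, match="inconsistent"):
            resolve_provenance("T" * 30, matures)

    def test_mitochondrial_proxy_sorts_after_autosomes(self):
        core = _random_seq(25, seed=59)
        mt = TRNALocus("mt1", "LysTTT", "MT", "+", 10, 10 + 64)
        nuc = TRNALocus("trna9", "LysTTT", "chr9", "+", 10, 10 + 64)
        matures = [_mature(mt, _random_seq(20, 1) + core + _random_seq(20, 2)),
                   _mature(nuc, _random_seq(20, 3) + core + _random_seq(20, 4))]
        *_, proxy = resolve_provenance(core, matures)
        assert proxy.locus.id == "trna9"


def _record(locus, L, fs, fe, seq, counts):
    p = Placement(locus, L, fs, fe)
    return FragmentRecord(seq=seq, placements=(p,), proxy=p,
                          n_anticodons=counts[0], n_pseudo=counts[1], n_loci=counts[2])


class TestLabels:
    def test_internal_fragment_label_formats_as_printed(self):
        locus = TRNALocus("trna116", "GluCTC", "1", "-", 145399233, 145399304)
        rec = _record(locus, 72, 23, 45, _random_seq(23), (1, 0, 8))
        assert make_label(rec) == "trna116_GluCTC_1_-_145399233_145399304@23.45.23__1_0_8"

    def test_cca_ending_fragment_carries_infix(self):
        locus = TRNALocus("trna75", "MetCAT", "6", "+", 28912352, 28912424)
        rec = _record(locus, 73, 57, 76, _random_seq(20), (1, 0, 2))
        assert make_label(rec) == "trna75_MetCAT_6_+_28912352_28912424@57.76.20.CCA__1_0_2"

    @pytest.mark.parametrize(
        "label, fields",
        [
            ("trna116_GluCTC_1_-_145399233_145399304@23.45.23__1_0_8",
             ("trna116", "GluCTC", "1", "-", 23, 45, 23, False, 1, 0, 8, "i")),
            ("trna75_MetCAT_6_+_28912352_28912424@57.76.20.CCA__1_0_2",
             ("trna75", "MetCAT", "6", "+", 57, 76, 20, True, 1, 0, 2, "3p")),
            ("trna14_TyrGTA_6_+_26569086_26569176@32.50.19__1_0_12",
             ("trna14", "TyrGTA", "6", "+", 32, 50, 19, False, 1, 0, 12, "i")),
        ],
    )
    def test_parse_recovers_printed_fields(self, label, fields):
        p = parse_label(label)
        got = (p.locus_id, p.anticodon_name, p.chrom, p.strand, p.frag_start,
               p.frag_end, p.length, p.cca, p.n_anticodons, p.n_pseudo,
               p.n_loci, p.region)
        assert got == fields
        assert p.length == p.frag_end - p.frag_start + 1

    @pytest.mark.parametrize("bad", [
        "trna1_GlyGCC_1_+_10_80@5.20.16",          # missing counts
        "trna1_GlyGCC_1_+_10_80@5.20.17__1_0_1",   # wrong length arithmetic
        "trna1_GlyGCC_1_+_10_80@5.20__1_0_1",      # malformed fragment part
        "trna1_GlyGCC_1_*_10_80@5.20.16__1_0_1",   # bad strand
        "garbage",
    ])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(LabelError, match="position"):
            parse_label(bad)

    @given(
        lid=st.integers(1, 999), fs=st.integers(1, 60), ln=st.integers(16, 50),
        L=st.integers(59, 95), counts=st.tuples(st.integers(1, 9), st.integers(0, 9),
                                                st.integers(1, 99)),
        start=st.integers(1, 10**8), span=st.integers(59, 120),
        strand=st.sampled_from("+-"), chrom=st.sampled_from(["1", "12", "X", "MT"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, lid, fs, ln, L, counts, start, span, strand, chrom):
        """parse(make(record)) recovers every field of any valid record."""
        fe = fs + ln - 1
        if fe > L + 3:
            fe = L + 3
            fs = fe - ln + 1
            if fs < 1:
                return
        locus = TRNALocus(f"trna{lid}", "GluCTC", chrom, strand, start, start + span)
        rec = _record(locus, L, fs, fe, "A" * ln, counts)
        p = parse_label(make_label(rec))
        assert (p.locus_id, p.anticodon_name, p.chrom, p.strand) == (
            locus.id, "GluCTC", chrom, strand)
        assert (p.start, p.end) == (start, start + span)
        assert (p.frag_start, p.frag_end, p.length) == (fs, fe, ln)
        assert p.cca == (fe > L)
        assert (p.n_anticodons, p.n_pseudo, p.n_loci) == counts


class TestBuildLookup:
    def test_matches_brute_force_oracle(self, universe, space, matures, cca_genome, lookup):
        """Lookup exclusivity equals the naive both-strand scan, window by window."""
        windows = naive_window_set(matures)
        expected = {
            seq for seq, jh in windows.items()
            if naive_exclusive(seq, cca_genome, space.loci, jh)
        }
        assert lookup.sequences() == expected

    def test_single_trna_only_genome_keeps_all_windows(self):
        templated = _random_seq(70, seed=12)
        genome = {"chr1": _random_seq(100, 13) + templated + _random_seq(100, 14)}
        locus = TRNALocus("trna1", "AspGTC", "chr1", "+", 101, 170)
        space = TRNASpace([locus])
        from trfspace import build_cca_genome, splice_mature
        cca = build_cca_genome(genome, space)
        m = splice_mature(locus, cca)
        lk = build_lookup(space, [m], cca)
        assert len(lk) == len({w[0] for w in enumerate_windows(m)})

    def test_identical_copy_inside_space_gives_n_loci_two(self):
        templated = _random_seq(70, seed=15)
        genome = {"chr1": (_random_seq(100, 16) + templated + _random_seq(100, 17)
                           + templated + _random_seq(100, 18))}
        l1 = TRNALocus("trna1", "AspGTC", "chr1", "+", 101, 170)
        l2 = TRNALocus("trna2", "AspGTC", "chr1", "+", 271, 340)
        space = TRNASpace([l1, l2])
        from trfspace import build_cca_genome, splice_mature
        cca = build_cca_genome(genome, space)
        ms = [splice_mature(l, cca) for l in (l1, l2)]
        lk = build_lookup(space, ms, cca)
        assert len(lk) > 0
        assert all(rec.n_loci == 2 for rec in lk.records())

    def test_added_decoy_only_removes_records(self, universe, space, matures,
                                              cca_genome, lookup):
        """Planting a window copy outside space never adds lookup entries."""
        victim = next(rec for rec in lookup.records() if rec.length == 20)
        genome2 = dict(cca_genome)
        genome2["chr1"] = genome2["chr1"] + "T" * 10 + victim.seq
        lk2 = build_lookup(space, matures, genome2)
        s1, s2 = lookup.sequences(), lk2.sequences()
        assert s2 <= s1
        assert victim.seq in s1 - s2

    def test_serialization_is_deterministic_and_round_trips(self, lookup, space,
                                                            matures, cca_genome, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        lookup.to_tsv(p1)
        build_lookup(space, matures, cca_genome).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        from trfspace import LookupTable
        lk2 = LookupTable.from_tsv(p1, space)
        assert lk2.sequences() == lookup.sequences()
        for rec in lookup.records()[::500]:
            r2 = lk2.get(rec.seq)
            assert r2.label == rec.label
            assert (r2.n_anticodons, r2.n_pseudo, r2.n_loci) == (
                rec.n_anticodons, rec.n_pseudo, rec.n_loci)
            assert r2.region == rec.region
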