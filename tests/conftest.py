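"""Shared fixtures: a small synthetic universe with its lookup table, and an
independent brute-force exclusivity oracle used to cross-check the lookup
construction."""

from __future__ import annotations

import re

import pytest
from Bio.Seq import reverse_complement

from trfspace import build_cca_genome, build_lookup
from trfspace.simulate import SimConfig, generate_genome


@pytest.fixture(scope="session")
def universe():
    return generate_genome(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def space(universe):
    return universe.space()


@pytest.fixture(scope="session")
def matures(universe):
    return universe.matures()


@pytest.fixture(scope="session")
def cca_genome(universe, space):
    return build_cca_genome(universe.genome, space)


@pytest.fixture(scope="session")
def lookup(space, matures, cca_genome):
    return build_lookup(space, matures, cca_genome)


# ---------------------------------------------------------------------------
# independent oracle: naive regex scan + linear interval checks

def naive_space_intervals(loci):
    """Strand-aware locus intervals extended by the 3 CCA-substituted bases."""
    out = []
    for l in loci:
        if l.strand == "+":
            out.append((l.chrom, l.start, l.end + 3))
        else:
            out.append((l.chrom, l.start - 3, l.end))
    return out


def naive_occurrences(seq, genome):
    """Every exact occurrence of seq on either strand, by regex lookahead."""
    hits = []
    for chrom, contig in genome.items():
        for strand, needle in (("+", seq), ("-", reverse_complement(seq))):
            for m in re.finditer(f"(?={re.escape(needle)})", contig):
                hits.append((chrom, strand, m.start() + 1, m.start() + len(seq)))
    return hits


def naive_exclusive(seq, genome, loci, junction_hit=False):
    """Brute-force exclusivity: every occurrence inside some locus interval."""
    hits = naive_occurrences(seq, genome)
    if not hits:
        return junction_hit
    intervals = naive_space_intervals(loci)
    for chrom, _strand, s, e in hits:
        if not any(c == chrom and lo <= s and e <= hi for c, lo, hi in intervals):
            return False
    return True


def naive_window_set(matures, min_len=16, max_len=50):
    """All distinct mature substrings in the length range, with junction flags."""
    seqs: dict[str, bool] = {}
    for m in matures:
        s = m.seq
        for k in range(min_len, min(max_len, len(s)) + 1):
            for i in range(len(s) - k + 1):
                sub = s[i : i + k]
                jh = any(i + 1 <= j < i + k for j in m.junctions)
                seqs[sub] = seqs.get(sub, False) or jh
    return seqs
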