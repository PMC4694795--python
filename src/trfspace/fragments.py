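"""Fragment space: exhaustive windows, genome-wide exclusivity, labels.

A candidate fragment is any 16-50 nt substring of a mature tRNA (CCA tail
included).  A fragment is *exclusive* to tRNA space when every exact
occurrence of its sequence in the CCA-modified genome - on either strand -
lies fully within a tRNA-space interval; sequences that never occur in the
genome are exclusive only when they straddle an exon-exon junction of an
intron-bearing tRNA (they exist solely in the spliced molecule).  Only
exclusive fragments enter the lookup table used for read profiling.

Each distinct exclusive sequence is summarised by one record carrying all its
mature placements, the counts (distinct anticodons, pseudo loci, total loci)
and one deterministically chosen source-proxy locus, from which the augmented
label is formatted::

    {id}_{anticodon}_{chrom}_{strand}_{start}_{end}@{fs}.{fe}.{len}[.CCA]__{nA}_{nP}_{nL}
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

from .reference import MatureTRNA, TRNALocus, TRNASpace, chrom_sort_key
from .regions import classify_region, is_full_span

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 16
DEFAULT_MAX_LEN = 50
DEFAULT_CAP = 10_000

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Placement:
    """One occurrence of a fragment within a mature tRNA (mature coordinates)."""

    locus: TRNALocus
    L: int
    frag_start: int
    frag_end: int

    @property
    def region(self) -> str:
        return classify_region(self.frag_start, self.frag_end, self.L)

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.locus.chrom), self.locus.start, self.locus.strand,
                self.locus.id, self.frag_start)


@dataclass(frozen=True)
class FragmentRecord:
    """A distinct exclusive fragment sequence with provenance and label data."""

    seq: str
    placements: tuple[Placement, ...]
    proxy: Placement
    n_anticodons: int
    n_pseudo: int
    n_loci: int
    exclusive: bool = True

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def region(self) -> str:
        return self.proxy.region

    @property
    def region_ambiguous(self) -> bool:
        return len({p.region for p in self.placements}) > 1

    @property
    def full_span(self) -> bool:
        return is_full_span(self.proxy.frag_start, self.proxy.frag_end, self.proxy.L)

    @property
    def label(self) -> str:
        return make_label(self)


@dataclass(frozen=True)
class FragmentLabel:
    """Parsed form of an augmented fragment label."""

    locus_id: str
    anticodon_name: str
    chrom: str
    strand: str
    start: int
    end: int
    frag_start: int
    frag_end: int
    length: int
    cca: bool
    n_anticodons: int
    n_pseudo: int
    n_loci: int

    @property
    def region(self) -> str:
        if self.cca:
            return "3p"
        return "5p" if self.frag_start == 1 else "i"


# ---------------------------------------------------------------------------
# window enumeration

def enumerate_windows(
    mature: MatureTRNA, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> list[tuple[str, int, int]]:
    """All substrings of the mature sequence (CCA included) with length in range.

    Returns ``(seq, frag_start, frag_end)`` tuples in mature coordinates.
    Junction-crossing windows are included: the mature sequence is contiguous.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    s = mature.seq
    n = len(s)
    out = []
    for k in range(min_len, min(max_len, n) + 1):
        for i in range(n - k + 1):
            out.append((s[i : i + k], i + 1, i + k))
    return out


# ---------------------------------------------------------------------------
# genome occurrence analysis

def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def genome_occurrences(
    seq: str, cca_genome: Mapping[str, str], cap: int = DEFAULT_CAP
) -> list[tuple[str, str, int, int]]:
    """All exact occurrences of ``seq`` in the genome, both strands.

    A minus-strand placement means the reverse complement of ``seq`` appears on
    the forward strand there (i.e. the minus strand reads ``seq`` 5'->3').
    Returns ``(chrom, strand, start, end)`` in forward-strand 1-based inclusive
    coordinates.  At most ``cap + 1`` placements are collected; a result longer
    than ``cap`` marks the sequence as saturated and it must be excluded from
    downstream use.
    """
    if not seq or not _ACGT.issuperset(seq):
        raise ValueError(f"sequence must be nonempty over ACGT, got {seq!r}")
    rc = reverse_complement(seq)
    k = len(seq)
    hits: list[tuple[str, str, int, int]] = []
    for chrom in sorted(cca_genome, key=chrom_sort_key):
        contig = cca_genome[chrom]
        for strand, needle in (("+", seq), ("-", rc)):
            for i in _find_all(contig, needle):
                hits.append((chrom, strand, i + 1, i + k))
                if len(hits) > cap:
                    return hits
    return hits


def is_saturated(placements: Sequence, cap: int = DEFAULT_CAP) -> bool:
    return len(placements) > cap


def assess_exclusivity(
    seq: str,
    placements: Sequence[tuple[str, str, int, int]],
    space: TRNASpace,
    junction_hit: bool = False,
) -> bool:
    """Decide tRNA-space exclusivity from whole-genome placements.

    True iff every genomic placement lies fully within a tRNA-space interval.
    A sequence with zero genomic placements is exclusive iff it straddles an
    exon-exon junction of a spliced mature tRNA (``junction_hit``); such
    sequences exist only in the mature molecule.
    """
    if not placements:
        return junction_hit
    return all(space.contains(chrom, start, end) for chrom, _strand, start, end in placements)


# ---------------------------------------------------------------------------
# provenance

def _provenance(placements: Sequence[Placement]) -> tuple[Placement, int, int, int]:
    ordered = sorted(placements, key=Placement.sort_key)
    proxy = ordered[0]
    loci = {p.locus.id: p.locus for p in ordered}
    n_anticodons = len({l.anticodon_name for l in loci.values()})
    n_pseudo = sum(1 for l in loci.values() if l.is_pseudo)
    return proxy, n_anticodons, n_pseudo, len(loci)


def resolve_provenance(
    seq: str, matures: Sequence[MatureTRNA]
) -> tuple[list[Placement], int, int, int, Placement]:
    """Locate ``seq`` in every mature tRNA and summarise its provenance.

    Returns the mature-coordinate placements, the number of distinct anticodon
    names, pseudo loci and total loci containing the sequence, and the
    deterministically chosen source-proxy placement (natural chromosome order,
    then start, strand, locus id; mitochondrial chromosomes sort last).
    """
    placements: list[Placement] = []
    for m in matures:
        for i in _find_all(m.seq, seq):
            placements.append(Placement(m.locus, m.L, i + 1, i + len(seq)))
    if not placements:
        raise ValueError(f"sequence {seq!r} not found in any mature tRNA (inconsistent index)")
    proxy, n_ac, n_ps, n_loci = _provenance(placements)
    return placements, n_ac, n_ps, n_loci, proxy


# ---------------------------------------------------------------------------
# labels

class LabelError(ValueError):
    pass


def make_label(rec: FragmentRecord) -> str:
    p = rec.proxy
    loc = p.locus
    cca = ".CCA" if p.frag_end > p.L else ""
    return (
        f"{loc.id}_{loc.anticodon_name}_{loc.chrom}_{loc.strand}_{loc.start}_{loc.end}"
        f"@{p.frag_start}.{p.frag_end}.{rec.length}{cca}"
        f"__{rec.n_anticodons}_{rec.n_pseudo}_{rec.n_loci}"
    )


def parse_label(s: str) -> FragmentLabel:
    """Parse an augmented fragment label; inverse of :func:`make_label`."""

    def fail(part: str, what: str):
        pos = s.find(part) if part and part in s else 0
        raise LabelError(f"malformed label {s!r} at position {pos}: {what}")

    head, sep, counts = s.rpartition("__")
    if not sep:
        fail(s, "missing '__' count separator")
    cparts = counts.split("_")
    if len(cparts) != 3 or not all(c.isdigit() for c in cparts):
        fail(counts, "counts must be three '_'-separated integers")
    locpart, sep, fragpart = head.partition("@")
    if not sep:
        fail(head, "missing '@' separator")
    fparts = fragpart.split(".")
    cca = False
    if len(fparts) == 4 and fparts[3] == "CCA":
        cca = True
        fparts = fparts[:3]
    if len(fparts) != 3 or not all(p.isdigit() for p in fparts):
        fail(fragpart, "fragment part must be fs.fe.len with optional .CCA")
    fs, fe, ln = (int(x) for x in fparts)
    if fe - fs + 1 != ln:
        fail(fragpart, f"length {ln} != fe-fs+1 = {fe - fs + 1}")
    lparts = locpart.rsplit("_", 4)
    if len(lparts) != 5:
        fail(locpart, "locus part needs id_anticodon_chrom_strand_start_end")
    head2, chrom, strand, start, end = lparts
    if strand not in {"+", "-"}:
        fail(strand, "strand must be '+' or '-'")
    if not (start.isdigit() and end.isdigit()):
        fail(start, "start/end must be integers")
    lid, sep, anticodon = head2.rpartition("_")
    if not sep or not lid or not anticodon:
        fail(head2, "cannot split locus id and anticodon")
    return FragmentLabel(
        locus_id=lid,
        anticodon_name=anticodon,
        chrom=chrom,
        strand=strand,
        start=int(start),
        end=int(end),
        frag_start=fs,
        frag_end=fe,
        length=ln,
        cca=cca,
        n_anticodons=int(cparts[0]),
        n_pseudo=int(cparts[1]),
        n_loci=int(cparts[2]),
    )


# ---------------------------------------------------------------------------
# lookup construction

class LookupTable:
    """Exclusive fragment sequences -> FragmentRecord, with TSV serialization."""

    def __init__(self, records: Iterable[FragmentRecord]):
        self._by_seq: dict[str, FragmentRecord] = {}
        for rec in records:
            self._by_seq[rec.seq] = rec

    def __len__(self) -> int:
        return len(self._by_seq)

    def __contains__(self, seq: str) -> bool:
        return seq in self._by_seq

    def get(self, seq: str) -> FragmentRecord | None:
        return self._by_seq.get(seq)

    def records(self) -> list[FragmentRecord]:
        return [self._by_seq[s] for s in sorted(self._by_seq)]

    def sequences(self) -> set[str]:
        return set(self._by_seq)

    def annotation_frame(self):
        """Per-label annotation (region, length, origin, anticodon, frag_start)."""
        import pandas as pd

        rows = []
        for rec in self.records():
            rows.append(
                {
                    "label": rec.label,
                    "seq": rec.seq,
                    "region": rec.region,
                    "length": rec.length,
                    "origin": rec.proxy.locus.origin,
                    "anticodon": rec.proxy.locus.anticodon_name,
                    "frag_start": rec.proxy.frag_start,
                    "n_anticodons": rec.n_anticodons,
                    "n_pseudo": rec.n_pseudo,
                    "n_loci": rec.n_loci,
                }
            )
        return pd.DataFrame(rows).set_index("label")

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(
                "seq\tlabel\tregion\tlength\tn_anticodons\tn_pseudo\tn_loci\torigin\tplacements\n"
            )
            for rec in self.records():
                pl = ";".join(
                    f"{p.locus.id}:{p.frag_start}-{p.frag_end}:{p.L}" for p in rec.placements
                )
                fh.write(
                    f"{rec.seq}\t{rec.label}\t{rec.region}\t{rec.length}\t"
                    f"{rec.n_anticodons}\t{rec.n_pseudo}\t{rec.n_loci}\t"
                    f"{rec.proxy.locus.origin}\t{pl}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, space: TRNASpace | None = None) -> "LookupTable":
        """Rehydrate a lookup table; locus objects are rebuilt from the labels.

        When ``space`` is given, placements are resolved against its loci; the
        serialized per-placement coordinates are used either way, so profiling
        and summaries are fully reconstructable from the TSV alone (non-proxy
        placement loci fall back to label-derived stubs).
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        by_id: dict[str, TRNALocus] = {l.id: l for l in space.loci} if space else {}
        records = []
        for _, row in df.iterrows():
            lab = parse_label(row["label"])
            proxy_locus = by_id.get(lab.locus_id) or TRNALocus(
                id=lab.locus_id,
                anticodon_name=lab.anticodon_name,
                chrom=lab.chrom,
                strand=lab.strand,
                start=lab.start,
                end=lab.end,
                origin=row.get("origin", "nuclear"),
            )
            placements = []
            for token in str(row["placements"]).split(";"):
                lid, span, L = token.split(":")
                fs, _, fe = span.partition("-")
                locus = by_id.get(lid)
                if locus is None:
                    locus = proxy_locus if lid == lab.locus_id else TRNALocus(
                        id=lid, anticodon_name=lab.anticodon_name, chrom=lab.chrom,
                        strand=lab.strand, start=lab.start, end=lab.end,
                        origin=row.get("origin", "nuclear"),
                    )
                placements.append(Placement(locus, int(L), int(fs), int(fe)))
            proxy = next(
                p for p in placements
                if p.locus.id == lab.locus_id and p.frag_start == lab.frag_start
            )
            records.append(
                FragmentRecord(
                    seq=row["seq"],
                    placements=tuple(placements),
                    proxy=proxy,
                    n_anticodons=int(row["n_anticodons"]),
                    n_pseudo=int(row["n_pseudo"]),
                    n_loci=int(row["n_loci"]),
                )
            )
        return cls(records)


def build_lookup(
    space: TRNASpace,
    matures: Sequence[MatureTRNA],
    cca_genome: Mapping[str, str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    cap: int = DEFAULT_CAP,
) -> LookupTable:
    """Enumerate, exclusivity-test and summarise all fragments of a reference.

    Identical sequences arising from multiple matures are merged into one
    record (distinct-sequence semantics); sequences exceeding the occurrence
    cap are dropped and logged, mirroring the multi-mapping cap.
    """
    windows: dict[str, list[Placement]] = {}
    junction: dict[str, bool] = {}
    for m in matures:
        jset = set(m.junctions)
        for seq, fs, fe in enumerate_windows(m, min_len, max_len):
            windows.setdefault(seq, []).append(Placement(m.locus, m.L, fs, fe))
            if jset and any(fs <= j < fe for j in jset):
                junction[seq] = True
    records = []
    n_saturated = n_nonexclusive = 0
    for seq in sorted(windows):
        occ = genome_occurrences(seq, cca_genome, cap=cap)
        if is_saturated(occ, cap):
            n_saturated += 1
            log.info("sequence saturated the %d-occurrence cap; dropped: %s...", cap, seq[:20])
            continue
        if not assess_exclusivity(seq, occ, space, junction_hit=junction.get(seq, False)):
            n_nonexclusive += 1
            continue
        proxy, n_ac, n_ps, n_loci = _provenance(windows[seq])
        rec = FragmentRecord(
            seq=seq,
            placements=tuple(sorted(windows[seq], key=Placement.sort_key)),
            proxy=proxy,
            n_anticodons=n_ac,
            n_pseudo=n_ps,
            n_loci=n_loci,
        )
        if rec.region_ambiguous:
            log.debug("region-ambiguous fragment %s (proxy region %s)", rec.label, rec.region)
        records.append(rec)
    log.info(
        "lookup built: %d exclusive, %d non-exclusive, %d saturated",
        len(records), n_nonexclusive, n_saturated,
    )
    return LookupTable(records)
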