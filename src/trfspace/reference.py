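"""Reference construction: annotated tRNA loci, mature sequences, CCA genome.

The reference "tRNA space" is the set of genomic intervals accepted as
legitimate sources of tRNA fragments: nuclear tRNA genes, the mitochondrial
tRNA genes, and nuclear intervals that are *exactly* identical copies of
mitochondrial tRNAs (lookalikes).  Mature sequences are obtained by splicing
out introns and appending the nontemplated CCA; the genome used for occurrence
analysis carries CCA substituted over the three bases immediately downstream
of every locus so that CCA-ending reads map exactly.

All genomic coordinates are 1-based inclusive; mature coordinates are 1-based
with +1 = first nucleotide of the mature tRNA.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

ORIGINS = ("nuclear", "mitochondrial", "lookalike")

_MITO_CHROMS = {"MT", "M", "chrM", "chrMT"}


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: 1..22, X, Y, then mitochondrial, then others."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    if name == "X":
        return (1, 0, "")
    if name == "Y":
        return (2, 0, "")
    if name in {"M", "MT"}:
        return (3, 0, "")
    return (4, 0, name)


@dataclass(frozen=True)
class TRNALocus:
    """One annotated genomic tRNA interval (nuclear, mitochondrial or lookalike)."""

    id: str
    anticodon_name: str
    chrom: str
    strand: str
    start: int
    end: int
    introns: tuple[tuple[int, int], ...] = ()
    origin: str = "nuclear"
    is_pseudo: bool = False

    def __post_init__(self):
        if "_" in self.id or "_" in self.anticodon_name or "_" in self.chrom:
            raise ValueError(
                f"locus {self.id!r}: id, anticodon and chromosome tokens must be "
                "underscore-free (required by the fragment label grammar)"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"locus {self.id!r}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 < self.start <= self.end):
            raise ValueError(f"locus {self.id!r}: require 0 < start <= end, got {self.start}..{self.end}")
        if self.origin not in ORIGINS:
            raise ValueError(f"locus {self.id!r}: unknown origin {self.origin!r}")
        for (s, e) in self.introns:
            if not (self.start < s <= e < self.end):
                raise ValueError(
                    f"locus {self.id!r}: intron {s}-{e} not strictly inside locus "
                    f"{self.start}-{self.end}"
                )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.start, self.strand, self.id)


@dataclass(frozen=True)
class MatureTRNA:
    """Spliced mature tRNA sequence with the CCA tail appended.

    ``seq`` is the 5'->3' mature sequence of length ``L + 3``; ``junctions``
    lists the mature positions p such that exon boundaries abut between
    positions p and p+1.
    """

    locus: TRNALocus
    seq: str
    L: int
    junctions: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.seq) != self.L + 3:
            raise ValueError(f"{self.locus.id}: len(seq)={len(self.seq)} != L+3={self.L + 3}")
        if not self.seq.endswith("CCA"):
            raise ValueError(f"{self.locus.id}: mature sequence must end with CCA")


class TRNASpace:
    """The set of tRNA-space loci with a queryable genomic interval index.

    Intervals cover every locus plus, per locus, the three genomic positions
    immediately downstream of the mature 3' end (the CCA-substituted bases),
    so that CCA-ending reads landing there remain attributable to the tRNA.
    Membership queries are strand-agnostic and deterministic.
    """

    def __init__(self, loci: Sequence[TRNALocus]):
        ids = [l.id for l in loci]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids: {dup}")
        self.loci: list[TRNALocus] = sorted(loci, key=TRNALocus.sort_key)
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._build_index()

    def _build_index(self) -> None:
        raw: dict[str, list[tuple[int, int]]] = {}
        for loc in self.loci:
            lo, hi = (loc.start, loc.end + 3) if loc.strand == "+" else (loc.start - 3, loc.end)
            raw.setdefault(loc.chrom, []).append((lo, hi))
        for chrom, ivals in raw.items():
            merged: list[tuple[int, int]] = []
            for lo, hi in sorted(ivals):
                if merged and lo <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
                else:
                    merged.append((lo, hi))
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    def __len__(self) -> int:
        return len(self.loci)

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end] lies fully within one tRNA-space interval."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, start) - 1
        return i >= 0 and self._ends[chrom][i] >= end

    def by_origin(self, origin: str) -> list[TRNALocus]:
        return [l for l in self.loci if l.origin == origin]

    def composition(self) -> dict[str, int]:
        return {o: len(self.by_origin(o)) for o in ORIGINS}


# ---------------------------------------------------------------------------
# annotation I/O

def _parse_introns(cell) -> tuple[tuple[int, int], ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() in {"", "."}:
        return ()
    out = []
    for part in str(cell).split(","):
        s, _, e = part.strip().partition("-")
        out.append((int(s), int(e)))
    return tuple(out)


def load_annotation(
    annotation_table: str | Path,
    lookalike_table: str | Path | None = None,
    exclude_anticodon_prefixes: Iterable[str] = ("SeC", "Undet"),
) -> TRNASpace:
    """Parse a tRNA annotation table (+ optional lookalike table) into a TRNASpace.

    The annotation table is a TSV with header columns
    ``id, anticodon_name, chrom, strand, start, end, introns, origin, is_pseudo``
    (introns as comma-separated ``start-end`` pairs, 1-based inclusive; ``#``
    lines are comments).  The lookalike table is a BED-like TSV with header
    ``chrom, start, end, id, strand, mito_anticodon`` (coordinates 1-based
    inclusive); lookalike rows inherit the anticodon of the mitochondrial tRNA
    they duplicate and become full members of tRNA space.

    Selenocysteine / undetermined-anticodon entries are excluded with a logged
    flag, mirroring the curation applied when composing a reference registry.
    """
    loci: list[TRNALocus] = []
    ann = pd.read_csv(annotation_table, sep="\t", comment="#", dtype=str)
    required = {"id", "anticodon_name", "chrom", "strand", "start", "end"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{annotation_table}: missing columns {sorted(missing)}")
    prefixes = tuple(exclude_anticodon_prefixes)
    n_excluded = 0
    for idx, row in ann.iterrows():
        line = idx + 2  # header is line 1
        try:
            anticodon = str(row["anticodon_name"])
            if prefixes and anticodon.startswith(prefixes):
                n_excluded += 1
                continue
            loci.append(
                TRNALocus(
                    id=str(row["id"]),
                    anticodon_name=anticodon,
                    chrom=str(row["chrom"]),
                    strand=str(row["strand"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    introns=_parse_introns(row.get("introns")),
                    origin=str(row.get("origin", "nuclear") or "nuclear"),
                    is_pseudo=str(row.get("is_pseudo", "False")).strip().lower()
                    in {"1", "true", "yes"},
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{annotation_table}, line {line}: {exc}") from exc
    if n_excluded:
        log.warning("excluded %d annotation rows by anticodon prefix %s", n_excluded, prefixes)

    if lookalike_table is not None:
        la = pd.read_csv(lookalike_table, sep="\t", comment="#", dtype=str)
        if len(la):
            need = {"chrom", "start", "end", "id", "strand", "mito_anticodon"}
            missing = need - set(la.columns)
            if missing:
                raise ValueError(f"{lookalike_table}: missing columns {sorted(missing)}")
            for idx, row in la.iterrows():
                line = idx + 2
                try:
                    loci.append(
                        TRNALocus(
                            id=str(row["id"]),
                            anticodon_name=str(row["mito_anticodon"]),
                            chrom=str(row["chrom"]),
                            strand=str(row["strand"]),
                            start=int(row["start"]),
                            end=int(row["end"]),
                            origin="lookalike",
                        )
                    )
                except (ValueError, TypeError) as exc:
                    raise ValueError(f"{lookalike_table}, line {line}: {exc}") from exc
    return TRNASpace(loci)


def write_annotation(loci: Sequence[TRNALocus], path: str | Path) -> None:
    """Serialize nuclear+mito loci as the annotation TSV read by load_annotation."""
    rows = []
    for l in loci:
        rows.append(
            {
                "id": l.id,
                "anticodon_name": l.anticodon_name,
                "chrom": l.chrom,
                "strand": l.strand,
                "start": l.start,
                "end": l.end,
                "introns": ",".join(f"{s}-{e}" for s, e in l.introns),
                "origin": l.origin,
                "is_pseudo": l.is_pseudo,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_lookalikes(loci: Sequence[TRNALocus], path: str | Path) -> None:
    rows = [
        {
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "id": l.id,
            "strand": l.strand,
            "mito_anticodon": l.anticodon_name,
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand", "mito_anticodon"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# genome handling

def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as a dict of uppercase contig sequences.

    Soft-masked lowercase bases are treated as ordinary bases.  Uses pyfaidx
    for indexed access so large references are not re-parsed on every call.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def splice_mature(locus: TRNALocus, genome: Mapping[str, str]) -> MatureTRNA:
    """Extract, splice and CCA-append the mature sequence of a locus.

    Minus-strand loci are reverse-complemented; introns are removed in genomic
    coordinates before orientation, and exon junctions are reported in mature
    coordinates (position of the last base of each non-terminal exon).
    """
    contig = genome.get(locus.chrom)
    if contig is None:
        raise ValueError(f"locus {locus.id}: chromosome {locus.chrom!r} not in genome")
    if locus.end > len(contig):
        raise ValueError(
            f"locus {locus.id}: interval {locus.start}-{locus.end} exceeds "
            f"contig {locus.chrom} length {len(contig)}"
        )
    # exon segments in genomic order
    exons: list[str] = []
    pos = locus.start
    for (is_, ie) in sorted(locus.introns):
        exons.append(contig[pos - 1 : is_ - 1])
        pos = ie + 1
    exons.append(contig[pos - 1 : locus.end])
    if locus.strand == "-":
        exons = [reverse_complement(x) for x in reversed(exons)]
    spliced = "".join(exons)
    junctions: list[int] = []
    acc = 0
    for x in exons[:-1]:
        acc += len(x)
        junctions.append(acc)
    return MatureTRNA(locus=locus, seq=spliced + "CCA", L=len(spliced), junctions=tuple(junctions))


def build_cca_genome(genome: Mapping[str, str], space: TRNASpace) -> dict[str, str]:
    """Return a genome copy with CCA written over the 3 bases downstream of each locus.

    For a plus-strand locus ending at position e the forward-strand bases
    e+1..e+3 become ``CCA``; for a minus-strand locus starting at position s the
    forward-strand bases s-3..s-1 become ``TGG`` (so the transcribed strand
    reads CCA).  Substitutions are applied in locus-sorted order; overlapping
    windows are written last-wins and logged.
    """
    out = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    written: dict[str, set[int]] = {name: set() for name in genome}
    for loc in space.loci:
        contig = out.get(loc.chrom)
        if contig is None:
            raise ValueError(f"locus {loc.id}: chromosome {loc.chrom!r} not in genome")
        if loc.strand == "+":
            lo0 = loc.end  # 0-based index of first downstream base
            patch = b"CCA"
        else:
            lo0 = loc.start - 4
            patch = b"TGG"
        if lo0 < 0 or lo0 + 3 > len(contig):
            raise ValueError(
                f"locus {loc.id}: fewer than 3 genomic bases downstream of the "
                f"mature 3' end on {loc.chrom}"
            )
        overlap = written[loc.chrom].intersection(range(lo0, lo0 + 3))
        if overlap:
            log.warning("CCA substitution window of %s overlaps a previous window", loc.id)
        contig[lo0 : lo0 + 3] = patch
        written[loc.chrom].update(range(lo0, lo0 + 3))
    return {name: bytes(seq).decode("ascii") for name, seq in out.items()}
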