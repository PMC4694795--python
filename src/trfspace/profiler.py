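"""Read profiling: collapse reads, exact lookup, single counting per fragment.

Classification is a dictionary lookup against the exclusive fragment table.
Because exclusivity was decided at lookup-build time by exhaustive exact
whole-genome occurrence analysis, this is equivalent to exact multi-mapping of
each read on the genome followed by the inside/outside-tRNA-space filter - but
deterministic and self-contained.  A read present at many tRNA-space loci
contributes its count exactly once, to the merged record whose label names the
source-proxy locus.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .fragments import DEFAULT_MAX_LEN, DEFAULT_MIN_LEN, LookupTable
from .regions import REGIONS, classify_region  # noqa: F401  (re-exported surface)

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class ReadSet:
    """Collapsed reads of one dataset: exact sequence -> count.

    ``total_reads`` is the sequencing depth used for normalization (total
    input reads after collapsing, configurable upstream).  Sequences with
    non-ACGT characters are dropped at construction and tallied.
    """

    dataset_id: str
    counts: dict[str, int]
    total_reads: int
    metadata: dict = field(default_factory=dict)
    bad_base_count: int = 0

    @classmethod
    def from_pairs(
        cls, dataset_id: str, pairs: Iterable[tuple[str, int]], metadata: dict | None = None
    ) -> "ReadSet":
        counts: dict[str, int] = {}
        bad = 0
        total = 0
        for seq, c in pairs:
            c = int(c)
            if c < 1:
                raise ValueError(f"read count must be >= 1, got {c} for {seq!r}")
            seq = seq.upper()
            total += c
            if not _ACGT.issuperset(seq):
                bad += c
                continue
            counts[seq] = counts.get(seq, 0) + c
        return cls(dataset_id, counts, total_reads=total, metadata=metadata or {},
                   bad_base_count=bad)

    @classmethod
    def from_fastq(cls, path: str | Path, dataset_id: str | None = None,
                   metadata: dict | None = None) -> "ReadSet":
        """Collapse a FASTQ (optionally gzipped) by exact sequence."""
        from Bio import SeqIO

        dataset_id = dataset_id or Path(str(path)).name.split(".")[0]
        with _open_text(path) as fh:
            pairs = ((str(rec.seq), 1) for rec in SeqIO.parse(fh, "fastq"))
            return cls.from_pairs(dataset_id, pairs, metadata)

    @classmethod
    def from_tsv(cls, path: str | Path, dataset_id: str | None = None,
                 metadata: dict | None = None) -> "ReadSet":
        """Read a 2-column (seq, count) TSV, '#' comments allowed."""
        dataset_id = dataset_id or Path(str(path)).name.split(".")[0]
        pairs = []
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("seq\t"):
                    continue
                seq, _, c = line.partition("\t")
                pairs.append((seq, int(c)))
        return cls.from_pairs(dataset_id, pairs, metadata)


@dataclass
class Profile:
    """Per-dataset fragment counts plus discard tallies."""

    dataset_id: str
    counts: dict[str, int]           # fragment label -> raw count
    region_totals: dict[str, int]
    tallies: dict[str, int]
    metadata: dict = field(default_factory=dict)

    @property
    def counted(self) -> int:
        return self.tallies["counted"]

    def conserved(self) -> bool:
        t = self.tallies
        return (
            t["counted"] + t["not_in_lookup"] + t["out_of_range"] + t["bad_bases"]
            == t["total_input"]
        )

    def to_tsv(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("label\traw_count\n")
            for label in sorted(self.counts):
                fh.write(f"{label}\t{self.counts[label]}\n")
        sidecar = Path(str(path)).with_suffix(Path(str(path)).suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"dataset_id": self.dataset_id, "tallies": self.tallies,
                 "region_totals": self.region_totals, "metadata": self.metadata},
                fh, indent=2,
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Profile":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("label\t"):
                    continue
                label, _, c = line.partition("\t")
                counts[label] = int(c)
        sidecar = Path(str(path)).with_suffix(Path(str(path)).suffix + ".json")
        meta = {}
        tallies = {}
        region_totals = {}
        dataset_id = Path(str(path)).name.split(".")[0]
        if sidecar.exists():
            with open(sidecar) as fh:
                side = json.load(fh)
            dataset_id = side.get("dataset_id", dataset_id)
            tallies = side.get("tallies", {})
            region_totals = side.get("region_totals", {})
            meta = side.get("metadata", {})
        return cls(dataset_id, counts, region_totals, tallies, meta)


def profile_reads(
    reads: ReadSet,
    lookup: LookupTable,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> Profile:
    """Assign collapsed reads to exclusive fragment records.

    Each read sequence found in the lookup contributes its count to exactly
    one record; sequences not in the lookup (non-exclusive, non-tRNA, or
    mismatch-bearing) are tallied as discarded; lengths outside
    ``[min_len, max_len]`` are tallied as out-of-range.
    """
    counts: dict[str, int] = {}
    region_totals = {r: 0 for r in REGIONS}
    counted = not_in_lookup = out_of_range = 0
    for seq, c in reads.counts.items():
        if not (min_len <= len(seq) <= max_len):
            out_of_range += c
            continue
        rec = lookup.get(seq)
        if rec is None:
            not_in_lookup += c
            continue
        label = rec.label
        counts[label] = counts.get(label, 0) + c
        region_totals[rec.region] += c
        counted += c
    tallies = {
        "total_input": reads.total_reads,
        "counted": counted,
        "not_in_lookup": not_in_lookup,
        "out_of_range": out_of_range,
        "bad_bases": reads.bad_base_count,
    }
    return Profile(reads.dataset_id, counts, region_totals, tallies, dict(reads.metadata))
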