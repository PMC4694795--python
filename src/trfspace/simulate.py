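"""Synthetic test universes with planted ground truth.

The generator emits a small random genome with planted tRNA loci covering the
awkward cases the deduction method must handle - minus-strand loci,
intron-bearing loci, identical multi-copy isodecoders, mitochondrial tRNAs and
their exact nuclear lookalikes - together with *decoys* placed outside tRNA
space: partial tRNA copies (which break the exclusivity of the windows they
replicate) and single-mismatch copies (which exact matching must ignore).
Read sets are drawn per dataset from configurable region/length abundance
profiles, and everything is recorded in a truth manifest that fully determines
the expected profiler output.

All randomness flows from one integer seed through ``numpy``'s Philox-backed
``default_rng`` seed-sequence spawning, so outputs are byte-identical across
runs and platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .profiler import ReadSet
from .reference import (MatureTRNA, TRNALocus, TRNASpace, splice_mature,
                        write_annotation, write_genome, write_lookalikes)

BASES = np.array(list("ACGT"))

#: A canonical LCL-like abundance law: per region, fragment-length -> mass.
#: Internal fragments dominated by 36-mers; 5' and 3' fragments spread over
#: the literature lengths (18, 22, 26, 33, 36 nt).
DEFAULT_PROFILE: dict[str, dict[int, float]] = {
    "5p": {18: 0.10, 22: 0.08, 26: 0.05, 33: 0.07, 36: 0.05},
    "i": {20: 0.07, 36: 0.23},
    "3p": {18: 0.12, 22: 0.08, 33: 0.10, 36: 0.05},
}


def anticodon_alphabet() -> list[str]:
    """Anticodon names (AminoAcid + anticodon triplet) from the standard code."""
    from Bio.Data.CodonTable import standard_dna_table
    from Bio.SeqUtils import seq3

    names = []
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        names.append(f"{seq3(aa)}{reverse_complement(codon)}")
    return names


@dataclass(frozen=True)
class SimConfig:
    """Shape of the synthetic universe (counts, lengths, composition)."""

    n_chroms: int = 2
    chrom_length: int = 20_000
    mito_length: int = 2_000
    n_nuclear: int = 5
    n_mito: int = 2
    n_lookalikes: int = 1
    n_identical_copies: int = 2     # copies of the first nuclear tRNA (1 = unique)
    n_intron_loci: int = 1
    intron_length: int = 20
    minus_strand_fraction: float = 0.4
    pseudo_fraction: float = 0.2
    trna_len_min: int = 59          # templated lengths within the biological range
    trna_len_max: int = 95
    n_partial_decoys: int = 1
    partial_decoy_length: int = 24
    n_mismatch_decoys: int = 1
    gc: float = 0.5
    margin: int = 10                # clearance between planted elements

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class TruthManifest:
    """Ground truth: planted loci, decoys, per-dataset planted read counts."""

    seed: int
    config: dict
    config_hash: str
    loci: list[dict] = field(default_factory=list)
    lookalikes: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)
    datasets: dict[str, dict] = field(default_factory=dict)

    def expected_counts(self, dataset_id: str) -> dict[str, int]:
        """Planted (countable) reads per fragment sequence for one dataset."""
        return dict(self.datasets[dataset_id]["planted"])

    def expected_discards(self, dataset_id: str) -> int:
        return sum(self.datasets[dataset_id]["noise"].values())

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticUniverse:
    """A generated genome with its annotation and truth manifest."""

    genome: dict[str, str]
    loci: list[TRNALocus]           # nuclear + mitochondrial
    lookalike_loci: list[TRNALocus]
    manifest: TruthManifest

    def space(self) -> TRNASpace:
        return TRNASpace(self.loci + self.lookalike_loci)

    def matures(self) -> list[MatureTRNA]:
        return [splice_mature(l, self.genome) for l in self.loci + self.lookalike_loci]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, outdir / "genome.fa")
        write_annotation(self.loci, outdir / "trna.tsv")
        write_lookalikes(self.lookalike_loci, outdir / "lookalikes.tsv")
        self.manifest.save(outdir / "manifest.json")


# ---------------------------------------------------------------------------
# genome generation

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


class _Placer:
    """Non-overlapping slot allocation on the synthetic chromosomes."""

    def __init__(self, rng: np.random.Generator, genome: dict[str, str], margin: int):
        self.rng = rng
        self.lengths = {c: len(s) for c, s in genome.items()}
        self.margin = margin
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def place(self, length: int, chroms: Sequence[str], max_tries: int = 200) -> tuple[str, int]:
        """Return (chrom, 1-based start) of a free slot; margin enforced."""
        for _ in range(max_tries):
            chrom = str(self.rng.choice(list(chroms)))
            limit = self.lengths[chrom] - length - self.margin
            if limit <= self.margin:
                continue
            start = int(self.rng.integers(self.margin + 1, limit))
            lo, hi = start - self.margin, start + length + self.margin
            if all(hi < s or lo > e for s, e in self.used[chrom]):
                self.used[chrom].append((lo, hi))
                return chrom, start
        raise RuntimeError(
            f"could not place a {length} nt element after {max_tries} tries; "
            "increase chromosome length or reduce element count"
        )


def _plant(genome: dict[str, str], chrom: str, start: int, forward_seq: str) -> None:
    s = genome[chrom]
    genome[chrom] = s[: start - 1] + forward_seq + s[start - 1 + len(forward_seq):]


def generate_genome(config: SimConfig | None = None, seed: int = 0) -> SyntheticUniverse:
    """Generate a genome, annotation and manifest with planted ground truth."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    rng_bg, rng_elem = [np.random.default_rng(s) for s in ss.spawn(2)]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {c: _random_seq(rng_bg, config.chrom_length, config.gc) for c in chrom_names}
    genome["MT"] = _random_seq(rng_bg, config.mito_length, config.gc)
    placer = _Placer(rng_elem, genome, config.margin)

    alphabet = anticodon_alphabet()
    picks = rng_elem.choice(len(alphabet), size=config.n_nuclear + config.n_mito, replace=False)
    manifest = TruthManifest(seed=seed, config=asdict(config), config_hash=config.hash())
    loci: list[TRNALocus] = []

    def register(locus: TRNALocus, mature_seq: str) -> None:
        loci.append(locus)
        manifest.loci.append(
            {"id": locus.id, "anticodon": locus.anticodon_name, "chrom": locus.chrom,
             "strand": locus.strand, "start": locus.start, "end": locus.end,
             "introns": list(map(list, locus.introns)), "origin": locus.origin,
             "is_pseudo": locus.is_pseudo, "mature_seq": mature_seq}
        )

    # --- nuclear tRNAs (index 0 may be multi-copy; first few carry introns)
    n_id = 0
    transcribed: dict[str, str] = {}   # locus id -> templated (spliced) sequence
    for i in range(config.n_nuclear):
        anticodon = alphabet[picks[i]]
        L = int(rng_elem.integers(config.trna_len_min, config.trna_len_max + 1))
        spliced = _random_seq(rng_elem, L, config.gc)
        has_intron = i >= 1 and (i - 1) < config.n_intron_loci
        is_pseudo = bool(rng_elem.random() < config.pseudo_fraction)
        copies = config.n_identical_copies if i == 0 else 1
        intron_seq = _random_seq(rng_elem, config.intron_length, config.gc) if has_intron else ""
        # canonical intron position: after base 37 of the templated sequence
        cut = min(37, L - 10)
        for _ in range(copies):
            strand = "-" if rng_elem.random() < config.minus_strand_fraction else "+"
            if has_intron:
                genomic_tx = spliced[:cut] + intron_seq + spliced[cut:]
            else:
                genomic_tx = spliced
            fwd = genomic_tx if strand == "+" else reverse_complement(genomic_tx)
            chrom, start = placer.place(len(fwd), chrom_names)
            _plant(genome, chrom, start, fwd)
            end = start + len(fwd) - 1
            if has_intron:
                if strand == "+":
                    introns = ((start + cut, start + cut + config.intron_length - 1),)
                else:
                    ie = end - cut
                    introns = ((ie - config.intron_length + 1, ie),)
            else:
                introns = ()
            n_id += 1
            locus = TRNALocus(
                id=f"trna{n_id}", anticodon_name=anticodon, chrom=chrom, strand=strand,
                start=start, end=end, introns=introns, origin="nuclear",
                is_pseudo=is_pseudo,
            )
            register(locus, spliced + "CCA")
            transcribed[locus.id] = spliced

    # --- mitochondrial tRNAs (single copy, forward strand of MT)
    mito_ids = []
    for j in range(config.n_mito):
        anticodon = alphabet[picks[config.n_nuclear + j]]
        L = int(rng_elem.integers(config.trna_len_min, min(config.trna_len_max, 75) + 1))
        spliced = _random_seq(rng_elem, L, config.gc)
        chrom, start = placer.place(L, ["MT"])
        _plant(genome, chrom, start, spliced)
        n_id += 1
        locus = TRNALocus(
            id=f"trna{n_id}", anticodon_name=anticodon, chrom=chrom, strand="+",
            start=start, end=start + L - 1, origin="mitochondrial",
        )
        register(locus, spliced + "CCA")
        transcribed[locus.id] = spliced
        mito_ids.append(locus.id)

    # --- exact nuclear lookalikes of mitochondrial tRNAs
    lookalikes: list[TRNALocus] = []
    for k in range(config.n_lookalikes):
        src = loci[[l.id for l in loci].index(mito_ids[k % len(mito_ids)])]
        seq = transcribed[src.id]
        chrom, start = placer.place(len(seq), chrom_names)
        _plant(genome, chrom, start, seq)
        la = TRNALocus(
            id=f"lookalike{k + 1}", anticodon_name=src.anticodon_name, chrom=chrom,
            strand="+", start=start, end=start + len(seq) - 1, origin="lookalike",
        )
        lookalikes.append(la)
        manifest.lookalikes.append(
            {"id": la.id, "mito_anticodon": la.anticodon_name, "chrom": la.chrom,
             "strand": la.strand, "start": la.start, "end": la.end, "source": src.id}
        )

    # --- decoys outside tRNA space
    nuclear = [l for l in loci if l.origin == "nuclear" and not l.introns]
    for d in range(config.n_partial_decoys):
        src = nuclear[d % len(nuclear)]
        frag = transcribed[src.id][: config.partial_decoy_length]   # 5' window copy
        chrom, start = placer.place(len(frag), chrom_names)
        _plant(genome, chrom, start, frag)
        manifest.decoys.append(
            {"type": "partial", "source": src.id, "chrom": chrom, "start": start,
             "end": start + len(frag) - 1, "seq": frag}
        )
    for d in range(config.n_mismatch_decoys):
        src = nuclear[(config.n_partial_decoys + d) % len(nuclear)]
        seq = list(transcribed[src.id])
        pos = int(rng_elem.integers(0, len(seq)))
        old = seq[pos]
        seq[pos] = str(rng_elem.choice([b for b in "ACGT" if b != old]))
        mut = "".join(seq)
        chrom, start = placer.place(len(mut), chrom_names)
        _plant(genome, chrom, start, mut)
        manifest.decoys.append(
            {"type": "mismatch", "source": src.id, "chrom": chrom, "start": start,
             "end": start + len(mut) - 1, "seq": mut}
        )

    return SyntheticUniverse(genome, loci, lookalikes, manifest)


# ---------------------------------------------------------------------------
# read generation

def _validate_spec(spec: Mapping[str, Mapping[int, float]]) -> None:
    total = sum(m for lens in spec.values() for m in lens.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"profile masses must sum to 1, got {total}")
    for region in spec:
        if region not in {"5p", "i", "3p"}:
            raise ValueError(f"unknown region {region!r} in profile spec")


def _fragment_pool(
    universe: SyntheticUniverse,
    cells: set[tuple[str, int]],
    rng: np.random.Generator,
    fragments_per_cell: int,
) -> dict[tuple[str, int], list[tuple[str, str, int, int]]]:
    """Choose concrete (seq, locus, fs, fe) fragments for each (region, length).

    Loci whose sequence was copied (whole or in part, with or without a
    mismatch) into a decoy are avoided so that planted reads stay exclusive
    and the manifest exactly predicts profiling: even a single-mismatch decoy
    replicates exactly the source windows that do not cover the mutated base.
    """
    decoy_sources = {d["source"] for d in universe.manifest.decoys}
    matures = {m.locus.id: m for m in universe.matures()}
    eligible = [m for m in matures.values()
                if m.locus.id not in decoy_sources and m.locus.origin != "lookalike"]
    pool: dict[tuple[str, int], list[tuple[str, str, int, int]]] = {}
    for region, length in sorted(cells):
        chosen: list[tuple[str, str, int, int]] = []
        cands = [m for m in eligible if m.L >= length + 2]
        if not cands:
            raise ValueError(f"no planted locus can host a {length} nt {region} fragment")
        tries = 0
        while len(chosen) < fragments_per_cell and tries < 100:
            tries += 1
            m = cands[int(rng.integers(0, len(cands)))]
            if region == "5p":
                fs, fe = 1, length
            elif region == "i":
                fs = int(rng.integers(2, m.L - length + 2))
                fe = fs + length - 1
            else:
                fe = int(rng.choice([m.L + 1, m.L + 2, m.L + 3]))
                fs = fe - length + 1
                if fs < 2:
                    continue
            seq = m.seq[fs - 1: fe]
            if any(seq == c[0] for c in chosen):
                continue
            chosen.append((seq, m.locus.id, fs, fe))
        pool[(region, length)] = chosen
    return pool


def generate_reads(
    universe: SyntheticUniverse,
    profile_spec: Mapping[str, Mapping[int, float]]
    | Mapping[str, Mapping[str, Mapping[int, float]]]
    | None = None,
    n_datasets: int | Mapping[str, int] = 3,
    reads_per_dataset: int = 2_000,
    seed: int = 0,
    noise: Mapping[str, float] | None = None,
    fragments_per_cell: int = 2,
) -> list[ReadSet]:
    """Draw per-dataset read sets from region/length abundance laws.

    ``profile_spec`` is either one law (region -> {length: mass}, masses
    summing to 1) or a mapping of group name -> law; ``n_datasets`` is then an
    int per group or a mapping.  ``noise`` assigns read-mass fractions to
    ``random`` (random sequences), ``mismatch`` (planted fragments with one
    substitution) and ``decoy`` (partial-decoy sequences); noise reads are
    guaranteed not to match any exclusive fragment.  Planted and noise counts
    are recorded in the universe's manifest.
    """
    ss = np.random.SeedSequence(seed)
    rng_pool, rng_draw = [np.random.default_rng(s) for s in ss.spawn(2)]
    noise = dict(noise or {})
    noise_frac = sum(noise.values())
    if not (0 <= noise_frac <= 1):
        raise ValueError("noise fractions must sum to within [0, 1]")

    if profile_spec is None:
        profile_spec = DEFAULT_PROFILE
    first = next(iter(profile_spec.values()))
    grouped = isinstance(first, Mapping) and first and isinstance(
        next(iter(first.values())), Mapping
    )
    specs: dict[str, Mapping[str, Mapping[int, float]]]
    if grouped:
        specs = {str(g): s for g, s in profile_spec.items()}
    else:
        specs = {"all": profile_spec}  # type: ignore[dict-item]
    for s in specs.values():
        _validate_spec(s)
    if isinstance(n_datasets, Mapping):
        n_per_group = {str(g): int(n) for g, n in n_datasets.items()}
    else:
        n_per_group = {g: int(n_datasets) for g in specs}
    if set(n_per_group) != set(specs):
        raise ValueError("group names of profile_spec and n_datasets differ")

    cells = {(r, ln) for s in specs.values() for r, lens in s.items() for ln in lens}
    pool = _fragment_pool(universe, cells, rng_pool, fragments_per_cell)

    # flat fragment list + per-group probability vectors
    frags: list[tuple[str, str, int, int]] = []
    index: dict[tuple[str, int], list[int]] = {}
    for cell, members in sorted(pool.items()):
        index[cell] = []
        for fr in members:
            index[cell].append(len(frags))
            frags.append(fr)
    probs: dict[str, np.ndarray] = {}
    for g, s in specs.items():
        p = np.zeros(len(frags))
        for region, lens in s.items():
            for ln, mass in lens.items():
                ids = index[(region, ln)]
                for i in ids:
                    p[i] += mass / len(ids)
        probs[g] = p / p.sum()

    matures = universe.matures()
    partial_decoys = [d for d in universe.manifest.decoys if d["type"] == "partial"]

    def noise_seq(kind: str) -> str:
        for _ in range(100):
            if kind == "random":
                cand = _random_seq(rng_draw, 22, 0.5)
            elif kind == "mismatch":
                base = frags[int(rng_draw.integers(0, len(frags)))][0]
                pos = int(rng_draw.integers(0, len(base)))
                alt = str(rng_draw.choice([b for b in "ACGT" if b != base[pos]]))
                cand = base[:pos] + alt + base[pos + 1:]
            elif kind == "decoy":
                if not partial_decoys:
                    raise ValueError("decoy noise requested but no partial decoys planted")
                cand = partial_decoys[int(rng_draw.integers(0, len(partial_decoys)))]["seq"]
                return cand  # by construction non-exclusive
            else:
                raise ValueError(f"unknown noise kind {kind!r}")
            if not any(cand in m.seq for m in matures):
                return cand
        raise RuntimeError(f"could not generate a clean {kind!r} noise sequence")

    readsets: list[ReadSet] = []
    idx = 0
    for g in sorted(specs):
        for _ in range(n_per_group[g]):
            ds_id = f"d{idx:02d}" + (f"_{g}" if grouped else "")
            idx += 1
            n_noise = int(round(reads_per_dataset * noise_frac))
            n_plant = reads_per_dataset - n_noise
            counts = rng_draw.multinomial(n_plant, probs[g])
            planted = {frags[i][0]: int(c) for i, c in enumerate(counts) if c > 0}
            noise_counts: dict[str, int] = {}
            if n_noise:
                kinds = list(noise)
                kp = np.array([noise[k] for k in kinds]) / noise_frac
                per_kind = rng_draw.multinomial(n_noise, kp)
                for kind, kc in zip(kinds, per_kind):
                    for _ in range(int(kc)):
                        s = noise_seq(kind)
                        noise_counts[s] = noise_counts.get(s, 0) + 1
            pairs = list(planted.items()) + list(noise_counts.items())
            rs = ReadSet.from_pairs(ds_id, pairs, metadata={"group": g})
            readsets.append(rs)
            universe.manifest.datasets[ds_id] = {
                "group": g, "planted": planted, "noise": noise_counts,
            }
    return readsets


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    """Expand a collapsed read set into a plain FASTQ (constant quality)."""
    with open(path, "w") as fh:
        i = 0
        for seq in sorted(readset.counts):
            for _ in range(readset.counts[seq]):
                fh.write(f"@{readset.dataset_id}.{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1
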