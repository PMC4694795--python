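"""Expression matrices: assembly, support filtering, three normalizations.

Rows are fragment labels, columns dataset ids.  The pipeline order mirrors
common small-RNA practice: filter on raw counts (a fragment must reach a
minimum read count in a minimum number of datasets), then depth-normalize to
RPM, optionally rescale per sequencing laboratory using samples shared by all
laboratories, and finally (for cross-study comparison) rank-normalize each
dataset with average ranks on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiler import Profile

log = logging.getLogger(__name__)

#: (min_reads, min_datasets) support presets for cohort filtering.
PRESETS: dict[str, tuple[int, int]] = {"lcl": (30, 30), "brca": (30, 20), "clip": (30, 3)}


@dataclass
class ExpressionMatrix:
    """Fragments x datasets abundance table with column metadata.

    ``col_meta`` is indexed by dataset id and may carry ``lab``, ``group`` and
    ``depth`` columns.  ``norm`` tags the normalization state
    (``raw``, ``rpm``, ``rpm+lab``, ``rank`` ...).
    """

    data: pd.DataFrame
    col_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    norm: str = "raw"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate fragment labels in matrix rows")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate dataset ids in matrix columns")
        if self.col_meta.empty:
            self.col_meta = pd.DataFrame(index=self.data.columns)

    @property
    def n_fragments(self) -> int:
        return self.data.shape[0]

    @property
    def n_datasets(self) -> int:
        return self.data.shape[1]

    def groups(self, key: str = "group") -> dict[str, list[str]]:
        if key not in self.col_meta.columns:
            return {}
        out: dict[str, list[str]] = {}
        for ds, g in self.col_meta[key].items():
            out.setdefault(str(g), []).append(ds)
        return out

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# norm={self.norm}\n")
            self.data.to_csv(fh, sep="\t", index_label="label")

    @classmethod
    def from_tsv(cls, path: str | Path, meta_path: str | Path | None = None) -> "ExpressionMatrix":
        norm = "raw"
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "norm=" in line:
                    norm = line.split("norm=", 1)[1].strip()
        df = pd.read_csv(path, sep="\t", comment="#", index_col="label")
        meta = pd.DataFrame(index=df.columns)
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0, dtype=str)
            meta = meta.reindex(df.columns)
            if "depth" in meta.columns:
                meta["depth"] = meta["depth"].astype(float)
        return cls(df, meta, norm)


def from_profiles(
    profiles: Sequence[Profile], metadata: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Assemble raw profiles into one matrix (union of labels, zeros filled).

    Sequencing depth is taken from each profile's ``total_input`` tally and
    stored in the column metadata together with any per-profile metadata.
    """
    ids = [p.dataset_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset ids among profiles")
    data = (
        pd.DataFrame({p.dataset_id: pd.Series(p.counts, dtype=float) for p in profiles})
        .fillna(0.0)
        .sort_index()
    )
    meta_rows = {}
    for p in profiles:
        row = dict(p.metadata)
        row["depth"] = float(p.tallies.get("total_input", 0)) or np.nan
        meta_rows[p.dataset_id] = row
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(data.columns)
    if metadata is not None:
        meta = meta.combine_first(metadata.reindex(data.columns))
    return ExpressionMatrix(data, meta, "raw")


def filter_matrix(
    m: ExpressionMatrix, min_reads: int = 30, min_datasets: int | None = None,
    preset: str | None = None,
) -> ExpressionMatrix:
    """Keep fragments with >= min_reads raw reads in >= min_datasets datasets.

    ``preset`` selects the cohort thresholds (``lcl``: 30/30, ``brca``: 30/20,
    ``clip``: 30/3).  The column set is unchanged.
    """
    if preset is not None:
        min_reads, min_datasets = PRESETS[preset]
    if min_datasets is None:
        raise ValueError("min_datasets (or a preset) is required")
    if min_datasets > m.n_datasets:
        raise ValueError(
            f"min_datasets={min_datasets} exceeds the {m.n_datasets} available datasets"
        )
    keep = (m.data >= min_reads).sum(axis=1) >= min_datasets
    return replace(m, data=m.data.loc[keep].copy())


def depth_normalize(
    m: ExpressionMatrix, depths: Mapping[str, float] | pd.Series | None = None,
    scale: float = 1e6,
) -> ExpressionMatrix:
    """Reads-per-``scale`` normalization by per-dataset sequencing depth."""
    if depths is None:
        if "depth" not in m.col_meta.columns:
            raise ValueError("no depths supplied and no 'depth' column in metadata")
        depths = m.col_meta["depth"]
    depths = pd.Series(depths, dtype=float).reindex(m.data.columns)
    if depths.isna().any() or (depths <= 0).any():
        bad = list(depths.index[depths.isna() | (depths <= 0)])
        raise ValueError(f"missing or non-positive depth for datasets {bad}")
    return replace(m, data=m.data * scale / depths, norm="rpm")


def lab_rescale(
    m: ExpressionMatrix,
    lab_of: Mapping[str, str] | pd.Series | None = None,
    shared: Sequence[str] | None = None,
    ref_lab: str | None = None,
) -> ExpressionMatrix:
    """Cross-laboratory rescaling anchored on samples sequenced in every lab.

    For each laboratory X and fragment f the factor is
    ``mean_f(shared samples of the reference lab) / mean_f(shared samples of
    X)``; every dataset of X is multiplied row-wise by that factor.  The
    reference laboratory defaults to the one with the most datasets.
    Undefined or zero-mean factors fall back to 1 with a warning.  Intended to
    run on depth-normalized values.
    """
    if lab_of is None:
        if "lab" not in m.col_meta.columns:
            raise ValueError("no lab assignment supplied and no 'lab' metadata column")
        lab_of = m.col_meta["lab"]
    lab_of = pd.Series(lab_of).reindex(m.data.columns)
    if lab_of.isna().any():
        raise ValueError(f"datasets without lab assignment: {list(lab_of.index[lab_of.isna()])}")
    labs = sorted(lab_of.unique())
    if shared is None:
        if "shared" in m.col_meta.columns:
            flags = m.col_meta["shared"].astype(str).str.lower().isin({"1", "true", "yes"})
            shared = list(m.col_meta.index[flags])
        else:
            raise ValueError("the shared-sample list is required")
    shared = list(shared)
    if not shared:
        raise ValueError("shared sample list is empty")
    if ref_lab is None:
        ref_lab = lab_of.value_counts().idxmax()
    if ref_lab not in labs:
        raise ValueError(f"reference lab {ref_lab!r} not among labs {labs}")

    # mean expression over shared samples, per lab; shared samples are
    # identified by a sample name column when datasets are lab-specific runs
    sample_of = (
        m.col_meta["sample"]
        if "sample" in m.col_meta.columns
        else pd.Series(m.data.columns, index=m.data.columns)
    )
    means: dict[str, pd.Series] = {}
    for lab in labs:
        cols = [c for c in m.data.columns if lab_of[c] == lab and sample_of[c] in shared]
        if not cols:
            raise ValueError(f"lab {lab!r} has no datasets among the shared samples")
        means[lab] = m.data[cols].mean(axis=1)
    out = m.data.copy()
    for lab in labs:
        if lab == ref_lab:
            continue
        denom = means[lab]
        factor = means[ref_lab] / denom
        undefined = ~np.isfinite(factor)
        if undefined.any():
            log.warning(
                "lab %s: %d fragments with zero/undefined shared-sample mean; factor set to 1",
                lab, int(undefined.sum()),
            )
            factor = factor.where(~undefined, 1.0)
        cols = [c for c in m.data.columns if lab_of[c] == lab]
        out[cols] = out[cols].mul(factor, axis=0)
    return replace(m, data=out, norm=m.norm + "+lab")


def rank_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each dataset's values by ascending ranks (average ranks on ties).

    Column sums equal n(n+1)/2 for n fragments.  Downstream correlation or
    ordination is invariant to the ascending/descending choice up to sign.
    """
    return replace(m, data=m.data.rank(axis=0, method="average"), norm="rank")
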