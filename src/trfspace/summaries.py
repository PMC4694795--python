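"""Cohort summaries: length distributions, origin decompositions, correlations,
nonparametric group comparisons.

Length distributions are computed per dataset as relative abundance per
fragment length (16..50 nt by default) within a region (``5p``, ``i``, ``3p``
or ``all``), then aggregated per group as mean +/- standard error across
datasets.  By default fractions are taken over the union of all regions, so
the three per-region panels of a figure sum to the combined panel; a
``normalize="region"`` flag switches to within-region fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import LookupTable, parse_label
from .matrix import ExpressionMatrix
from .regions import REGION_ORDER, REGIONS

log = logging.getLogger(__name__)

DEFAULT_LENGTHS = range(16, 51)


def _annotation(ann) -> pd.DataFrame:
    """Accept a LookupTable or a prebuilt per-label annotation DataFrame."""
    if isinstance(ann, LookupTable):
        return ann.annotation_frame()
    return ann


def _label_fallback_annotation(labels: Sequence[str]) -> pd.DataFrame:
    """Region/length/anticodon/start recovered from the labels themselves."""
    rows = []
    for lab in labels:
        p = parse_label(lab)
        rows.append(
            {"label": lab, "region": p.region, "length": p.length,
             "anticodon": p.anticodon_name, "frag_start": p.frag_start,
             "origin": "nuclear"}
        )
    return pd.DataFrame(rows).set_index("label")


@dataclass
class LengthDistribution:
    """Relative abundance per fragment length, with per-group mean and SE."""

    region: str
    fractions: pd.DataFrame   # lengths x datasets, relative abundances
    abundance: pd.DataFrame   # lengths x datasets, absolute (normalized) abundance
    group_stats: pd.DataFrame  # columns: group, length, mean, se, n

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out = self.group_stats.copy()
            out.insert(0, "region", self.region)
            out.to_csv(fh, sep="\t", index=False)


@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney U comparison of two dataset groups."""

    u: float
    p_value: float
    n1: int
    n2: int

    def __post_init__(self):
        if not (0 <= self.u <= self.n1 * self.n2):
            raise ValueError(f"U={self.u} outside [0, {self.n1 * self.n2}]")


def _group_map(m: ExpressionMatrix, groups) -> dict[str, list[str]]:
    if groups is None:
        g = m.groups()
        return g if g else {"all": list(m.data.columns)}
    if isinstance(groups, Mapping):
        return {str(k): list(v) for k, v in groups.items()}
    raise TypeError("groups must be a mapping group -> dataset ids, or None")


def length_distribution(
    m: ExpressionMatrix,
    ann,
    region: str = "all",
    groups: Mapping[str, Sequence[str]] | None = None,
    normalize: str = "union",
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> LengthDistribution:
    """Per-dataset length histogram of (normalized) fragment abundance.

    ``ann`` supplies region and length per fragment label (a LookupTable or an
    annotation frame).  ``normalize="union"`` divides by each dataset's total
    over all regions; ``"region"`` divides by the within-region total.
    """
    if region not in set(REGIONS) | {"all"}:
        raise ValueError(f"unknown region {region!r}")
    ann = _annotation(ann)
    ann = ann.reindex(m.data.index)
    if ann["region"].isna().any():
        missing = list(m.data.index[ann["region"].isna()])[:3]
        raise ValueError(f"labels missing from annotation, e.g. {missing}")
    in_region = ann["region"] == region if region != "all" else pd.Series(True, index=m.data.index)
    if region != "all" and not in_region.any():
        warnings.warn(f"no fragments in region {region!r}; empty distribution")
    lengths = list(lengths)
    sub = m.data.loc[in_region]
    by_len = sub.groupby(ann.loc[in_region, "length"]).sum().reindex(lengths).fillna(0.0)
    denom = m.data.sum(axis=0) if normalize == "union" else sub.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = by_len.div(denom.replace(0, np.nan), axis=1).fillna(0.0)

    rows = []
    for gname, cols in _group_map(m, groups).items():
        sel = fractions[list(cols)]
        n = sel.shape[1]
        mean = sel.mean(axis=1)
        se = sel.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=sel.index)
        for ln in lengths:
            rows.append({"group": gname, "length": ln, "mean": mean[ln],
                         "se": float(se[ln]) if n > 1 else 0.0, "n": n})
    return LengthDistribution(region, fractions, by_len, pd.DataFrame(rows))


def decompose_by_origin(
    m: ExpressionMatrix,
    ann,
    region: str = "all",
    groups: Mapping[str, Sequence[str]] | None = None,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    lookalike_as: str = "mitochondrial",
) -> dict[str, LengthDistribution]:
    """Split a length distribution into nuclear and mitochondrial contributions.

    The origin of each fragment is that of its source-proxy locus; exact
    nuclear lookalikes of mitochondrial tRNAs are grouped with the
    mitochondrial contribution by default (``lookalike_as``).  Per-length
    absolute contributions of the two panels sum to the combined panel, and so
    do the union-normalized fractions.
    """
    ann = _annotation(ann).reindex(m.data.index)
    origin = ann["origin"].replace({"lookalike": lookalike_as})
    out: dict[str, LengthDistribution] = {}
    denom_total = m.data.sum(axis=0)
    for o in ("nuclear", "mitochondrial"):
        sel = origin == o
        sub_m = ExpressionMatrix(m.data.loc[sel].copy(), m.col_meta.copy(), m.norm)
        sub_ann = ann.loc[sel]
        if sel.any():
            ld = length_distribution(sub_m, sub_ann, region=region, groups=groups,
                                     normalize="union", lengths=lengths)
            # re-express fractions against the *combined* totals so panels add up
            with np.errstate(invalid="ignore", divide="ignore"):
                fr = ld.abundance.div(denom_total.replace(0, np.nan), axis=1).fillna(0.0)
            rows = []
            for gname, cols in _group_map(m, groups).items():
                selc = fr[list(cols)]
                n = selc.shape[1]
                mean = selc.mean(axis=1)
                se = selc.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=selc.index)
                for ln in lengths:
                    rows.append({"group": gname, "length": ln, "mean": mean[ln],
                                 "se": float(se[ln]) if n > 1 else 0.0, "n": n})
            out[o] = LengthDistribution(region, fr, ld.abundance, pd.DataFrame(rows))
        else:
            empty = pd.DataFrame(0.0, index=list(lengths), columns=m.data.columns)
            out[o] = LengthDistribution(region, empty, empty.copy(), pd.DataFrame(
                columns=["group", "length", "mean", "se", "n"]))
    return out


def anticodon_correlation(m: ExpressionMatrix, ann, anticodon_name: str) -> pd.DataFrame:
    """Pearson correlation matrix over one anticodon's fragments.

    Rows/columns are fragment labels ordered by (region, start, length);
    zero-variance fragments yield NaN correlations (undefined markers), with
    the diagonal fixed at 1.
    """
    ann = _annotation(ann).reindex(m.data.index)
    sel = ann["anticodon"] == anticodon_name
    if int(sel.sum()) < 2:
        raise ValueError(f"need >= 2 fragments for anticodon {anticodon_name!r}, "
                         f"found {int(sel.sum())}")
    if m.n_datasets < 3:
        raise ValueError("need >= 3 datasets for a correlation matrix")
    sub_ann = ann.loc[sel].copy()
    sub_ann["_r"] = sub_ann["region"].map(REGION_ORDER)
    order = sub_ann.sort_values(["_r", "frag_start", "length"]).index
    corr = m.data.loc[order].T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_threshold: int = 8,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test with tie correction.

    Uses the exact null distribution when ``min(n1, n2) <= exact_threshold``
    and the data are tie-free, and the tie-corrected normal approximation with
    continuity correction otherwise.  The reported U is for the first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied across both groups; p set to 1")
        return GroupComparison(u=a.size * b.size / 2, p_value=1.0, n1=a.size, n2=b.size)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= exact_threshold and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(u=float(res.statistic), p_value=float(res.pvalue),
                           n1=a.size, n2=b.size)


def per_length_group_tests(
    dist: LengthDistribution,
    groups: Mapping[str, Sequence[str]],
    lengths: Sequence[int] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Mann-Whitney tests per length between two groups of datasets.

    Raw two-sided p-values are reported (Benjamini-Hochberg adjustment is
    available but off by default).
    """
    names = list(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups are required")
    lengths = list(lengths) if lengths is not None else list(dist.fractions.index)
    rows = []
    for ln in lengths:
        va = dist.fractions.loc[ln, list(groups[names[0]])].to_numpy()
        vb = dist.fractions.loc[ln, list(groups[names[1]])].to_numpy()
        if np.unique(np.concatenate([va, vb])).size == 1:
            cmp = GroupComparison(u=va.size * vb.size / 2, p_value=1.0, n1=va.size, n2=vb.size)
        else:
            cmp = compare_groups(va, vb)
        rows.append({"group1": names[0], "group2": names[1], "region": dist.region,
                     "length": ln, "U": cmp.u, "p": cmp.p_value})
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def start_length_table(
    m: ExpressionMatrix, ann, region: str = "i"
) -> pd.DataFrame:
    """Mean abundance by (start position, length) for one region.

    The tidy table underlying start-position/length surface renderings.
    """
    ann = _annotation(ann).reindex(m.data.index)
    sel = ann["region"] == region
    sub = m.data.loc[sel]
    key = ann.loc[sel, ["frag_start", "length"]]
    mean = sub.mean(axis=1)
    out = (
        pd.DataFrame({"frag_start": key["frag_start"], "length": key["length"],
                      "mean_abundance": mean})
        .groupby(["frag_start", "length"], as_index=False)["mean_abundance"].sum()
        .sort_values(["frag_start", "length"], ignore_index=True)
    )
    return out
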