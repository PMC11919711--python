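"""Statistics for pooled CRISPRi fitness screens.

The central quantity is the fitness score

    gamma = log2( (RPM_final / negctrl_median_RPM_final)
                / (RPM_initial / negctrl_median_RPM_initial) ) / total_doublings

interpreted as the fractional defect in cell fitness per population
doubling; negative-control constructs have median gamma = 0 in every
replicate by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "rpm",
    "filter_low_coverage",
    "fitness_score",
    "call_hits",
    "metagene_profile",
    "aggregate_top_contexts",
    "position_recall",
    "assign_gene_tss",
    "top_k_per_tss",
    "CategoryKey",
    "categorize_construct",
    "category_summary",
    "moi_from_fraction",
    "knockdown_metrics",
]


def rpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Reads per million mapped, per sample (column)."""
    totals = counts.sum(axis=0) if isinstance(counts, pd.DataFrame) else counts.sum()
    if np.any(np.asarray(totals) == 0):
        raise ValueError("sample with zero total reads")
    return counts / totals * 1e6


def filter_low_coverage(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    rpm_threshold: float = 1.0,
    timepoint: str = "T0",
    rule: str = "either_replicate",
) -> pd.Index:
    """Constructs with adequate initial read coverage.

    Under the default ``either_replicate`` rule a construct is removed
    iff its RPM (computed before pseudocounting) falls below the
    threshold in any replicate at the initial timepoint.
    """
    t0_samples = sample_meta.loc[
        sample_meta["timepoint"] == timepoint, "sample"
    ].unique()
    if len(t0_samples) == 0:
        raise ValueError(f"no samples at timepoint {timepoint!r}")
    r = rpm(counts[list(t0_samples)])
    if rule == "either_replicate":
        keep = (r >= rpm_threshold).all(axis=1)
    elif rule == "all_replicates":
        keep = (r >= rpm_threshold).any(axis=1)
    else:
        raise ValueError("rule must be 'either_replicate' or 'all_replicates'")
    return counts.index[keep]


def fitness_score(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    negctrl_ids: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-construct fitness scores, one column per replicate plus mean.

    A pseudocount is added to the raw counts of the (pre-filtered)
    constructs and RPM recomputed; per replicate, gamma is the log2
    ratio of final to initial negative-control-median-normalised RPM,
    divided by that replicate's total doublings.  A shared initial
    sample may be aliased to several replicates via ``sample_meta``.
    """
    negctrl_ids = [c for c in negctrl_ids if c in counts.index]
    if not negctrl_ids:
        raise ValueError("no negative-control constructs present in table")
    pseudo = counts + pseudocount
    r = rpm(pseudo)
    out = pd.DataFrame(index=counts.index)
    reps = sorted(sample_meta["replicate"].unique())
    for rep in reps:
        sub = sample_meta[sample_meta["replicate"] == rep]
        try:
            s0 = sub.loc[sub["timepoint"] == "T0", "sample"].iloc[0]
            sf = sub.loc[sub["timepoint"] == "Tfinal", "sample"].iloc[0]
        except IndexError:
            raise ValueError(
                f"replicate {rep} lacks a T0 or Tfinal sample"
            ) from None
        doublings = float(
            sub.loc[sub["timepoint"] == "Tfinal", "total_doublings"].iloc[0]
        )
        if doublings <= 0:
            raise ValueError("total_doublings must be > 0")
        norm0 = r[s0] / r.loc[negctrl_ids, s0].median()
        normf = r[sf] / r.loc[negctrl_ids, sf].median()
        out[f"gamma_rep{rep}"] = np.log2(normf / norm0) / doublings
    out["gamma_mean"] = out.mean(axis=1)
    return out


def call_hits(
    scores: pd.Series,
    negctrl_scores: Sequence[float],
    percentile: float = 5.0,
    direction: str = "below",
) -> tuple[pd.Series, float]:
    """Flag scores beyond a percentile of the negative-control null.

    The threshold is the linear-interpolation percentile of the
    negative-control scores; hits are strictly beyond it.
    """
    import warnings

    negctrl_scores = np.asarray(list(negctrl_scores), dtype=float)
    if negctrl_scores.size == 0:
        raise ValueError("empty negative-control score set")
    if negctrl_scores.size < 20:
        warnings.warn(
            f"only {negctrl_scores.size} negative-control scores; "
            "percentile threshold will be noisy",
            stacklevel=2,
        )
    if direction == "below":
        threshold = float(np.percentile(negctrl_scores, percentile))
        flags = scores < threshold
    elif direction == "above":
        threshold = float(np.percentile(negctrl_scores, 100 - percentile))
        flags = scores > threshold
    else:
        raise ValueError("direction must be 'below' or 'above'")
    return flags, threshold


def metagene_profile(
    scores: pd.Series,
    pam_positions_rel_tss: pd.Series,
    window_bp: int = 50,
    window: tuple[int, int] = (-50, 300),
    pam_classes: Optional[pd.Series] = None,
    pam_class_filter: Optional[str] = "canonical_TTTV",
) -> pd.DataFrame:
    """Moving-average fitness score by PAM position relative to the TSS.

    At each integer position in ``window`` the profile is the mean of
    scores whose PAM positions lie within +/- window_bp/2; positions
    with no observations yield NaN.
    """
    mask = pam_positions_rel_tss.notna() & scores.notna()
    if pam_classes is not None and pam_class_filter is not None:
        mask &= pam_classes == pam_class_filter
    pos = pam_positions_rel_tss[mask].to_numpy(dtype=float)
    val = scores[mask].to_numpy(dtype=float)
    half = window_bp / 2.0
    grid = np.arange(window[0], window[1] + 1)
    means = np.full(grid.shape, np.nan)
    ns = np.zeros(grid.shape, dtype=int)
    order = np.argsort(pos)
    pos, val = pos[order], val[order]
    lo = np.searchsorted(pos, grid - half, side="left")
    hi = np.searchsorted(pos, grid + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(val)])
    for i in range(len(grid)):
        n = hi[i] - lo[i]
        ns[i] = n
        if n > 0:
            means[i] = (csum[hi[i]] - csum[lo[i]]) / n
    return pd.DataFrame(
        {"position": grid, "mean_score": means, "n": ns}
    ).set_index("position")


def aggregate_top_contexts(
    scores: pd.DataFrame,
    k: int = 3,
) -> pd.DataFrame:
    """Mean of the k strongest (most negative) context scores.

    ``scores`` has columns test_spacer, position, context_set, score
    (replicate-mean gamma per construct).  Returns one row per
    (test_spacer, position) with the aggregated score; groups with
    fewer than k contexts are averaged over all and flagged.
    """
    required = {"test_spacer", "position", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (ts, pos), grp in scores.groupby(["test_spacer", "position"]):
        vals = np.sort(grp["score"].to_numpy(dtype=float))
        if vals.size == 0:
            raise ValueError(f"no contexts for {ts!r} at position {pos}")
        flagged = vals.size < k
        agg = float(vals[: min(k, vals.size)].mean())
        rows.append((ts, pos, agg, flagged))
    return pd.DataFrame(
        rows, columns=["test_spacer", "position", "score", "underpowered"]
    )


def position_recall(
    aggregated: pd.DataFrame,
    negctrl_aggregated: pd.DataFrame,
    active_set: Sequence[str],
    percentile: float = 5.0,
) -> pd.DataFrame:
    """Percent of truly active test spacers recovered at each position.

    A spacer is recovered at a position iff its aggregated score is
    strictly below the given percentile of the negative-control
    aggregated scores at the same position.
    """
    active = set(active_set)
    if not active:
        raise ValueError("active_set is empty")
    rows = []
    for pos, neg_grp in negctrl_aggregated.groupby("position"):
        threshold = float(np.percentile(neg_grp["score"], percentile))
        sub = aggregated[
            (aggregated["position"] == pos)
            & (aggregated["test_spacer"].isin(active))
        ]
        n_active = sub["test_spacer"].nunique()
        n_recovered = int((sub["score"] < threshold).sum())
        recall = 100.0 * n_recovered / len(active)
        rows.append((pos, threshold, n_active, n_recovered, recall))
    return pd.DataFrame(
        rows,
        columns=["position", "threshold", "n_active", "n_recovered", "recall_pct"],
    )


def assign_gene_tss(scores: pd.DataFrame) -> pd.Series:
    """Assign each gene the TSS of its strongest (most negative) crRNA.

    ``scores`` has columns gene, tss, score.  Ties are broken by the
    lexicographically smallest TSS id.
    """
    out = {}
    for gene, grp in scores.groupby("gene"):
        best = grp["score"].min()
        tss = sorted(grp.loc[grp["score"] == best, "tss"])[0]
        out[gene] = tss
    return pd.Series(out, name="tss")


def top_k_per_tss(scores: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Mean of the k most-negative crRNA scores per TSS.

    TSSs with fewer than k crRNAs are averaged over all and flagged.
    """
    rows = []
    for tss, grp in scores.groupby("tss"):
        vals = np.sort(grp["score"].to_numpy(dtype=float))
        flagged = vals.size < k
        rows.append((tss, float(vals[: min(k, vals.size)].mean()), flagged))
    return pd.DataFrame(rows, columns=["tss", "score", "underpowered"])


class CategoryKey(NamedTuple):
    """Presence bits for the four targeted cis-regulatory elements."""

    promoter: bool
    e1: bool
    e2: bool
    e3: bool

    @property
    def n_elements(self) -> int:
        return sum(self)


ELEMENTS = ("promoter", "e1", "e2", "e3")


def categorize_construct(
    spacer_ids: Sequence[str],
    element_map: Mapping[str, str],
) -> CategoryKey:
    """Group-testing category of a construct.

    Bit b(element) is set iff the construct carries at least one spacer
    targeting that element; negative spacers set no bit.  16 categories
    are possible for four elements.
    """
    present = set()
    for sid in spacer_ids:
        if sid not in element_map:
            raise KeyError(f"spacer {sid!r} missing from element map")
        el = element_map[sid]
        if el in ELEMENTS:
            present.add(el)
        elif el != "negative":
            raise ValueError(f"unknown element {el!r} for spacer {sid!r}")
    return CategoryKey(*(e in present for e in ELEMENTS))


def category_summary(
    scores: pd.Series,
    keys: Mapping[str, CategoryKey],
) -> pd.DataFrame:
    """Distribution summary (median, IQR, n) of scores per category.

    All 16 categories are reported; empty ones carry n = 0 and NaN
    summaries.
    """
    groups: dict[CategoryKey, list[float]] = {}
    for cid, key in keys.items():
        if cid in scores.index:
            groups.setdefault(key, []).append(float(scores[cid]))
    rows = []
    for bits in range(16):
        key = CategoryKey(*(bool(bits >> i & 1) for i in range(4)))
        vals = np.array(groups.get(key, []), dtype=float)
        if vals.size:
            median = float(np.median(vals))
            iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))
        else:
            median = iqr = float("nan")
        rows.append(
            (*key, key.n_elements, vals.size, median, iqr)
        )
    return pd.DataFrame(
        rows,
        columns=["promoter", "e1", "e2", "e3", "n_elements", "n", "median", "iqr"],
    )


def moi_from_fraction(fraction_transduced: float) -> float:
    """Multiplicity of infection from the transduced-cell fraction.

    Under Poisson infection statistics, MOI = -ln(1 - f).
    """
    if not 0.0 <= fraction_transduced < 1.0:
        raise ValueError("fraction transduced must be in [0, 1)")
    return -math.log1p(-fraction_transduced)


def knockdown_metrics(
    target_cells: np.ndarray,
    ntc_cells: np.ndarray,
) -> dict[str, float]:
    """Flow-cytometry knockdown summary against a non-targeting control.

    Returns median knockdown percent, 100*(1 - median(target)/median(ntc)),
    and the percent of target cells strictly below the 5th percentile of
    the control population.
    """
    target = np.asarray(target_cells, dtype=float)
    ntc = np.asarray(ntc_cells, dtype=float)
    if target.size == 0 or ntc.size == 0:
        raise ValueError("expression vectors must be non-empty")
    ntc_median = float(np.median(ntc))
    if ntc_median <= 0:
        raise ValueError("non-targeting control median must be > 0")
    p5 = float(np.percentile(ntc, 5))
    return {
        "median_knockdown_pct": 100.0 * (1.0 - float(np.median(target)) / ntc_median),
        "pct_below_ntc_5th": 100.0 * float(np.mean(target < p5)),
    }
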