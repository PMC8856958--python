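"""Categorical co-expression statistics for marker/reporter cell tables.

Cell tables are pandas DataFrames with (at least) the columns

    cell_id, section_id, region_id, compartment, treated (bool),
    marker ('ChAT' or 'AChE'), marker_level ('strong'|'medium'|'weak'),
    reporter_level ('RU'|'RN'|'RW'|'RM'|'RS')

and region tables with

    region_id, section_id, compartment, treated (bool), construct,
    area_mm2

Marker levels are scored strong=1, medium=2, weak=3 and reporter levels
RU=1 .. RS=5, so an inverse marker/reporter relation (stronger reporter,
weaker marker) yields a positive trend statistic.  Untreated cells carry
reporter level RU by definition; treated cells carry RN..RS.

Core statistic: the asymptotic linear-by-linear association (trend) test
for an ordered r x c contingency table.  With row scores u_i, column
scores v_j and counts n_ij (n total), the score statistic is
T = sum_ij u_i v_j n_ij; standardised under the permutation null it is
Z = r_uv * sqrt(n - 1), where r_uv is the sample correlation of the
(u, v) scores over the n cells.  Z is referred to the standard normal
(two-sided).  This is a 1-df trend test; the (r-1)(c-1) table df is
recorded as metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MARKER_LEVELS",
    "REPORTER_LEVELS",
    "GofResult",
    "TrendTestResult",
    "DensityResult",
    "PenetranceResult",
    "build_category_table",
    "load_category_table",
    "chisq_goodness_of_fit",
    "linear_by_linear_test",
    "pearson_trend",
    "compare_densities",
    "exact_rank_sum_p",
    "penetrance",
]

MARKER_LEVELS = {"strong": 1, "medium": 2, "weak": 3}
REPORTER_LEVELS = {"RU": 1, "RN": 2, "RW": 3, "RM": 4, "RS": 5}

_MARKER_ORDER = ["strong", "medium", "weak"]
_REPORTER_ORDER = ["RU", "RN", "RW", "RM", "RS"]


def build_category_table(
    cells: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    construct: str | None = None,
    marker: str = "ChAT",
    include_untreated: bool = True,
) -> pd.DataFrame:
    """Marker-level x reporter-level count table for one construct.

    Selects treated cells lying in regions annotated with ``construct``
    (all treated cells if no construct/region table given) plus, when
    ``include_untreated``, the surrounding untreated cells (the RU
    column).  Rows are strong/medium/weak, columns RU..RS (RU dropped if
    untreated cells are excluded).  The table sum equals the number of
    selected cells.
    """
    sel = cells[cells["marker"] == marker]
    treated = sel[sel["treated"]]
    if construct is not None:
        if regions is None:
            raise ValueError("selecting by construct requires a region table")
        region_ids = set(regions.loc[regions["construct"] == construct, "region_id"])
        treated = treated[treated["region_id"].isin(region_ids)]
    frames = [treated]
    if include_untreated:
        frames.append(sel[~sel["treated"]])
    chosen = pd.concat(frames)
    if chosen.empty:
        raise ValueError(
            f"no cells selected (marker={marker!r}, construct={construct!r})"
        )
    cols = _REPORTER_ORDER if include_untreated else _REPORTER_ORDER[1:]
    table = pd.crosstab(chosen["marker_level"], chosen["reporter_level"])
    table = table.reindex(index=_MARKER_ORDER, columns=cols, fill_value=0).fillna(0)
    return table.astype(int)


def load_category_table(path) -> pd.DataFrame:
    """Read a marker x reporter count table from CSV (levels as row index
    and column headers), e.g. a transcription of published raw counts."""
    table = pd.read_csv(path, index_col=0)
    cols = [c for c in _REPORTER_ORDER if c in table.columns]
    return table.reindex(index=_MARKER_ORDER, columns=cols).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# goodness of fit vs untreated reference ratios

@dataclass
class GofResult:
    x2: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    reference_ratios: np.ndarray


def chisq_goodness_of_fit(observed, reference_ratios) -> GofResult:
    """Chi-square test of treated category counts against the untreated
    category ratio (df = categories - 1, asymptotic upper-tail p).

    Reference ratios not summing to 1 are renormalised with a warning; a
    zero reference ratio with a positive observed count is undefined.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference_ratios, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("observed and reference_ratios must have equal length")
    total = ref.sum()
    if not np.isclose(total, 1.0):
        warnings.warn(f"reference ratios sum to {total:.6g}; renormalising")
        ref = ref / total
    if np.any((ref == 0) & (obs > 0)):
        raise ValueError("zero reference ratio with positive observed count")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts sum to zero")
    keep = ref > 0
    expected = n * ref
    x2, p = stats.chisquare(obs[keep], f_exp=expected[keep])
    df = int(keep.sum()) - 1
    # scipy uses df = k-1 over the kept cells, which is what we report
    return GofResult(float(x2), df, float(p), obs, expected, ref)


# ---------------------------------------------------------------------------
# linear-by-linear association

@dataclass
class TrendTestResult:
    T: float
    Z: float
    p: float
    r: float
    u: np.ndarray
    v: np.ndarray
    n: int
    df_table: int  # (rows-1)(cols-1), metadata only; the test itself is 1-df

    @property
    def chi2_1df(self) -> float:
        """The equivalent 1-df chi-square statistic, Z**2."""
        return self.Z**2


def linear_by_linear_test(
    table: pd.DataFrame | np.ndarray,
    u=None,
    v=None,
) -> TrendTestResult:
    """Asymptotic linear-by-linear association test on an ordered table.

    Default scores are equally spaced integers 1..r and 1..c.  Z is
    invariant to affine rescaling of either score vector.  Degenerate
    margins (a single nonzero row or column) leave the score correlation
    undefined and raise ``ValueError``.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    r_, c_ = counts.shape
    u = np.arange(1, r_ + 1, dtype=float) if u is None else np.asarray(u, dtype=float)
    v = np.arange(1, c_ + 1, dtype=float) if v is None else np.asarray(v, dtype=float)
    if u.shape != (r_,) or v.shape != (c_,):
        raise ValueError("score vectors must match table dimensions")
    n = counts.sum()
    if n <= 1:
        raise ValueError("need n > 1 cells")
    row_margin = counts.sum(axis=1)
    col_margin = counts.sum(axis=0)
    if (row_margin > 0).sum() < 2 or (col_margin > 0).sum() < 2:
        raise ValueError("degenerate margins: correlation of scores undefined")

    T = float(np.einsum("i,j,ij->", u, v, counts))
    ubar = (u * row_margin).sum() / n
    vbar = (v * col_margin).sum() / n
    su2 = ((u - ubar) ** 2 * row_margin).sum() / n
    sv2 = ((v - vbar) ** 2 * col_margin).sum() / n
    cov = float(np.einsum("i,j,ij->", u - ubar, v - vbar, counts)) / n
    r = cov / np.sqrt(su2 * sv2)
    Z = r * np.sqrt(n - 1)
    p = float(2 * stats.norm.sf(abs(Z)))
    return TrendTestResult(
        T=T, Z=float(Z), p=min(p, 1.0) if p > 0 else np.nextafter(0, 1), r=float(r),
        u=u, v=v, n=int(n), df_table=(r_ - 1) * (c_ - 1),
    )


def pearson_trend(proportions) -> tuple[float, float]:
    """Pearson correlation of an ordered proportion profile against its
    rank 1..k (two-sided p on k points).

    Used for strong/weak marker ratios ordered RU..RS.  Constant
    proportions leave the correlation undefined.
    """
    y = np.asarray(proportions, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 ordered points")
    if np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    x = np.arange(1, y.size + 1, dtype=float)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# densities and penetrance

@dataclass
class DensityResult:
    densities: pd.DataFrame  # region_id, treated, n_cells, area_mm2, density
    W: float                 # rank-sum (Mann-Whitney U of the treated group)
    p: float
    method: str              # 'exact' | 'asymptotic'


def exact_rank_sum_p(x, y) -> tuple[float, float]:
    """Two-sided exact Wilcoxon-Mann-Whitney p by full enumeration.

    Enumerates every assignment of the pooled values into the two groups
    (C(n1+n2, n1) splits), computes the U distribution, and returns
    ``(U_obs, p)`` with ``p = min(1, 2*min(P(U<=u), P(U>=u)))``.  Handles
    ties naturally; intended for small groups (<= 8 per group).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum())
    us = np.asarray(us) - n1 * (n1 + 1) / 2
    total = comb(len(pooled), n1)
    p_low = (us <= u_obs + 1e-9).sum() / total
    p_high = (us >= u_obs - 1e-9).sum() / total
    return u_obs, min(1.0, 2 * min(p_low, p_high))


def compare_densities(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    construct: str | None = None,
    marker: str = "ChAT",
) -> DensityResult:
    """Per-region marker-positive cell density (cells/mm^2), treated vs
    untreated, compared with a Wilcoxon-Mann-Whitney test.

    Treated regions are those annotated with ``construct`` (all treated
    regions when None); the comparison uses exact enumeration when both
    groups have <= 8 regions, otherwise the tie-corrected normal
    approximation (no continuity correction).
    """
    regs = regions.copy()
    if construct is not None:
        regs = regs[(~regs["treated"]) | (regs["construct"] == construct)]
    if (regs["area_mm2"] <= 0).any():
        raise ValueError("region areas must be positive")
    counts = (
        cells[cells["marker"] == marker]
        .groupby("region_id")
        .size()
        .reindex(regs["region_id"], fill_value=0)
        .to_numpy()
    )
    dens = regs[["region_id", "treated", "area_mm2"]].copy()
    dens["n_cells"] = counts
    dens["density"] = dens["n_cells"] / dens["area_mm2"]
    treated = dens.loc[dens["treated"], "density"].to_numpy()
    untreated = dens.loc[~dens["treated"], "density"].to_numpy()
    if len(treated) == 0 or len(untreated) == 0:
        raise ValueError("need at least one treated and one untreated region")
    if len(treated) <= 8 and len(untreated) <= 8:
        W, p = exact_rank_sum_p(treated, untreated)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            treated, untreated, alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        W, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return DensityResult(densities=dens, W=W, p=p, method=method)


@dataclass
class PenetranceResult:
    per_region: pd.Series  # region_id -> fraction
    pooled: float


def penetrance(
    cells: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    construct: str | None = None,
    marker: str = "ChAT",
) -> PenetranceResult:
    """Fraction of marker-positive cells in treated regions that also
    express detectable reporter (level >= RW; RN = "reporter not
    detected" counts as negative), per region and pooled."""
    sel = cells[(cells["marker"] == marker) & cells["treated"]]
    if construct is not None:
        if regions is None:
            raise ValueError("selecting by construct requires a region table")
        region_ids = set(regions.loc[regions["construct"] == construct, "region_id"])
        sel = sel[sel["region_id"].isin(region_ids)]
    if sel.empty:
        raise ValueError("no marker-positive treated cells selected")
    codes = sel["reporter_level"].map(REPORTER_LEVELS)
    positive = codes >= REPORTER_LEVELS["RW"]
    per_region = positive.groupby(sel["region_id"]).mean()
    return PenetranceResult(per_region=per_region, pooled=float(positive.mean()))
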