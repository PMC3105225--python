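"""Per-parameter group comparison and phenotype "barcode" classification.

Each (parameter, DIV) cell compares three culture groups — untransfected,
non-targeting control (NTC) and knockdown — by one-way fixed-effects
ANOVA followed by Fisher's protected least-significant-difference (PLSD)
pairwise tests, which are plain two-sided t tests on the ANOVA's pooled
within-group mean square.  The experimental unit is the culture, never
the electrode.

A cell is called an *increase* when the knockdown differs significantly
(p < alpha) from BOTH controls, the two controls do NOT differ
(p >= alpha), and the knockdown mean exceeds both control means;
*decrease* is the mirror image; anything else is *none*.  Stacking the
calls over parameters (rows) and DIV (columns) yields the barcode matrix
for one gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .netparams import PARAMETER_NAMES

__all__ = [
    "GroupData",
    "AnovaResult",
    "PLSDResult",
    "BarcodeEntry",
    "DegenerateDataError",
    "one_way_anova",
    "fishers_plsd",
    "classify_effect",
    "build_barcode",
    "barcode_matrix",
]

logger = logging.getLogger(__name__)

Call = Literal["increase", "decrease", "none"]


class DegenerateDataError(ValueError):
    """The F statistic is undefined (no within-group variability)."""


@dataclass(frozen=True)
class GroupData:
    """Per-condition culture values for one (parameter, DIV) cell.

    ``values`` maps condition name to that condition's per-culture
    parameter values; missing (None/NaN) cultures are dropped with a
    logged count on construction.
    """

    parameter: str
    div: int
    values: dict[str, tuple[float, ...]]

    @classmethod
    def from_lists(cls, parameter: str, div: int,
                   values: Mapping[str, Sequence[float | None]]) -> "GroupData":
        clean: dict[str, tuple[float, ...]] = {}
        for cond, vals in values.items():
            kept = tuple(float(v) for v in vals
                         if v is not None and np.isfinite(v))
            dropped = len(vals) - len(kept)
            if dropped:
                logger.info("dropped %d missing value(s) for %s/%s at DIV %d",
                            dropped, parameter, cond, div)
            clean[cond] = kept
        return cls(parameter, div, clean)

    def testable(self) -> bool:
        return len(self.values) >= 2 and all(len(v) >= 2 for v in self.values.values())


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    mse: float
    group_means: dict[str, float]
    group_ns: dict[str, int]


def one_way_anova(groups: GroupData | Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the classical sum-of-squares
    decomposition, exposing the pooled MSE and degrees of freedom the
    PLSD tests reuse.

    Raises :class:`DegenerateDataError` when every group is internally
    constant (zero within-group sum of squares), where F is undefined.
    """
    data = groups.values if isinstance(groups, GroupData) else groups
    if len(data) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs at least two values")
    ns = {k: a.size for k, a in arrays.items()}
    means = {k: float(a.mean()) for k, a in arrays.items()}
    grand = float(np.concatenate(list(arrays.values())).mean())
    n_total = sum(ns.values())
    k = len(arrays)
    ss_between = sum(n * (means[g] - grand) ** 2 for g, n in ns.items())
    ss_within = sum(float(((a - means[g]) ** 2).sum()) for g, a in arrays.items())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        raise DegenerateDataError(
            "zero within-group variance: F statistic undefined")
    mse = ss_within / df_w
    F = (ss_between / df_b) / mse
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(mse), means, ns)


@dataclass(frozen=True)
class PLSDResult:
    """Pairwise t/p table on the pooled ANOVA error.

    ``omnibus_significant`` records whether the protected interpretation
    (pairwise calls only when the omnibus ANOVA rejects) applies.
    """

    pairwise_t: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]
    group_means: dict[str, float]
    omnibus_significant: bool
    alpha: float

    def t(self, a: str, b: str) -> float:
        return self.pairwise_t[tuple(sorted((a, b)))]

    def p(self, a: str, b: str) -> float:
        return self.pairwise_p[tuple(sorted((a, b)))]


def fishers_plsd(groups: GroupData | Mapping[str, Sequence[float]],
                 anova: AnovaResult, alpha: float = 0.05) -> PLSDResult:
    """Fisher's (protected) LSD: every unordered pair tested with
    t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)) on the ANOVA's
    within-group degrees of freedom, two-sided."""
    data = groups.values if isinstance(groups, GroupData) else groups
    ts: dict[tuple[str, str], float] = {}
    ps: dict[tuple[str, str], float] = {}
    for a, b in combinations(sorted(data), 2):
        se = np.sqrt(anova.mse * (1.0 / anova.group_ns[a] + 1.0 / anova.group_ns[b]))
        t = (anova.group_means[a] - anova.group_means[b]) / se
        ts[(a, b)] = float(t)
        ps[(a, b)] = float(2.0 * sps.t.sf(abs(t), anova.df_within))
    return PLSDResult(ts, ps, dict(anova.group_means),
                      omnibus_significant=anova.p < alpha, alpha=alpha)


def classify_effect(kd_vs_ut_p: float | None, kd_vs_ntc_p: float | None,
                    ut_vs_ntc_p: float | None, kd_mean: float,
                    ut_mean: float, ntc_mean: float,
                    alpha: float = 0.05) -> Call:
    """Barcode decision rule for one cell.

    increase: knockdown significantly different from both controls, the
    controls not different from each other, and the knockdown mean above
    both control means; decrease symmetric below; otherwise none.
    Missing p values give none.
    """
    if kd_vs_ut_p is None or kd_vs_ntc_p is None or ut_vs_ntc_p is None:
        logger.info("missing pairwise p value; call is none")
        return "none"
    kd_differs = kd_vs_ut_p < alpha and kd_vs_ntc_p < alpha
    controls_agree = ut_vs_ntc_p >= alpha
    if kd_differs and controls_agree:
        if kd_mean > ut_mean and kd_mean > ntc_mean:
            return "increase"
        if kd_mean < ut_mean and kd_mean < ntc_mean:
            return "decrease"
    return "none"


@dataclass(frozen=True)
class BarcodeEntry:
    gene: str
    parameter: str
    div: int
    call: Call


def _cell_groups(table: pd.DataFrame, parameter: str, div: int,
                 conditions: Iterable[str]) -> GroupData:
    sub = table[table["div"] == div]
    return GroupData.from_lists(parameter, div, {
        cond: sub.loc[sub["condition"] == cond, parameter].tolist()
        for cond in conditions})


def build_barcode(table: pd.DataFrame, kd_condition: str, *,
                  ut_condition: str = "control", ntc_condition: str = "ntc",
                  parameters: Sequence[str] = PARAMETER_NAMES,
                  divs: Sequence[int] | None = None,
                  alpha: float = 0.05, protected: bool = True,
                  gene: str | None = None) -> list[BarcodeEntry]:
    """Classify every (parameter, DIV) cell of one gene's experiment.

    ``table`` is a long parameter table with columns ``condition``,
    ``culture``, ``div`` and one column per parameter.  Degenerate or
    untestable cells (too few values, zero within-group variance) are
    called none.  With ``protected=True`` (default) pairwise calls are
    interpreted only when the omnibus ANOVA rejects at ``alpha``.
    """
    gene = gene if gene is not None else kd_condition
    if divs is None:
        divs = sorted(table["div"].unique())
    entries = []
    conditions = (ut_condition, ntc_condition, kd_condition)
    for parameter in parameters:
        for div in divs:
            groups = _cell_groups(table, parameter, div, conditions)
            call: Call = "none"
            if groups.testable():
                try:
                    anova = one_way_anova(groups)
                except DegenerateDataError:
                    logger.info("degenerate cell %s @ DIV %d: no test", parameter, div)
                else:
                    plsd = fishers_plsd(groups, anova, alpha)
                    if not protected or plsd.omnibus_significant:
                        call = classify_effect(
                            plsd.p(kd_condition, ut_condition),
                            plsd.p(kd_condition, ntc_condition),
                            plsd.p(ut_condition, ntc_condition),
                            anova.group_means[kd_condition],
                            anova.group_means[ut_condition],
                            anova.group_means[ntc_condition],
                            alpha)
            entries.append(BarcodeEntry(gene, parameter, div, call))
    return entries


def barcode_matrix(entries: Sequence[BarcodeEntry]) -> pd.DataFrame:
    """Barcode entries as a parameter (rows) x DIV (columns) call matrix."""
    df = pd.DataFrame([(e.parameter, e.div, e.call) for e in entries],
                      columns=["parameter", "div", "call"])
    mat = df.pivot(index="parameter", columns="div", values="call")
    order = [p for p in PARAMETER_NAMES if p in mat.index]
    return mat.loc[order]
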