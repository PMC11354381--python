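"""Co-occurrence screening, group comparisons and survival by mutation burden.

Fisher exact tests are two-sided and unadjusted (a Benjamini–Hochberg
column is available on request).  Rank tests switch from the exact to the
mid-rank normal-approximation method above a pooled n of 50.  Survival uses
the Kaplan–Meier product-limit estimator with the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genesets import MR_ICC22
from .types import PatientRecord, VariantCall, VariantClass

ALPHA = 0.05


# ---------------------------------------------------------------- matrices

def build_matrix(
    variants: Sequence[VariantCall],
    min_mutated: int = 1,
    patients: Optional[Sequence[str]] = None,
    collapse_flt3: bool = True,
) -> pd.DataFrame:
    """Boolean patient-by-gene incidence matrix over O/LO variants.

    Genes mutated in fewer than ``min_mutated`` patients are dropped.
    FLT3-ITD and FLT3-TKD collapse to one FLT3 column unless
    ``collapse_flt3`` is False, in which case they become FLT3_ITD /
    FLT3_TKD columns.
    """
    rows = []
    for v in variants:
        if not v.is_olo:
            continue
        gene = v.gene
        if not collapse_flt3 and v.variant_class in (VariantClass.FLT3_ITD, VariantClass.FLT3_TKD):
            gene = v.variant_class.value
        rows.append((v.patient_id, gene))
    index = list(patients) if patients is not None else sorted({p for p, _ in rows})
    genes = sorted({g for _, g in rows})
    mat = pd.DataFrame(False, index=pd.Index(index, name="patient_id"), columns=genes)
    for pid, gene in rows:
        if pid in mat.index:
            mat.loc[pid, gene] = True
    keep = [g for g in genes if int(mat[g].sum()) >= min_mutated]
    return mat[keep]


# ------------------------------------------------------------------ fisher

class Direction(str, Enum):
    CO_OCCURRENCE = "co_occurrence"
    EXCLUSIVITY = "exclusivity"
    NONE = "none"


@dataclass(frozen=True)
class PairResult:
    gene_a: str
    gene_b: str
    n11: int  # both mutated
    n10: int  # a only
    n01: int  # b only
    n00: int  # neither
    odds_ratio: float
    p_two_sided: float
    direction: Direction


def fisher_pair(matrix: pd.DataFrame, a: str, b: str) -> PairResult:
    """Two-sided Fisher exact test on the 2x2 of genes ``a`` and ``b``.

    The odds ratio is the sample (conditional-table) ratio
    ``n11*n00 / (n10*n01)``, infinite on a zero denominator.  Degenerate
    margins (a gene mutated in none or all patients) give p = 1 and
    direction ``none``.
    """
    ca = matrix[a].to_numpy(dtype=bool)
    cb = matrix[b].to_numpy(dtype=bool)
    n11 = int(np.sum(ca & cb))
    n10 = int(np.sum(ca & ~cb))
    n01 = int(np.sum(~ca & cb))
    n00 = int(np.sum(~ca & ~cb))
    n = n11 + n10 + n01 + n00
    degenerate = (n11 + n10) in (0, n) or (n11 + n01) in (0, n)
    if n10 * n01 == 0:
        odds = float("inf") if n11 * n00 > 0 else (0.0 if n11 + n00 == 0 else float("inf"))
    else:
        odds = (n11 * n00) / (n10 * n01)
    if degenerate:
        return PairResult(a, b, n11, n10, n01, n00, odds, 1.0, Direction.NONE)
    _, p = sps.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    p = float(min(p, 1.0))
    if p <= ALPHA and odds > 1:
        direction = Direction.CO_OCCURRENCE
    elif p <= ALPHA and odds < 1:
        direction = Direction.EXCLUSIVITY
    else:
        direction = Direction.NONE
    return PairResult(a, b, n11, n10, n01, n00, odds, p, direction)


def pairwise_screen(matrix: pd.DataFrame, adjust: bool = False) -> List[PairResult]:
    """All unordered gene pairs, sorted by ascending p (unadjusted).

    With ``adjust=True`` the results are returned with Benjamini–Hochberg
    adjusted p-values in place of the raw ones (directions recomputed at
    the same 0.05 threshold).
    """
    results = [fisher_pair(matrix, a, b) for a, b in combinations(matrix.columns, 2)]
    results.sort(key=lambda r: (r.p_two_sided, r.gene_a, r.gene_b))
    if adjust and results:
        m = len(results)
        ps = np.array([r.p_two_sided for r in results])
        adj = np.minimum.accumulate((ps * m / np.arange(m, 0, -1))[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = []
        for r, q in zip(results, adj):
            if q <= ALPHA and r.odds_ratio > 1:
                d = Direction.CO_OCCURRENCE
            elif q <= ALPHA and r.odds_ratio < 1:
                d = Direction.EXCLUSIVITY
            else:
                d = Direction.NONE
            out.append(PairResult(r.gene_a, r.gene_b, r.n11, r.n10, r.n01, r.n00,
                                  r.odds_ratio, float(q), d))
        return out
    return results


# ---------------------------------------------------------- group compares

@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p: float
    group_sizes: Tuple[int, ...]


EXACT_RANKSUM_MAX_N = 50


def group_compare(values: Sequence, grouping: Sequence, categorical: bool = False) -> GroupTestResult:
    """Two groups: Wilcoxon rank-sum; three or more: Kruskal–Wallis;
    categorical values: Fisher exact on the 2x2 contingency."""
    values = list(values)
    grouping = list(grouping)
    if len(values) != len(grouping):
        raise ValueError("values and grouping must have equal length")
    labels = sorted(set(grouping), key=str)
    groups = [[v for v, g in zip(values, grouping) if g == lab] for lab in labels]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("every group must be non-empty and there must be >= 2 groups")
    sizes = tuple(len(g) for g in groups)

    if categorical:
        cats = sorted(set(values), key=str)
        if len(cats) != 2 or len(groups) != 2:
            raise ValueError("categorical comparison supports 2 groups x 2 categories")
        table = [[sum(1 for v in g if v == c) for c in cats] for g in groups]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return GroupTestResult("fisher", float(odds), float(p), sizes)

    if len(groups) == 2:
        x, y = np.asarray(groups[0], float), np.asarray(groups[1], float)
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return GroupTestResult(f"ranksum_{method}", float(res.statistic), float(res.pvalue), sizes)

    stat, p = sps.kruskal(*groups)
    return GroupTestResult("kruskal", float(stat), float(p), sizes)


# -------------------------------------------------------------- survival

@dataclass(frozen=True)
class SurvivalResult:
    rule: str
    curves: Mapping[str, pd.DataFrame]  # columns: time, at_risk, survival
    logrank_stat: float
    p: float
    strata_sizes: Mapping[str, int]


def _burden(rule: str, vs: Sequence[VariantCall]) -> int:
    if rule == "olo_gt3":
        return sum(1 for v in vs if v.is_olo)
    if rule == "all_gt4":
        return len(list(vs))
    if rule == "mr_runx1_gt1":
        return sum(1 for v in vs if v.is_olo and v.gene in MR_ICC22)
    raise ValueError(f"unknown strata rule {rule!r}; allowed: olo_gt3, all_gt4, mr_runx1_gt1")


_THRESHOLDS = {"olo_gt3": 3, "all_gt4": 4, "mr_runx1_gt1": 1}


def burden_strata(
    patients: Sequence[PatientRecord],
    variants: Sequence[VariantCall],
    rule: str,
) -> Dict[str, str]:
    """Partition the cohort into 'high'/'low' burden strata for ``rule``."""
    cut = _THRESHOLDS.get(rule)
    if cut is None:
        _burden(rule, [])  # raises with the allowed-rules message
    by_pid: Dict[str, List[VariantCall]] = {}
    for v in variants:
        by_pid.setdefault(v.patient_id, []).append(v)
    return {
        p.patient_id: ("high" if _burden(rule, by_pid.get(p.patient_id, [])) > cut else "low")
        for p in patients
    }


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival curve as a (time, at_risk, survival) frame."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, bool))
    tab = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame({
        "time": tab.index.to_numpy(float),
        "at_risk": tab["at_risk"].to_numpy(int),
        "survival": surv.reindex(tab.index).to_numpy(float),
    })


def km_logrank(
    patients: Sequence[PatientRecord],
    variants: Sequence[VariantCall],
    rule: str = "olo_gt3",
) -> SurvivalResult:
    """Kaplan–Meier curves for the burden strata of ``rule`` plus the
    two-group log-rank test (chi-square, 1 df)."""
    from lifelines.statistics import logrank_test

    strata = burden_strata(patients, variants, rule)
    with_fu = [p for p in patients if p.os_months is not None and p.os_event is not None]
    if not with_fu:
        raise ValueError("no patients with follow-up (os_months/os_event)")
    grouped: Dict[str, List[PatientRecord]] = {"low": [], "high": []}
    for p in with_fu:
        grouped[strata[p.patient_id]].append(p)
    for name, members in grouped.items():
        if not members:
            raise ValueError(f"stratum {name!r} is empty under rule {rule!r}")
    curves = {
        name: kaplan_meier(
            [p.os_months for p in members], [bool(p.os_event) for p in members]
        )
        for name, members in grouped.items()
    }
    res = logrank_test(
        [p.os_months for p in grouped["low"]],
        [p.os_months for p in grouped["high"]],
        event_observed_A=[bool(p.os_event) for p in grouped["low"]],
        event_observed_B=[bool(p.os_event) for p in grouped["high"]],
    )
    return SurvivalResult(
        rule=rule,
        curves=curves,
        logrank_stat=float(res.test_statistic),
        p=float(res.p_value),
        strata_sizes={k: len(v) for k, v in grouped.items()},
    )
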