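"""Cognitive domain comparison and cognition-imaging Spearman correlation.

The cognitive battery yields 16 age-standardized domain scores per subject
(the Neurocognitive Index plus 15 domains, mean around 100). Group
comparisons use uncorrected pooled two-sample t tests (the battery analysis
is exploratory by design); cognition-imaging associations use Spearman rank
correlation between domain scores and per-subject imaging markers (mean
metric or connectivity z over a significant cluster's voxels), reported both
raw and BH-FDR adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import Cluster, StatMap

__all__ = [
    "COGNITIVE_DOMAINS",
    "CorrelationResult",
    "ImagingMarkerVector",
    "extract_marker",
    "domain_group_ttest",
    "spearman",
    "correlate_battery",
]

#: Domain short names in battery order: overall index first, then 15 domains.
COGNITIVE_DOMAINS = [
    "NCI",
    "CM",
    "VerbM",
    "VisM",
    "PsyMotSpd",
    "RT",
    "ComA",
    "CogFlex",
    "ProcSpd",
    "ExeFun",
    "SocAcu",
    "Reason",
    "WM",
    "SustA",
    "SimA",
    "MotSpd",
]

#: Exact permutation p-values are used at or below this sample size.
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    x_name: str = ""
    y_name: str = ""
    p_adjusted: float | None = None
    p_exact: float | None = None


@dataclass
class ImagingMarkerVector:
    """One scalar per subject, extracted from a named cluster."""

    values: np.ndarray
    subject_ids: list[str]
    marker_name: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape[0] != len(self.subject_ids):
            raise ValueError("one value per subject required")
        self.values = values


def extract_marker(
    maps: list[StatMap],
    cluster: Cluster,
    subject_ids: list[str],
    marker_name: str = "",
) -> ImagingMarkerVector:
    """Per-subject unweighted mean of map values over the cluster's voxels."""
    if cluster.size_voxels == 0:
        raise ValueError("empty cluster")
    if len(maps) != len(subject_ids):
        raise ValueError("maps and subject ids must align")
    idx = tuple(cluster.voxels.T)
    for m in maps:
        if m.values.shape != maps[0].values.shape:
            raise ValueError("subject maps are on different grids")
    values = np.array([m.values[idx].mean() for m in maps])
    return ImagingMarkerVector(values, list(subject_ids), marker_name)


def domain_group_ttest(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Uncorrected pooled two-sample t test per cognitive domain.

    ``table`` needs columns ``subject_id``, ``group`` (patient/control) and
    one column per domain; rows with a missing score are dropped per domain.
    Returns a frame with per-domain group means, t, two-tailed p and a
    significance flag at ``alpha``.
    """
    domains = [c for c in COGNITIVE_DOMAINS if c in table.columns]
    if not domains:
        raise ValueError("no cognitive domain columns found")
    rows = []
    for domain in domains:
        sub = table[["group", domain]].dropna()
        a = sub.loc[sub["group"] == "patient", domain].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == "control", domain].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"domain {domain}: fewer than 2 subjects in a group")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            dict(
                domain=domain,
                patient_mean=a.mean(),
                control_mean=b.mean(),
                n_patient=len(a),
                n_control=len(b),
                t=float(t),
                p=float(p),
                significant=bool(p < alpha),
            )
        )
    return pd.DataFrame(rows)


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Spearman rank correlation with average ranks on ties.

    rho is the Pearson correlation of the rank vectors. The two-tailed
    p value uses the t approximation t = rho sqrt((n-2)/(1-rho^2)); for
    n <= 9 an exact permutation p (all n! orderings of y) is computed as
    well, since the approximation is rough at such sample sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need equal-length vectors with n >= 3")
    rho = _rank_rho(x, y)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    p_exact = None
    if n <= EXACT_PERMUTATION_MAX_N:
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_rho(x, np.asarray(perm))) >= abs(rho) - 1e-12:
                count += 1
        p_exact = count / total
    return CorrelationResult(rho=rho, p_value=p, n=n, x_name=x_name, y_name=y_name, p_exact=p_exact)


def correlate_battery(
    table: pd.DataFrame,
    markers: list[ImagingMarkerVector],
    adjust: bool = False,
    domains: list[str] | None = None,
    patients_only: bool = False,
) -> list[CorrelationResult]:
    """All domain x marker Spearman correlations over aligned subjects.

    Subjects missing from either source are dropped pairwise; correlations
    pool patients and controls unless ``patients_only``. With ``adjust`` the
    whole result list is BH-FDR corrected into ``p_adjusted``.
    """
    if domains is None:
        domains = [c for c in COGNITIVE_DOMAINS if c in table.columns]
    use = table if not patients_only else table[table["group"] == "patient"]
    use = use.set_index("subject_id")
    results: list[CorrelationResult] = []
    for marker in markers:
        marker_by_id = dict(zip(marker.subject_ids, marker.values))
        common = [sid for sid in use.index if sid in marker_by_id]
        if not results and not common and markers:
            raise ValueError("no overlapping subjects between cognition table and markers")
        for domain in domains:
            scores = use.loc[common, domain].to_numpy(dtype=float)
            values = np.array([marker_by_id[sid] for sid in common])
            keep = np.isfinite(scores) & np.isfinite(values)
            if keep.sum() < 3:
                continue
            results.append(
                spearman(
                    values[keep],
                    scores[keep],
                    x_name=marker.marker_name,
                    y_name=domain,
                )
            )
    if adjust and results:
        p = [r.p_value for r in results]
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular view of a correlation battery."""
    return pd.DataFrame(
        [
            dict(
                marker=r.x_name,
                domain=r.y_name,
                rho=r.rho,
                p=r.p_value,
                p_adjusted=r.p_adjusted,
                p_exact=r.p_exact,
                n=r.n,
            )
            for r in results
        ]
    )
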