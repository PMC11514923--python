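"""Cohort-level statistics for the delta-qT1 biomarkers.

The analysis layer mirrors a standard neuroimaging group workflow:
Kruskal-Wallis omnibus tests across ROIs with Dunn's post hoc pairwise
comparisons (Bonferroni-adjusted, capped at 1), Glass' delta effect
sizes with the whole cortex as reference group (an effect is regarded
as large if |delta| > 0.8), ordinary least-squares models with
duration-by-ROI interactions under treatment coding (cortex as the
reference level), and dichotomization of standardized memory scores at
one SD below the normative mean (impaired iff score < 90).

ROIs measured within the same subjects are compared with unpaired rank
tests, replicating the published workflow; a paired Wilcoxon variant is
available but off by default.  No correction is applied across the many
scenario analyses, matching the published workflow (and its stated
limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "glass_delta",
    "compare_rois",
    "fit_linear_model",
    "classify_memory",
    "run_group_analyses",
    "GroupComparisonResult",
    "RegressionResult",
]

#: Glass' delta magnitude regarded as a large effect.
LARGE_EFFECT = 0.8

#: Memory-impairment cutoff: one SD below the normative mean of 100/10.
MEMORY_CUTOFF = 90.0

REFERENCE_ROI = "cortex"


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("non-finite observations")
    return arrs


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Mid-ranks for ties; p from chi-square with k-1 degrees of freedom.
    The degenerate all-identical case is defined as (H, p) = (0, 1).
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(groups, adjustment: str = "bonferroni") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's post hoc test on pooled mid-ranks.

    For groups i, j with mean pooled ranks r_i, r_j,

        z_ij = (r_i - r_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]

    with tie term T = sum(t^3 - t).  Two-sided p from the standard
    normal, adjusted by Bonferroni (default) or Holm and capped at 1.

    Returns (p_adjusted, z) as symmetric DataFrames indexed by group
    position (or by key when ``groups`` is a dict); the p diagonal is 1.
    """
    if adjustment not in ("bonferroni", "holm", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if isinstance(groups, dict):
        names = list(groups)
        arrs = _check_groups(list(groups.values()))
    else:
        arrs = _check_groups(groups)
        names = list(range(len(arrs)))
    k = len(arrs)
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrs]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s

    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))
    z = np.zeros((k, k))
    raw = np.ones((k, k))
    pairs = list(combinations(range(k), 2))
    raw_list = []
    for i, j in pairs:
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        z[i, j], z[j, i] = zij, -zij
        pij = 2.0 * stats.norm.sf(abs(zij))
        raw[i, j] = raw[j, i] = pij
        raw_list.append(pij)

    m = len(pairs)
    adj = np.ones((k, k))
    if adjustment == "bonferroni":
        for (i, j), pij in zip(pairs, raw_list):
            adj[i, j] = adj[j, i] = min(1.0, pij * m)
    elif adjustment == "holm":
        order = np.argsort(raw_list)
        running = 0.0
        for rank, idx in enumerate(order):
            i, j = pairs[idx]
            running = max(running, min(1.0, (m - rank) * raw_list[idx]))
            adj[i, j] = adj[j, i] = running
    else:
        for (i, j), pij in zip(pairs, raw_list):
            adj[i, j] = adj[j, i] = min(1.0, pij)
    p_df = pd.DataFrame(adj, index=names, columns=names)
    z_df = pd.DataFrame(z, index=names, columns=names)
    return p_df, z_df


def glass_delta(
    roi_values, reference_values, small_sample_correction: bool = False
) -> tuple[float, bool]:
    """Glass' delta: mean difference standardized by the reference SD.

    delta = (mean(roi) - mean(reference)) / sampleSD(reference).  The
    second return value flags |delta| > 0.8 (a large effect).

    The raw estimator is biased away from zero in small samples because
    E[1/s] > 1/sigma; ``small_sample_correction=True`` multiplies by the
    Hedges J factor Gamma(m/2) / (sqrt(m/2) Gamma((m-1)/2)) with
    m = n_ref - 1, giving a nearly unbiased estimate.  The raw value is
    the default, matching common reporting practice.

    Raises ``ValueError`` when the reference SD is zero or the reference
    has fewer than two observations.
    """
    roi = np.asarray(roi_values, dtype=float).ravel()
    ref = np.asarray(reference_values, dtype=float).ravel()
    if ref.size < 2:
        raise ValueError("reference group needs at least 2 observations")
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise ValueError("reference group has zero standard deviation")
    delta = float((np.mean(roi) - np.mean(ref)) / sd)
    if small_sample_correction:
        from scipy.special import gammaln

        m = ref.size - 1
        j = np.exp(gammaln(m / 2.0) - gammaln((m - 1) / 2.0)) / np.sqrt(m / 2.0)
        delta *= j
    return delta, abs(delta) > LARGE_EFFECT


@dataclass
class GroupComparisonResult:
    """Omnibus + post hoc comparison of ROI distributions."""

    h_statistic: float
    omnibus_p: float
    dunn_p: pd.DataFrame
    dunn_z: pd.DataFrame
    glass: dict[str, float]
    glass_large: dict[str, bool]
    n_per_roi: dict[str, int]


def compare_rois(
    values_by_roi: dict[str, np.ndarray],
    reference: str = REFERENCE_ROI,
    adjustment: str = "bonferroni",
    paired: bool = False,
) -> GroupComparisonResult:
    """Kruskal-Wallis across ROIs, Dunn post hoc and Glass' delta vs reference.

    ``paired=True`` switches the post hoc layer to Wilcoxon signed-rank
    tests against the reference ROI (Bonferroni-adjusted) — an
    alternative acknowledging the within-subject pairing, off by
    default for fidelity with the unpaired published workflow.
    """
    if reference not in values_by_roi:
        raise ValueError(f"reference ROI {reference!r} missing from input")
    names = list(values_by_roi)
    h, p = kruskal_wallis(list(values_by_roi.values()))
    if paired:
        k = len(names)
        adj = np.ones((k, k))
        z = np.zeros((k, k))
        m = k - 1
        ref_vals = np.asarray(values_by_roi[reference], dtype=float)
        for i, name in enumerate(names):
            if name == reference:
                continue
            res = stats.wilcoxon(np.asarray(values_by_roi[name], dtype=float), ref_vals)
            j = names.index(reference)
            adj[i, j] = adj[j, i] = min(1.0, res.pvalue * m)
        dunn_p = pd.DataFrame(adj, index=names, columns=names)
        dunn_z = pd.DataFrame(z, index=names, columns=names)
    else:
        dunn_p, dunn_z = dunn_posthoc(values_by_roi, adjustment=adjustment)
    glass, large = {}, {}
    for name in names:
        if name == reference:
            continue
        glass[name], large[name] = glass_delta(values_by_roi[name], values_by_roi[reference])
    return GroupComparisonResult(
        h, p, dunn_p, dunn_z, glass, large,
        {n: int(np.asarray(v).size) for n, v in values_by_roi.items()},
    )


@dataclass
class RegressionResult:
    """OLS coefficient table plus the fitted formula and sample size."""

    formula: str
    n: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.params, "se": self.bse, "p": self.pvalues})


def fit_linear_model(
    table: pd.DataFrame,
    response: str = "value",
    terms: tuple[str, ...] = ("duration", "latency"),
    roi_term: bool = True,
    interactions: bool = False,
    interaction_var: str = "duration",
) -> RegressionResult:
    """OLS with ROI treatment-coded against the whole-cortex reference.

    With ``interactions=True`` the ``interaction_var`` is crossed with
    the ROI factor, so each interaction coefficient reads directly as
    the slope difference of that ROI from cortex.  Raises on a
    rank-deficient design, naming the aliased columns.
    """
    rhs = list(terms)
    if roi_term:
        roi_fac = f"C(roi, Treatment('{REFERENCE_ROI}'))"
        if interactions:
            if interaction_var not in terms:
                rhs.append(interaction_var)
            rhs = [t for t in rhs if t != interaction_var]
            rhs.append(f"{interaction_var} * {roi_fac}")
        else:
            rhs.append(roi_fac)
    elif interactions:
        raise ValueError("interactions require the ROI factor")
    formula = f"{response} ~ " + " + ".join(rhs)
    model = smf.ols(formula, data=table)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        u, s, vt = np.linalg.svd(model.exog)
        aliased = [
            model.exog_names[i]
            for i in np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]
        ]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    fit = model.fit()
    return RegressionResult(
        formula, int(fit.nobs), fit.params, fit.bse, fit.pvalues, float(fit.rsquared)
    )


def classify_memory(score: float) -> str | None:
    """Dichotomize a standardized memory score.

    Impaired iff score < 90 (strictly one SD below the normative mean);
    missing scores yield ``None`` and are excluded from memory analyses.
    """
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return None
    if not np.isfinite(score):
        raise ValueError(f"memory score must be finite, got {score}")
    return "impaired" if score < MEMORY_CUTOFF else "unimpaired"


# ---------------------------------------------------------------------------
# scenario driver


def _bilateral(table: pd.DataFrame) -> pd.DataFrame:
    """Average left/right rows into one value per subject x ROI x kind."""
    keys = ["subject", "roi", "kind"]
    covs = [
        c for c in table.columns
        if c not in keys + ["hemisphere", "value"]
    ]
    agg = {c: "first" for c in covs}
    agg["value"] = "mean"
    return table.groupby(keys, as_index=False).agg(agg)


def _values_by_roi(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        roi: sub.sort_values("subject")["value"].to_numpy()
        for roi, sub in df.groupby("roi")
    }


def _comparison_rows(cmp: GroupComparisonResult, reference: str, **tags) -> list[dict]:
    rows = []
    for roi, delta in cmp.glass.items():
        rows.append(
            dict(
                tags,
                roi=roi,
                h_statistic=cmp.h_statistic,
                omnibus_p=cmp.omnibus_p,
                dunn_p=float(cmp.dunn_p.loc[roi, reference]),
                glass_delta=delta,
                large_effect=cmp.glass_large[roi],
                n=cmp.n_per_roi[roi],
            )
        )
    return rows


@dataclass
class CohortAnalysisResults:
    """Tidy result tables per scenario plus skip diagnostics."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)


ALL_SCENARIOS = (
    "group_roi_comparison",
    "duration_regression",
    "ipsilateral",
    "memory",
)


def run_group_analyses(
    table: pd.DataFrame,
    scenarios: tuple[str, ...] = ALL_SCENARIOS,
    adjustment: str = "bonferroni",
) -> CohortAnalysisResults:
    """Run the cohort analysis matrix on a tidy biomarker table.

    ``table`` must hold one row per subject x ROI x hemisphere x map
    kind with the covariate columns produced by
    :func:`qt1bbb.cohort.simulate_cohort` (or the image pipeline joined
    to a clinical table).  Scenarios whose prerequisites are unmet (for
    example no subject with known onset side) are skipped with a logged
    reason rather than failing the run.  Results are invariant to the
    row order of the input.
    """
    table = table.sort_values(
        ["subject", "roi", "hemisphere", "kind"], kind="mergesort"
    ).reset_index(drop=True)
    out = CohortAnalysisResults()
    bilat = _bilateral(table)

    if "group_roi_comparison" in scenarios:
        rows = []
        for (group, kind), sub in bilat.groupby(["group", "kind"]):
            by_roi = _values_by_roi(sub)
            if len(by_roi) < 2 or REFERENCE_ROI not in by_roi:
                continue
            cmp = compare_rois(by_roi, adjustment=adjustment)
            rows += _comparison_rows(cmp, REFERENCE_ROI, scenario="group_roi_comparison",
                                     group=group, kind=kind)
        if rows:
            out.tables["group_roi_comparison"] = pd.DataFrame(rows)
        else:
            out.skipped.append(("group_roi_comparison", "no group/kind cell with >=2 ROIs"))

    if "duration_regression" in scenarios:
        rows = []
        for kind, sub in bilat.groupby("kind"):
            sub = sub.assign(latency=sub["latency_ii"] if kind == "ni" else sub["latency_pi"])
            for interactions in (False, True):
                res = fit_linear_model(sub, interactions=interactions)
                for name in res.params.index:
                    rows.append(
                        {
                            "scenario": "duration_regression",
                            "kind": kind,
                            "model": "interaction" if interactions else "main",
                            "term": name,
                            "beta": float(res.params[name]),
                            "se": float(res.bse[name]),
                            "p": float(res.pvalues[name]),
                            "n": res.n,
                        }
                    )
        out.tables["duration_regression"] = pd.DataFrame(rows)

    if "ipsilateral" in scenarios:
        known = table[table["side"].isin(["left", "right"])]
        ipsi = known[known["hemisphere"] == known["side"]]
        if ipsi.empty:
            out.skipped.append(("ipsilateral", "no subject with known onset side"))
        else:
            rows = []
            for kind, sub in ipsi.groupby("kind"):
                sub = sub.assign(
                    latency=sub["latency_ii"] if kind == "ni" else sub["latency_pi"]
                )
                res = fit_linear_model(
                    sub, terms=("latency",), interactions=True, interaction_var="latency"
                )
                for name in res.params.index:
                    rows.append(
                        {
                            "scenario": "ipsilateral",
                            "kind": kind,
                            "model": "latency_x_roi",
                            "term": name,
                            "beta": float(res.params[name]),
                            "se": float(res.bse[name]),
                            "p": float(res.pvalues[name]),
                            "n": res.n,
                        }
                    )
            out.tables["ipsilateral"] = pd.DataFrame(rows)

    if "memory" in scenarios:
        rows = []
        specs = [
            ("verbal_memory", "left"),  # verbal memory is left-lateralized
            ("figural_memory", "right"),
        ]
        for score_col, hemi in specs:
            sub = table[table["hemisphere"] == hemi].copy()
            sub["memory_status"] = sub[score_col].map(classify_memory)
            impaired = sub[sub["memory_status"] == "impaired"]
            for subset_name, subset in (
                ("all", impaired),
                ("TLE", impaired[impaired["group"] == "TLE"]),
            ):
                for kind, cell in subset.groupby("kind"):
                    by_roi = _values_by_roi(cell)
                    sizes = {len(v) for v in by_roi.values()}
                    if len(by_roi) < 2 or REFERENCE_ROI not in by_roi or min(sizes) < 3:
                        out.skipped.append(
                            (
                                "memory",
                                f"{score_col}/{subset_name}/{kind}: too few impaired subjects",
                            )
                        )
                        continue
                    cmp = compare_rois(by_roi, adjustment=adjustment)
                    rows += _comparison_rows(
                        cmp, REFERENCE_ROI, scenario="memory", domain=score_col,
                        hemisphere=hemi, subset=subset_name, kind=kind,
                    )
        if rows:
            out.tables["memory"] = pd.DataFrame(rows)

    return out
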