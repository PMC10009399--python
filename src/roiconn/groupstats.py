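"""Three-group ANCOVA inference over the six network-connectivity metrics.

For each metric the model is

    metric ~ group + age + mean_fd        (dummy-coded group, no interactions)

fit by ordinary least squares.  The omnibus group F comes from the nested
residual-sum-of-squares comparison of the full model against the
covariates-only model; its effect size is partial eta squared,

    eta2p = SS_group / (SS_group + SS_error) = F*df1 / (F*df1 + df2).

The six omnibus p-values form one Benjamini–Hochberg FDR family.  Group
means are estimated marginal means — model predictions per group at the
whole-sample covariate means — and pairwise contrasts are Fisher's protected
LSD: unadjusted two-sided t tests on the adjusted-mean differences using the
omnibus model's pooled error, flagged (not suppressed) when the omnibus test
is non-significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .connectivity import METRIC_NAMES

GROUPS = ("OCD", "AC", "HC")
DEFAULT_COVARIATES = ("age", "mean_fd")
ALPHA = 0.05

SEVERITY_SCOPES = {"cybocs": ("OCD",), "masc": GROUPS, "ocir": GROUPS}


def validate_cohort(cohort: pd.DataFrame, metrics: Sequence[str] = METRIC_NAMES,
                    covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Check the cohort table invariants; returns the frame untouched."""
    needed = {"subject_id", "group", *metrics, *covariates}
    missing = needed - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s) {sorted(missing)}")
    unknown = set(cohort["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) {sorted(unknown)}")
    cols = list(metrics) + list(covariates)
    if not np.all(np.isfinite(cohort[cols].to_numpy(dtype=float))):
        raise ValueError("non-finite metric or covariate value in cohort table")
    return cohort


@dataclass
class AncovaResult:
    """Omnibus ANCOVA result for one metric."""

    metric: str
    F: float
    df1: int
    df2: int
    p: float
    eta2p: float
    emmeans: dict[str, tuple[float, float]]  # group -> (adjusted mean, SE)
    p_fdr: float | None = None
    #: fitted statsmodels results + bookkeeping, used by lsd_posthoc
    _fit: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class PosthocResult:
    """One LSD pairwise contrast on adjusted means."""

    metric: str
    pair: tuple[str, str]
    diff: float
    t: float
    df: int
    p: float
    omnibus_significant: bool


def _design(cohort: pd.DataFrame, covariates: Sequence[str], reference: str = "HC"):
    """Dummy-coded design matrix with `reference` as baseline group."""
    groups_present = [g for g in GROUPS if g in set(cohort["group"])]
    if reference not in groups_present:
        reference = groups_present[-1]
    others = [g for g in groups_present if g != reference]
    n = len(cohort)
    X = np.ones((n, 1 + len(others) + len(covariates)))
    for k, g in enumerate(others):
        X[:, 1 + k] = (cohort["group"] == g).to_numpy(float)
    for k, c in enumerate(covariates):
        X[:, 1 + len(others) + k] = cohort[c].to_numpy(float)
    names = ["intercept", *[f"group[{g}]" for g in others], *covariates]
    return X, names, groups_present, others, reference


def ancova(
    cohort: pd.DataFrame,
    metric: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AncovaResult:
    """One-way ANCOVA of ``metric`` on group, adjusting for ``covariates``.

    df1 = G - 1 and df2 = N - G - C; adjusted means are evaluated at the
    whole-sample covariate means with model-based standard errors.
    """
    validate_cohort(cohort, metrics=[metric], covariates=covariates)
    y = cohort[metric].to_numpy(float)
    X, names, groups_present, others, reference = _design(cohort, covariates)
    G, C, N = len(groups_present), len(covariates), len(cohort)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for metric {metric!r} "
            f"(constant or collinear covariate among {list(covariates)})"
        )
    if N - G - C < 1:
        raise ValueError(f"error df {N - G - C} < 1 (N={N}, G={G}, C={C})")

    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.delete(X, range(1, 1 + len(others)), axis=1)).fit()
    df1, df2 = G - 1, int(full.df_resid)
    ss_group = reduced.ssr - full.ssr
    F = (ss_group / df1) / (full.ssr / df2)
    p = float(st.f.sf(F, df1, df2))
    eta2p = ss_group / (ss_group + full.ssr)

    cov_means = cohort[list(covariates)].mean().to_numpy(float)
    cov = full.cov_params()
    emmeans = {}
    rows = {}
    for g in groups_present:
        x = np.zeros(X.shape[1])
        x[0] = 1.0
        if g != reference:
            x[1 + others.index(g)] = 1.0
        x[1 + len(others):] = cov_means
        emmeans[g] = (float(x @ full.params), float(np.sqrt(x @ cov @ x)))
        rows[g] = x
    return AncovaResult(
        metric=metric, F=float(F), df1=df1, df2=df2, p=p, eta2p=float(eta2p),
        emmeans=emmeans,
        _fit={"results": full, "rows": rows, "groups": groups_present},
    )


def lsd_posthoc(result: AncovaResult, alpha: float = ALPHA) -> list[PosthocResult]:
    """Fisher's LSD pairwise t tests on the adjusted means.

    Each unordered group pair gets t = (difference of adjusted means) /
    SE(difference), with the SE from the omnibus model's coefficient
    covariance and df = the omnibus error df.  No multiplicity adjustment;
    ``omnibus_significant`` records the protected-LSD gate.
    """
    if not result._fit:
        raise ValueError("result carries no fitted model; rerun ancova()")
    fit = result._fit["results"]
    rows = result._fit["rows"]
    groups = result._fit["groups"]
    cov = fit.cov_params()
    gate = result.p < alpha
    out = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            ga, gb = groups[a], groups[b]
            c = rows[ga] - rows[gb]
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ cov @ c))
            t = diff / se
            p = float(2.0 * st.t.sf(abs(t), result.df2))
            out.append(PosthocResult(
                metric=result.metric, pair=(ga, gb), diff=diff, t=float(t),
                df=result.df2, p=p, omnibus_significant=gate,
            ))
    return out


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adjusted_(i) = min over j >= i of m * p_(j) / j on the sorted sequence,
    capped at 1; monotone non-decreasing in the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_group_analysis(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    metrics: Sequence[str] = METRIC_NAMES,
) -> tuple[list[AncovaResult], list[PosthocResult]]:
    """The primary analysis: one ANCOVA per metric, BH-FDR over the family of
    omnibus p-values, and LSD post-hocs for every metric."""
    results = [ancova(cohort, m, covariates) for m in metrics]
    adj = fdr_bh([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    posthocs = [ph for r in results for ph in lsd_posthoc(r)]
    return results, posthocs


def severity_correlations(
    cohort: pd.DataFrame,
    scale: str,
    groups: Sequence[str] | None = None,
    metrics: Sequence[str] = METRIC_NAMES,
) -> pd.DataFrame:
    """Pearson correlation of a severity scale with each metric.

    CYBOCS is scoped to the OCD group by default; MASC and OCI-R to all
    groups.  Missing scale values are dropped pairwise, with the n used
    reported per row.
    """
    if groups is None:
        groups = SEVERITY_SCOPES.get(scale, GROUPS)
    if scale not in cohort.columns:
        raise ValueError(f"cohort table has no column {scale!r}")
    scoped = cohort[cohort["group"].isin(groups)]
    rows = []
    for m in metrics:
        sub = scoped[[scale, m]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"fewer than 3 subjects with {scale!r} in scope")
        x, y = sub[scale].to_numpy(float), sub[m].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"constant {scale!r} or {m!r} within scope")
        r, p = st.pearsonr(x, y)
        rows.append({"metric": m, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def sensitivity(
    cohort: pd.DataFrame,
    mode: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    metrics: Sequence[str] = METRIC_NAMES,
) -> tuple[list[AncovaResult], list[PosthocResult]]:
    """The two robustness re-analyses.

    ``add_depress_covariate`` refits with the binary depressive-disorder flag
    as a third covariate (df2 = N - G - 3); ``exclude_over_18`` drops
    subjects older than 18 years and reruns the primary analysis on the
    reduced N.
    """
    if mode == "add_depress_covariate":
        if "depress_flag" not in cohort.columns:
            raise ValueError("cohort table has no 'depress_flag' column")
        return run_group_analysis(
            cohort, covariates=[*covariates, "depress_flag"], metrics=metrics
        )
    if mode == "exclude_over_18":
        kept = cohort[cohort["age"] <= 18]
        if kept.empty:
            raise ValueError("age filter excluded every subject")
        return run_group_analysis(kept, covariates=covariates, metrics=metrics)
    raise ValueError(f"unknown sensitivity mode {mode!r}")


def apply_exclusions(enrolled: dict[str, int], excluded: dict[str, int]) -> dict[str, int]:
    """Per-group retained counts after subject exclusions (simple bookkeeping)."""
    bad = {g: n for g, n in excluded.items() if n > enrolled.get(g, 0)}
    if bad:
        raise ValueError(f"more exclusions than enrolled in group(s) {sorted(bad)}")
    return {g: n - excluded.get(g, 0) for g, n in enrolled.items()}


# ---------------------------------------------------------------------------
# tabular / JSON export

def stats_frame(results: list[AncovaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"metric": r.metric, "F": r.F, "df1": r.df1, "df2": r.df2,
               "p": r.p, "p_fdr": r.p_fdr, "eta2p": r.eta2p}
        for g, (m, se) in r.emmeans.items():
            row[f"M_{g}"] = m
            row[f"SE_{g}"] = se
        rows.append(row)
    return pd.DataFrame(rows)


def posthoc_frame(posthocs: list[PosthocResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"metric": ph.metric, "group_a": ph.pair[0], "group_b": ph.pair[1],
         "diff": ph.diff, "t": ph.t, "df": ph.df, "p": ph.p,
         "omnibus_significant": ph.omnibus_significant}
        for ph in posthocs
    ])


def results_bundle(results: list[AncovaResult], posthocs: list[PosthocResult]) -> dict:
    return {
        "ancova": stats_frame(results).to_dict(orient="records"),
        "posthoc": posthoc_frame(posthocs).to_dict(orient="records"),
    }


def save_results(results, posthocs, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats_frame(results).to_csv(out / "stats.csv", index=False, float_format="%.6g")
    posthoc_frame(posthocs).to_csv(out / "posthoc.csv", index=False, float_format="%.6g")
    with open(out / "results.json", "w") as fh:
        json.dump(results_bundle(results, posthocs), fh, indent=2, default=float)
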