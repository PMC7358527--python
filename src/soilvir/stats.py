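"""Correlation, repeated-measures ANOVA, and constrained ordination.

The statistical layer of the field study: Spearman rank correlations
between abundances and soil edaphic variables, one-way repeated-measures
ANOVA with a Tukey HSD post-hoc across soils, the variability-vs-organic-
carbon analysis, and canonical correspondence analysis (CCA) of the
community matrix constrained by environmental predictors, with a Monte
Carlo permutation test of the constrained inertia.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RmAnovaResult",
    "CcaResult",
    "spearman",
    "rm_anova_tukey",
    "abundance_variability",
    "cca",
    "cca_permutation_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value."""

    r: float
    p: float
    n: int

    def significance_tier(self) -> str:
        """Reporting tier: '***' p<0.001, '**' p<0.01, '*' p<0.05, '' otherwise."""
        for mark, level in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
            if self.p < level:
                return mark
        return ""


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_mc: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete missing handling.

    r is the Pearson correlation of mid-ranks (average ranks on ties).  The
    two-sided p-value uses the t approximation for n >= 10; for n < 10 it is
    computed by permutation — exhaustive enumeration up to n = 7, otherwise
    `n_mc` Monte Carlo permutations (add-one convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        # standard t approximation
        r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
        t = r_clip * np.sqrt((n - 2) / (1 - r_clip**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    else:
        if n <= 7:
            perms = np.array(list(_permutations(range(n))))
            permuted = ry[perms]
            add_one = 0
        else:
            rng = np.random.default_rng(seed)
            permuted = rng.permuted(np.tile(ry, (n_mc, 1)), axis=1)
            add_one = 1
        rxc = rx - rx.mean()
        ryc = permuted - permuted.mean(axis=1, keepdims=True)
        rps = ryc @ rxc / np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
        count = int((np.abs(rps) >= abs(r) - 1e-12).sum())
        p = (add_one + count) / (add_one + len(rps))
    return CorrelationResult(r=r, p=min(p, 1.0), n=n)


@dataclass(frozen=True)
class RmAnovaResult:
    f: float
    p: float
    df_groups: int
    df_error: int
    tukey: pd.DataFrame


def rm_anova_tukey(
    values: np.ndarray, groups: np.ndarray, subjects: np.ndarray, alpha: float = 0.05
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with a Tukey HSD post-hoc.

    Requires a balanced design: every subject measured once in every group.
    The F statistic is SS_groups/(k-1) over SS_error/((k-1)(n-1)) with the
    subject effect removed.  Tukey HSD uses the studentized range on group
    means with the within-subjects MS error, the appropriate error term for
    a repeated-measures design.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    subjects = np.asarray(subjects)
    group_levels = np.array(sorted(set(groups.tolist())))
    subject_levels = np.array(sorted(set(subjects.tolist())))
    k, n = len(group_levels), len(subject_levels)
    if k < 2 or n < 2:
        raise ValueError("need at least two groups and two subjects")
    table = np.full((n, k), np.nan)
    for value, g, s in zip(values, groups, subjects):
        i = int(np.where(subject_levels == s)[0][0])
        j = int(np.where(group_levels == g)[0][0])
        if not np.isnan(table[i, j]):
            raise ValueError(f"duplicate cell (subject={s!r}, group={g!r})")
        table[i, j] = value
    if np.isnan(table).any():
        raise ValueError(
            "unbalanced design: every subject needs one value per group "
            "(complete cases listwise before calling)"
        )
    grand = table.mean()
    group_means = table.mean(axis=0)
    subject_means = table.mean(axis=1)
    ss_groups = n * float(((group_means - grand) ** 2).sum())
    ss_subjects = k * float(((subject_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_error = ss_total - ss_groups - ss_subjects
    df_g, df_e = k - 1, (k - 1) * (n - 1)
    ms_g = ss_groups / df_g
    ms_e = ss_error / df_e
    if ms_e <= 0:
        f = 0.0 if ms_g == 0 else np.inf
        p = 1.0 if ms_g == 0 else 0.0
    else:
        f = ms_g / ms_e
        p = float(sps.f.sf(f, df_g, df_e))
    rows = []
    se = np.sqrt(ms_e / n) if ms_e > 0 else 0.0
    for a in range(k):
        for b in range(a + 1, k):
            diff = float(group_means[a] - group_means[b])
            if se > 0:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_e))
            else:
                p_adj = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "group_a": group_levels[a],
                    "group_b": group_levels[b],
                    "mean_diff": diff,
                    "p_adj": p_adj,
                    "reject": p_adj < alpha,
                }
            )
    return RmAnovaResult(
        f=float(f), p=p, df_groups=df_g, df_error=df_e, tukey=pd.DataFrame(rows)
    )


def abundance_variability(
    enumeration: pd.DataFrame,
    edaphics: pd.DataFrame,
    abundance_col: str = "viral_abundance",
    env_col: str = "organic_c",
) -> tuple[pd.DataFrame, CorrelationResult]:
    """Seasonal variability of abundance per treatment vs an edaphic variable.

    For each treatment: the sample SD of the monthly mean abundances, paired
    with the treatment-mean of `env_col`.  Returns the per-treatment table
    and the Spearman correlation between the two (the seasonal-variability
    vs organic-carbon analysis).
    """
    monthly = (
        enumeration.groupby(["treatment", "month"], sort=False, observed=True)[abundance_col]
        .mean()
        .reset_index()
    )
    rows = []
    for treatment, group in monthly.groupby("treatment", sort=False, observed=True):
        if group["month"].nunique() < 3:
            raise ValueError(f"treatment {treatment!r} has fewer than 3 months")
        rows.append(
            {
                "treatment": treatment,
                "abundance_sd": float(group[abundance_col].std(ddof=1)),
                env_col: float(
                    edaphics.loc[edaphics["treatment"] == treatment, env_col].mean()
                ),
            }
        )
    per_treatment = pd.DataFrame(rows)
    corr = spearman(
        per_treatment["abundance_sd"].to_numpy(), per_treatment[env_col].to_numpy()
    )
    return per_treatment, corr


# ---------------------------------------------------------------------------
# canonical correspondence analysis


@dataclass(frozen=True)
class CcaResult:
    """Constrained ordination axes of a community matrix.

    ``eigenvalues`` are the constrained axes' inertia contributions;
    ``proportion_explained`` divides by the total inertia of the
    correspondence analysis, so the percentages are invariant to score
    scaling.  Site scores use Hill's scaling (inter-sample distance focus):
    the weighted-average scores divided by sqrt(1 - eigenvalue).
    """

    eigenvalues: np.ndarray
    total_inertia: float
    site_scores: np.ndarray
    species_scores: np.ndarray
    p_value: float | None = None

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia


def downweight_rare(species: np.ndarray, fraction: float = 5.0) -> np.ndarray:
    """Down-weight rare species columns, CANOCO style.

    A species occurring in fewer than (max frequency / `fraction`) samples
    has its column multiplied by frequency / (max frequency / `fraction`).
    """
    species = np.asarray(species, dtype=float)
    freq = (species > 0).sum(axis=0).astype(float)
    lim = freq.max() / fraction
    weights = np.ones_like(freq)
    rare = freq < lim
    weights[rare] = freq[rare] / lim
    return species * weights[None, :]


def _cca_core(species: np.ndarray, env: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    y = np.asarray(species, dtype=float)
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)  # site weights
    c = p.sum(axis=0)  # species weights
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("species matrix must have positive row and column sums")
    # chi-square standardized residuals
    expected = np.outer(r, c)
    q = (p - expected) / np.sqrt(expected)
    # weighted projection of q's site space onto the predictors
    x = np.asarray(env, dtype=float)
    xw = x - (r @ x)[None, :]  # weighted centering
    xr = xw * np.sqrt(r)[:, None]
    u_x, s_x, _ = np.linalg.svd(xr, full_matrices=False)
    rank = int((s_x > s_x[0] * 1e-10).sum()) if s_x.size else 0
    if rank < xr.shape[1]:
        raise np.linalg.LinAlgError("predictor matrix is rank deficient (collinear columns)")
    proj = u_x[:, :rank]
    q_fit = proj @ (proj.T @ q)
    u, s, vt = np.linalg.svd(q_fit, full_matrices=False)
    eig = s**2
    keep = eig > 1e-12
    return eig[keep], float((q**2).sum()), u[:, keep], vt[keep, :], (r, c, s[keep])


def cca(
    species: np.ndarray,
    env: np.ndarray,
    downweight: bool = False,
    env_names: list[str] | None = None,
) -> CcaResult:
    """Canonical correspondence analysis (chi-square metric, weighted projection).

    The community matrix is chi-square transformed, its site dimension is
    projected onto the span of the (weighted-centered) environmental
    predictors, and the projected matrix is eigen-decomposed.  Constrained
    eigenvalues, their share of total inertia, Hill-scaled site scores and
    species scores are returned.

    Raises a collinearity error for rank-deficient predictors, naming the
    offending column when it can be identified.
    """
    species = np.asarray(species, dtype=float)
    env = np.asarray(env, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    n, m = species.shape
    if env.shape[0] != n:
        raise ValueError("species and env must have the same number of samples")
    if n <= env.shape[1]:
        raise ValueError("need more samples than predictors")
    if np.any(species < 0):
        raise ValueError("species abundances must be non-negative")
    if downweight:
        species = downweight_rare(species)
    try:
        eig, total, u, vt, (r, c, s) = _cca_core(species, env)
    except np.linalg.LinAlgError:
        # identify the offending predictor for the error message
        names = env_names or [f"env{j}" for j in range(env.shape[1])]
        for j in range(1, env.shape[1]):
            sub = env[:, : j + 1]
            if np.linalg.matrix_rank(sub - sub.mean(axis=0)) <= j:
                raise ValueError(
                    f"collinear predictor column: {names[j]!r}"
                ) from None
        raise ValueError("collinear predictor columns") from None
    # weighted-average (WA) site scores, then Hill's scaling: divide by
    # sqrt(1 - lambda) to focus the biplot on inter-sample distances
    site = (u / np.sqrt(r)[:, None]) * s[None, :]
    hill = site / np.sqrt(np.clip(1.0 - eig, 1e-12, None))[None, :]
    species_scores = (vt / np.sqrt(c)[None, :]).T
    return CcaResult(
        eigenvalues=eig,
        total_inertia=total,
        site_scores=hill,
        species_scores=species_scores,
    )


def cca_permutation_test(
    species: np.ndarray,
    env: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    downweight: bool = False,
) -> tuple[float, CcaResult]:
    """Monte Carlo permutation test of the constrained inertia.

    The statistic is the trace (sum of constrained eigenvalues); sample rows
    of `env` are permuted `n_perm` times and the p-value follows the
    add-one convention p = (1 + #{trace_perm >= trace_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    species = np.asarray(species, dtype=float)
    env = np.asarray(env, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    if downweight:
        species = downweight_rare(species)
    result = cca(species, env)
    observed = float(result.eigenvalues.sum())
    rng = np.random.default_rng(seed)
    n = species.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        eig, _, _, _, _ = _cca_core(species, env[perm])
        count += float(eig.sum()) >= observed - 1e-12
    p = (1 + count) / (1 + n_perm)
    result = CcaResult(
        eigenvalues=result.eigenvalues,
        total_inertia=result.total_inertia,
        site_scores=result.site_scores,
        species_scores=result.species_scores,
        p_value=p,
    )
    return p, result
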