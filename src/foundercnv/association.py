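"""Association statistics for founder-population case-control studies.

The centre-piece is the relatedness-corrected allelic chi-square: in a
pedigree the allele-frequency contrast between cases and controls has
null variance inflated by the kinship structure, and the corrected test
replaces the binomial variance with the quadratic form c' (2 Phi) c in
the additive relationship matrix.  Around it sit the allelic odds ratio
with binomial frequency standard errors, the Wilcoxon rank-sum test for
multi-allelic copy numbers (exact by full enumeration over group
assignments when feasible), the Cochran-Mantel-Haenszel stratified
combination for replication cohorts, a population-frequency comparison,
and a SKAT-O-style covariate-adjusted variance-component/burden set test
over a grid of mixing parameters rho with moment-matched analytic
per-rho p-values and a permutation-calibrated minimum-p combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

__all__ = [
    "AssociationResult",
    "AllelicOr",
    "DegenerateDataError",
    "allelic_or",
    "corrected_chisq_test",
    "wilcoxon_cn_test",
    "cmh_combined",
    "compare_population_frequencies",
    "set_score_test",
    "bonferroni",
]


class DegenerateDataError(ValueError):
    """Input too degenerate for the requested statistic (all-zero margins,
    singular variance, perfect separation)."""


@dataclass
class AssociationResult:
    target_id: str
    statistic: float
    p_value: float
    odds_ratio: float | None
    case_freq: float | None
    control_freq: float | None
    test: str
    tail: str = "two_sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (
            math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0
        ):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Allelic odds ratio with binomial standard errors
# ---------------------------------------------------------------------------


@dataclass
class AllelicOr:
    odds_ratio: float  # math.inf sentinel when the control frequency is 0
    case_freq: float
    control_freq: float
    se_case: float | None = None  # only available from counts
    se_control: float | None = None


def _freq_and_se(value) -> tuple[float, float | None]:
    if isinstance(value, (tuple, list)):
        count, n_alleles = value
        if n_alleles <= 0 or not 0 <= count <= n_alleles:
            raise ValueError("counts must satisfy 0 <= count <= n_alleles")
        f = count / n_alleles
        return f, math.sqrt(f * (1 - f) / n_alleles)
    f = float(value)
    if not 0.0 <= f <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return f, None


def allelic_or(case, control, haldane: bool = False) -> AllelicOr:
    """Allelic odds ratio between case and control allele frequencies.

    Each argument is either a frequency in [0, 1] or a ``(carrier_alleles,
    total_alleles)`` count pair; with counts the binomial standard error
    sqrt(f(1-f)/n) of each frequency is also reported.  A zero control
    frequency yields an explicit infinite-OR sentinel (rendered "Inf" in
    reports) unless ``haldane=True`` applies the 0.5-count correction,
    which requires count input.
    """
    f_case, se_case = _freq_and_se(case)
    f_ctrl, se_ctrl = _freq_and_se(control)
    if haldane:
        if not (isinstance(case, (tuple, list)) and isinstance(control, (tuple, list))):
            raise ValueError("Haldane-Anscombe correction requires count input")
        a, na = case
        b, nb = control
        odds_case = (a + 0.5) / (na - a + 0.5)
        odds_ctrl = (b + 0.5) / (nb - b + 0.5)
        return AllelicOr(odds_case / odds_ctrl, f_case, f_ctrl, se_case, se_ctrl)
    if f_ctrl == 0.0:
        or_ = math.inf if f_case > 0 else math.nan
    elif f_case == 1.0 or f_ctrl == 1.0:
        or_ = math.inf if f_ctrl < 1.0 else math.nan
    else:
        or_ = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
    return AllelicOr(or_, f_case, f_ctrl, se_case, se_ctrl)


# ---------------------------------------------------------------------------
# Kinship-corrected allelic chi-square
# ---------------------------------------------------------------------------


def corrected_chisq_test(
    allele_counts: Sequence[int] | pd.Series,
    phenotype: Sequence | pd.Series,
    kinship=None,
    target_id: str = "",
) -> AssociationResult:
    """Allelic case-control chi-square with kinship-corrected variance.

    With ``x_i`` the 0/1/2 allele count, the statistic contrasts the case
    and control allele frequencies, Delta = (1/2n_A) sum_cases x_i -
    (1/2n_U) sum_controls x_i, against the quasi-likelihood null variance
    Var(Delta) = (p(1-p)/2) c' (2 Phi) c, where c_i = 1/n_A for cases and
    -1/n_U for controls, p is the pooled allele frequency, and Phi is the
    kinship matrix.  Delta^2 / Var(Delta) is referred to chi-square with
    one degree of freedom.  ``kinship=None`` uses Phi = I/2 (unrelated
    samples), in which case the statistic equals the classical allelic
    chi-square exactly.

    ``phenotype`` may hold booleans (True = case) or the labels
    "asthma"/"control"; other labels (unknown, BHR-only) are excluded.
    """
    x = np.asarray(allele_counts, dtype=float)
    pheno = np.asarray(phenotype)
    if pheno.dtype == bool:
        is_case = pheno
        keep = np.ones(len(pheno), dtype=bool)
    else:
        is_case = pheno == "asthma"
        keep = is_case | (pheno == "control")
    if kinship is None:
        phi2 = np.eye(int(keep.sum()))
    else:
        mat = kinship.matrix if hasattr(kinship, "matrix") else np.asarray(kinship)
        phi2 = 2.0 * mat[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
    x = x[keep]
    is_case = is_case[keep]

    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need at least one case and one control")

    f_case = x[is_case].sum() / (2 * n_case)
    f_ctrl = x[~is_case].sum() / (2 * n_ctrl)
    p_hat = x.sum() / (2 * len(x))

    if p_hat in (0.0, 1.0):
        return AssociationResult(
            target_id, 0.0, 1.0, 1.0, f_case, f_ctrl,
            "corrected_chisq", extra={"monomorphic": True},
        )

    c = np.where(is_case, 1.0 / n_case, -1.0 / n_ctrl)
    var = (p_hat * (1 - p_hat) / 2.0) * float(c @ phi2 @ c)
    if var <= 0:
        raise DegenerateDataError("singular kinship-corrected variance")
    delta = f_case - f_ctrl
    statistic = delta**2 / var
    p_value = float(stats.chi2.sf(statistic, df=1))
    return AssociationResult(
        target_id,
        float(statistic),
        p_value,
        allelic_or(f_case, f_ctrl).odds_ratio,
        f_case,
        f_ctrl,
        "corrected_chisq" if kinship is not None else "allelic_chisq",
        extra={"n_case": n_case, "n_control": n_ctrl, "pooled_freq": p_hat},
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum for multi-allelic copy numbers
# ---------------------------------------------------------------------------

_EXACT_ENUMERATION_LIMIT = 200_000


def _rank_sum_exact_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration over group assignments.

    Midranks handle ties, so the null distribution is the exact
    permutation distribution of the rank sum conditional on the observed
    (possibly tied) values.

    Two-sided means twice the smaller one-sided tail (capped at 1), the
    same convention as the tie-corrected normal approximation, so the
    exact and approximate paths agree in the large-sample limit even when
    ties make the permutation distribution asymmetric.
    """
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(case)
    observed = ranks[:n1].sum()
    ge = le = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        t = ranks[list(idx)].sum()
        if t >= observed - 1e-9:
            ge += 1
        if t <= observed + 1e-9:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def wilcoxon_cn_test(
    case_cn: Sequence[float],
    control_cn: Sequence[float],
    target_id: str = "",
) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum comparison of copy numbers.

    Used for multi-allelic CNVs where an allelic 2x2 contrast is not
    defined.  Small samples (<= 200k distinct group assignments) get an
    exact enumeration p-value; larger ones the tie-corrected normal
    approximation.
    """
    case = np.asarray(list(case_cn), dtype=float)
    control = np.asarray(list(control_cn), dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    u_stat = float(
        stats.mannwhitneyu(case, control, alternative="two-sided", method="asymptotic").statistic
    )
    if comb(case.size + control.size, case.size, exact=True) <= _EXACT_ENUMERATION_LIMIT:
        p = _rank_sum_exact_p(case, control)
        method = "exact_enumeration"
    else:
        p = float(
            stats.mannwhitneyu(case, control, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "normal_tie_corrected"
    return AssociationResult(
        target_id, u_stat, float(p), None, None, None,
        "wilcoxon_rank_sum", extra={"method": method},
    )


# ---------------------------------------------------------------------------
# Cochran-Mantel-Haenszel stratified combination
# ---------------------------------------------------------------------------


def cmh_combined(
    strata: Sequence,
    tail: str = "two_sided",
    risk_direction: str = "case_enriched",
    target_id: str = "",
) -> AssociationResult:
    """Cochran-Mantel-Haenszel common odds ratio and chi-square.

    ``strata`` holds 2x2 allele-count tables (objects with a ``.table``
    attribute, e.g. :class:`foundercnv.simulate.StratumTable`, or raw
    ``[[a, b], [c, d]]`` arrays with rows = case/control and columns =
    carrier/non-carrier).  Strata with a zero margin contribute nothing
    and are dropped with a note; if all are degenerate the combination is
    an error state.  The chi-square uses the score-type variance
    r1 r2 c1 c2 / N^3 (no continuity correction), which makes the
    single-stratum statistic reduce exactly to the uncorrected Pearson
    chi-square on that table.  One-sided p halves the two-sided p when the
    pooled odds ratio points in the configured risk direction
    (``case_enriched``: OR > 1), else it is its complement.
    """
    if tail not in ("two_sided", "one_sided"):
        raise ValueError("tail must be two_sided or one_sided")
    tables = []
    dropped = []
    for k, s in enumerate(strata):
        t = np.asarray(s.table if hasattr(s, "table") else s, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
        if min(margins) <= 0:
            dropped.append(getattr(s, "label", str(k)))
            continue
        tables.append(t)
    if not tables:
        raise DegenerateDataError("all strata have a zero margin")

    num = 0.0  # sum of (a - E[a])
    var = 0.0
    or_num = 0.0
    or_den = 0.0
    a_total = b_total = c_total = d_total = 0.0
    for t in tables:
        a, b = t[0]
        c, d = t[1]
        n = t.sum()
        num += a - (a + b) * (a + c) / n
        var += (a + b) * (c + d) * (a + c) * (b + d) / n**3
        or_num += a * d / n
        or_den += b * c / n
        a_total += a
        b_total += b
        c_total += c
        d_total += d
    statistic = num**2 / var
    p_two = float(stats.chi2.sf(statistic, df=1))
    or_mh = math.inf if or_den == 0 else or_num / or_den
    if tail == "one_sided":
        matches = or_mh > 1.0 if risk_direction == "case_enriched" else or_mh < 1.0
        p = p_two / 2.0 if matches else 1.0 - p_two / 2.0
    else:
        p = p_two
    return AssociationResult(
        target_id,
        float(statistic),
        p,
        or_mh,
        a_total / (a_total + b_total),
        c_total / (c_total + d_total),
        "cmh",
        tail=tail,
        extra={"n_strata": len(tables), "dropped_strata": dropped, "p_two_sided": p_two},
    )


# ---------------------------------------------------------------------------
# Population frequency comparison
# ---------------------------------------------------------------------------


def compare_population_frequencies(
    freqs_a: Sequence[float],
    freqs_b: Sequence[float],
    diff_threshold: float = 0.4,
) -> dict:
    """Squared Pearson correlation and frequency differences between
    matched per-locus allele frequencies of two populations."""
    a = np.asarray(list(freqs_a), dtype=float)
    b = np.asarray(list(freqs_b), dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired loci")
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise DegenerateDataError("zero variance in a frequency vector")
    r = float(np.corrcoef(a, b)[0, 1])
    abs_diff = np.abs(a - b)
    return {
        "r_squared": r**2,
        "abs_diff": abs_diff,
        "n_exceeding": int((abs_diff > diff_threshold).sum()),
        "threshold": diff_threshold,
    }


# ---------------------------------------------------------------------------
# SKAT-O-style covariate-adjusted set test
# ---------------------------------------------------------------------------


def _liu_pvalue(q: float | np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Moment-matched p-value for Q = sum lambda_j chi2_1j (Liu-Tang-Zhang).

    Matches the first four cumulants of the weighted chi-square mixture to
    a (non-central) chi-square; exact when a single eigenvalue is present.
    """
    lam = np.asarray(lambdas, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2 if s2 > 0 else 1.0
    q = np.asarray(q, dtype=float)
    t_star = (q - c1) / math.sqrt(2 * c2)
    x = t_star * math.sqrt(2 * (df + 2 * delta)) + (df + delta)
    if delta > 0:
        return stats.ncx2.sf(x, df, delta)
    return stats.chi2.sf(x, df)


def _fit_null_logistic(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Null logistic model of phenotype on covariates; returns (mu, X)."""
    import statsmodels.api as sm

    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        X = np.column_stack([X, covariates])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit()
    except Exception as err:  # pragma: no cover - separation diagnostics
        raise DegenerateDataError(f"null logistic fit failed: {err}") from err
    mu = np.asarray(fit.fittedvalues, dtype=float)
    if np.any(mu <= 1e-10) or np.any(mu >= 1 - 1e-10):
        raise DegenerateDataError(
            "separation in null logistic fit (fitted probabilities at 0/1)"
        )
    return mu, X


def set_score_test(
    genotypes: np.ndarray | pd.DataFrame,
    phenotype: Sequence,
    covariates: np.ndarray | pd.DataFrame | None = None,
    weights: Sequence[float] | None = None,
    rho_grid: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
    n_permutations: int = 999,
    seed: int = 0,
    target_id: str = "",
) -> AssociationResult:
    """Variance-component/burden set test over a grid of mixing parameters.

    The null model is a logistic regression of case status on the
    covariates (global and transcript-local ancestry proportions in the
    intended application).  With per-variant scores S_j = sum_i
    (y_i - mu_i) g_ij, the test statistic at mixing parameter rho is
    Q_rho = (1 - rho) sum_j w_j^2 S_j^2 + rho (sum_j w_j S_j)^2 — pure
    variance-component (SKAT) at rho = 0, pure burden at rho = 1.  Each
    Q_rho is referred to its moment-matched weighted chi-square-mixture
    null; the reported p-value is the minimum over the grid, calibrated by
    permuting the null-model residuals (``n_permutations`` draws, seeded),
    so the grid search costs no anti-conservativeness.  A single-element
    grid returns the analytic per-rho p directly.  Variants are weighted
    equally by default.  Missing genotypes (NaN) are mean-imputed.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotypes must be a samples x variants matrix")
    n, m = G.shape
    if m == 0:
        return AssociationResult(
            target_id, math.nan, math.nan, None, None, None,
            "set_score_test", extra={"testable": False, "reason": "no qualifying variants"},
        )
    pheno = np.asarray(phenotype)
    y = pheno.astype(float) if pheno.dtype != object else (pheno == "asthma").astype(float)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
    # mean-impute missing genotype calls
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)

    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValueError("weights must be one per variant")

    mu, X = _fit_null_logistic(y, covariates)
    v = mu * (1 - mu)
    # project covariates out of the genotypes (weighted least squares)
    XtWX = X.T @ (X * v[:, None])
    beta = np.linalg.pinv(XtWX) @ (X.T @ (G * v[:, None]))
    G_tilde = G - X @ beta
    V = G_tilde.T @ (G_tilde * v[:, None])  # null covariance of scores
    resid = y - mu
    S = G_tilde.T @ resid

    rho_grid = list(rho_grid)
    lambdas_by_rho = []
    for rho in rho_grid:
        M = (1 - rho) * np.diag(w**2) + rho * np.outer(w, w)
        # eigenvalues of M^{1/2} V M^{1/2} = eig of M V (symmetric similarity)
        evals, evecs = np.linalg.eigh(M)
        evals = np.clip(evals, 0, None)
        root = evecs @ np.diag(np.sqrt(evals)) @ evecs.T
        lam = np.linalg.eigvalsh(root @ V @ root)
        lam = lam[lam > 1e-10 * max(lam.max(), 1.0)]
        if lam.size == 0:
            raise DegenerateDataError("score covariance is singular")
        lambdas_by_rho.append(lam)

    def q_values(scores: np.ndarray) -> list[np.ndarray]:
        # scores: m x k matrix of per-variant score vectors
        ws = w[:, None] * scores
        burden = ws.sum(axis=0) ** 2
        skat = (ws**2).sum(axis=0)
        return [(1 - rho) * skat + rho * burden for rho in rho_grid]

    q_obs = q_values(S[:, None])
    p_by_rho = {
        rho: float(_liu_pvalue(q[0], lam))
        for rho, q, lam in zip(rho_grid, q_obs, lambdas_by_rho)
    }
    p_min_obs = min(p_by_rho.values())

    if len(rho_grid) == 1:
        p_combined = p_min_obs
    else:
        rng = np.random.default_rng(seed)
        perm = np.empty((n, n_permutations))
        for b in range(n_permutations):
            perm[:, b] = resid[rng.permutation(n)]
        S_perm = G_tilde.T @ perm  # m x B
        q_perm = q_values(S_perm)
        p_perm = np.min(
            [
                _liu_pvalue(q, lam)
                for q, lam in zip(q_perm, lambdas_by_rho)
            ],
            axis=0,
        )
        p_combined = (1 + int((p_perm <= p_min_obs + 1e-15).sum())) / (n_permutations + 1)

    is_case = y > 0.5
    carriers = (G > 0.5).any(axis=1)
    case_rate = float(carriers[is_case].mean()) if is_case.any() else None
    ctrl_rate = float(carriers[~is_case].mean()) if (~is_case).any() else None
    return AssociationResult(
        target_id,
        float(q_obs[-1][0]),
        float(p_combined),
        None,
        case_rate,
        ctrl_rate,
        "set_score_test",
        extra={
            "testable": True,
            "p_by_rho": p_by_rho,
            "p_min": p_min_obs,
            "rho_grid": rho_grid,
            "n_variants": m,
            "n_permutations": n_permutations if len(rho_grid) > 1 else 0,
        },
    )


def bonferroni(p_value: float, n_transcripts: int, n_modes: int = 2) -> float:
    """Bonferroni adjustment over transcripts x test modes, capped at 1."""
    return min(1.0, p_value * n_transcripts * n_modes)
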