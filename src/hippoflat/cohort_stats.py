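"""Subject stratification and cohort statistics.

Implements the gene-environment analysis design: subjects are stratified
into three genetic-risk levels from APOE genotype and first-degree family
history, split into lower/higher education groups at the cohort mean, and
mean medial-temporal cortical thickness is modelled by a two-factor ANCOVA

    thickness_mean ~ education_group * risk_level + age + gender

with sum-to-zero factor coding and Type III F tests (the education x risk
interaction is the quantity of interest; with n=54 complete subjects the
residual df is 46).  Post-hoc, education-thickness Pearson correlations are
computed per risk stratum and subregion.  Demographic group comparisons use
Pearson chi-square (no continuity correction) for categorical rows and a
pooled two-sample t test for continuous summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import SUBREGION_NAMES

VALID_GENOTYPES = ("2/2", "2/3", "2/4", "3/3", "3/4", "4/4")
RISK_LEVELS = ("low", "intermediate", "high")

#: model terms and the number of design columns each occupies
_TERMS = (("education", 1), ("risk", 2), ("age", 1), ("gender", 1), ("education_x_risk", 2))
N_DESIGN_COLUMNS = 1 + sum(k for _, k in _TERMS)  # intercept + terms = 8


class RankDeficiencyError(ValueError):
    """Raised when an education x risk cell is empty."""


class InsufficientDataError(ValueError):
    """Raised when too few subjects remain to fit the model."""


def assign_risk_level(genotype: str, family_history: bool) -> str:
    """Composite genetic-risk level from APOE genotype and family history.

    high: ε4 homozygous, or ε4 carrier with a positive family history;
    intermediate: one risk factor (ε4 heterozygous without family history,
    or family history without ε4); low: neither.
    """
    if genotype not in VALID_GENOTYPES:
        raise ValueError(
            f"unknown APOE genotype {genotype!r}; expected one of {VALID_GENOTYPES}")
    n_e4 = genotype.split("/").count("4")
    if n_e4 == 2 or (n_e4 >= 1 and family_history):
        return "high"
    if n_e4 >= 1 or family_history:
        return "intermediate"
    return "low"


def assign_education_group(education_years: float, cohort_mean: float) -> str:
    """Below the cohort mean -> 'lower'; at or above -> 'higher'."""
    return "lower" if education_years < cohort_mean else "higher"


@dataclass
class ModelFit:
    terms: pd.DataFrame          # name, F, df1, df2, p
    coefficients: pd.Series
    n_used: int
    residual_df: int
    residual_ss: float

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("name").loc[name]


def build_design_matrix(cohort: pd.DataFrame) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Sum-to-zero-coded design for the two-factor ANCOVA.

    Columns: intercept | education (higher +1 / lower -1) | risk (2 columns,
    'high' as the implicitly coded level) | age | gender (female +1) |
    education x risk (2 columns).  Returns the matrix, column names, and the
    column indices of each testable term.
    """
    edu = np.where(cohort["education_group"].to_numpy() == "higher", 1.0, -1.0)
    rl = cohort["risk_level"].to_numpy()
    r1 = np.where(rl == "low", 1.0, np.where(rl == "high", -1.0, 0.0))
    r2 = np.where(rl == "intermediate", 1.0, np.where(rl == "high", -1.0, 0.0))
    age = cohort["age_years"].to_numpy(float)
    gender = np.where(cohort["gender"].to_numpy() == "female", 1.0, -1.0)
    X = np.column_stack([
        np.ones(len(cohort)), edu, r1, r2, age, gender, edu * r1, edu * r2,
    ])
    names = ["intercept", "education", "risk[low]", "risk[intermediate]",
             "age", "gender", "education:risk[low]", "education:risk[intermediate]"]
    cols = {"education": [1], "risk": [2, 3], "age": [4], "gender": [5],
            "education_x_risk": [6, 7]}
    return X, names, cols


def fit_education_risk_glm(cohort: pd.DataFrame) -> ModelFit:
    """Fixed-effects ANCOVA with Type III F tests for every term.

    Uses MRI-available subjects only.  Each term's F compares the full
    least-squares fit against the fit with that term's sum-to-zero columns
    removed (a partial, order-independent test).  Denominator df is
    ``n_used - 8``.
    """
    data = cohort[cohort["mri_available"]] if "mri_available" in cohort else cohort
    n = len(data)
    if n <= N_DESIGN_COLUMNS:
        raise InsufficientDataError(
            f"need more than {N_DESIGN_COLUMNS} MRI-available subjects, got {n}")
    cells = data.groupby(["education_group", "risk_level"], observed=True).size()
    for eg in ("lower", "higher"):
        for rl in RISK_LEVELS:
            if cells.get((eg, rl), 0) == 0:
                raise RankDeficiencyError(
                    f"empty design cell: education={eg}, risk={rl}")

    y = data["thick_mean"].to_numpy(float)
    X, names, cols = build_design_matrix(data)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    resid = y - X @ beta
    sse_full = float(resid @ resid)
    df_res = n - X.shape[1]
    # degenerate fit (e.g. constant response): every term is null
    degenerate = sse_full <= 1e-12 * max(1.0, float(y @ y))

    rows = []
    for term, k in _TERMS:
        keep = [i for i in range(X.shape[1]) if i not in cols[term]]
        beta_r, *_ = np.linalg.lstsq(X[:, keep], y, rcond=None)
        r = y - X[:, keep] @ beta_r
        sse_r = float(r @ r)
        if degenerate:
            F, p = 0.0, 1.0
        else:
            F = max((sse_r - sse_full) / k / (sse_full / df_res), 0.0)
            p = f_pvalue(F, k, df_res)
        rows.append({"name": term, "F": F, "df1": k, "df2": df_res, "p": p})

    return ModelFit(
        terms=pd.DataFrame(rows),
        coefficients=pd.Series(beta, index=names),
        n_used=n,
        residual_df=df_res,
        residual_ss=sse_full,
    )


def f_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if F < 0:
        raise ValueError(f"F statistic must be nonnegative, got {F}")
    return float(stats.f.sf(F, df1, df2))


def subgroup_correlations(cohort: pd.DataFrame) -> pd.DataFrame:
    """Education-thickness Pearson correlations per risk level and subregion.

    Rows cover each subregion plus the across-subregion mean ('combined');
    two-sided p-values via the t transform with df = n - 2.  Strata with
    fewer than 3 MRI-available subjects are flagged not estimable (NaN).
    """
    data = cohort[cohort["mri_available"]] if "mri_available" in cohort else cohort
    targets = {name: f"thick_{name}" for name in SUBREGION_NAMES}
    targets["combined"] = "thick_mean"
    rows = []
    for rl in RISK_LEVELS:
        sub = data[data["risk_level"] == rl]
        for name, col in targets.items():
            n = len(sub)
            if n < 3 or sub["education_years"].nunique() < 2:
                rows.append({"risk_level": rl, "subregion": name, "r": np.nan,
                             "n": n, "p": np.nan, "estimable": False})
                continue
            r, p = stats.pearsonr(sub["education_years"], sub[col])
            rows.append({"risk_level": rl, "subregion": name, "r": float(r),
                         "n": n, "p": float(p), "estimable": True})
    return pd.DataFrame(rows)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df=1, no continuity correction."""
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square is undefined for a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Two-sided pooled-variance t test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def build_table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographic summary table by education group with per-row tests.

    Continuous rows (age, education, MMSE): group mean ± SD and a pooled t
    test; categorical rows (gender, APOE genotypes, family history): counts
    and a chi-square test of that category against the rest.  Tests with a
    zero margin are flagged rather than computed.
    """
    g = {name: cohort[cohort["education_group"] == name] for name in ("lower", "higher")}
    n_l, n_h = len(g["lower"]), len(g["higher"])
    rows = [{"row": "N", "lower": n_l, "lower_sd": "", "higher": n_h,
             "higher_sd": "", "p": "", "test": ""}]

    def cont_row(label, col):
        m = [g[k][col].mean() for k in ("lower", "higher")]
        s = [g[k][col].std(ddof=1) for k in ("lower", "higher")]
        try:
            _, _, p = two_sample_t_from_summary(m[0], s[0], n_l, m[1], s[1], n_h)
            p_txt, test = round(p, 3), "pooled t"
        except ValueError as e:
            p_txt, test = "", f"not computed ({e})"
        rows.append({"row": label, "lower": round(m[0], 1), "lower_sd": round(s[0], 1),
                     "higher": round(m[1], 1), "higher_sd": round(s[1], 1),
                     "p": p_txt, "test": test})

    def cat_row(label, in_lower, in_higher):
        table = [[in_lower, n_l - in_lower], [in_higher, n_h - in_higher]]
        try:
            _, p = chi_square_2x2(table)
            p_txt, test = round(p, 3), "chi-square"
        except ValueError as e:
            p_txt, test = "", f"not computed ({e})"
        rows.append({"row": label, "lower": in_lower, "lower_sd": "",
                     "higher": in_higher, "higher_sd": "", "p": p_txt, "test": test})

    cont_row("Age (years)", "age_years")
    cat_row("Female sex (no.)",
            int((g["lower"]["gender"] == "female").sum()),
            int((g["higher"]["gender"] == "female").sum()))
    cont_row("Education (years)", "education_years")
    for geno in ("2/3", "3/3", "3/4", "4/4"):
        cat_row(f"APOE {geno} (no.)",
                int((g["lower"]["apoe_genotype"] == geno).sum()),
                int((g["higher"]["apoe_genotype"] == geno).sum()))
    cat_row("First-degree family history (no.)",
            int(g["lower"]["family_history"].sum()),
            int(g["higher"]["family_history"].sum()))
    cont_row("MMSE (0-30)", "mmse")
    return pd.DataFrame(rows)
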