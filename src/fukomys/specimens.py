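"""Specimen tables and the univariate/multivariate statistics of the study.

The packaged collection table (one row per animal: species, site, colony,
sex, body weight in grams, tooth-wear age class) drives the body-size
summaries and the sexual-dimorphism t test; craniometric matrices feed the
MANOVA/ANOVA machinery.

Sex codes: M, F definite; M?, F? tentative (counted with their base sex);
BrF breeding female (counted female); na unknown (excluded from sex-based
tests).  Age class 1 is young; "adult" filters exclude known class 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

MALE_CODES = {"M", "M?"}
FEMALE_CODES = {"F", "F?", "BrF"}


def load_specimen_table(path=None) -> pd.DataFrame:
    """Load a specimen CSV (defaults to the packaged collection table).

    Columns: species, sample_qmul, location, lat, lon, altitude_m, colony,
    sex, body_weight_g, age_class, accession, haplotype, specimen_type.
    Missing values are encoded as 'na' in sex and empty cells elsewhere.
    """
    if path is None:
        path = resources.files("fukomys.data") / "specimens_table1.csv"
    df = pd.read_csv(path, dtype={"colony": "string", "sex": "string"})
    df["body_weight_g"] = pd.to_numeric(df["body_weight_g"], errors="coerce")
    df["age_class"] = pd.to_numeric(df["age_class"], errors="coerce")
    return df


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float | None
    minimum: float
    maximum: float


def group_summary(df: pd.DataFrame, mask) -> GroupSummary:
    """n, mean, SEM (sample sd / sqrt(n)) and range of body weight.

    ``mask`` is a boolean Series/array selecting rows; rows without a weight
    are dropped after filtering.  A single record has no SEM (returned as
    None).
    """
    sel = df.loc[np.asarray(mask, dtype=bool), "body_weight_g"].dropna()
    if sel.empty:
        raise StatsError("no records with a body weight pass the filter")
    n = int(sel.size)
    sem = float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return GroupSummary(
        n=n,
        mean=float(sel.mean()),
        sem=sem,
        minimum=float(sel.min()),
        maximum=float(sel.max()),
    )


def adult_mask(df: pd.DataFrame, species: str, rule: str) -> pd.Series:
    """Adult filters: 'exclude_class1' keeps unknown-age animals (rows whose
    age class is not a known 1); 'class2_plus' requires a known class >= 2."""
    base = df["species"] == species
    if rule == "exclude_class1":
        return base & (df["age_class"].isna() | (df["age_class"] != 1))
    if rule == "class2_plus":
        return base & (df["age_class"] >= 2)
    raise ValueError(f"unknown adult rule {rule!r}")


def sex_mask(df: pd.DataFrame, sex: str) -> pd.Series:
    codes = MALE_CODES if sex == "male" else FEMALE_CODES
    return df["sex"].isin(codes)


@dataclass
class StatResult:
    name: str
    value: float
    df: tuple
    p_value: float
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def pooled_t_test(weights_a, weights_b) -> StatResult:
    """Two-sided Student's two-sample t test with pooled variance."""
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        return StatResult("t", 0.0, (len(a) + len(b) - 2,), 1.0)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        raise StatsError("zero pooled variance; t statistic undefined")
    return StatResult("t", float(t), (len(a) + len(b) - 2,), float(p))


def manova_pillai(responses, groups) -> StatResult:
    """One-way MANOVA: Pillai's trace with its standard approximate F.

    ``responses`` is (n, p); rows must be complete cases.  Pillai's trace
    ``V = tr(H (H+E)^-1)`` uses the between-group (H) and within-group (E)
    cross-product matrices; the F approximation is the conventional one with
    ``s = min(p, g-1)`` and df ``(s(2m+s+1), s(2n'+s+1))``, which reduces
    exactly to the one-way ANOVA F when p = 1.
    """
    y = np.asarray(responses, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2:
        raise StatsError("responses must be a 2-D matrix")
    if np.any(~np.isfinite(y)):
        raise StatsError("responses must be complete cases (no missing values)")
    levels = pd.unique(groups)
    g = len(levels)
    if g < 2:
        raise StatsError("MANOVA needs at least two groups")
    n, p = y.shape
    grand = y.mean(axis=0)
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for lev in levels:
        block = y[groups == lev]
        diff = block.mean(axis=0) - grand
        h += len(block) * np.outer(diff, diff)
        centered = block - block.mean(axis=0)
        e += centered.T @ centered
    try:
        v = float(np.trace(np.linalg.solve(h + e, h)))
    except np.linalg.LinAlgError as exc:
        raise StatsError(
            "singular within-group covariance; reduce the number of "
            "response variables"
        ) from exc
    s = min(p, g - 1)
    m = (abs(p - (g - 1)) - 1) / 2
    n_prime = (n - g - p - 1) / 2
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_prime + s + 1)
    if df2 <= 0:
        raise StatsError("not enough residual degrees of freedom for MANOVA")
    ratio = v / s
    f = (df2 / df1) * ratio / (1 - ratio) if ratio < 1 else np.inf
    p_value = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return StatResult("Pillai's trace", v, (float(df1), float(df2)), p_value)


def anova_tukey_bonferroni(
    responses: pd.DataFrame, groups, m_tests: int | None = None
) -> pd.DataFrame:
    """Per-variable one-way ANOVA with Tukey HSD and Bonferroni adjustment.

    Returns one row per (variable, pairwise comparison) with the ANOVA F/p
    for the variable, the Tukey-adjusted pairwise p, and the Bonferroni
    correction ``min(1, m * p)`` across the ``m_tests`` variables tested
    (default: the number of variable columns).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = pd.Series(np.asarray(groups))
    counts = groups.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        import warnings

        warnings.warn(f"groups with n<2 excluded: {small}")
        keep = ~groups.isin(small).to_numpy()
        responses = responses.loc[keep]
        groups = groups[keep]
    if m_tests is None:
        m_tests = responses.shape[1]
    rows = []
    for var in responses.columns:
        y = responses[var].to_numpy(dtype=float)
        samples = [y[groups.to_numpy() == g] for g in groups.unique()]
        f, p = sps.f_oneway(*samples)
        tk = pairwise_tukeyhsd(y, groups.to_numpy())
        res_df = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        for _, r in res_df.iterrows():
            p_adj_tukey = float(r["p-adj"])
            rows.append(
                {
                    "variable": var,
                    "anova_F": float(f),
                    "anova_p": float(p),
                    "group1": r["group1"],
                    "group2": r["group2"],
                    "mean_diff": float(r["meandiff"]),
                    "tukey_p": p_adj_tukey,
                    "bonferroni_p": min(1.0, m_tests * p_adj_tukey),
                    "significant": min(1.0, m_tests * p_adj_tukey) < 0.05,
                }
            )
    return pd.DataFrame(rows)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def dimorphism_t_test(df: pd.DataFrame, species: str = "F. hanangensis") -> StatResult:
    """Adult male vs female pooled t test on body weight for one species."""
    adults = adult_mask(df, species, "exclude_class1")
    males = df.loc[adults & sex_mask(df, "male"), "body_weight_g"].dropna()
    females = df.loc[adults & sex_mask(df, "female"), "body_weight_g"].dropna()
    return pooled_t_test(males, females)
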