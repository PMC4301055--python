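"""Univariate statistics around the discriminant analysis.

Oral/nasal comparisons of per-individual mean features (two-level
repeated-measures ANOVA, equivalent to a paired t test), Yates-corrected
2x2 chi-squared comparisons of classification rates, Pearson correlations
of features with cube-root body mass, and the sex x body-mass ANCOVA for
calf call variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class FTestResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float


def rm_anova_calltype(
    oral: Sequence[float], nasal: Sequence[float]
) -> FTestResult:
    """Two-level within-subject ANOVA on per-individual mean values.

    With two repeated levels this is exactly the squared paired t test:
    F(1, n-1) = t^2.  Pairs with a missing member must be excluded by the
    caller; NaNs raise.
    """
    oral = np.asarray(oral, dtype=float)
    nasal = np.asarray(nasal, dtype=float)
    if oral.shape != nasal.shape:
        raise ValueError("oral and nasal vectors must pair up one per individual")
    if np.isnan(oral).any() or np.isnan(nasal).any():
        raise ValueError("missing member of an oral/nasal pair")
    n = len(oral)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    d = oral - nasal
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return FTestResult(F=0.0, df1=1, df2=n - 1, p=1.0)
        raise ValueError("zero variance of non-zero differences: F undefined")
    t = d.mean() / (sd / np.sqrt(n))
    F = t ** 2
    return FTestResult(F=float(F), df1=1, df2=n - 1,
                       p=float(sps.f.sf(F, 1, n - 1)))


#: Same computation applied to per-individual percent-correct values.
rm_anova_assignment = rm_anova_calltype


def reconstruct_counts(pct_correct: float, n_calls: int) -> tuple[int, int]:
    """(n_correct, n_incorrect) from a printed percentage and sample size."""
    if not 0 <= pct_correct <= 100:
        raise ValueError("percentage outside [0, 100]")
    n_correct = int(round(pct_correct * n_calls / 100.0))
    return n_correct, n_calls - n_correct


def yates_chi2(table: Sequence[Sequence[int]]) -> Chi2Result:
    """Continuity-corrected 2x2 chi-squared test of independence."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: test undefined")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=True)
    return Chi2Result(chi2=float(chi2), df=int(df), p=float(p))


def compare_assignment_rates(
    pct_a: float, n_a: int, pct_b: float, n_b: int
) -> Chi2Result:
    """Yates chi-squared on correct/incorrect counts reconstructed from two
    printed classification percentages."""
    return yates_chi2([reconstruct_counts(pct_a, n_a),
                       reconstruct_counts(pct_b, n_b)])


def transform_mass(masses: Sequence[float], transform: str = "cube_root"
                   ) -> np.ndarray:
    """Body-mass transform for correlations with linear acoustic dimensions.

    Mass scales with the cube of a linear body dimension, so the default
    is the cube root; a literal log-base-3 option is kept because the
    conventional shorthand "log_3 mass" is ambiguous.
    """
    m = np.asarray(masses, dtype=float)
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    if transform == "cube_root":
        return np.cbrt(m)
    if transform == "log3":
        return np.log(m) / np.log(3.0)
    raise ValueError("transform must be 'cube_root' or 'log3'")


def mass_correlation(
    masses: Sequence[float],
    feature_means: Sequence[float],
    transform: str = "cube_root",
) -> tuple[float, float]:
    """Pearson correlation of per-individual feature means with transformed
    body mass; two-tailed p."""
    x = transform_mass(masses, transform)
    y = np.asarray(feature_means, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ancova_sex_mass(
    features: Sequence[float],
    sex: Sequence[str],
    mass: Sequence[float],
) -> dict[str, FTestResult]:
    """Type-III ANCOVA: sex (fixed categorical), body mass (continuous),
    and their interaction; denominator df = n - 4.

    Returns a dict with keys "sex", "mass", "sex_x_mass".
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(features, dtype=float),
        "sex": list(sex),
        "mass": np.asarray(mass, dtype=float),
    })
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    if len(df) <= 4:
        raise ValueError("need more than 4 observations")
    # Sum-coded sex so the Type-III decomposition is well defined
    model = smf.ols("y ~ C(sex, Sum) * mass", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    df2 = int(model.df_resid)
    out = {}
    for key, term in (("sex", "C(sex, Sum)"), ("mass", "mass"),
                      ("sex_x_mass", "C(sex, Sum):mass")):
        row = table.loc[term]
        out[key] = FTestResult(F=float(row["F"]), df1=int(row["df"]),
                               df2=df2, p=float(row["PR(>F)"]))
    return out


def one_way_anova(
    values: Sequence[float], groups: Sequence
) -> FTestResult:
    """Standard one-way ANOVA across the levels of ``groups``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    F, p = sps.f_oneway(*samples)
    df1 = len(levels) - 1
    df2 = len(values) - len(levels)
    return FTestResult(F=float(F), df1=df1, df2=df2, p=float(p))


def paired_means(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "individual_id",
    type_col: str = "call_type",
) -> pd.DataFrame:
    """Per-individual mean feature value for oral and for nasal calls.

    Individuals missing either call type are dropped (listed in the
    returned frame's attrs under "excluded").
    """
    means = (table.groupby([group_col, type_col])[feature]
             .mean().unstack(type_col))
    complete = means.dropna(subset=["oral", "nasal"])
    complete.attrs["excluded"] = sorted(set(means.index) - set(complete.index))
    return complete
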