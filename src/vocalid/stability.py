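"""Between-year stability of individual vocal signatures.

Within each year, discriminability of individuals is estimated exactly as
in the main analysis (fit + resubstitution classify + permutation null).
Stability is then probed by transfer: calls from the second year are
scored with the discriminant functions fitted on the first year's calls,
in the raw variable space (no re-standardization).  A collapse of the
transfer accuracy into the chance band indicates that individual
signatures did not persist across years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DFA_VARIABLES
from .dfa import (ClassificationResult, PermutationNull, classify, fit_dfa,
                  permutation_null, significance, DEFAULT_GROUP_COL)
from .group_stats import Chi2Result, yates_chi2
from .synth import (PopulationSpec, apply_year_drift, make_population,
                    sample_features_direct)


@dataclass
class YearSplit:
    """Feature tables of the same individuals in two consecutive years."""

    table_a: pd.DataFrame
    table_b: pd.DataFrame
    variables: tuple[str, ...] = tuple(DFA_VARIABLES)
    group_col: str = DEFAULT_GROUP_COL
    year_a: int = 2011
    year_b: int = 2012

    def __post_init__(self) -> None:
        ids_a = set(self.table_a[self.group_col])
        ids_b = set(self.table_b[self.group_col])
        if ids_a != ids_b:
            raise ValueError(
                f"individual sets differ between years: "
                f"only-A={sorted(ids_a - ids_b)} only-B={sorted(ids_b - ids_a)}")

    def table(self, year: str) -> pd.DataFrame:
        if year not in ("a", "b"):
            raise ValueError("year must be 'a' or 'b'")
        return self.table_a if year == "a" else self.table_b


def within_year_dfa(
    split: YearSplit, year: str, n_perm: int = 1000, seed: int = 0
) -> tuple[ClassificationResult, PermutationNull]:
    """Resubstitution accuracy and its permutation null for one year alone."""
    t = split.table(year)
    model = fit_dfa(t, split.variables, group_col=split.group_col)
    result = classify(model, t, group_col=split.group_col)
    null = permutation_null(t, split.variables, group_col=split.group_col,
                            n_perm=n_perm, seed=seed)
    return result, null


def cross_year_classify(split: YearSplit) -> ClassificationResult:
    """Score year-B calls with the discriminant functions fitted on year A."""
    model = fit_dfa(split.table_a, split.variables, group_col=split.group_col)
    return classify(model, split.table_b, group_col=split.group_col)


def compare_results(a: ClassificationResult, b: ClassificationResult
                    ) -> Chi2Result:
    """Yates chi-squared on the correct/incorrect counts of two
    classification results.

    When both results are perfect (or both completely wrong) a margin of
    the 2x2 table is zero and the test statistic degenerates to 0: the
    rates are identical, so independence cannot be rejected.
    """
    table = np.array([[a.n_correct, a.n_calls - a.n_correct],
                      [b.n_correct, b.n_calls - b.n_correct]])
    if (table.sum(axis=0) == 0).any():
        return Chi2Result(chi2=0.0, df=1, p=1.0)
    return yates_chi2(table)


def stability_report(
    split: YearSplit, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Full two-year analysis: within-year accuracies and nulls, the
    cross-year transfer accuracy, and the chi-squared bracket comparisons."""
    res_a, null_a = within_year_dfa(split, "a", n_perm=n_perm, seed=seed)
    res_b, null_b = within_year_dfa(split, "b", n_perm=n_perm, seed=seed + 1)
    cross = cross_year_classify(split)
    return {
        "year_a": {"result": res_a.to_dict(), "null": null_a.to_dict(),
                   "significance": significance(res_a.average_pct_correct,
                                                null_a)},
        "year_b": {"result": res_b.to_dict(), "null": null_b.to_dict(),
                   "significance": significance(res_b.average_pct_correct,
                                                null_b)},
        "cross_year": {
            "result": cross.to_dict(),
            "vs_null_b": significance(cross.average_pct_correct, null_b),
            "chi2_vs_year_a": vars(compare_results(res_a, cross)),
            "chi2_vs_year_b": vars(compare_results(res_b, cross)),
        },
        "chi2_year_a_vs_b": vars(compare_results(res_a, res_b)),
    }


def simulate_year_split(
    spec: PopulationSpec,
    n_individuals: int,
    n_calls_per_year: int,
    seed: int,
    call_type: str = "oral",
) -> YearSplit:
    """Two-year synthetic split of one call type.

    Year-A profiles are drawn from ``spec``; year-B profiles are the same
    individuals after one year of latent drift (``spec.year_drift_sd``).
    """
    profiles = make_population(spec, n_individuals, seed)
    drifted = apply_year_drift(spec, profiles, seed + 1)
    table_a = sample_features_direct(spec, profiles, n_calls_per_year,
                                     seed + 2, call_types=(call_type,),
                                     year=2011)
    table_b = sample_features_direct(spec, drifted, n_calls_per_year,
                                     seed + 3, call_types=(call_type,),
                                     year=2012)
    return YearSplit(table_a=table_a, table_b=table_b)


def drift_sweep(
    base_spec: PopulationSpec,
    drift_values: Sequence[float],
    n_individuals: int = 5,
    n_calls_per_year: int = 13,
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean cross-year accuracy as a function of the year-drift magnitude.

    Averages over ``n_reps`` seed replicates per drift value; used to
    verify that transfer accuracy is monotone non-increasing in drift.
    """
    from dataclasses import replace
    rows = []
    for drift in drift_values:
        spec = replace(base_spec, year_drift_sd=drift)
        accs = []
        for rep in range(n_reps):
            split = simulate_year_split(spec, n_individuals, n_calls_per_year,
                                        seed=seed + 1000 * rep)
            accs.append(cross_year_classify(split).average_pct_correct)
        rows.append({"year_drift_sd": drift,
                     "cross_year_accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
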