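"""Comparative-CT qPCR quantification, collagen abundance and t-tests.

The comparative-CT (delta-delta-Ct) method expresses a gene's abundance in
a treatment group relative to a reference group after normalising to a
housekeeping gene:

    dCt_s   = Ct_gene,s - Ct_housekeeping,s        (per sample s)
    ddCt    = mean dCt(treatment) - mean dCt(reference)
    fold    = 2 ** -ddCt

The SEM of ddCt is, by default, the per-group SEMs of dCt combined in
quadrature (config-switchable to the treatment group's SEM alone, since
some workflows hold the calibrator fixed); the fold-change interval is
obtained by exponentiating ``ddCt -/+ SEM``, which is symmetric in log2
space and asymmetric on the linear scale.  Following MIQE practice, a
minimum two-fold difference (fold >= 2 or <= 0.5) is flagged before a
change is reported as meaningful.

Collagen abundance is the ratio of soluble-collagen (Sircol) to total
protein (Lowry) concentration, in percent.  The two t-tests mirror a
standard Prism workflow: an equal-variance two-sample Student's t-test
(Welch optional) and a one-sample t-test against a reference value (1 for
vehicle-normalised data), with *, **, *** at p < 0.05, 0.01, 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "DeltaDeltaCtResult",
    "delta_delta_ct",
    "FoldChangeResult",
    "fold_change",
    "AbundanceResult",
    "collagen_abundance",
    "TTestResult",
    "two_sample_t",
    "one_sample_t",
    "significance_stars",
]


@dataclass
class DeltaDeltaCtResult:
    gene: str
    ddct: float
    sem: float
    n_reference: int
    n_treatment: int
    sem_mode: str
    mean_dct_reference: float
    mean_dct_treatment: float


def _dct_per_sample(
    table: pd.DataFrame, gene: str, reference_gene: str
) -> pd.DataFrame:
    pivot = table.pivot_table(
        index=["sample", "group"], columns="gene", values="ct"
    ).reset_index()
    for g in (gene, reference_gene):
        if g not in pivot.columns:
            raise InvalidInputError(f"gene {g!r} missing from the Ct table")
    if pivot[reference_gene].isna().any():
        raise InvalidInputError(
            "incomplete table: some samples lack a reference-gene Ct"
        )
    if pivot[gene].isna().any():
        raise InvalidInputError(f"incomplete table: missing Ct values for {gene!r}")
    pivot["dct"] = pivot[gene] - pivot[reference_gene]
    return pivot[["sample", "group", "dct"]]


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    reference_group: str,
    treatment_group: str | None = None,
    sem_mode: str = "quadrature",
) -> DeltaDeltaCtResult:
    """Comparative-CT statistic for one gene between two groups.

    ``table`` is long-format with columns sample/group/gene/ct.  ``sem_mode``
    is ``"quadrature"`` (default: combine both group SEMs) or
    ``"treatment"`` (treatment-group dCt SEM only).
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"Ct table needs columns {sorted(required)}")
    if sem_mode not in ("quadrature", "treatment"):
        raise InvalidInputError("sem_mode must be 'quadrature' or 'treatment'")
    groups = set(table["group"])
    if reference_group not in groups:
        raise InvalidInputError(f"reference group {reference_group!r} not in table")
    if treatment_group is None:
        others = sorted(groups - {reference_group})
        if len(others) != 1:
            raise InvalidInputError(
                "treatment_group must be named when more than two groups exist"
            )
        treatment_group = others[0]
    dct = _dct_per_sample(table, gene, reference_gene)
    ref = dct.loc[dct["group"] == reference_group, "dct"].to_numpy()
    trt = dct.loc[dct["group"] == treatment_group, "dct"].to_numpy()
    if len(ref) == 0 or len(trt) == 0:
        raise InvalidInputError("both groups need at least one sample")
    sem_trt = float(stats.sem(trt)) if len(trt) > 1 else np.nan
    sem_ref = float(stats.sem(ref)) if len(ref) > 1 else np.nan
    if sem_mode == "treatment":
        sem = sem_trt
    else:
        sem = float(np.sqrt(sem_trt**2 + sem_ref**2))
    return DeltaDeltaCtResult(
        gene=gene,
        ddct=float(trt.mean() - ref.mean()),
        sem=sem,
        n_reference=len(ref),
        n_treatment=len(trt),
        sem_mode=sem_mode,
        mean_dct_reference=float(ref.mean()),
        mean_dct_treatment=float(trt.mean()),
    )


@dataclass
class FoldChangeResult:
    gene: str | None
    fold_change: float
    sem_low: float   # 2 ** -(ddct + sem)
    sem_high: float  # 2 ** -(ddct - sem)
    meets_two_fold_rule: bool
    ddct: float
    sem: float


def fold_change(
    ddct: float, sem: float = np.nan, gene: str | None = None
) -> FoldChangeResult:
    """2^-ddCt fold change with an asymmetric SEM interval and 2-fold flag."""
    if not np.isfinite(ddct):
        raise InvalidInputError("ddCt must be finite")
    fc = float(2.0 ** (-ddct))
    return FoldChangeResult(
        gene=gene,
        fold_change=fc,
        sem_low=float(2.0 ** (-(ddct + sem))) if np.isfinite(sem) else np.nan,
        sem_high=float(2.0 ** (-(ddct - sem))) if np.isfinite(sem) else np.nan,
        meets_two_fold_rule=bool(fc >= 2.0 or fc <= 0.5),
        ddct=float(ddct),
        sem=float(sem),
    )


@dataclass
class AbundanceResult:
    collagen_conc_mg_ml: float
    total_protein_conc_mg_ml: float
    abundance_pct: float
    exceeds_total_protein: bool


def collagen_abundance(
    collagen_conc_mg_ml: float, total_protein_conc_mg_ml: float
) -> AbundanceResult:
    """Collagen as a percentage of total protein concentration.

    Collagen physically cannot exceed total protein, so values above 100%
    are reported with a warning flag rather than rejected (assay noise can
    produce them).
    """
    if total_protein_conc_mg_ml <= 0:
        raise InvalidInputError("total protein concentration must be positive")
    if collagen_conc_mg_ml <= 0:
        raise InvalidInputError("collagen concentration must be positive")
    pct = 100.0 * collagen_conc_mg_ml / total_protein_conc_mg_ml
    return AbundanceResult(
        collagen_conc_mg_ml=float(collagen_conc_mg_ml),
        total_protein_conc_mg_ml=float(total_protein_conc_mg_ml),
        abundance_pct=float(pct),
        exceeds_total_protein=bool(pct > 100.0),
    )


def significance_stars(p: float) -> str:
    """Prism-style significance tiers."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TTestResult:
    t: float
    p: float
    stars: str
    df: float


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> TTestResult:
    """Two-sided Student's t-test (equal-variance default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: both groups constant; scipy yields NaN here
        return _degenerate_t(a.mean() - b.mean(), float(a.size + b.size - 2))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)), df=df,
    )


def _degenerate_t(mean_diff: float, df: float) -> TTestResult:
    if mean_diff == 0.0:
        return TTestResult(t=0.0, p=1.0, stars="ns", df=df)
    t = float(np.sign(mean_diff)) * np.inf
    return TTestResult(t=t, p=0.0, stars=significance_stars(0.0), df=df)


def one_sample_t(values: np.ndarray, mu0: float = 1.0) -> TTestResult:
    """Two-sided one-sample t-test against ``mu0`` (1 for normalised data)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("need at least 2 values")
    if v.std(ddof=1) == 0.0:
        return _degenerate_t(float(v.mean() - mu0), float(v.size - 1))
    res = stats.ttest_1samp(v, popmean=mu0)
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)), df=float(v.size - 1),
    )
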