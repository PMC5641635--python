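"""Codon-utilization statistics over quantified peptides.

Two deliberately distinct code paths exist:

* abundance-weighted per-sample codon totals with a two-group t-test
  (``weighted_codon_totals`` / ``compare_codon_totals``), and
* unweighted codon-frequency enrichment of the >2-fold-downregulated peptide
  set against the total peptide set, with ranks over the 61 sense codons
  (``codon_enrichment``), plus a codon-table heatmap layout.

A mixed-effects regression relates each peptide's log2 fold change to its
AAA codon percentage with a random intercept per protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError, ValidationError
from .genetics import BASE_ORDER, SENSE_CODONS, STOP_CODONS
from .mapping import PROFILE_META_COLUMNS
from .simulate import SampleDesign

__all__ = [
    "GroupComparisonRow",
    "RegressionResult",
    "weighted_codon_totals",
    "compare_codon_totals",
    "compare_all_codons",
    "fold_changes",
    "codon_enrichment",
    "heatmap_layout",
    "regress_fc_on_aaa",
    "loglog_table",
]


def _counts_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Peptide-indexed 61-column count block of a codon-profile table."""
    missing = [c for c in SENSE_CODONS if c not in profiles.columns]
    if missing:
        raise ValidationError(f"profile table lacks codon columns {missing[:5]}")
    out = profiles.set_index("peptide")[list(SENSE_CODONS)]
    if out.index.has_duplicates:
        raise ValidationError("duplicate peptides in profile table")
    return out


def weighted_codon_totals(peptide_quant: pd.DataFrame,
                          profiles: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted codon totals per sample.

    ``totals[sample][codon] = sum over peptides of codon count x abundance``.
    Returns a sample x 61 DataFrame. Every quantified peptide must have a
    codon profile; offenders are listed in the error.
    """
    counts = _counts_matrix(profiles)
    missing = peptide_quant.index.difference(counts.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} quantified peptides lack codon profiles, e.g. "
            f"{sorted(missing)[:5]}")
    counts = counts.loc[peptide_quant.index]
    totals = peptide_quant.T.to_numpy() @ counts.to_numpy()
    return pd.DataFrame(totals, index=peptide_quant.columns,
                        columns=list(SENSE_CODONS))


@dataclass(frozen=True)
class GroupComparisonRow:
    codon: str
    mean_control: float
    mean_ko: float
    t_statistic: float
    p_value: float


def compare_codon_totals(totals: pd.DataFrame, design: SampleDesign,
                         codon: str) -> GroupComparisonRow:
    """Equal-variance two-sided t-test of per-sample totals for one codon.

    Identical zero-variance groups give t = 0, p = 1 rather than NaN.
    """
    if codon not in totals.columns:
        raise ValidationError(f"unknown codon {codon!r}")
    ctrl = totals.loc[list(design.samples_in("control")), codon].to_numpy(float)
    ko = totals.loc[list(design.samples_in("ko")), codon].to_numpy(float)
    if len(ctrl) < 2 or len(ko) < 2:
        raise DegenerateDesignError("need >= 2 samples per group for a t-test")
    if ctrl.std() == 0 and ko.std() == 0 and ctrl.mean() == ko.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(ctrl, ko, equal_var=True)
    return GroupComparisonRow(codon, float(ctrl.mean()), float(ko.mean()),
                              float(t), float(p))


def compare_all_codons(totals: pd.DataFrame,
                       design: SampleDesign) -> pd.DataFrame:
    """t-test rows for all 61 codons, in alphabetical codon order."""
    rows = [compare_codon_totals(totals, design, c) for c in SENSE_CODONS]
    return pd.DataFrame([r.__dict__ for r in rows])


def fold_changes(quant: pd.DataFrame, design: SampleDesign,
                 threshold_fold: float = 2.0,
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-unit group means and KO/control log2 fold change.

    ``log2fc = log2((mean_ko + eps) / (mean_control + eps))`` with a
    pseudocount eps on both means so ratios stay finite. ``is_down_2x`` is
    true iff log2fc <= -log2(threshold_fold). Units with zero signal in
    every sample are dropped (their count is reported in ``attrs``).
    """
    if threshold_fold <= 1.0:
        raise ValidationError("threshold_fold must exceed 1")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    ctrl = quant[list(design.samples_in("control"))].mean(axis=1)
    ko = quant[list(design.samples_in("ko"))].mean(axis=1)
    absent = (quant.sum(axis=1) == 0)
    out = pd.DataFrame({
        "mean_control": ctrl,
        "mean_ko": ko,
        "log2fc": np.log2((ko + pseudocount) / (ctrl + pseudocount)),
    }).loc[~absent]
    out["is_down_2x"] = out["log2fc"] <= -np.log2(threshold_fold)
    out.index.name = quant.index.name
    out.attrs["n_dropped_absent"] = int(absent.sum())
    return out


def _set_frequencies(counts: pd.DataFrame, members: Iterable[str]) -> pd.Series:
    sub = counts.loc[list(members)]
    total = sub.to_numpy().sum()
    if total == 0:
        raise ValidationError("peptide set has zero codon total")
    return 100.0 * sub.sum(axis=0) / total


def codon_enrichment(profiles: pd.DataFrame, down_set: Iterable[str],
                     total_set: Iterable[str] | None = None) -> pd.DataFrame:
    """Unweighted codon-frequency enrichment of downregulated vs total peptides.

    For each peptide set, a codon's frequency is 100 x (codon occurrences in
    the set) / (total codons in the set). ``delta_percent`` is down minus
    total; rank 1 is the largest delta, ties broken alphabetically by codon.
    An empty down set yields NaN deltas/ranks and ``attrs['undefined']``.
    """
    counts = _counts_matrix(profiles)
    total_ids = list(total_set) if total_set is not None else list(counts.index)
    if not total_ids:
        raise ValidationError("total peptide set is empty")
    down_ids = [p for p in down_set]
    extra = set(down_ids) - set(total_ids)
    if extra:
        raise ValidationError(
            f"down set contains peptides outside the total set, e.g. "
            f"{sorted(extra)[:5]}")

    freq_total = _set_frequencies(counts, total_ids)
    out = pd.DataFrame({"codon": list(SENSE_CODONS)})
    out["freq_total_percent"] = freq_total.to_numpy()
    if not down_ids:
        out["freq_down_percent"] = np.nan
        out["delta_percent"] = np.nan
        out["rank"] = np.nan
        out.attrs["undefined"] = True
        return out
    freq_down = _set_frequencies(counts, down_ids)
    out["freq_down_percent"] = freq_down.to_numpy()
    out["delta_percent"] = out["freq_down_percent"] - out["freq_total_percent"]
    order = sorted(range(len(out)),
                   key=lambda i: (-out["delta_percent"].iat[i],
                                  out["codon"].iat[i]))
    ranks = np.empty(len(out), dtype=np.int64)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    out.attrs["undefined"] = False
    return out


def heatmap_layout(enrichment: pd.DataFrame,
                   value: str = "delta_percent") -> pd.DataFrame:
    """Arrange per-codon values as a 16x4 codon-table matrix.

    Rows are (first base, second base) pairs and columns the third base, all
    in T, C, A, G order; the three stop positions are NaN.
    """
    values = dict(zip(enrichment["codon"], enrichment[value]))
    missing = set(SENSE_CODONS) - set(values)
    if missing:
        raise ValidationError(f"enrichment table lacks codons {sorted(missing)[:5]}")
    index = pd.MultiIndex.from_product([list(BASE_ORDER), list(BASE_ORDER)],
                                       names=["first_base", "second_base"])
    mat = pd.DataFrame(np.nan, index=index, columns=list(BASE_ORDER))
    mat.columns.name = "third_base"
    for b1 in BASE_ORDER:
        for b2 in BASE_ORDER:
            for b3 in BASE_ORDER:
                codon = b1 + b2 + b3
                if codon not in STOP_CODONS:
                    mat.loc[(b1, b2), b3] = values[codon]
    return mat


@dataclass(frozen=True)
class RegressionResult:
    """Slope of log2 fold change on percent-AAA with its uncertainty."""

    slope: float
    standard_error: float
    p_value: float
    grouping_variable: str
    converged: bool
    n_observations: int
    n_groups: int
    method: str  # "mixedlm" or "ols_fallback"


def regress_fc_on_aaa(fc_table: pd.DataFrame, profiles: pd.DataFrame,
                      grouping: str = "protein_id") -> RegressionResult:
    """Mixed-effects regression of peptide log2fc on percent AAA codons.

    Fits ``log2fc ~ percent_AAA`` with a random intercept per grouping unit
    (maximum likelihood) and reports the Wald slope test. Falls back to
    ordinary least squares with ``converged=False`` when the random-effect
    variance collapses or the optimizer fails.
    """
    import statsmodels.api as sm

    if grouping not in profiles.columns:
        raise ValidationError(f"profiles lack grouping column {grouping!r}")
    pct = (100.0 * profiles["AAA"] / profiles["length"]).rename("percent_aaa")
    data = pd.DataFrame({
        "peptide": profiles["peptide"],
        "group": profiles[grouping],
        "percent_aaa": pct,
    }).merge(fc_table[["log2fc"]], left_on="peptide", right_index=True,
             how="inner")

    n_obs = len(data)
    n_groups = data["group"].nunique()
    if n_obs < 10 or n_groups < 3:
        raise DegenerateDesignError(
            f"need >= 10 peptides across >= 3 groups (got {n_obs} peptides, "
            f"{n_groups} groups)")
    if np.ptp(data["percent_aaa"].to_numpy()) == 0:
        raise DegenerateDesignError("percent_AAA is constant across peptides")
    if np.ptp(data["log2fc"].to_numpy()) == 0:
        return RegressionResult(0.0, float("nan"), 1.0, grouping, False,
                                n_obs, n_groups, "degenerate")

    endog = data["log2fc"].to_numpy()
    exog = sm.add_constant(data["percent_aaa"].to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(endog, exog, groups=data["group"]).fit(reml=False)
        re_var = float(np.asarray(fit.cov_re).ravel()[0])
        converged = bool(fit.converged) and re_var > 1e-10
        if converged and np.isfinite(fit.bse[1]) and fit.bse[1] > 0:
            return RegressionResult(float(fit.params[1]), float(fit.bse[1]),
                                    float(fit.pvalues[1]), grouping, True,
                                    n_obs, n_groups, "mixedlm")
    except Exception:
        pass
    ols = sm.OLS(endog, exog).fit()
    return RegressionResult(float(ols.params[1]), float(ols.bse[1]),
                            float(ols.pvalues[1]), grouping, False,
                            n_obs, n_groups, "ols_fallback")


def loglog_table(protein_fc: pd.DataFrame,
                 threshold_fold: float = 2.0) -> pd.DataFrame:
    """Plot-ready log-log scatter table of protein group means.

    Adds log10 axes and a flag for proteins changed more than
    ``threshold_fold``-fold in either direction.
    """
    cut = np.log2(threshold_fold)
    out = protein_fc[["mean_control", "mean_ko", "log2fc"]].copy()
    with np.errstate(divide="ignore"):
        out["log10_mean_control"] = np.log10(out["mean_control"])
        out["log10_mean_ko"] = np.log10(out["mean_ko"])
    out["is_changed_2x"] = out["log2fc"].abs() >= cut
    return out
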