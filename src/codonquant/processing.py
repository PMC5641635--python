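"""PSM filtering, target-decoy FDR collapse, parsimony inference, quantification.

Filter boundary semantics are literal: a PSM is excluded when *more than*
``max_missing_channels`` reporter channels are missing, or when its summed
reporter S:N is *strictly less than* ``min_summed_sn``; exactly 8 missing
channels or a summed S:N of exactly 100 is retained under the defaults.

FDR collapse uses the decoy/target count estimator with monotone (q-value
style) smoothing; parsimony inference is greedy set cover with deterministic
tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import sn_columns
from .simulate import SampleDesign

__all__ = [
    "FilterThresholds",
    "FdrResult",
    "ProteinGroup",
    "filter_psms",
    "apply_fdr",
    "assemble_parsimony",
    "quantify",
]

# exclusion reasons in first-failing-rule attribution order
RULE_NO_MS3 = "no_ms3"
RULE_MISSING = "too_many_missing_channels"
RULE_LOW_SN = "low_summed_sn"
RULE_ORDER = (RULE_NO_MS3, RULE_MISSING, RULE_LOW_SN)


@dataclass(frozen=True)
class FilterThresholds:
    """PSM exclusion thresholds; defaults are the study's stated values."""

    max_missing_channels: int = 8
    min_summed_sn: float = 100.0
    require_ms3: bool = True
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01

    def validate(self, n_channels: int | None = None) -> None:
        for name in ("peptide_fdr", "protein_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.max_missing_channels < 0:
            raise ConfigurationError("max_missing_channels must be >= 0")
        if n_channels is not None and self.max_missing_channels >= n_channels:
            raise ConfigurationError(
                "max_missing_channels must be below the channel count")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_psms(psms: pd.DataFrame, thresholds: FilterThresholds,
                design: SampleDesign | None = None,
                ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the reporter-quality exclusion rules.

    A PSM is retained iff it has an MS3 spectrum (when required), at most
    ``max_missing_channels`` reporter channels are missing, and the sum of
    its present reporter S:N values is at least ``min_summed_sn``. The tally
    attributes each exclusion to the first failing rule in that order.
    """
    if psms.empty:
        raise ValidationError("PSM table is empty")
    cols = sn_columns(psms)
    if design is not None and len(cols) != design.n_channels:
        raise ValidationError(
            f"PSM table has {len(cols)} reporter columns but the design has "
            f"{design.n_channels} channels")
    thresholds.validate(len(cols))

    sn = psms[cols].to_numpy(float)
    n_missing = np.isnan(sn).sum(axis=1)
    summed = np.nansum(sn, axis=1)

    fail_ms3 = (~psms["has_ms3"].astype(bool).to_numpy()
                if thresholds.require_ms3 else np.zeros(len(psms), bool))
    fail_missing = n_missing > thresholds.max_missing_channels
    fail_sn = summed < thresholds.min_summed_sn

    reason = np.select(
        [fail_ms3, fail_missing, fail_sn],
        [RULE_NO_MS3, RULE_MISSING, RULE_LOW_SN],
        default="")
    retained = psms.loc[reason == ""].copy()
    tally = {"input": len(psms)}
    for rule in RULE_ORDER:
        tally[rule] = int((reason == rule).sum())
    tally["retained"] = len(retained)
    return retained, tally


@dataclass(frozen=True)
class FdrResult:
    """Outcome of a target-decoy FDR collapse at one unit level."""

    unit: str
    retained: tuple[Hashable, ...]  # target unit keys passing the threshold
    threshold: float
    estimated_fdr: float
    n_targets: int
    n_decoys: int
    reliable: bool = True  # False when no decoys were present


def _unit_key(psms: pd.DataFrame, unit: str) -> pd.Series:
    if unit == "peptide":
        return psms["peptide"]
    if unit == "protein":
        # representative accession: first listed candidate
        return psms["protein_ids"].str.split(";").str[0]
    raise ValidationError(f"unknown FDR unit {unit!r}")


def apply_fdr(psms: pd.DataFrame, level: float, unit: str = "peptide",
              ) -> FdrResult:
    """Collapse PSMs to units (best score per unit) at the given FDR level.

    Estimated FDR at threshold t is ``#decoys(score>=t) / max(1,
    #targets(score>=t))``; after monotone smoothing the most permissive
    threshold with smoothed FDR <= level is chosen. Decoy units are never
    returned. With zero decoys present the estimate is unreliable: a warning
    is issued, every target is accepted and the reported FDR is 0.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("FDR level must be in (0, 1)")
    if psms.empty:
        return FdrResult(unit, (), float("inf"), 0.0, 0, 0, True)

    keys = _unit_key(psms, unit)
    units = (pd.DataFrame({"key": keys,
                           "score": psms["score"].astype(float),
                           "is_decoy": psms["is_decoy"].astype(bool)})
             .groupby("key", sort=True)
             .agg(score=("score", "max"), is_decoy=("is_decoy", "any"))
             .reset_index())

    n_targets = int((~units["is_decoy"]).sum())
    n_decoys = int(units["is_decoy"].sum())
    if n_targets == 0:
        return FdrResult(unit, (), float("inf"), 0.0, 0, n_decoys, True)
    if n_decoys == 0:
        warnings.warn("no decoy units present: FDR estimate is unreliable; "
                      "accepting all targets", stacklevel=2)
        kept = tuple(sorted(units.loc[~units["is_decoy"], "key"]))
        return FdrResult(unit, kept, -np.inf, 0.0, n_targets, 0, False)

    units = units.sort_values(["score", "key"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    scores = units["score"].to_numpy()
    decoy = units["is_decoy"].to_numpy()
    cum_d = np.cumsum(decoy)
    cum_t = np.cumsum(~decoy)
    # evaluate at distinct scores only: a threshold admits all tied units
    is_last_of_tie = np.r_[scores[1:] != scores[:-1], True]
    idx = np.flatnonzero(is_last_of_tie)
    fdr = cum_d[idx] / np.maximum(1, cum_t[idx])
    # monotone smoothing: q_i = min of fdr at this or any lower threshold
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    ok = np.flatnonzero(q <= level)
    if len(ok) == 0:
        return FdrResult(unit, (), float("inf"), float(fdr.min()),
                         n_targets, n_decoys, True)
    k = ok[-1]  # most permissive distinct score with smoothed FDR <= level
    threshold = float(scores[idx[k]])
    admitted = units.iloc[:idx[k] + 1]
    kept = tuple(sorted(admitted.loc[~admitted["is_decoy"], "key"]))
    return FdrResult(unit, kept, threshold, float(fdr[k]),
                     n_targets, n_decoys, True)


@dataclass(frozen=True)
class ProteinGroup:
    """One parsimony-selected protein and the peptides assigned to it."""

    representative_protein_id: str
    member_peptides: tuple[str, ...]

    def __post_init__(self):
        if not self.member_peptides:
            raise ValidationError("a protein group needs >= 1 peptide")


def assemble_parsimony(pep_to_prots: Mapping[str, Iterable[str]],
                       ) -> list[ProteinGroup]:
    """Greedy minimal set cover of peptides by proteins.

    Repeatedly selects the protein covering the most still-uncovered
    peptides (ties: larger total peptide count, then lexicographically
    smaller id); each peptide is assigned to the protein that first covered
    it. The union of group members always equals the input peptide set.
    """
    prot_to_peps: dict[str, set[str]] = {}
    for pep, prots in pep_to_prots.items():
        prots = list(prots)
        if not prots:
            raise ValidationError(f"peptide {pep!r} has no candidate protein")
        for prot in prots:
            prot_to_peps.setdefault(prot, set()).add(pep)

    uncovered = set(pep_to_prots)
    groups: list[ProteinGroup] = []
    while uncovered:
        best = min(
            prot_to_peps,
            key=lambda pr: (-len(prot_to_peps[pr] & uncovered),
                            -len(prot_to_peps[pr]), pr))
        newly = prot_to_peps[best] & uncovered
        if not newly:  # cannot happen while uncovered peptides remain
            raise AssertionError("greedy cover stalled")
        groups.append(ProteinGroup(best, tuple(sorted(newly))))
        uncovered -= newly
    return groups


def assignment_of(groups: Sequence[ProteinGroup]) -> dict[str, str]:
    """peptide -> representative protein mapping implied by the groups."""
    out: dict[str, str] = {}
    for g in groups:
        for pep in g.member_peptides:
            out[pep] = g.representative_protein_id
    return out


def quantify(psms: pd.DataFrame, assignment: Mapping[str, str] | None,
             design: SampleDesign, unit: str = "protein") -> pd.DataFrame:
    """Sum reporter S:N across matching PSMs per unit and sample.

    Missing reporter values contribute 0 to the sums (they are never
    imputed). Output columns follow the design's sample order; rows are the
    sorted unit ids.
    """
    if unit not in ("peptide", "protein"):
        raise ValidationError(f"unknown quantification unit {unit!r}")
    cols = sn_columns(psms)
    if len(cols) != design.n_channels:
        raise ValidationError(
            f"PSM table has {len(cols)} reporter columns but the design has "
            f"{design.n_channels} channels")

    if unit == "peptide":
        unit_ids = psms["peptide"]
    else:
        if assignment is None:
            raise ValidationError("protein-level quantification needs an "
                                  "assignment mapping")
        unit_ids = psms["peptide"].map(assignment)
        if unit_ids.isna().any():
            missing = sorted(psms.loc[unit_ids.isna(), "peptide"].unique())
            raise ValidationError(
                f"{len(missing)} peptides lack a protein assignment, e.g. "
                f"{missing[:5]}")

    chan_to_sample = dict(zip(design.channels, design.sample_ids))
    col_samples = []
    for c in cols:
        chan = f"ch{int(c[5:]):02d}"
        if chan not in chan_to_sample:
            raise ValidationError(f"reporter column {c} references channel "
                                  f"{chan!r} absent from the design")
        col_samples.append(chan_to_sample[chan])

    mat = psms[cols].fillna(0.0)
    mat.columns = col_samples
    mat.index = unit_ids.values
    out = mat.groupby(level=0, sort=True).sum()
    out = out[list(design.sample_ids)]  # design column order
    out.index.name = unit
    return out
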