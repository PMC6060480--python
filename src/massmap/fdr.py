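"""FDR control for the two-level hypothesis tree: BH, hierarchical BH, SST.

Discovery uses the strict rule ``adjusted < q`` by default (configurable to
``<=``).  All stage-2 procedures run at the same nominal level as stage 1;
an optional multiplier on the stage levels is exposed for users who want a
corrected threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import ValidationError


def bh_adjust(p, m_total: int | None = None) -> np.ndarray:
    """Step-up BH adjusted p-values, mapped back to input order.

    ``m_total`` may exceed ``len(p)``; the missing hypotheses are assumed to
    rank after all provided ones (a documented contract used to reproduce
    published tables from printed p-value subsets).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    n = p.size
    m = n if m_total is None else int(m_total)
    if m < n:
        raise ValidationError("m_total must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _rejects(adjusted: np.ndarray, q: float, strict: bool) -> np.ndarray:
    return adjusted < q if strict else adjusted <= q


@dataclass
class HypothesisTree:
    """Screening-rank p-values plus per-group target-rank p-values.

    ``target_pvalues[g]`` may be None when the group was never carried to
    the target rank (two-stage economy); procedures only read the entries
    of discovered groups.
    """

    group_ids: list
    screening_pvalues: np.ndarray
    target_ids: list             # per group: list of taxon ids
    target_pvalues: list         # per group: array of raw p-values or None

    def __post_init__(self):
        self.screening_pvalues = np.asarray(self.screening_pvalues, dtype=float)
        if len(self.group_ids) != len(self.screening_pvalues):
            raise ValidationError("group ids and screening p-values differ in length")
        if len(self.target_ids) != len(self.group_ids) or len(self.target_pvalues) != len(
            self.group_ids
        ):
            raise ValidationError("per-group target lists must match group count")
        if len(self.group_ids) == 0:
            raise ValidationError("empty hypothesis tree")


@dataclass
class FdrOutcome:
    """Adjusted p-values and rejection sets with stage bookkeeping."""

    procedure: str
    q: float
    discovered_groups: list
    adjusted_screening: np.ndarray
    adjusted_target: dict        # taxon id -> adjusted p (tested taxa only)
    rejected_taxa: list
    n_selected: int = 0          # size of the selected subset (stage-2 pool)


def _stage1(tree: HypothesisTree, q: float, strict: bool) -> tuple:
    adj0 = bh_adjust(tree.screening_pvalues)
    disc = np.flatnonzero(_rejects(adj0, q, strict))
    return adj0, disc


def hbh(tree: HypothesisTree, q: float, strict: bool = True) -> FdrOutcome:
    """Hierarchical BH: BH on groups, then BH within each discovered group."""
    adj0, disc = _stage1(tree, q, strict)
    adjusted_target: dict = {}
    rejected: list = []
    n_selected = 0
    for g in disc:
        ids = tree.target_ids[g]
        pg = tree.target_pvalues[g]
        if pg is None:
            raise ValidationError(f"discovered group {tree.group_ids[g]!r} has no target p-values")
        pg = np.asarray(pg, dtype=float)
        n_selected += len(ids)
        adj = bh_adjust(pg)
        for tid, a in zip(ids, adj):
            adjusted_target[tid] = float(a)
        rejected.extend(tid for tid, a in zip(ids, adj) if _rejects(np.array([a]), q, strict)[0])
    return FdrOutcome(
        procedure="hbh",
        q=q,
        discovered_groups=[tree.group_ids[g] for g in disc],
        adjusted_screening=adj0,
        adjusted_target=adjusted_target,
        rejected_taxa=rejected,
        n_selected=n_selected,
    )


def sst(tree: HypothesisTree, q: float, strict: bool = True) -> FdrOutcome:
    """Selected subset testing: BH on the pooled p-values of discovered groups."""
    adj0, disc = _stage1(tree, q, strict)
    pooled_ids: list = []
    pooled_p: list = []
    for g in disc:
        pg = tree.target_pvalues[g]
        if pg is None:
            raise ValidationError(f"discovered group {tree.group_ids[g]!r} has no target p-values")
        pooled_ids.extend(tree.target_ids[g])
        pooled_p.extend(np.asarray(pg, dtype=float))
    adjusted_target: dict = {}
    rejected: list = []
    if pooled_ids:
        adj = bh_adjust(np.asarray(pooled_p))
        keep = _rejects(adj, q, strict)
        adjusted_target = {tid: float(a) for tid, a in zip(pooled_ids, adj)}
        rejected = [tid for tid, k in zip(pooled_ids, keep) if k]
    return FdrOutcome(
        procedure="sst",
        q=q,
        discovered_groups=[tree.group_ids[g] for g in disc],
        adjusted_screening=adj0,
        adjusted_target=adjusted_target,
        rejected_taxa=rejected,
        n_selected=len(pooled_ids),
    )


def one_stage_bh(
    target_pvalues_all,
    q: float,
    ids: Sequence | None = None,
    m_total: int | None = None,
    strict: bool = True,
) -> FdrOutcome:
    """Benchmark path: plain BH over all target-rank p-values."""
    p = np.asarray(target_pvalues_all, dtype=float)
    if ids is None:
        ids = list(range(p.size))
    adj = bh_adjust(p, m_total=m_total)
    keep = _rejects(adj, q, strict)
    return FdrOutcome(
        procedure="bh",
        q=q,
        discovered_groups=[],
        adjusted_screening=np.empty(0),
        adjusted_target={tid: float(a) for tid, a in zip(ids, adj)},
        rejected_taxa=[tid for tid, k in zip(ids, keep) if k],
        n_selected=p.size,
    )
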