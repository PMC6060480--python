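"""End-to-end orchestration: screen -> target tests -> FDR, plus the
one-stage benchmark, result tables and serialization."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    AbundanceMatrix,
    PhyloTree,
    TaxonomyMap,
    TraitData,
    ValidationError,
    rank_index,
)
from .fdr import FdrOutcome, HypothesisTree, bh_adjust, hbh, one_stage_bh, sst
from .score import PermutationSet, fit_null, permutation_pvalues
from .screen import (
    GAMMA_DEFAULT,
    KERNELS_DEFAULT,
    KERNELS_WITH_TREE,
    ConfigurationError,
    GroupScreenResult,
    screen_rank,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a two-stage (or benchmark one-stage) run."""

    screening_rank: str = "family"
    target_rank: str = "species"
    method: str = "omiat"            # omiat | aggregated | one_stage
    fdr_procedure: str = "hbh"       # hbh | sst | bh
    q: float = 0.05
    n_permutations: int = 100_000
    seed: int = 1
    gammas: tuple = GAMMA_DEFAULT
    kernels: tuple | None = None     # None -> bray_curtis (+ UniFracs if tree)
    standardize_spu: bool = True
    renormalize_groups: bool = False
    strict: bool = True
    test_all_taxa: bool = False      # debug: target-test every taxon
    min_prevalence: int = 3
    min_mean_ra: float = 0.001

    def __post_init__(self):
        if self.method != "one_stage" and rank_index(self.screening_rank) >= rank_index(
            self.target_rank
        ):
            raise ConfigurationError("screening rank must be strictly above target rank")
        if self.q <= 0 or self.q > 1:
            raise ValidationError("q must lie in (0, 1]")

    def resolved_kernels(self, tree) -> tuple:
        if self.kernels is not None:
            return tuple(self.kernels)
        return KERNELS_WITH_TREE if tree is not None else KERNELS_DEFAULT

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gammas"] = [("inf" if np.isinf(g) else g) for g in self.gammas]
        d["kernels"] = list(self.kernels) if self.kernels is not None else None
        return d


@dataclass
class MassMapResult:
    """Everything produced by one run, with provenance."""

    config: RunConfig
    screen: GroupScreenResult | None
    taxon_ids: list                   # taxa tested at the target rank
    taxon_pvalues: dict               # taxon id -> raw p
    taxon_groups: dict                # taxon id -> group id ("" for one-stage)
    fdr: FdrOutcome
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_massmap(
    ab: AbundanceMatrix,
    tax: TaxonomyMap,
    trait: TraitData,
    config: RunConfig,
    tree: PhyloTree | None = None,
) -> MassMapResult:
    """Fit the null once, screen, target-test discovered groups, control FDR.

    Deterministic given ``config.seed``.  Zero discovered groups is a valid
    outcome with an empty rejection set.
    """
    if ab.n_samples != trait.n:
        raise ValidationError("abundance and trait sample counts differ (align first)")
    null = fit_null(trait)
    perms = PermutationSet.generate(ab.n_samples, config.n_permutations, seed=config.seed)

    if config.method == "one_stage":
        pvals = permutation_pvalues(null, ab.values, perms)
        fdr = one_stage_bh(pvals, config.q, ids=ab.taxon_ids, strict=config.strict)
        return MassMapResult(
            config=config,
            screen=None,
            taxon_ids=list(ab.taxon_ids),
            taxon_pvalues=dict(zip(ab.taxon_ids, map(float, pvals))),
            taxon_groups={t: "" for t in ab.taxon_ids},
            fdr=fdr,
            provenance=_provenance(config),
        )

    screen = screen_rank(
        ab,
        tax,
        None,
        rank=config.screening_rank,
        perms=perms,
        method=config.method,
        tree=tree,
        null=null,
        target_rank=config.target_rank,
        gammas=config.gammas,
        kinds=config.resolved_kernels(tree),
        standardize=config.standardize_spu,
        renormalize=config.renormalize_groups,
    )

    adj0 = bh_adjust(screen.p_values)
    discovered = adj0 < config.q if config.strict else adj0 <= config.q
    taxon_pvalues: dict = {}
    taxon_groups: dict = {}
    target_pvalues: list = []
    for g, (gid, members) in enumerate(zip(screen.group_ids, screen.group_members)):
        if discovered[g] or config.test_all_taxa:
            Zg = ab.values[:, [ab.taxon_ids.index(t) for t in members]]
            pg = permutation_pvalues(null, Zg, perms)
            target_pvalues.append(pg)
            for t, p in zip(members, pg):
                taxon_pvalues[t] = float(p)
                taxon_groups[t] = gid
        else:
            target_pvalues.append(None)

    tree_h = HypothesisTree(
        group_ids=screen.group_ids,
        screening_pvalues=screen.p_values,
        target_ids=screen.group_members,
        target_pvalues=target_pvalues,
    )
    proc = {"hbh": hbh, "sst": sst}.get(config.fdr_procedure)
    if proc is None:
        raise ConfigurationError(
            f"fdr_procedure {config.fdr_procedure!r} invalid for a two-stage run"
        )
    fdr = proc(tree_h, config.q, strict=config.strict)
    logger.info(
        "discovered %d group(s); selected subset of %d taxa; %d rejected",
        len(fdr.discovered_groups),
        fdr.n_selected,
        len(fdr.rejected_taxa),
    )
    return MassMapResult(
        config=config,
        screen=screen,
        taxon_ids=[t for t in taxon_pvalues],
        taxon_pvalues=taxon_pvalues,
        taxon_groups=taxon_groups,
        fdr=fdr,
        provenance=_provenance(config),
    )


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": _config_hash(config), "seed": config.seed, "version": __version__}


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

SCREENING_COLUMNS = ["group_id", "raw_p", "adjusted_p", "discovered", "n_members", "method"]
TARGET_COLUMNS = ["taxon_id", "group_id", "raw_p", "adjusted_p", "rejected", "procedure", "floored"]


def screening_table(result: MassMapResult) -> pd.DataFrame:
    if result.screen is None:
        return pd.DataFrame(columns=SCREENING_COLUMNS)
    adj = result.fdr.adjusted_screening
    disc = set(result.fdr.discovered_groups)
    return pd.DataFrame(
        {
            "group_id": result.screen.group_ids,
            "raw_p": result.screen.p_values,
            "adjusted_p": adj,
            "discovered": [g in disc for g in result.screen.group_ids],
            "n_members": [len(m) for m in result.screen.group_members],
            "method": result.screen.method,
        },
        columns=SCREENING_COLUMNS,
    )


def target_table(result: MassMapResult) -> pd.DataFrame:
    floor = 1.0 / (result.config.n_permutations + 1)
    rejected = set(result.fdr.rejected_taxa)
    rows = []
    for t, p in result.taxon_pvalues.items():
        rows.append(
            {
                "taxon_id": t,
                "group_id": result.taxon_groups.get(t, ""),
                "raw_p": p,
                "adjusted_p": result.fdr.adjusted_target.get(t, np.nan),
                "rejected": t in rejected,
                "procedure": result.fdr.procedure,
                "floored": p <= floor * (1 + 1e-12),
            }
        )
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def write_results(result: MassMapResult, out_dir) -> dict:
    """Write screening.tsv, target.tsv and run_log.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "screening": out / "screening.tsv",
        "target": out / "target.tsv",
        "log": out / "run_log.json",
    }
    screening_table(result).to_csv(paths["screening"], sep="\t", index=False, float_format="%.17g")
    target_table(result).to_csv(paths["target"], sep="\t", index=False, float_format="%.17g")
    log = {
        "config": result.config.to_dict(),
        "provenance": result.provenance,
        "n_discovered_groups": len(result.fdr.discovered_groups),
        "n_selected_taxa": result.fdr.n_selected,
        "n_rejected_taxa": len(result.fdr.rejected_taxa),
    }
    paths["log"].write_text(json.dumps(log, indent=2))
    return paths
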