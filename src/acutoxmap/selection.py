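"""Greedy minimal-assay set cover over burst-active toxic chemicals.

At each step every candidate assay is scored by the number of still-uncovered
toxic chemicals it would cover minus the number of nontoxic chemicals
burst-active in it (a static penalty — covered toxics are removed, nontoxics
never are).  Ties are broken, in order, by the total number of toxic
burst-actives in the assay (including already-covered ones), then ascending
FDR from the toxic-vs-all enrichment, then ascending FDR from the very-toxic
enrichment, then lexicographic assay id.  Selection stops once every
coverable toxic chemical is covered; an assay that would cover no new toxic
chemical is never selected.

The selection FDR is the fraction of flagged chemicals that are nontoxic:
``|flagged nontoxics| / (|flagged nontoxics| + |covered toxics|)``.

Global scope draws candidates from every assay with at least one burst-active
toxic chemical and penalizes with all nontoxic chemicals.  Cluster scope
draws candidates from the cluster's enriched assays (falling back to every
assay with a burst-active toxic member when none is enriched) and restricts
both the toxic targets and the nontoxic penalty to the cluster's members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .data_io import AssayDataset, ChemicalRecord
from .enrichment import EnrichmentResult

__all__ = [
    "SelectionStep",
    "AssaySelection",
    "candidate_pool",
    "greedy_min_cover",
    "select_global",
    "per_cluster_selection",
    "selection_to_frame",
]


@dataclass
class SelectionStep:
    assay_id: str
    newly_covered: int
    nontoxic_hits: int


@dataclass
class AssaySelection:
    """Result of one greedy cover run (global or one cluster)."""

    scope: str  # "global" or "cluster"
    cluster_id: Optional[int]
    steps: list[SelectionStep]
    covered_toxics: set[str]
    uncovered_toxics: set[str]
    flagged_nontoxics: set[str]
    fallback: bool = False

    @property
    def selected_assays(self) -> list[str]:
        return [s.assay_id for s in self.steps]

    @property
    def selection_fdr(self) -> float:
        total = len(self.flagged_nontoxics) + len(self.covered_toxics)
        return len(self.flagged_nontoxics) / total if total else 0.0


def _fdr_map(results: Sequence[EnrichmentResult]) -> dict[str, float]:
    return {r.assay_id: r.fdr for r in results}


def candidate_pool(
    scope: str,
    assays: AssayDataset,
    chemicals: Sequence[ChemicalRecord],
    clusters: Optional[ClusterAssignment] = None,
    cluster_id: Optional[int] = None,
    cluster_enrichment: Optional[Sequence[EnrichmentResult]] = None,
    exclude_assays: Sequence[str] = (),
) -> tuple[list[str], bool]:
    """Candidate assay ids for a cover run; returns (pool, fallback_used).

    Global scope: every assay with >=1 burst-active toxic chemical.  Cluster
    scope: the cluster's enriched assays; when none is enriched, fall back to
    every assay with >=1 burst-active toxic cluster member (``fallback_used``
    is then True).  ``exclude_assays`` removes e.g. cytotoxicity-type assays
    from cluster pools.
    """
    if assays.burst_hit is None:
        raise ValueError("burst_hit not computed")
    toxic = {c.chem_id for c in chemicals if c.toxic is True}
    active = assays.burst_hit == 1
    toxic_rows = np.array([c in toxic for c in assays.chem_ids])
    excluded = set(exclude_assays)

    if scope == "global":
        has_toxic = (active & toxic_rows[:, None]).any(axis=0)
        pool = [a for a, ok in zip(assays.assay_ids, has_toxic) if ok and a not in excluded]
        return pool, False
    if scope != "cluster":
        raise ValueError(f"unknown scope: {scope!r}")
    if clusters is None or cluster_id is None:
        raise ValueError("cluster scope requires clusters and cluster_id")
    memb = clusters.as_dict()
    if cluster_id not in set(memb.values()):
        raise ValueError(f"unknown cluster_id: {cluster_id}")
    enriched = [
        r.assay_id
        for r in (cluster_enrichment or [])
        if r.cluster_id == cluster_id and r.enriched and r.assay_id not in excluded
    ]
    if enriched:
        return sorted(set(enriched)), False
    member_toxic_rows = np.array(
        [memb.get(c) == cluster_id and c in toxic for c in assays.chem_ids]
    )
    has_member = (active & member_toxic_rows[:, None]).any(axis=0)
    pool = [
        a for a, ok in zip(assays.assay_ids, has_member) if ok and a not in excluded
    ]
    return pool, True


def greedy_min_cover(
    pool: Sequence[str],
    toxic_active: Mapping[str, set[str]],
    nontoxic_active: Mapping[str, set[str]],
    fdr_toxic: Optional[Mapping[str, float]] = None,
    fdr_verytoxic: Optional[Mapping[str, float]] = None,
    scope: str = "global",
    cluster_id: Optional[int] = None,
    fallback: bool = False,
    toxics_to_cover: Optional[set[str]] = None,
) -> AssaySelection:
    """Run the greedy cover over ``pool``.

    ``toxic_active`` / ``nontoxic_active`` map each assay to the burst-active
    toxic / nontoxic chemical sets it would flag.  ``fdr_toxic`` and
    ``fdr_verytoxic`` feed tie-break levels 3 and 4; assays missing from them
    rank last within that level (+inf).  ``toxics_to_cover`` is the target
    chemical set (default: every toxic reachable through the pool); targets
    unreachable through the pool end up in ``uncovered_toxics`` with a
    warning rather than an error.
    """
    fdr_toxic = fdr_toxic or {}
    fdr_verytoxic = fdr_verytoxic or {}
    reachable: set[str] = set()
    for a in pool:
        reachable |= toxic_active.get(a, set())
    targets = set(toxics_to_cover) if toxics_to_cover is not None else set(reachable)
    uncovered = targets & reachable
    unreachable = targets - reachable
    steps: list[SelectionStep] = []
    flagged: set[str] = set()
    chosen: set[str] = set()

    if unreachable:
        warnings.warn(
            f"{len(unreachable)} toxic chemical(s) not coverable by the "
            "candidate pool",
            stacklevel=2,
        )

    while uncovered:
        best_key = None
        best_assay = None
        for a in sorted(set(pool) - chosen):
            tox = toxic_active.get(a, set())
            gain = len(tox & uncovered)
            if gain == 0:
                continue
            penalty = len(nontoxic_active.get(a, set()))
            key = (
                -(gain - penalty),
                -len(tox),  # static total including covered toxics
                fdr_toxic.get(a, math.inf),
                fdr_verytoxic.get(a, math.inf),
                a,
            )
            if best_key is None or key < best_key:
                best_key, best_assay = key, a
        if best_assay is None:
            break
        tox = toxic_active.get(best_assay, set())
        newly = tox & uncovered
        steps.append(
            SelectionStep(
                assay_id=best_assay,
                newly_covered=len(newly),
                nontoxic_hits=len(nontoxic_active.get(best_assay, set())),
            )
        )
        uncovered -= newly
        flagged |= nontoxic_active.get(best_assay, set())
        chosen.add(best_assay)

    return AssaySelection(
        scope=scope,
        cluster_id=cluster_id,
        steps=steps,
        covered_toxics=(targets & reachable) - uncovered,
        uncovered_toxics=uncovered | unreachable,
        flagged_nontoxics=flagged,
        fallback=fallback,
    )


def _active_maps(
    assays: AssayDataset,
    chemicals: Sequence[ChemicalRecord],
    restrict_to: Optional[set[str]] = None,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-assay burst-active toxic and nontoxic chemical-id sets."""
    toxic = {c.chem_id for c in chemicals if c.toxic is True}
    nontoxic = {c.chem_id for c in chemicals if c.toxic is False}
    if restrict_to is not None:
        toxic &= restrict_to
        nontoxic &= restrict_to
    active = assays.burst_hit == 1
    tox_map: dict[str, set[str]] = {}
    non_map: dict[str, set[str]] = {}
    for j, a in enumerate(assays.assay_ids):
        hit_ids = {assays.chem_ids[i] for i in np.nonzero(active[:, j])[0]}
        tox_map[a] = hit_ids & toxic
        non_map[a] = hit_ids & nontoxic
    return tox_map, non_map


def select_global(
    chemicals: Sequence[ChemicalRecord],
    assays: AssayDataset,
    enrichment_toxic: Sequence[EnrichmentResult] = (),
    enrichment_verytoxic: Sequence[EnrichmentResult] = (),
    exclude_assays: Sequence[str] = (),
) -> AssaySelection:
    """Greedy cover over all toxic chemicals without cluster information."""
    pool, _ = candidate_pool("global", assays, chemicals, exclude_assays=exclude_assays)
    tox_map, non_map = _active_maps(assays, chemicals)
    return greedy_min_cover(
        pool,
        tox_map,
        non_map,
        _fdr_map(enrichment_toxic),
        _fdr_map(enrichment_verytoxic),
        scope="global",
    )


def per_cluster_selection(
    chemicals: Sequence[ChemicalRecord],
    clusters: ClusterAssignment,
    assays: AssayDataset,
    cluster_enrichment: Sequence[EnrichmentResult],
    enrichment_toxic: Sequence[EnrichmentResult] = (),
    enrichment_verytoxic: Sequence[EnrichmentResult] = (),
    exclude_assays: Sequence[str] = (),
) -> tuple[list[AssaySelection], dict]:
    """One greedy cover per cluster with >=1 burst-active toxic member.

    Both the toxic targets and the nontoxic penalty are the cluster's own
    members.  The summary reports the union assay count, the pooled
    selection FDR over all clusters, and the histogram of per-cluster
    selected-assay counts.
    """
    memb = clusters.as_dict()
    toxic = {c.chem_id for c in chemicals if c.toxic is True}
    active_any = dict(
        zip(assays.chem_ids, (assays.burst_hit == 1).any(axis=1))
    )
    fdr_tox = _fdr_map(enrichment_toxic)
    fdr_very = _fdr_map(enrichment_verytoxic)

    selections: list[AssaySelection] = []
    for cid in sorted(set(memb.values())):
        members = {c for c, k in memb.items() if k == cid}
        if not any(c in toxic and active_any.get(c, False) for c in members):
            continue
        pool, fallback = candidate_pool(
            "cluster",
            assays,
            chemicals,
            clusters,
            cid,
            cluster_enrichment,
            exclude_assays=exclude_assays,
        )
        tox_map, non_map = _active_maps(assays, chemicals, restrict_to=members)
        selections.append(
            greedy_min_cover(
                pool,
                tox_map,
                non_map,
                fdr_tox,
                fdr_very,
                scope="cluster",
                cluster_id=cid,
                fallback=fallback,
            )
        )

    union_assays = sorted({a for s in selections for a in s.selected_assays})
    covered = set().union(*(s.covered_toxics for s in selections)) if selections else set()
    flagged = set().union(*(s.flagged_nontoxics for s in selections)) if selections else set()
    denom = len(covered) + len(flagged)
    hist: dict[int, int] = {}
    for s in selections:
        hist[len(s.steps)] = hist.get(len(s.steps), 0) + 1
    summary = {
        "n_clusters_selected": len(selections),
        "union_assay_count": len(union_assays),
        "union_assays": union_assays,
        "covered_toxics": len(covered),
        "flagged_nontoxics": len(flagged),
        "pooled_selection_fdr": len(flagged) / denom if denom else 0.0,
        "assay_count_histogram": {str(k): v for k, v in sorted(hist.items())},
    }
    return selections, summary


def selection_to_frame(selections: Sequence[AssaySelection]) -> pd.DataFrame:
    rows = []
    for s in selections:
        for rank, step in enumerate(s.steps, start=1):
            rows.append(
                {
                    "scope": s.scope,
                    "cluster_id": s.cluster_id,
                    "rank": rank,
                    "assay_id": step.assay_id,
                    "newly_covered": step.newly_covered,
                    "nontoxic_hits": step.nontoxic_hits,
                    "fallback_flag": s.fallback,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scope",
            "cluster_id",
            "rank",
            "assay_id",
            "newly_covered",
            "nontoxic_hits",
            "fallback_flag",
        ],
    )
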