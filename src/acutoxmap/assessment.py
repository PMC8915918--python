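"""Composite AC50 assignment and activity-toxicity association tests.

Each chemical receives a composite AC50: the minimum of (a) its best AC50
among the assays selected for its structural cluster (raw hit calls — the
cytotoxicity range is re-admitted here via the minimum with the cytotoxicity
point) and (b) its cytotoxicity point.  Chemicals with a composite AC50
below 1 mM are *active*; chemicals tested in a cluster assay or carrying a
cytotoxicity point but without activity are *inactive*; everything else is
*unevaluable*.

Association with in vivo toxicity uses Fisher's exact test for the binary
2x2 comparison and a fixed-margins Monte-Carlo Fisher test for r x c tables
(multiclass GHS comparisons), estimated from 20,000 replicates by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .clustering import ClusterAssignment
from .data_io import GHS_UNCLASSIFIED, AssayDataset, ChemicalRecord
from .enrichment import fisher_exact_2x2

__all__ = [
    "ACTIVITY_THRESHOLD_UM",
    "CompositeActivity",
    "composite_ac50",
    "compute_composite_activity",
    "binary_association",
    "montecarlo_fisher_rxc",
    "ghs_association",
    "cluster_ghs_span",
    "composite_to_frame",
]

#: Composite-AC50 activity cut-off: 1 mM in µM.
ACTIVITY_THRESHOLD_UM: float = 1000.0


@dataclass
class CompositeActivity:
    """Composite potency and activity status for one chemical."""

    chem_id: str
    cluster_ac50: Optional[float]  # µM
    cytotox_ac50: Optional[float]  # µM
    composite_ac50: Optional[float]  # µM
    status: str  # "active" | "inactive" | "unevaluable"


def composite_ac50(
    chemical: ChemicalRecord,
    cluster_assays: Sequence[str],
    assays: AssayDataset,
    activity_threshold: float = ACTIVITY_THRESHOLD_UM,
) -> CompositeActivity:
    """Composite AC50 for one chemical given its cluster's assay list.

    ``cluster_ac50`` is the minimum AC50 over the cluster assays in which the
    chemical is raw-active; ``cytotox_ac50`` is the chemical's cytotoxicity
    point.  The composite is the minimum of whichever are defined.  A
    chemical neither tested in any cluster assay nor carrying a cytotoxicity
    point is unevaluable.
    """
    ci = assays.chem_index()
    ai = assays.assay_index()
    i = ci.get(chemical.chem_id)
    cluster_vals = []
    tested_in_cluster = False
    if i is not None:
        for a in cluster_assays:
            j = ai.get(a)
            if j is None:
                continue
            if assays.tested[i, j]:
                tested_in_cluster = True
            if assays.raw_hit[i, j] and np.isfinite(assays.ac50[i, j]):
                cluster_vals.append(float(assays.ac50[i, j]))
    cluster_val = min(cluster_vals) if cluster_vals else None
    cyto_val = chemical.cytotox_point
    defined = [v for v in (cluster_val, cyto_val) if v is not None]
    comp = min(defined) if defined else None
    if comp is not None:
        status = "active" if comp < activity_threshold else "inactive"
    elif tested_in_cluster or cyto_val is not None:
        status = "inactive"
    else:
        status = "unevaluable"
    return CompositeActivity(chemical.chem_id, cluster_val, cyto_val, comp, status)


def compute_composite_activity(
    chemicals: Sequence[ChemicalRecord],
    clusters: Optional[ClusterAssignment],
    cluster_assay_map: Mapping[int, Sequence[str]],
    assays: AssayDataset,
    activity_threshold: float = ACTIVITY_THRESHOLD_UM,
) -> list[CompositeActivity]:
    """Composite activity for every chemical.

    ``cluster_assay_map`` maps cluster id to its selected assay list;
    chemicals without a cluster (or whose cluster has no assays) fall back to
    the cytotoxicity AC50 alone.
    """
    memb = clusters.as_dict() if clusters is not None else {}
    out = []
    for c in chemicals:
        cid = memb.get(c.chem_id)
        cluster_assays = cluster_assay_map.get(cid, ()) if cid is not None else ()
        out.append(composite_ac50(c, cluster_assays, assays, activity_threshold))
    return out


def binary_association(
    activities: Sequence[CompositeActivity],
    chemicals: Sequence[ChemicalRecord],
) -> tuple[np.ndarray, float, float]:
    """2x2 activity-by-toxicity table with Fisher exact p and odds ratio.

    Rows = (active, inactive), columns = (toxic, nontoxic); only evaluable
    chemicals with a defined binary toxicity label enter.
    """
    tox = {c.chem_id: c.toxic for c in chemicals}
    table = np.zeros((2, 2), dtype=np.int64)
    for a in activities:
        t = tox.get(a.chem_id)
        if a.status == "unevaluable" or t is None:
            continue
        table[0 if a.status == "active" else 1, 0 if t else 1] += 1
    if table.sum() == 0:
        raise ValueError("no evaluable chemicals with a toxicity label")
    p, odds = fisher_exact_2x2(table[0, 0], table[0, 1], table[1, 0], table[1, 1])
    return table, p, odds


def _log_table_prob(tables: np.ndarray) -> np.ndarray:
    """Fixed-margin log-probability up to a margin-only constant.

    P(table) = prod(Ri!) prod(Cj!) / (N! prod nij!); with margins fixed only
    -sum(log nij!) varies, so that is what is returned.
    """
    return -gammaln(tables + 1.0).sum(axis=(-2, -1))


def montecarlo_fisher_rxc(
    table: np.ndarray,
    n_reps: int = 20000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo Fisher test for an r x c table with both margins fixed.

    Replicate tables are generated by randomly permuting the column label
    vector against the row labels.  The add-one estimator
    ``(1 + #{P(sim) <= P(obs)}) / (1 + n_reps)`` is returned, so the p-value
    is never exactly zero.  Zero rows/columns are dropped with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows_ok = t.sum(axis=1) > 0
    cols_ok = t.sum(axis=0) > 0
    if not rows_ok.all() or not cols_ok.all():
        warnings.warn("dropping zero rows/columns from contingency table", stacklevel=2)
        t = t[rows_ok][:, cols_ok]
    r, c = t.shape
    if r < 2 or c < 2:
        return 1.0
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    row_margin = t.sum(axis=1)
    col_margin = t.sum(axis=0)
    n = int(t.sum())
    row_labels = np.repeat(np.arange(r), row_margin)
    col_labels = np.repeat(np.arange(c), col_margin)

    obs_logp = _log_table_prob(t)
    # simulate in blocks to bound memory at ~ block * n ints
    block = max(1, min(n_reps, 4_000_000 // max(n, 1)))
    exceed = 0
    done = 0
    row_onehot = [row_labels == i for i in range(r)]
    while done < n_reps:
        b = min(block, n_reps - done)
        perms = rng.permuted(np.tile(col_labels, (b, 1)), axis=1)
        sims = np.empty((b, r, c), dtype=np.int64)
        for i in range(r):
            sub = perms[:, row_onehot[i]]
            for j in range(c):
                sims[:, i, j] = (sub == j).sum(axis=1)
        sim_logp = _log_table_prob(sims)
        exceed += int((sim_logp <= obs_logp + 1e-9).sum())
        done += b
    return (1 + exceed) / (1 + n_reps)


def ghs_association(
    activities: Sequence[CompositeActivity],
    chemicals: Sequence[ChemicalRecord],
    n_reps: int = 20000,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """Activity (active/inactive) x GHS category table with Monte-Carlo p.

    Unclassified chemicals (LD50 above the top band, or no LD50) are excluded.
    """
    ghs = {c.chem_id: c.ghs_category for c in chemicals}
    cats = sorted(
        {
            g
            for g in ghs.values()
            if g is not None and g != GHS_UNCLASSIFIED
        }
    )
    table = pd.DataFrame(0, index=["active", "inactive"], columns=cats)
    for a in activities:
        g = ghs.get(a.chem_id)
        if a.status == "unevaluable" or g is None or g == GHS_UNCLASSIFIED:
            continue
        table.loc[a.status, g] += 1
    p = montecarlo_fisher_rxc(table.to_numpy(), n_reps=n_reps, seed=seed)
    return table, p


def cluster_ghs_span(
    clusters: ClusterAssignment,
    chemicals: Sequence[ChemicalRecord],
    restrict_to_evaluable: bool = False,
    activities: Optional[Sequence[CompositeActivity]] = None,
) -> tuple[dict[int, set[int]], dict[str, float]]:
    """GHS categories represented in each cluster, with span fractions.

    The summary gives, among clusters containing >=1 toxic chemical, the
    fraction spanning exactly one category and the fraction spanning at most
    two *neighboring* (consecutive) categories.  Unclassified chemicals are
    excluded from span computation.
    """
    if restrict_to_evaluable and activities is None:
        raise ValueError("restrict_to_evaluable requires activities")
    evaluable = (
        {a.chem_id for a in activities if a.status != "unevaluable"}
        if restrict_to_evaluable
        else None
    )
    by_id = {c.chem_id: c for c in chemicals}
    memb = clusters.as_dict()
    spans: dict[int, set[int]] = {}
    has_toxic: dict[int, bool] = {}
    for chem_id, cid in memb.items():
        c = by_id[chem_id]
        if evaluable is not None and chem_id not in evaluable:
            continue
        spans.setdefault(cid, set())
        has_toxic.setdefault(cid, False)
        if c.toxic is True:
            has_toxic[cid] = True
        if c.ghs_category is not None and c.ghs_category != GHS_UNCLASSIFIED:
            spans[cid].add(c.ghs_category)
    eligible = [cid for cid, t in has_toxic.items() if t and spans[cid]]
    if eligible:
        single = sum(1 for cid in eligible if len(spans[cid]) == 1)
        le2_neighboring = sum(
            1
            for cid in eligible
            if len(spans[cid]) == 1
            or (len(spans[cid]) == 2 and max(spans[cid]) - min(spans[cid]) == 1)
        )
        summary = {
            "n_clusters_with_toxic": float(len(eligible)),
            "frac_single_category": single / len(eligible),
            "frac_le2_neighboring": le2_neighboring / len(eligible),
        }
    else:
        summary = {
            "n_clusters_with_toxic": 0.0,
            "frac_single_category": math.nan,
            "frac_le2_neighboring": math.nan,
        }
    return spans, summary


def composite_to_frame(activities: Sequence[CompositeActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chem_id": a.chem_id,
                "cluster_ac50_uM": a.cluster_ac50,
                "cytotox_ac50_uM": a.cytotox_ac50,
                "composite_ac50_uM": a.composite_ac50,
                "status": a.status,
            }
            for a in activities
        ]
    )
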