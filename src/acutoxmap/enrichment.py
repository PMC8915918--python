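"""Per-assay enrichment: 2x2 tables, MCC, Fisher exact p and BH-FDR.

Three contrasts are supported, each asking which assays are preferentially
burst-active in a group of chemicals:

``toxic_vs_all``
    toxic chemicals against all chemicals with a defined toxicity label;
``verytoxic_vs_verytoxic_plus_nontoxic``
    very acutely toxic chemicals (LD50 <= 50 mg/kg by default) against the
    pooled very-toxic + nontoxic set;
``cluster_toxics_vs_all_toxics``
    toxic members of one structural cluster against all toxic chemicals.

A chemical enters an assay's 2x2 table only when tested in that assay.  An
assay is *enriched* when MCC >= 0.1, Fisher p <= 0.05 and at least 3 labeled
chemicals are active (all thresholds configurable).  FDR is the
Benjamini-Hochberg adjustment across the assays of one analysis (per cluster
for the cluster contrast).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment
from .data_io import AssayDataset, ChemicalRecord, toxic_vector, very_toxic_label

__all__ = [
    "CONTRASTS",
    "EnrichmentThresholds",
    "EnrichmentResult",
    "two_by_two",
    "mcc",
    "fisher_exact_2x2",
    "bh_fdr",
    "run_enrichment",
    "enrichment_to_frame",
]

CONTRASTS = (
    "toxic_vs_all",
    "verytoxic_vs_verytoxic_plus_nontoxic",
    "cluster_toxics_vs_all_toxics",
)


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Enrichment call thresholds: MCC floor, p ceiling, minimum actives."""

    mcc_min: float = 0.1
    p_max: float = 0.05
    min_active: int = 3


@dataclass
class EnrichmentResult:
    assay_id: str
    contrast: str
    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float
    p_value: float
    fdr: float
    enriched: bool
    cluster_id: Optional[int] = None


def two_by_two(
    label: np.ndarray, activity: np.ndarray, eligible: np.ndarray
) -> tuple[int, int, int, int]:
    """Tally (tp, fp, fn, tn) over eligible chemicals.

    Conventional orientation: tp = labeled & active, fp = unlabeled & active,
    fn = labeled & inactive, tn = unlabeled & inactive.
    """
    lab = np.asarray(label, dtype=bool)
    act = np.asarray(activity, dtype=bool)
    eli = np.asarray(eligible, dtype=bool)
    tp = int((eli & lab & act).sum())
    fp = int((eli & ~lab & act).sum())
    fn = int((eli & lab & ~act).sum())
    tn = int((eli & ~lab & ~act).sum())
    return tp, fp, fn, tn


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when a marginal sum is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def fisher_exact_2x2(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    """Two-sided Fisher exact p and the sample odds ratio tp*tn/(fp*fn).

    The odds ratio is +inf when fp*fn = 0 with tp*tn > 0, and NaN for the
    fully degenerate 0/0 case.
    """
    p = float(stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")[1])
    if fp * fn == 0:
        odds = math.inf if tp * tn > 0 else math.nan
    else:
        odds = tp * tn / (fp * fn)
    return p, odds


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def _contrast_vectors(
    contrast: str,
    chemicals: Sequence[ChemicalRecord],
    clusters: Optional[ClusterAssignment],
    very_toxic_threshold: float,
    cluster_id: Optional[int],
) -> tuple[np.ndarray, np.ndarray]:
    """(label, base eligibility) vectors in chemical-record order."""
    toxic = toxic_vector(chemicals)
    if contrast == "toxic_vs_all":
        eligible = toxic.notna() if hasattr(toxic, "notna") else ~pd.isna(toxic)
        label = toxic.fillna(False).to_numpy(dtype=bool)
        return label, np.asarray(eligible)
    if contrast == "verytoxic_vs_verytoxic_plus_nontoxic":
        very = very_toxic_label(chemicals, very_toxic_threshold)
        nontoxic = (toxic == False).fillna(False).to_numpy(dtype=bool)  # noqa: E712
        verybool = very.fillna(False).to_numpy(dtype=bool)
        return verybool, verybool | nontoxic
    if contrast == "cluster_toxics_vs_all_toxics":
        assert clusters is not None and cluster_id is not None
        member = np.array(
            [clusters.as_dict().get(c.chem_id) == cluster_id for c in chemicals]
        )
        eligible = toxic.fillna(False).to_numpy(dtype=bool)  # toxic chemicals only
        return member, eligible
    raise ValueError(f"unknown contrast: {contrast!r}")


def run_enrichment(
    contrast: str,
    chemicals: Sequence[ChemicalRecord],
    assays: AssayDataset,
    clusters: Optional[ClusterAssignment] = None,
    thresholds: EnrichmentThresholds = EnrichmentThresholds(),
    very_toxic_threshold: float = 50.0,
    cluster_ids: Optional[Sequence[int]] = None,
) -> list[EnrichmentResult]:
    """Run one contrast over every assay with >=1 eligible tested chemical.

    Activity is the burst-filtered hit call.  For the cluster contrast one
    analysis is run per cluster (all clusters by default), and FDR is
    adjusted within each cluster's analysis.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast: {contrast!r} (expected one of {CONTRASTS})")
    if assays.burst_hit is None:
        raise ValueError("burst_hit not computed; run apply_burst_filter first")
    if contrast == "cluster_toxics_vs_all_toxics":
        if clusters is None:
            raise ValueError("cluster contrast requires a ClusterAssignment")
        known = sorted(set(int(k) for k in clusters.cluster_id))
        if cluster_ids is None:
            cluster_ids = known
        else:
            bad = sorted(set(cluster_ids) - set(known))
            if bad:
                raise ValueError(f"unknown cluster_id(s): {bad}")
        groups = [(cid,) for cid in cluster_ids]
    else:
        groups = [(None,)]

    order = {c.chem_id: i for i, c in enumerate(chemicals)}
    row_of = np.array([order[c] for c in assays.chem_ids])
    active = assays.burst_hit == 1

    results: list[EnrichmentResult] = []
    for (cid,) in groups:
        label_all, eligible_all = _contrast_vectors(
            contrast, chemicals, clusters, very_toxic_threshold, cid
        )
        label = label_all[row_of]
        base_eligible = eligible_all[row_of]
        batch: list[EnrichmentResult] = []
        for j, assay_id in enumerate(assays.assay_ids):
            eligible = base_eligible & assays.tested[:, j]
            if not eligible.any():
                continue
            tp, fp, fn, tn = two_by_two(label, active[:, j], eligible)
            m = mcc(tp, fp, fn, tn)
            p, _ = fisher_exact_2x2(tp, fp, fn, tn)
            batch.append(
                EnrichmentResult(
                    assay_id=assay_id,
                    contrast=contrast,
                    tp=tp,
                    fp=fp,
                    fn=fn,
                    tn=tn,
                    mcc=m,
                    p_value=p,
                    fdr=math.nan,
                    enriched=(
                        m >= thresholds.mcc_min
                        and p <= thresholds.p_max
                        and tp >= thresholds.min_active
                    ),
                    cluster_id=cid,
                )
            )
        fdrs = bh_fdr([r.p_value for r in batch])
        for r, q in zip(batch, fdrs):
            r.fdr = float(q)
        results.extend(batch)
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "assay_id": r.assay_id,
                "contrast": r.contrast,
                "cluster_id": r.cluster_id,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "tn": r.tn,
                "mcc": r.mcc,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )
    return df
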