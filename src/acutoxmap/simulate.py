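"""Synthetic study generator with planted cluster/mechanism ground truth.

Emulates the structure of a curated acute-oral-toxicity reference set joined
to a sparse high-throughput bioactivity database:

- structural clusters appear as shared fingerprint core-bit patterns with
  per-bit noise, plus unclustered background chemicals with random sparse
  fingerprints;
- each cluster sits on a base GHS tier; members drift to a neighboring tier
  with small probability, so clusters span 1-2 neighboring GHS categories by
  construction, and toxicity (LD50 <= 2,000 mg/kg, i.e. tiers 1-4) follows
  from the tier;
- each cluster with at least one toxic member is assigned one or more
  "mechanism" assays in which its toxic members are potently active, below
  their cytotoxicity lower bound, so the planted signal survives the burst
  filter;
- cytotoxicity points are lognormal with a tier-dependent median — more
  toxic tiers are cytotoxic at lower concentrations — planting a positive
  activity-toxicity dependence in the composite-AC50 assessment;
- background activity is sprinkled uniformly over tested pairs, most of it
  at or above the cytotoxicity range (and hence burst-filtered away).

All randomness flows through one ``numpy`` Generator in a fixed draw order
(cluster cores -> cluster tiers -> sizes -> fingerprints -> member tiers and
LD50s -> cytotoxicity -> testing mask -> mechanism potencies -> background
hits), so a seed pins the study byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (
    AssayDataset,
    ChemicalRecord,
    FingerprintMatrix,
    derive_toxicity_labels,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_study",
    "null_study",
    "write_ground_truth",
]

# GHS LD50 bands (mg/kg), tiers 1..5
_TIER_BANDS = {
    1: (0.5, 5.0),
    2: (5.0, 50.0),
    3: (50.0, 300.0),
    4: (300.0, 2000.0),
    5: (2000.0, 5000.0),
}


@dataclass
class GeneratorConfig:
    """Study-generation parameters.

    Defaults describe a desk-scale study: 40 structural clusters of 6-15
    chemicals plus 40 unclustered background chemicals, a 256-bit fingerprint
    with 24 shared core bits per cluster and 2% per-bit noise, and 120 assays
    of which one per toxic cluster is a planted mechanism assay.  Testing
    coverage is 70%; background hits occur at 1% of tested pairs with 30% of
    them potent (below the cytotoxicity lower bound).  Cluster base tiers are
    the four toxic GHS categories with probability ``toxic_fraction_per_cluster``
    (split evenly) and the nontoxic tier 5 otherwise; members drift to a
    neighboring tier with probability ``neighbor_tier_prob``.  Cytotoxicity
    points are lognormal with median ``cytotox_median_toxic_uM *
    cytotox_tier_scale**(tier-1)`` for toxic tiers and
    ``cytotox_median_nontoxic_uM`` for tier 5; mechanism potencies are
    lognormal around 1 µM, stochastically below the cytotoxicity lower
    bounds so planted hits survive the burst filter with high probability.
    """

    n_clusters: int = 40
    chems_per_cluster: tuple[int, int] = (6, 15)
    n_background_chemicals: int = 40
    F: int = 256
    core_bits_per_cluster: int = 24
    bit_flip_prob: float = 0.02
    n_assays: int = 120
    mechanism_assays_per_cluster: int = 1
    p_tested: float = 0.7
    p_background_hit: float = 0.01
    p_potent_background: float = 0.3
    toxic_fraction_per_cluster: float = 0.8
    neighbor_tier_prob: float = 0.2
    nontoxic_flag_only_prob: float = 0.1
    ld50_sigma: float = 0.5  # lognormal sigma within a tier (log-units)
    cytotox_median_toxic_uM: float = 20.0
    cytotox_tier_scale: float = 1.8
    cytotox_median_nontoxic_uM: float = 1500.0
    cytotox_sigma: float = 0.9
    cytotox_lower_divisor: float = 3.0
    mechanism_potency_median_uM: float = 1.0
    mechanism_potency_sigma: float = 0.7
    seed: int = 42

    def validate(self) -> None:
        for name in ("bit_flip_prob", "p_tested", "p_background_hit",
                     "p_potent_background", "toxic_fraction_per_cluster",
                     "neighbor_tier_prob", "nontoxic_flag_only_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_clusters", "F", "core_bits_per_cluster", "n_assays",
                     "mechanism_assays_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("ld50_sigma", "cytotox_median_toxic_uM", "cytotox_tier_scale",
                     "cytotox_median_nontoxic_uM", "cytotox_sigma",
                     "cytotox_lower_divisor", "mechanism_potency_median_uM",
                     "mechanism_potency_sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.chems_per_cluster
        if not 1 <= lo <= hi:
            raise ValueError("chems_per_cluster must be an increasing positive range")
        if self.core_bits_per_cluster > self.F:
            raise ValueError("core_bits_per_cluster cannot exceed F")
        if self.mechanism_assays_per_cluster * self.n_clusters > self.n_assays:
            raise ValueError("not enough assays for the requested mechanism assays")
        # planted potency must sit stochastically below the cytotoxicity lower
        # bound or the burst filter would erase the ground truth
        if not (
            self.mechanism_potency_median_uM
            < self.cytotox_median_toxic_uM / self.cytotox_lower_divisor
        ):
            raise ValueError(
                "mechanism potency median must lie below the cytotoxicity "
                "lower-bound median of the most toxic tier"
            )


@dataclass
class GroundTruth:
    """Planted structure: cluster labels, mechanism assays, planted activity.

    ``true_cluster`` is 0 for background chemicals.  ``mechanism_assays``
    only lists clusters with at least one toxic member; ``planted_activity``
    holds the (chem_id, assay_id) mechanism pairs that are raw hits.
    """

    true_cluster: dict[str, int]
    mechanism_assays: dict[int, list[str]]
    planted_activity: set[tuple[str, str]]


def _sample_ld50(rng: np.random.Generator, tier: int, sigma: float) -> float:
    lo, hi = _TIER_BANDS[tier]
    mid = float(np.sqrt(lo * hi))
    return float(np.clip(mid * np.exp(sigma * rng.standard_normal()), lo, hi))


def generate_study(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[ChemicalRecord], FingerprintMatrix, AssayDataset, GroundTruth]:
    """Generate a complete synthetic study (fully seed-reproducible)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ncl = config.n_clusters
    lo, hi = config.chems_per_cluster

    # 1. cluster cores, 2. cluster base tiers, 3. membership sizes
    cores = [rng.choice(config.F, size=config.core_bits_per_cluster, replace=False)
             for _ in range(ncl)]
    p5 = 1.0 - config.toxic_fraction_per_cluster
    tier_probs = [config.toxic_fraction_per_cluster / 4] * 4 + [p5]
    cluster_tier = rng.choice(np.arange(1, 6), size=ncl, p=tier_probs)
    # one drift direction per cluster, so a cluster spans at most the base
    # tier and one neighboring tier
    drift = rng.choice((-1, 1), size=ncl)
    drift[cluster_tier == 1] = 1
    drift[cluster_tier == 5] = -1
    sizes = rng.integers(lo, hi + 1, size=ncl)

    chem_cluster: list[int] = []
    for k in range(ncl):
        chem_cluster.extend([k + 1] * int(sizes[k]))
    chem_cluster.extend([0] * config.n_background_chemicals)
    n = len(chem_cluster)
    chem_ids = [f"C{i + 1:05d}" for i in range(n)]

    # 4. fingerprints
    bits = np.zeros((n, config.F), dtype=np.uint8)
    density = config.core_bits_per_cluster / config.F
    for i, cl in enumerate(chem_cluster):
        if cl > 0:
            v = np.zeros(config.F, dtype=np.uint8)
            v[cores[cl - 1]] = 1
            flips = rng.random(config.F) < config.bit_flip_prob
            bits[i] = np.where(flips, 1 - v, v)
        else:
            bits[i] = (rng.random(config.F) < density).astype(np.uint8)

    # 5. member tiers (base with neighbor drift) and LD50s
    tier = np.zeros(n, dtype=np.int64)
    ld50 = np.full(n, np.nan)
    flag_only = np.zeros(n, dtype=bool)
    for i, cl in enumerate(chem_cluster):
        if cl > 0:
            t = int(cluster_tier[cl - 1])
            if rng.random() < config.neighbor_tier_prob:
                t = int(np.clip(t + drift[cl - 1], 1, 5))
        else:
            t = int(rng.integers(1, 6))
        tier[i] = t
        if t == 5 and rng.random() < config.nontoxic_flag_only_prob:
            flag_only[i] = True  # limit-test designation, no LD50
        else:
            ld50[i] = _sample_ld50(rng, t, config.ld50_sigma)
    toxic = tier <= 4

    # 6. cytotoxicity point and lower bound (tier-dependent median)
    median = np.where(
        toxic,
        config.cytotox_median_toxic_uM * config.cytotox_tier_scale ** (tier - 1),
        config.cytotox_median_nontoxic_uM,
    )
    cyto = median * np.exp(config.cytotox_sigma * rng.standard_normal(n))
    cyto_lower = cyto / config.cytotox_lower_divisor

    # 7. assays, mechanism assignment and testing mask
    assay_ids = [f"A{j + 1:04d}" for j in range(config.n_assays)]
    mech_flat = rng.choice(
        config.n_assays,
        size=ncl * config.mechanism_assays_per_cluster,
        replace=False,
    )
    aidx = {a: j for j, a in enumerate(assay_ids)}
    mechanism: dict[int, list[str]] = {}
    for k in range(ncl):
        members = [i for i, cl in enumerate(chem_cluster) if cl == k + 1 and toxic[i]]
        if members:
            mechanism[k + 1] = [
                assay_ids[j]
                for j in mech_flat[
                    k * config.mechanism_assays_per_cluster:
                    (k + 1) * config.mechanism_assays_per_cluster
                ]
            ]
    tested = rng.random((n, config.n_assays)) < config.p_tested
    # guarantee each mechanism assay sees at least one of its toxic members
    for k, assays_k in mechanism.items():
        members = [i for i, cl in enumerate(chem_cluster) if cl == k and toxic[i]]
        for a in assays_k:
            tested[members[0], aidx[a]] = True

    # 8. mechanism activity, 9. background hits
    raw_hit = np.zeros((n, config.n_assays), dtype=bool)
    ac50 = np.full((n, config.n_assays), np.nan)
    planted: set[tuple[str, str]] = set()
    for i, cl in enumerate(chem_cluster):
        if cl == 0 or not toxic[i] or cl not in mechanism:
            continue
        for a in mechanism[cl]:
            j = aidx[a]
            if tested[i, j]:
                planted.add((chem_ids[i], a))
                raw_hit[i, j] = True
                ac50[i, j] = config.mechanism_potency_median_uM * float(
                    np.exp(config.mechanism_potency_sigma * rng.standard_normal())
                )
    bg = tested & ~raw_hit & (rng.random((n, config.n_assays)) < config.p_background_hit)
    potent = rng.random((n, config.n_assays)) < config.p_potent_background
    u_low = rng.uniform(0.05, 0.8, size=(n, config.n_assays))
    u_high = rng.uniform(1.0, 5.0, size=(n, config.n_assays))
    raw_hit |= bg
    ac50 = np.where(bg & potent, cyto_lower[:, None] * u_low, ac50)
    ac50 = np.where(bg & ~potent, cyto[:, None] * u_high, ac50)

    chemicals = derive_toxicity_labels(
        [
            ChemicalRecord(
                chem_id=chem_ids[i],
                ld50=None if np.isnan(ld50[i]) else float(ld50[i]),
                nontoxic_flag=True if flag_only[i] else None,
                cytotox_point=float(cyto[i]),
                cytotox_lower_bound=float(cyto_lower[i]),
            )
            for i in range(n)
        ]
    )
    fps = FingerprintMatrix(chem_ids=chem_ids, bits=bits)
    assays = AssayDataset(chem_ids, assay_ids, tested, raw_hit, ac50)
    truth = GroundTruth(
        true_cluster=dict(zip(chem_ids, chem_cluster)),
        mechanism_assays=mechanism,
        planted_activity=planted,
    )
    return chemicals, fps, assays, truth


def null_study(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[ChemicalRecord], FingerprintMatrix, AssayDataset, GroundTruth]:
    """Matched study with toxicity labels permuted independently of activity.

    Fingerprints, cytotoxicity values and the assay matrices are identical to
    :func:`generate_study` at the same seed; only the (LD50, limit-test flag)
    pairs are shuffled across chemicals, severing the activity-toxicity link
    while preserving every marginal distribution.
    """
    chemicals, fps, assays, truth = generate_study(config)
    rng = np.random.default_rng(
        int(np.random.default_rng(config.seed).integers(2**31)) + 1
    )
    perm = rng.permutation(len(chemicals))
    shuffled = [
        ChemicalRecord(
            chem_id=c.chem_id,
            smiles=c.smiles,
            ld50=chemicals[k].ld50,
            nontoxic_flag=chemicals[k].nontoxic_flag,
            cytotox_point=c.cytotox_point,
            cytotox_lower_bound=c.cytotox_lower_bound,
        )
        for c, k in zip(chemicals, perm)
    ]
    return derive_toxicity_labels(shuffled), fps, assays, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_cluster": truth.true_cluster,
        "mechanism_assays": {str(k): v for k, v in truth.mechanism_assays.items()},
        "planted_activity": sorted(list(p) for p in truth.planted_activity),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
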