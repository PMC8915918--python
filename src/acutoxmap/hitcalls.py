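"""Cytotoxicity-burst filtering of raw hit calls.

High-throughput screens show a "burst" of non-specific activity near a
chemical's cytotoxic concentration.  A raw hit is kept as target-mediated
(burst hit = 1) only when its AC50 lies strictly below the chemical-specific
lower bound of cytotoxicity; hits at or above that bound are set to 0.
Untested chemical-assay combinations keep the distinct ``NOT_TESTED`` state.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import NOT_TESTED, AssayDataset, ChemicalRecord

__all__ = ["burst_hit_matrix", "apply_burst_filter", "activity_summary"]


def burst_hit_matrix(
    assays: AssayDataset,
    chemicals: Sequence[ChemicalRecord],
    missing_bound_policy: str = "no-burst-filter",
    global_default_bound: float = 1000.0,
    strict_below: bool = True,
) -> np.ndarray:
    """Compute the burst hit-call matrix (int8; 1, 0 or ``NOT_TESTED``).

    A tested combination is 1 iff it is a raw hit with a defined AC50
    strictly below the chemical's cytotoxicity lower bound ("below" is read
    strictly; ``strict_below=False`` admits equality).  Chemicals without a
    lower bound follow ``missing_bound_policy``:

    - ``"no-burst-filter"`` (default): every raw hit is treated as within the
      cytotoxicity range (burst_hit = 0) and the chemical is warned about —
      the conservative choice that never manufactures target-specific
      activity;
    - ``"global-default-bound"``: ``global_default_bound`` (µM) is used as
      the bound.
    """
    if missing_bound_policy not in ("no-burst-filter", "global-default-bound"):
        raise ValueError(f"unknown missing-bound policy: {missing_bound_policy!r}")
    order = {c.chem_id: c for c in chemicals}
    if set(assays.chem_ids) - set(order):
        raise ValueError("assay dataset contains chemicals without records")
    bounds = np.array(
        [
            np.nan
            if order[c].cytotox_lower_bound is None
            else order[c].cytotox_lower_bound
            for c in assays.chem_ids
        ]
    )
    no_bound = np.isnan(bounds)
    if missing_bound_policy == "global-default-bound":
        bounds = np.where(no_bound, global_default_bound, bounds)
    elif no_bound.any():
        affected = [c for c, miss in zip(assays.chem_ids, no_bound) if miss]
        has_hit = assays.raw_hit[no_bound].any(axis=1)
        if has_hit.any():
            warnings.warn(
                "chemicals with raw hits but no cytotoxicity lower bound; all "
                "their hits treated as within the cytotoxicity range: "
                + ", ".join(c for c, h in zip(affected, has_hit) if h),
                stacklevel=2,
            )

    burst = np.full(assays.shape, NOT_TESTED, dtype=np.int8)
    burst[assays.tested] = 0
    with np.errstate(invalid="ignore"):
        below = (
            assays.ac50 <= bounds[:, None]
            if not strict_below
            else assays.ac50 < bounds[:, None]
        )
    burst[assays.tested & assays.raw_hit & np.nan_to_num(below, nan=False)] = 1
    return burst


def apply_burst_filter(
    assays: AssayDataset,
    chemicals: Sequence[ChemicalRecord],
    **kwargs,
) -> AssayDataset:
    """Return a copy of the dataset with ``burst_hit`` populated."""
    return dataclasses.replace(
        assays, burst_hit=burst_hit_matrix(assays, chemicals, **kwargs)
    )


def activity_summary(
    chemicals: Sequence[ChemicalRecord], assays: AssayDataset
) -> pd.DataFrame:
    """Funnel counts per toxicity class (the pyramid-plot numbers).

    Rows ``toxic`` / ``nontoxic`` / ``undefined``; columns count chemicals in
    the input, tested in >=1 assay, raw-active in >=1 assay and burst-active
    in >=1 assay.  Counts are non-increasing left to right.
    """
    if assays.burst_hit is None:
        raise ValueError("burst_hit not computed; run apply_burst_filter first")
    by_id = {c.chem_id: c for c in chemicals}
    tox = np.array(
        [
            "undefined"
            if by_id[c].toxic is None
            else ("toxic" if by_id[c].toxic else "nontoxic")
            for c in assays.chem_ids
        ]
    )
    tested = assays.tested.any(axis=1)
    raw = assays.raw_hit.any(axis=1)
    burst = (assays.burst_hit == 1).any(axis=1)
    rows = {}
    for cls in ("toxic", "nontoxic", "undefined"):
        sel = tox == cls
        rows[cls] = {
            "n_input": int(sel.sum()),
            "n_tested": int((sel & tested).sum()),
            "n_raw_active": int((sel & raw).sum()),
            "n_burst_active": int((sel & burst).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
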