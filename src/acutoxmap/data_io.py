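"""Input/output layer: chemicals, fingerprints and assay tables.

All tables are UTF-8 comma-delimited with a header row; missing values are
empty fields.  The three input schemas are:

``chemicals.csv``
    ``chem_id,smiles,ld50_mgkg,nontoxic_flag,cytotox_point_uM,cytotox_lower_uM``
``fingerprints.csv``
    ``chem_id,f1..fF`` with binary entries
``assays.csv`` (long format)
    ``chem_id,assay_id,tested,hit,ac50_uM``

Toxicity labels follow the acute-oral convention: a chemical is *nontoxic*
when its rat oral LD50 exceeds 2,000 mg/kg or when it carries an explicit
limit-test "nontoxic" designation, and *toxic* otherwise.  GHS acute oral
categories are the five LD50 bands 1: <=5, 2: <=50, 3: <=300, 4: <=2000,
5: <=5000 mg/kg (boundaries inclusive in the lower category).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ChemicalRecord",
    "FingerprintMatrix",
    "AssayDataset",
    "NOT_TESTED",
    "GHS_UNCLASSIFIED",
    "NONTOXIC_LD50_THRESHOLD",
    "read_chemicals",
    "read_fingerprints",
    "read_assays",
    "read_inputs",
    "derive_toxicity_labels",
    "ghs_from_ld50",
    "very_toxic_label",
    "toxic_vector",
    "chemicals_to_frame",
    "write_chemicals",
    "write_fingerprints",
    "write_assays",
    "write_manifest",
]

#: Sentinel for chemical-assay combinations that were never tested.  Kept
#: distinct from 0/1 throughout; written as an empty field in CSV output.
NOT_TESTED: int = -1

#: GHS code for an LD50 above every category band (> 5,000 mg/kg by default).
GHS_UNCLASSIFIED: int = 0

#: LD50 cut-off (mg/kg) above which a chemical is classified nontoxic.
NONTOXIC_LD50_THRESHOLD: float = 2000.0

_GHS_UPPER_BOUNDS = (5.0, 50.0, 300.0, 2000.0, 5000.0)


class SchemaError(ValueError):
    """An input table violates its schema or an inter-table constraint."""


@dataclass
class ChemicalRecord:
    """One chemical with its in vivo toxicity and cytotoxicity summary.

    ``toxic`` and ``ghs_category`` are derived by
    :func:`derive_toxicity_labels`; they stay ``None`` until derived, and
    remain ``None`` when no LD50 / limit-test information exists.
    ``ghs_category`` is 1-5, :data:`GHS_UNCLASSIFIED` for LD50 above the top
    band, or ``None`` when no LD50 is present.
    """

    chem_id: str
    smiles: Optional[str] = None
    ld50: Optional[float] = None
    nontoxic_flag: Optional[bool] = None
    cytotox_point: Optional[float] = None
    cytotox_lower_bound: Optional[float] = None
    toxic: Optional[bool] = None
    ghs_category: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ld50 is not None and not self.ld50 > 0:
            raise SchemaError(f"{self.chem_id}: ld50 must be positive, got {self.ld50}")
        if self.cytotox_point is not None and not self.cytotox_point > 0:
            raise SchemaError(f"{self.chem_id}: cytotox_point must be positive")
        if self.cytotox_lower_bound is not None:
            if not self.cytotox_lower_bound > 0:
                raise SchemaError(f"{self.chem_id}: cytotox_lower_bound must be positive")
            if (
                self.cytotox_point is not None
                and self.cytotox_lower_bound > self.cytotox_point
            ):
                raise SchemaError(
                    f"{self.chem_id}: cytotox_lower_bound "
                    f"{self.cytotox_lower_bound} exceeds cytotox_point "
                    f"{self.cytotox_point}"
                )


@dataclass
class FingerprintMatrix:
    """Binary substructure fingerprints, one row per chemical."""

    chem_ids: list[str]
    bits: np.ndarray  # (n_chemicals, F) in {0, 1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.chem_ids):
            raise SchemaError(
                f"fingerprint matrix shape {self.bits.shape} does not match "
                f"{len(self.chem_ids)} chemicals"
            )
        bad = ~np.isin(self.bits, (0, 1))
        if bad.any():
            rows = sorted({self.chem_ids[i] for i in np.nonzero(bad)[0]})
            raise SchemaError(f"non-binary fingerprint entries for: {', '.join(rows)}")
        self.bits = self.bits.astype(np.uint8)

    @property
    def n_features(self) -> int:
        return self.bits.shape[1]


@dataclass
class AssayDataset:
    """Chemical x assay testing status, raw hit calls and AC50 potencies.

    ``ac50`` is in µM, NaN where undefined (untested or inactive).
    ``burst_hit`` is derived by :func:`acutoxmap.hitcalls.apply_burst_filter`;
    entries are 1/0 for tested combinations and :data:`NOT_TESTED` elsewhere.
    """

    chem_ids: list[str]
    assay_ids: list[str]
    tested: np.ndarray  # bool (n, m)
    raw_hit: np.ndarray  # bool (n, m), False wherever untested
    ac50: np.ndarray  # float (n, m), NaN where undefined
    burst_hit: Optional[np.ndarray] = None  # int8 in {-1, 0, 1}

    def __post_init__(self) -> None:
        n, m = len(self.chem_ids), len(self.assay_ids)
        self.tested = np.asarray(self.tested, dtype=bool)
        self.raw_hit = np.asarray(self.raw_hit, dtype=bool)
        self.ac50 = np.asarray(self.ac50, dtype=float)
        for name, arr in (("tested", self.tested), ("raw_hit", self.raw_hit), ("ac50", self.ac50)):
            if arr.shape != (n, m):
                raise SchemaError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        if (self.raw_hit & ~self.tested).any():
            raise SchemaError("raw_hit=1 for untested chemical-assay combinations")
        offending = np.isfinite(self.ac50) & ~self.raw_hit
        if offending.any():
            rows = [
                f"({self.chem_ids[i]}, {self.assay_ids[j]})"
                for i, j in zip(*np.nonzero(offending))
            ]
            raise SchemaError(
                "AC50 present without hit=1 for: " + ", ".join(rows[:20])
            )
        if (np.isfinite(self.ac50) & (self.ac50 <= 0)).any():
            raise SchemaError("AC50 values must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.chem_ids), len(self.assay_ids)

    def chem_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chem_ids)}

    def assay_index(self) -> dict[str, int]:
        return {a: j for j, a in enumerate(self.assay_ids)}


# ---------------------------------------------------------------------------
# readers


def _parse_optional_bool(value: object, where: str) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise SchemaError(f"{where}: cannot parse boolean value {value!r}")


def read_chemicals(path: str | Path) -> list[ChemicalRecord]:
    """Read and validate ``chemicals.csv``; duplicate IDs are an error."""
    df = pd.read_csv(path, dtype={"chem_id": str}, float_precision="round_trip")
    required = {"chem_id", "ld50_mgkg", "nontoxic_flag"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"chemicals table missing columns: {sorted(missing)}")
    dupes = df["chem_id"][df["chem_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"duplicate chem_id values: {sorted(set(dupes))}")

    def opt_float(v: object) -> Optional[float]:
        return None if pd.isna(v) else float(v)

    records = []
    for row in df.itertuples(index=False):
        records.append(
            ChemicalRecord(
                chem_id=str(row.chem_id),
                smiles=None
                if not hasattr(row, "smiles") or pd.isna(row.smiles)
                else str(row.smiles),
                ld50=opt_float(row.ld50_mgkg),
                nontoxic_flag=_parse_optional_bool(
                    row.nontoxic_flag, f"chem {row.chem_id} nontoxic_flag"
                ),
                cytotox_point=opt_float(getattr(row, "cytotox_point_uM", None)),
                cytotox_lower_bound=opt_float(getattr(row, "cytotox_lower_uM", None)),
            )
        )
    return records


def read_fingerprints(path: str | Path, chem_ids: Sequence[str]) -> FingerprintMatrix:
    """Read ``fingerprints.csv``; IDs must be a subset of the chemicals table.

    The returned row order follows the file.  Chemicals without fingerprints
    are simply absent (they are flagged "unclustered" downstream).
    """
    df = pd.read_csv(path, dtype={"chem_id": str}, float_precision="round_trip")
    if "chem_id" not in df.columns:
        raise SchemaError("fingerprint table missing chem_id column")
    known = set(chem_ids)
    unknown = [c for c in df["chem_id"] if c not in known]
    if unknown:
        raise SchemaError(
            f"fingerprint table contains unknown chemicals: {sorted(set(unknown))}"
        )
    dupes = df["chem_id"][df["chem_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"duplicate fingerprint rows: {sorted(set(dupes))}")
    bit_cols = [c for c in df.columns if c != "chem_id"]
    bits = df[bit_cols].to_numpy()
    if np.isnan(bits.astype(float)).any():
        bad = df["chem_id"][np.isnan(bits.astype(float)).any(axis=1)].tolist()
        raise SchemaError(f"fingerprint rows with missing bits: {bad}")
    return FingerprintMatrix(chem_ids=df["chem_id"].tolist(), bits=bits)


def read_assays(path: str | Path, chem_ids: Sequence[str]) -> AssayDataset:
    """Read the long-format assay table into dense matrices.

    Chemicals absent from the table are retained with all-untested rows;
    chemicals present in the table but not in ``chem_ids`` are an error.
    """
    df = pd.read_csv(path, dtype={"chem_id": str, "assay_id": str}, float_precision="round_trip")
    required = {"chem_id", "assay_id", "tested", "hit", "ac50_uM"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"assay table missing columns: {sorted(missing)}")
    known = set(chem_ids)
    unknown = sorted({c for c in df["chem_id"] if c not in known})
    if unknown:
        raise SchemaError(f"assay table contains unknown chemicals: {unknown}")

    assay_ids = sorted(df["assay_id"].unique())
    ci = {c: i for i, c in enumerate(chem_ids)}
    ai = {a: j for j, a in enumerate(assay_ids)}
    n, m = len(chem_ids), len(assay_ids)
    tested = np.zeros((n, m), dtype=bool)
    raw_hit = np.zeros((n, m), dtype=bool)
    ac50 = np.full((n, m), np.nan)

    rows = df["chem_id"].map(ci).to_numpy()
    cols = df["assay_id"].map(ai).to_numpy()
    t = df["tested"].astype(float).to_numpy() > 0
    h = df["hit"].astype(float).fillna(0).to_numpy() > 0
    a = df["ac50_uM"].astype(float).to_numpy()
    tested[rows, cols] = t
    raw_hit[rows, cols] = h
    ac50[rows, cols] = a
    return AssayDataset(list(chem_ids), assay_ids, tested, raw_hit, ac50)


def read_inputs(
    chemicals_path: str | Path,
    fingerprints_path: str | Path,
    assays_path: str | Path,
) -> tuple[list[ChemicalRecord], FingerprintMatrix, AssayDataset]:
    """Read and cross-validate the three input tables (ID-aligned)."""
    chemicals = read_chemicals(chemicals_path)
    ids = [c.chem_id for c in chemicals]
    fps = read_fingerprints(fingerprints_path, ids)
    assays = read_assays(assays_path, ids)
    return chemicals, fps, assays


# ---------------------------------------------------------------------------
# label derivation


def ghs_from_ld50(ld50: float, merge_above_5000: bool = False) -> int:
    """GHS acute oral category for an LD50 in mg/kg.

    Boundary doses fall in the lower (more toxic) category.  LD50 above
    5,000 mg/kg maps to :data:`GHS_UNCLASSIFIED` unless ``merge_above_5000``
    folds it into category 5.
    """
    if not ld50 > 0:
        raise ValueError(f"ld50 must be positive, got {ld50}")
    for cat, upper in enumerate(_GHS_UPPER_BOUNDS, start=1):
        if ld50 <= upper:
            return cat
    return 5 if merge_above_5000 else GHS_UNCLASSIFIED


def derive_toxicity_labels(
    chemicals: Iterable[ChemicalRecord],
    nontoxic_threshold: float = NONTOXIC_LD50_THRESHOLD,
    merge_above_5000: bool = False,
) -> list[ChemicalRecord]:
    """Fill ``toxic`` and ``ghs_category`` on fresh copies of the records.

    A chemical is nontoxic when its limit-test flag says so or its LD50
    exceeds ``nontoxic_threshold``; toxic when the LD50 is at or below the
    threshold or the flag is explicitly false; undefined when neither source
    exists.  A flag of "nontoxic" together with an LD50 at or below the
    threshold is an inconsistent record and raises.
    """
    out = []
    for rec in chemicals:
        rec = dataclasses.replace(rec)
        if rec.ld50 is not None and rec.ld50 <= nontoxic_threshold:
            if rec.nontoxic_flag is True:
                raise SchemaError(
                    f"{rec.chem_id}: nontoxic_flag=true conflicts with "
                    f"ld50={rec.ld50} <= {nontoxic_threshold}"
                )
            rec.toxic = True
        elif rec.ld50 is not None:  # ld50 > threshold
            rec.toxic = False
        elif rec.nontoxic_flag is not None:
            rec.toxic = not rec.nontoxic_flag
        else:
            rec.toxic = None
        rec.ghs_category = (
            None if rec.ld50 is None else ghs_from_ld50(rec.ld50, merge_above_5000)
        )
        out.append(rec)
    return out


def very_toxic_label(
    chemicals: Sequence[ChemicalRecord], threshold: float = 50.0
) -> pd.arrays.BooleanArray:
    """Per-chemical "very acutely toxic" flag: LD50 <= ``threshold`` mg/kg.

    Chemicals without an LD50 get ``pd.NA`` (excluded from contrasts).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    vals = [None if c.ld50 is None else bool(c.ld50 <= threshold) for c in chemicals]
    return pd.array(vals, dtype="boolean")


def toxic_vector(chemicals: Sequence[ChemicalRecord]) -> pd.arrays.BooleanArray:
    """Derived binary toxicity as a nullable boolean array."""
    return pd.array([c.toxic for c in chemicals], dtype="boolean")


# ---------------------------------------------------------------------------
# writers


def chemicals_to_frame(chemicals: Sequence[ChemicalRecord]) -> pd.DataFrame:
    rows = []
    for c in chemicals:
        rows.append(
            {
                "chem_id": c.chem_id,
                "smiles": c.smiles,
                "ld50_mgkg": c.ld50,
                "nontoxic_flag": c.nontoxic_flag,
                "cytotox_point_uM": c.cytotox_point,
                "cytotox_lower_uM": c.cytotox_lower_bound,
                "toxic": c.toxic,
                "ghs_category": c.ghs_category,
            }
        )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_chemicals(chemicals: Sequence[ChemicalRecord], path: str | Path) -> None:
    """Write the input-schema columns of ``chemicals.csv`` (no derived fields)."""
    df = chemicals_to_frame(chemicals).drop(columns=["toxic", "ghs_category"])
    df["nontoxic_flag"] = df["nontoxic_flag"].map(
        {True: "true", False: "false", None: ""}
    )
    _write_csv(df, path)


def write_fingerprints(fps: FingerprintMatrix, path: str | Path) -> None:
    cols = [f"f{i + 1}" for i in range(fps.n_features)]
    df = pd.DataFrame(fps.bits, columns=cols)
    df.insert(0, "chem_id", fps.chem_ids)
    _write_csv(df, path)


def write_assays(assays: AssayDataset, path: str | Path) -> None:
    """Write the long-format assay table; only tested combinations emitted."""
    rows_i, cols_j = np.nonzero(assays.tested)
    df = pd.DataFrame(
        {
            "chem_id": [assays.chem_ids[i] for i in rows_i],
            "assay_id": [assays.assay_ids[j] for j in cols_j],
            "tested": 1,
            "hit": assays.raw_hit[rows_i, cols_j].astype(int),
            "ac50_uM": assays.ac50[rows_i, cols_j],
        }
    )
    _write_csv(df, path)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: dict, seed: Optional[int],
                   outputs: Iterable[str | Path] = ()) -> None:
    """Write the JSON run manifest: config, seed, versions, output checksums."""
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "acutoxmap": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "checksums": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
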