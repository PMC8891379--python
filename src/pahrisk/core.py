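"""Domain types and I/O for censored PAH concentration data.

The analytical panel is the 16 EPA priority polycyclic aromatic
hydrocarbons (PAHs), each carried with its method limit of detection
(LOD), limit of quantification (LOQ) and a toxicity equivalency factor
(TEF) relative to benzo[a]pyrene.  Concentrations are stored internally
in ug/kg; measurements below the LOD are *censored* ("non-detect") and
carry no numeric value until :func:`impute_nondetects` substitutes a
deterministic surrogate (half the LOD by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ValidationError",
    "CongenerSpec",
    "CongenerPanel",
    "Measurement",
    "SampleRecord",
    "SampleDataset",
    "PAH4_MEMBERS",
    "ND_TOKENS",
    "IMPUTATION_RULES",
    "load_panel",
    "load_dataset",
    "write_dataset",
    "impute_nondetects",
    "convert_concentration",
]

PAH4_MEMBERS = ("BaA", "Ch", "BbF", "BaP")

#: non-detect spellings accepted on ingest (case-insensitive)
ND_TOKENS = frozenset({"nd", "<lod"})


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class CongenerSpec:
    """One congener of the analytical panel.

    ``lod``/``loq`` are method limits in ug/kg; ``tef`` is the
    dimensionless potency of the congener relative to benzo[a]pyrene.
    ``sim_ions`` carries GC-MS selected-ion metadata (quantification and
    confirmation m/z, retention-time window) and takes no part in any
    computation.
    """

    abbrev: str
    name: str
    lod: float
    loq: float
    tef: float
    sim_ions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValidationError(f"{self.abbrev}: LOD must be > 0, got {self.lod}")
        if self.loq < self.lod:
            raise ValidationError(
                f"{self.abbrev}: LOQ ({self.loq}) must be >= LOD ({self.lod})"
            )
        if self.tef < 0:
            raise ValidationError(f"{self.abbrev}: TEF must be >= 0, got {self.tef}")


@dataclass(frozen=True)
class CongenerPanel:
    """Ordered registry of exactly 16 congeners plus the PAH4 subset."""

    congeners: tuple[CongenerSpec, ...]
    pah4_members: tuple[str, ...] = PAH4_MEMBERS

    def __post_init__(self) -> None:
        abbrevs = [c.abbrev for c in self.congeners]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValidationError(f"duplicate congener abbreviations: {dupes}")
        if len(self.congeners) != 16:
            raise ValidationError(
                f"panel must contain exactly 16 congeners, got {len(self.congeners)}"
            )
        missing = [a for a in self.pah4_members if a not in abbrevs]
        if missing or len(self.pah4_members) != 4:
            raise ValidationError(f"invalid PAH4 subset {self.pah4_members}: {missing}")

    @property
    def abbrevs(self) -> tuple[str, ...]:
        return tuple(c.abbrev for c in self.congeners)

    def get(self, abbrev: str) -> CongenerSpec:
        for c in self.congeners:
            if c.abbrev == abbrev:
                return c
        raise KeyError(abbrev)

    def __iter__(self) -> Iterator[CongenerSpec]:
        return iter(self.congeners)

    def __len__(self) -> int:
        return len(self.congeners)

    @property
    def tefs(self) -> dict[str, float]:
        return {c.abbrev: c.tef for c in self.congeners}

    @property
    def lods(self) -> dict[str, float]:
        return {c.abbrev: c.lod for c in self.congeners}


@dataclass(frozen=True)
class Measurement:
    """A single concentration cell: numeric (ug/kg) or censored."""

    congener: str
    value: float | None
    censored: bool

    def __post_init__(self) -> None:
        if self.censored:
            if self.value is not None:
                raise ValidationError(
                    f"{self.congener}: censored measurement must not carry a value"
                )
        else:
            if self.value is None or self.value < 0:
                raise ValidationError(
                    f"{self.congener}: detected value must be >= 0, got {self.value}"
                )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    product_type: str
    brand: str
    measurements: tuple[Measurement, ...]

    def measurement(self, abbrev: str) -> Measurement:
        for m in self.measurements:
            if m.congener == abbrev:
                return m
        raise KeyError(abbrev)


@dataclass(frozen=True)
class SampleDataset:
    """Per-sample, per-congener measurements with product-type/brand labels."""

    panel: CongenerPanel
    records: tuple[SampleRecord, ...]
    imputed: bool = False

    def __post_init__(self) -> None:
        valid = set(self.panel.abbrevs)
        for rec in self.records:
            seen = [m.congener for m in rec.measurements]
            unknown = sorted(set(seen) - valid)
            if unknown:
                raise ValidationError(f"{rec.sample_id}: unknown congeners {unknown}")
            if len(seen) != len(valid) or set(seen) != valid:
                raise ValidationError(
                    f"{rec.sample_id}: expected one measurement per panel congener"
                )
            if self.imputed and any(m.censored for m in rec.measurements):
                raise ValidationError(
                    f"{rec.sample_id}: imputed dataset contains censored cells"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self, nd_token: str = "nd") -> pd.DataFrame:
        """Wide table: sample_id, product_type, brand, one column per congener.

        Censored cells are rendered as ``nd_token``; the frame round-trips
        through :func:`write_dataset` / :func:`load_dataset` losslessly.
        """
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "sample_id": rec.sample_id,
                "product_type": rec.product_type,
                "brand": rec.brand,
            }
            for ab in self.panel.abbrevs:
                m = rec.measurement(ab)
                row[ab] = nd_token if m.censored else m.value
            rows.append(row)
        return pd.DataFrame(rows)

    def concentrations(self) -> pd.DataFrame:
        """Numeric sample x congener matrix (requires an imputed dataset)."""
        if not self.imputed:
            raise ValidationError("dataset still contains censored cells; impute first")
        df = self.to_frame()
        df = df.set_index("sample_id")
        return df[list(self.panel.abbrevs)].astype(float)

    @property
    def product_types(self) -> pd.Series:
        return pd.Series(
            [r.product_type for r in self.records],
            index=[r.sample_id for r in self.records],
            name="product_type",
        )


def _packaged(name: str) -> Path:
    return Path(resources.files("pahrisk.data") / name)


def load_panel(path: str | Path | None = None) -> CongenerPanel:
    """Read a congener registry (defaults to the packaged study panel).

    The registry is delimited text with columns ``abbrev, name, lod_ug_kg,
    loq_ug_kg, tef`` and optional SIM-ion metadata columns.  Missing TEF
    cells fall back to the packaged default TEF set.
    """
    path = _packaged("congener_panel.csv") if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"abbrev", "name", "lod_ug_kg", "loq_ug_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"registry missing columns: {sorted(missing)}")
    default_tefs = DEFAULT_TEFS
    specs = []
    for _, row in df.iterrows():
        abbrev = str(row["abbrev"]).strip()
        tef_cell = row.get("tef")
        if tef_cell is None or (isinstance(tef_cell, float) and math.isnan(tef_cell)) \
                or str(tef_cell).strip() == "":
            tef = default_tefs.get(abbrev)
            if tef is None:
                raise ValidationError(f"{abbrev}: no TEF given and no default known")
        else:
            tef = float(tef_cell)
        ions = None
        if "quantification_ion" in df.columns:
            ions = {
                "quantification_ion": str(row.get("quantification_ion", "")),
                "confirmation_ions": str(row.get("confirmation_ions", "")),
                "time_window": str(row.get("time_window", "")),
            }
        specs.append(
            CongenerSpec(
                abbrev=abbrev,
                name=str(row["name"]).strip(),
                lod=float(row["lod_ug_kg"]),
                loq=float(row["loq_ug_kg"]),
                tef=tef,
                sim_ions=ions,
            )
        )
    return CongenerPanel(congeners=tuple(specs))


#: Nisbet & LaGoy relative-potency scheme (BaP reference); also the
#: fallback when a registry file omits its TEF column.
DEFAULT_TEFS: dict[str, float] = {
    "NA": 0.001, "Ace": 0.001, "Ac": 0.001, "F": 0.001, "Pa": 0.001,
    "A": 0.01, "Fl": 0.001, "P": 0.001, "BaA": 0.1, "Ch": 0.01,
    "BbF": 0.1, "BkF": 0.1, "BaP": 1.0, "DhA": 1.0, "IP": 0.1, "BgP": 0.01,
}


def _is_nd(cell: str, nd_token: str) -> bool:
    s = str(cell).strip().lower()
    return s == nd_token.lower() or s in ND_TOKENS


def load_dataset(
    path: str | Path,
    panel: CongenerPanel,
    nd_token: str = "nd",
) -> SampleDataset:
    """Parse a per-sample concentration table into a censored dataset.

    Expects columns ``sample_id, product_type, brand`` followed by one
    column per panel congener; cells are ug/kg numbers or a non-detect
    token (``nd``/``<LOD`` accepted case-insensitively).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta_cols = ["sample_id", "product_type", "brand"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"dataset missing columns: {missing}")
    data_cols = [c for c in df.columns if c not in meta_cols]
    unknown = sorted(set(data_cols) - set(panel.abbrevs))
    if unknown:
        raise ValidationError(f"unknown congener columns: {unknown}")
    absent = sorted(set(panel.abbrevs) - set(data_cols))
    if absent:
        raise ValidationError(f"missing congener columns: {absent}")
    records = []
    for _, row in df.iterrows():
        ms = []
        for ab in panel.abbrevs:
            cell = row[ab]
            if _is_nd(cell, nd_token):
                ms.append(Measurement(ab, None, True))
            else:
                v = float(cell)
                if v < 0:
                    raise ValidationError(
                        f"{row['sample_id']}/{ab}: negative concentration {v}"
                    )
                ms.append(Measurement(ab, v, False))
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                product_type=str(row["product_type"]),
                brand=str(row["brand"]),
                measurements=tuple(ms),
            )
        )
    return SampleDataset(panel=panel, records=tuple(records), imputed=False)


def write_dataset(ds: SampleDataset, path: str | Path, nd_token: str = "nd") -> None:
    ds.to_frame(nd_token=nd_token).to_csv(path, index=False)


IMPUTATION_RULES = ("half_lod", "zero", "lod", "loq")


def impute_nondetects(ds: SampleDataset, rule: str = "half_lod") -> SampleDataset:
    """Replace every censored cell by a deterministic surrogate.

    ``half_lod`` (the default) substitutes LOD/2, the study's convention
    for computing means over non-detects; ``zero``/``lod``/``loq`` are the
    standard lower/upper sensitivity bounds.  Detected values pass through
    unchanged, and imputing an already-imputed dataset is a no-op.
    """
    if rule not in IMPUTATION_RULES:
        raise ValidationError(f"unknown imputation rule {rule!r}; use {IMPUTATION_RULES}")
    if ds.imputed:
        return ds

    def surrogate(spec: CongenerSpec) -> float:
        if rule == "half_lod":
            return spec.lod / 2.0
        if rule == "zero":
            return 0.0
        if rule == "lod":
            return spec.lod
        return spec.loq

    new_records = []
    for rec in ds.records:
        ms = tuple(
            m if not m.censored
            else Measurement(m.congener, surrogate(ds.panel.get(m.congener)), False)
            for m in rec.measurements
        )
        new_records.append(replace(rec, measurements=ms))
    return SampleDataset(panel=ds.panel, records=tuple(new_records), imputed=True)


_UNIT_TO_UG = {
    "ug/kg": 1.0,
    "µg/kg": 1.0,   # micro sign
    "μg/kg": 1.0,   # greek mu
    "mg/kg": 1e3,
    "ng/kg": 1e-3,
}


def convert_concentration(value: float, from_unit: str, to_unit: str) -> float:
    """Exact power-of-ten conversion between ng/kg, ug/kg and mg/kg."""
    try:
        f = _UNIT_TO_UG[from_unit]
        t = _UNIT_TO_UG[to_unit]
    except KeyError as exc:
        raise ValidationError(f"unknown concentration unit {exc.args[0]!r}") from None
    return value * (f / t)
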