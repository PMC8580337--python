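"""Cohort containers and delimited-table I/O.

A cohort is an individuals × traits matrix of mixed-type quantitative
measurements plus per-individual metadata (chronological age, sex, vital
status, lifespan, study wave). Missing cells are carried as NaN in the
trait matrix; the iterative trait-blind cleaner removes them before any
modelling step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("physioage")

MISSING_TOKENS = {"", "na", "nan"}

META_COLUMNS = ["id", "age", "sex", "deceased", "lifespan", "wave"]

TRAIT_KINDS = ("continuous", "ordinal", "binary")


@dataclass(frozen=True)
class IndividualRecord:
    """One study participant.

    ``age`` is chronological age in years at the wave of measurement and is
    the prediction target; ``lifespan`` is age at death, present iff
    ``deceased``.
    """

    id: str
    age: float
    sex: int
    deceased: bool
    lifespan: float | None = None
    wave: int = 1

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age} for id {self.id!r}")
        if self.deceased and (self.lifespan is None or not np.isfinite(self.lifespan)):
            raise ValueError(f"deceased individual {self.id!r} has no lifespan")
        if self.wave < 1:
            raise ValueError(f"wave must be >= 1, got {self.wave}")


@dataclass(frozen=True)
class TraitDescriptor:
    name: str
    kind: str = "continuous"
    description: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.name!r}")


@dataclass
class CohortTable:
    """Individuals × traits matrix with typed columns and metadata.

    ``values`` is a float DataFrame indexed by individual id with one column
    per trait; missing cells are NaN. ``meta`` is indexed by the same ids.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    descriptors: list[TraitDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("trait matrix and metadata must share the same id index")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate id {dup!r}")
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("trait descriptor names are not unique")
        if self.descriptors and names != list(self.values.columns):
            raise ValueError("descriptor order does not match trait columns")
        if not self.descriptors:
            self.descriptors = [
                TraitDescriptor(c, infer_trait_kind(self.values[c]))
                for c in self.values.columns
            ]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def ages(self) -> np.ndarray:
        return self.meta["age"].to_numpy(float)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    def individuals(self) -> list[IndividualRecord]:
        out = []
        for pid, row in self.meta.iterrows():
            dead = bool(row["deceased"])
            lifespan = float(row["lifespan"]) if dead else None
            out.append(
                IndividualRecord(
                    id=str(pid),
                    age=float(row["age"]),
                    sex=int(row["sex"]),
                    deceased=dead,
                    lifespan=lifespan,
                    wave=int(row.get("wave", 1)),
                )
            )
        return out

    def subset(
        self, ids: Sequence[str] | None = None, traits: Sequence[str] | None = None
    ) -> "CohortTable":
        vals = self.values
        meta = self.meta
        desc = self.descriptors
        if traits is not None:
            traits = list(traits)
            vals = vals[traits]
            desc = [d for d in desc if d.name in set(traits)]
            desc = sorted(desc, key=lambda d: traits.index(d.name))
        if ids is not None:
            ids = list(ids)
            vals = vals.loc[ids]
            meta = meta.loc[ids]
        return CohortTable(vals.copy(), meta.copy(), list(desc))


def infer_trait_kind(col: pd.Series, ordinal_max_levels: int = 10) -> str:
    """Classify a numeric trait column as binary / ordinal / continuous.

    At most 2 distinct non-missing values -> binary; at most
    ``ordinal_max_levels`` distinct integer-coded values -> ordinal;
    otherwise continuous.
    """
    vals = col.dropna().unique()
    if len(vals) <= 2:
        return "binary"
    if len(vals) <= ordinal_max_levels and np.allclose(vals, np.round(vals)):
        return "ordinal"
    return "continuous"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return df


def _sep_for(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _to_float(raw: pd.DataFrame, context: str) -> pd.DataFrame:
    """Parse string cells to float, mapping missing tokens to NaN."""
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        parsed = []
        for i, cell in enumerate(raw[col]):
            token = cell.strip()
            if token.lower() in MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(token))
            except ValueError as exc:
                raise ValueError(
                    f"{context}: non-numeric value {cell!r} at row {i}, column {col!r}"
                ) from exc
        out[col] = parsed
    return out


def read_cohort(
    trait_path: str | Path,
    meta_path: str | Path,
    descriptor_path: str | Path | None = None,
) -> CohortTable:
    """Read a cohort from delimited trait and metadata tables.

    CSV vs TSV is auto-detected from the file extension. Empty cells and the
    tokens NA / NaN (case-insensitive) are treated as missing. Trait kinds
    are inferred unless ``descriptor_path`` overrides them.
    """
    traits_raw = _read_delimited(trait_path)
    meta_raw = _read_delimited(meta_path)
    for col in META_COLUMNS:
        if col not in meta_raw.columns:
            raise ValueError(f"metadata file is missing required column {col!r}")
    if "id" not in traits_raw.columns:
        raise ValueError("trait file is missing required column 'id'")

    for name, frame in (("trait", traits_raw), ("metadata", meta_raw)):
        dups = frame["id"][frame["id"].duplicated()]
        if len(dups):
            raise ValueError(f"duplicate id {dups.iloc[0]!r} in {name} table")

    meta = meta_raw.set_index("id")
    unknown = set(traits_raw["id"]) - set(meta.index)
    if unknown:
        raise ValueError(f"trait-table ids missing from metadata: {sorted(unknown)[:5]}")

    values = _to_float(traits_raw.set_index("id"), "trait table")
    meta_out = pd.DataFrame(index=values.index)
    meta_num = _to_float(meta[["age", "sex", "lifespan", "wave"]], "metadata")
    meta_out["age"] = meta_num.loc[values.index, "age"]
    meta_out["sex"] = meta_num.loc[values.index, "sex"].astype(int)
    dec_raw = meta.loc[values.index, "deceased"].str.strip().str.lower()
    meta_out["deceased"] = dec_raw.isin({"1", "true", "yes", "t"})
    meta_out["lifespan"] = meta_num.loc[values.index, "lifespan"]
    meta_out["wave"] = meta_num.loc[values.index, "wave"].fillna(1).astype(int)

    bad = meta_out.index[meta_out["deceased"] & meta_out["lifespan"].isna()]
    if len(bad):
        raise ValueError(f"deceased individual {bad[0]!r} has no lifespan")

    descriptors: list[TraitDescriptor] = []
    if descriptor_path is not None:
        ddf = _read_delimited(descriptor_path)
        by_name = {
            r["name"]: TraitDescriptor(
                r["name"], r["kind"], r.get("description", ""), r.get("units", "")
            )
            for _, r in ddf.iterrows()
        }
        descriptors = [
            by_name.get(c, TraitDescriptor(c, infer_trait_kind(values[c])))
            for c in values.columns
        ]
    return CohortTable(values, meta_out, descriptors)


def write_cohort(cohort: CohortTable, trait_path: str | Path, meta_path: str | Path) -> None:
    """Write trait and metadata tables in the dialect implied by each extension.

    Numeric values are emitted with 12+ significant digits so that a
    read/write cycle round-trips.
    """
    vals = cohort.values.copy()
    vals.index.name = "id"
    vals.to_csv(trait_path, sep=_sep_for(trait_path), float_format="%.17g", na_rep="NA")
    meta = cohort.meta.copy()
    meta.index.name = "id"
    meta["deceased"] = meta["deceased"].astype(int)
    meta.to_csv(meta_path, sep=_sep_for(meta_path), float_format="%.17g", na_rep="NA")


def clean_missing(
    cohort: CohortTable, trait_frac: float = 0.8, indiv_frac: float = 0.8
) -> CohortTable:
    """Trait-blind iterative removal of missing data.

    Alternates (a) dropping traits whose missing fraction exceeds
    ``1 - trait_frac`` and (b) dropping individuals whose missing fraction
    exceeds ``1 - indiv_frac``, recomputing fractions each pass. Once the
    thresholds no longer remove anything but missing cells remain, the
    worst-offending trait or individual (highest missing fraction, traits
    first on ties) is dropped one at a time until the matrix is
    complete-case. Deterministic given input order.
    """
    if not (0 < trait_frac <= 1 and 0 < indiv_frac <= 1):
        raise ValueError("trait_frac and indiv_frac must lie in (0, 1]")
    vals = cohort.values
    n_pass = 0
    while vals.size and vals.isna().any().any():
        n_pass += 1
        col_missing = vals.isna().mean(axis=0)
        keep_cols = col_missing[col_missing <= (1 - trait_frac)].index
        dropped_cols = vals.shape[1] - len(keep_cols)
        vals = vals[keep_cols]
        row_missing = vals.isna().mean(axis=1) if vals.shape[1] else pd.Series(dtype=float)
        keep_rows = row_missing[row_missing <= (1 - indiv_frac)].index
        dropped_rows = vals.shape[0] - len(keep_rows)
        vals = vals.loc[keep_rows]
        logger.info(
            "clean_missing pass %d: dropped %d traits, %d individuals",
            n_pass, dropped_cols, dropped_rows,
        )
        if dropped_cols == 0 and dropped_rows == 0:
            # thresholds satisfied but cells remain: greedy drop-worst
            col_missing = vals.isna().mean(axis=0)
            row_missing = vals.isna().mean(axis=1)
            if col_missing.max() >= row_missing.max():
                vals = vals.drop(columns=col_missing.idxmax())
            else:
                vals = vals.drop(index=row_missing.idxmax())
    if vals.shape[0] == 0 or vals.shape[1] == 0:
        raise ValueError(
            f"cleaning with trait_frac={trait_frac}, indiv_frac={indiv_frac} "
            "removed every trait or every individual"
        )
    return cohort.subset(ids=list(vals.index), traits=list(vals.columns))
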