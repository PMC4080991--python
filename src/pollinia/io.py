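"""Delimited-text I/O for visit and genotype tables, plus run configuration.

Two tables drive a run:

* the **visit table** — one row per observed inflorescence visit or bagged
  control, with the visitor taxon, behavior counts (flowers visited,
  pollinium insertions and removals) and floral-display sizes (open flowers
  on the focal inflorescence and on its stem);
* the **genotype table** — long format, one row per (sample, locus):
  ``sample_id, sample_kind (maternal|pollinium), locus, allele1, allele2``
  with missing calls left empty; pollinium rows additionally carry
  ``taxon``, ``visit_id`` and ``maternal_id`` linking each inserted
  pollinium to its maternal stem and visit.

Headers are matched through an alias map so both terse names
(``insertions``) and verbose supplementary-table style names
(``number of pollinium insertions``) load without editing the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genotypes import MultilocusGenotype, make_call
from .selfing import CONTROL, PolliniumRecord

logger = logging.getLogger("pollinia")

#: Each flower carries five pollinaria and five stigmatic slits, so a single
#: visit can neither remove nor insert more than five pollinia per flower.
MAX_POLLINIA_PER_FLOWER = 5


class TableSchemaError(ValueError):
    """A mandatory column is missing or a value cannot be parsed."""


class RowValidationError(ValueError):
    """One or more rows violate a record invariant; row numbers included."""


@dataclass(frozen=True)
class VisitRecord:
    """One observed inflorescence visit, or one bagged control."""

    visit_id: str
    taxon: str
    flowers_visited: int
    inflorescence_size: int
    stem_size: int
    insertions: int
    removals: int
    visit_time: Optional[float] = None
    maternal_genotype_id: Optional[str] = None
    site: Optional[str] = None
    period: str = "diurnal"

    def __post_init__(self) -> None:
        problems = self.validation_errors()
        if problems:
            raise ValueError(f"visit {self.visit_id!r}: " + "; ".join(problems))

    def validation_errors(self) -> list[str]:
        errs = []
        for name in ("flowers_visited", "insertions", "removals"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if self.inflorescence_size <= 0:
            errs.append("inflorescence_size must be > 0")
        if self.stem_size <= 0:
            errs.append("stem_size must be > 0")
        elif self.inflorescence_size > self.stem_size:
            errs.append("inflorescence_size exceeds stem_size")
        cap = MAX_POLLINIA_PER_FLOWER * self.inflorescence_size
        if self.insertions > cap:
            errs.append(
                f"insertions ({self.insertions}) exceed "
                f"{MAX_POLLINIA_PER_FLOWER} per flower ({cap})"
            )
        if self.removals > cap:
            errs.append(
                f"removals ({self.removals}) exceed "
                f"{MAX_POLLINIA_PER_FLOWER} per flower ({cap})"
            )
        if self.taxon == CONTROL and self.flowers_visited != 0:
            errs.append("CONTROL rows must have flowers_visited = 0")
        if self.period not in ("diurnal", "nocturnal"):
            errs.append(f"period must be diurnal|nocturnal, got {self.period!r}")
        return errs

    @property
    def is_control(self) -> bool:
        return self.taxon == CONTROL


@dataclass
class RunConfig:
    """Tunable parameters for one pipeline run.

    ``self_compatibility`` is the proportion of self insertions that can
    still sire seed (default 0.05, a conservative literature value); the
    self-incompatibility rate used by the importance indices is its
    complement. ``sampling_effort_ratio`` is diurnal observation hours
    divided by nocturnal observation hours and must be supplied by the
    study design — it is not estimable from the tables.
    """

    n_bootstrap: int = 1000
    n_permutation: int = 1000
    rng_seed: int = 0
    self_compatibility: float = 0.05
    sampling_effort_ratio: float = 1.0
    clamp_policy: str = "clamp"
    freq_method: str = "round_robin"  # round_robin | naive
    freq_basis: str = "pollen_pool"  # pollen_pool | maternal
    alpha_weighting: str = "pollinium"  # pollinium | inflorescence
    resample_unit: str = "pollinium"  # pollinium | inflorescence

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.n_permutation < 1:
            raise ValueError("replicate counts must be >= 1")
        if not 0.0 <= self.self_compatibility <= 1.0:
            raise ValueError("self_compatibility must be in [0, 1]")
        if self.sampling_effort_ratio <= 0:
            raise ValueError("sampling_effort_ratio must be > 0")
        for name, allowed in (
            ("clamp_policy", ("clamp", "error")),
            ("freq_method", ("round_robin", "naive")),
            ("freq_basis", ("pollen_pool", "maternal")),
            ("alpha_weighting", ("pollinium", "inflorescence")),
            ("resample_unit", ("pollinium", "inflorescence")),
        ):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")

    @property
    def self_incompatibility(self) -> float:
        return 1.0 - self.self_compatibility

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


#: Header aliases: verbose supplementary-table style names -> field names.
VISIT_COLUMN_ALIASES = {
    "visit_id": "visit_id",
    "sample number": "visit_id",
    "sample_number": "visit_id",
    "taxon": "taxon",
    "visitor taxon": "taxon",
    "visitor_taxon": "taxon",
    "flowers_visited": "flowers_visited",
    "number of flowers visited": "flowers_visited",
    "inflorescence_size": "inflorescence_size",
    "inflorescence size": "inflorescence_size",
    "number of flowers on the inflorescence": "inflorescence_size",
    "stem_size": "stem_size",
    "stem size": "stem_size",
    "number of flowers on the inflorescence's stem": "stem_size",
    "insertions": "insertions",
    "number of insertions": "insertions",
    "number of pollinium insertions": "insertions",
    "removals": "removals",
    "number of removals": "removals",
    "number of pollinium removals": "removals",
    "visit_time": "visit_time",
    "visiting time": "visit_time",
    "maternal_genotype_id": "maternal_genotype_id",
    "maternal genotype": "maternal_genotype_id",
    "site": "site",
    "period": "period",
}

_MANDATORY_VISIT_FIELDS = (
    "visit_id",
    "taxon",
    "flowers_visited",
    "inflorescence_size",
    "stem_size",
    "insertions",
    "removals",
)
_INT_VISIT_FIELDS = (
    "flowers_visited",
    "inflorescence_size",
    "stem_size",
    "insertions",
    "removals",
)


def _read_delimited(path, dialect: Optional[str]) -> pd.DataFrame:
    if dialect is None:
        return pd.read_csv(path, sep=None, engine="python", dtype=str)
    return pd.read_csv(path, sep=dialect, dtype=str)


def read_visit_table(
    path,
    dialect: Optional[str] = None,
    aliases: Optional[dict] = None,
) -> list[VisitRecord]:
    """Load and validate a visit table; delimiter autodetected by default.

    Unknown columns are ignored with a logged warning; missing mandatory
    columns raise :class:`TableSchemaError`; invariant-violating rows raise
    :class:`RowValidationError` naming the offending rows (1-based data row
    numbers).
    """
    alias_map = dict(VISIT_COLUMN_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    df = _read_delimited(path, dialect)

    rename = {}
    unknown = []
    for col in df.columns:
        key = col.strip().lower()
        if key in alias_map:
            rename[col] = alias_map[key]
        else:
            unknown.append(col)
    if unknown:
        logger.warning("ignoring unknown visit-table columns: %s", unknown)
    df = df.rename(columns=rename)[[c for c in rename.values()]]

    missing = [c for c in _MANDATORY_VISIT_FIELDS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"visit table missing mandatory columns: {missing}")

    records: list[VisitRecord] = []
    problems: list[str] = []
    for row_number, (_, row) in enumerate(df.iterrows(), start=1):
        kwargs: dict = {}
        for name in _MANDATORY_VISIT_FIELDS:
            raw = row[name]
            if name in _INT_VISIT_FIELDS:
                try:
                    kwargs[name] = int(float(raw))
                except (TypeError, ValueError):
                    raise TableSchemaError(
                        f"row {row_number}: non-numeric {name!r} value {raw!r}"
                    ) from None
            else:
                kwargs[name] = str(raw)
        for name in ("visit_time",):
            if name in df.columns and pd.notna(row[name]) and str(row[name]) != "":
                kwargs[name] = float(row[name])
        for name in ("maternal_genotype_id", "site", "period"):
            if name in df.columns and pd.notna(row[name]) and str(row[name]) != "":
                kwargs[name] = str(row[name])
        try:
            records.append(VisitRecord(**kwargs))
        except ValueError as exc:
            problems.append(f"row {row_number}: {exc}")
    if problems:
        raise RowValidationError(
            "visit table rows violate invariants:\n  " + "\n  ".join(problems)
        )
    return records


def write_visit_table(visits: Sequence[VisitRecord], path, sep: str = ",") -> None:
    rows = []
    for v in visits:
        rows.append(
            {
                "visit_id": v.visit_id,
                "taxon": v.taxon,
                "flowers_visited": v.flowers_visited,
                "inflorescence_size": v.inflorescence_size,
                "stem_size": v.stem_size,
                "insertions": v.insertions,
                "removals": v.removals,
                "visit_time": v.visit_time if v.visit_time is not None else "",
                "maternal_genotype_id": v.maternal_genotype_id or "",
                "site": v.site or "",
                "period": v.period,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


_GENOTYPE_COLUMNS = ("sample_id", "sample_kind", "locus", "allele1", "allele2")


def read_genotype_table(path, dialect: Optional[str] = None) -> pd.DataFrame:
    """Load the long-format genotype table (one row per sample x locus)."""
    df = _read_delimited(path, dialect)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"genotype table missing mandatory columns: {missing}")
    bad_kind = ~df["sample_kind"].isin(["maternal", "pollinium"])
    if bad_kind.any():
        rows = [i + 1 for i in df.index[bad_kind]]
        raise RowValidationError(f"invalid sample_kind in rows {rows}")
    return df


def genotypes_from_table(df: pd.DataFrame) -> tuple[dict, dict, pd.DataFrame]:
    """Assemble MultilocusGenotypes from the long-format genotype frame.

    Returns ``(maternal, pollinium, pollinium_meta)`` where the first two map
    sample_id -> genotype and the third carries per-pollinium ``taxon``,
    ``visit_id`` and ``maternal_id`` metadata (one row per pollinium).
    """
    loci = tuple(dict.fromkeys(df["locus"]))

    def _build(sub: pd.DataFrame) -> dict:
        out = {}
        for sample_id, grp in sub.groupby("sample_id", sort=False):
            calls = {}
            for _, row in grp.iterrows():
                a1 = row["allele1"] if pd.notna(row["allele1"]) else ""
                a2 = row["allele2"] if pd.notna(row["allele2"]) else ""
                if str(a1) == "" or str(a2) == "":
                    calls[row["locus"]] = None
                else:
                    calls[row["locus"]] = make_call(a1, a2)
            out[str(sample_id)] = MultilocusGenotype(str(sample_id), calls, loci=loci)
        return out

    maternal = _build(df[df["sample_kind"] == "maternal"])
    pol_df = df[df["sample_kind"] == "pollinium"]
    pollinium = _build(pol_df)
    meta_cols = [c for c in ("taxon", "visit_id", "maternal_id") if c in pol_df.columns]
    meta = (
        pol_df.groupby("sample_id", sort=False)[meta_cols].first().reset_index()
        if meta_cols
        else pd.DataFrame({"sample_id": list(pollinium)})
    )
    meta["sample_id"] = meta["sample_id"].astype(str)
    return maternal, pollinium, meta


def assemble_pollinium_records(
    maternal: dict, pollinium: dict, meta: pd.DataFrame
) -> list[PolliniumRecord]:
    """Join genotypes and metadata into PolliniumRecords."""
    required = {"taxon", "maternal_id"}
    if not required.issubset(meta.columns):
        raise TableSchemaError(
            f"pollinium metadata needs columns {sorted(required)}"
        )
    records = []
    for _, row in meta.iterrows():
        pid = str(row["sample_id"])
        mid = str(row["maternal_id"])
        if mid not in maternal:
            raise RowValidationError(
                f"pollinium {pid!r} references unknown maternal sample {mid!r}"
            )
        records.append(
            PolliniumRecord(
                pollinium_id=pid,
                maternal_genotype=maternal[mid],
                pollinium_genotype=pollinium[pid],
                taxon=str(row["taxon"]),
                visit_id=str(row["visit_id"]) if "visit_id" in meta.columns and pd.notna(row.get("visit_id")) else None,
            )
        )
    return records


def write_genotype_table(
    maternal: Iterable[MultilocusGenotype],
    pollinia: Sequence[PolliniumRecord],
    path,
    sep: str = ",",
) -> None:
    """Write maternal and pollinium genotypes back to long format."""
    rows = []
    for g in maternal:
        for locus in g.loci:
            call = g.call(locus)
            rows.append(
                {
                    "sample_id": g.sample_id,
                    "sample_kind": "maternal",
                    "locus": locus,
                    "allele1": call[0] if call else "",
                    "allele2": call[1] if call else "",
                    "taxon": "",
                    "visit_id": "",
                    "maternal_id": "",
                }
            )
    for p in pollinia:
        g = p.pollinium_genotype
        for locus in g.loci:
            call = g.call(locus)
            rows.append(
                {
                    "sample_id": g.sample_id,
                    "sample_kind": "pollinium",
                    "locus": locus,
                    "allele1": call[0] if call else "",
                    "allele2": call[1] if call else "",
                    "taxon": p.taxon,
                    "visit_id": p.visit_id or "",
                    "maternal_id": p.maternal_genotype.sample_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_study(
    visit_path, genotype_path, dialect: Optional[str] = None
) -> tuple[list[VisitRecord], list[PolliniumRecord]]:
    """Read both tables and assemble validated records."""
    visits = read_visit_table(visit_path, dialect=dialect)
    df = read_genotype_table(genotype_path, dialect=dialect)
    maternal, pollinium, meta = genotypes_from_table(df)
    return visits, assemble_pollinium_records(maternal, pollinium, meta)
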