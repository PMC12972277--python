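"""Cohort container: a subjects-by-variables table with column roles.

A :class:`CohortTable` wraps a :class:`pandas.DataFrame` holding one row per
subject and annotates each column with a *role* (age, sex, cognitive score,
brain-pathology marker, lifestyle/health variable, ...).  Missing values are
represented as NaN in the frame; :attr:`CohortTable.missing_mask` exposes the
per-cell boolean view the rest of the pipeline works with.

Serialization is plain CSV (empty string = missing) plus a JSON sidecar with
the column -> role/domain map, so a cohort round-trips losslessly through
text files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical column roles
ROLES = (
    "id",
    "age",
    "sex",
    "apoe4",
    "ticv",
    "cognitive",
    "brain",
    "lifestyle",
    "screening",
    "mmse",
)

#: the 8 lifestyle/health domains
LIFESTYLE_DOMAINS = (
    "sleep",
    "diet",
    "physical_activity",
    "physical_fitness",
    "mental_activity",
    "cardiovascular_risk",
    "mental_health",
    "physical_health",
)


@dataclass
class CohortTable:
    """Subjects x variables table with roles and a missingness mask.

    Parameters
    ----------
    data
        One row per subject.  Must contain ``subject_id``, ``age`` and
        ``sex`` columns.  Missing cells are NaN.
    roles
        Maps every data column to one of :data:`ROLES`.
    lifestyle_domains
        Maps every lifestyle column to one of :data:`LIFESTYLE_DOMAINS`.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    lifestyle_domains: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- role-based column accessors -------------------------------------
    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles.get(c) == role]

    @property
    def cognitive_columns(self) -> list[str]:
        return self.columns_with_role("cognitive")

    @property
    def brain_columns(self) -> list[str]:
        return self.columns_with_role("brain")

    @property
    def lifestyle_columns(self) -> list[str]:
        return self.columns_with_role("lifestyle")

    @property
    def screening_columns(self) -> list[str]:
        return self.columns_with_role("screening")

    @property
    def age(self) -> pd.Series:
        return self.data["age"]

    @property
    def sex(self) -> pd.Series:
        """Sex coded female=0, male=1."""
        return self.data["sex"]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a cell value is absent."""
        return self.data.isna()

    # -- validation -------------------------------------------------------
    def validate(self, age_range: tuple[float, float] = (60.0, 95.0)) -> None:
        df = self.data
        for mandatory in ("subject_id", "age", "sex"):
            if mandatory not in df.columns:
                raise ValueError(f"cohort table lacks mandatory column {mandatory!r}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variable names: {dupes}")
        unknown = [c for c in df.columns if c not in self.roles]
        if unknown:
            raise ValueError(f"columns without a role: {unknown}")
        bad_roles = {r for r in self.roles.values() if r not in ROLES}
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        age = df["age"].to_numpy(float)
        lo, hi = age_range
        if np.nanmin(age) < lo - 1e-9 or np.nanmax(age) > hi + 1e-9:
            raise ValueError(f"age outside configured range [{lo}, {hi}]")
        sex = df["sex"].dropna().unique()
        if not set(np.asarray(sex, float)) <= {0.0, 1.0}:
            raise ValueError("sex must be coded female=0 / male=1")
        for col in self.lifestyle_columns:
            dom = self.lifestyle_domains.get(col)
            if dom is None:
                raise ValueError(f"lifestyle variable {col!r} has no domain")
            if dom not in LIFESTYLE_DOMAINS:
                raise ValueError(f"unknown lifestyle domain {dom!r} for {col!r}")

    # -- serialization ----------------------------------------------------
    def copy(self) -> "CohortTable":
        return CohortTable(
            self.data.copy(), dict(self.roles), dict(self.lifestyle_domains)
        )

    def write_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Write the table as CSV plus a ``<path>.meta.json`` sidecar.

        The sidecar records the role and domain maps (and, optionally, any
        extra metadata such as the generative ground truth).
        """
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        meta = {
            "roles": self.roles,
            "lifestyle_domains": self.lifestyle_domains,
        }
        if sidecar:
            meta.update(sidecar)
        sidecar_path = path.with_suffix(path.suffix + ".meta.json")
        sidecar_path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_cohort_csv(path: str | Path, role_map: dict | None = None) -> CohortTable:
    """Read a cohort CSV written by :meth:`CohortTable.write_csv`.

    Empty strings parse as missing (NaN), never as zero.  ``role_map`` may
    override the sidecar; at least one of the two must supply roles.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    roles: dict[str, str] = {}
    domains: dict[str, str] = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        roles = meta.get("roles", {})
        domains = meta.get("lifestyle_domains", {})
    if role_map:
        roles = dict(role_map.get("roles", role_map))
        domains = dict(role_map.get("lifestyle_domains", domains))
    if not roles:
        raise ValueError(f"no role map for {path}: supply one or ship the sidecar")
    df = pd.read_csv(path, na_values=[""], keep_default_na=True)
    for mandatory in ("age", "sex"):
        if mandatory not in df.columns:
            raise ValueError(f"{path} lacks mandatory column {mandatory!r}")
    numeric = [c for c in df.columns if roles.get(c) != "id"]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {row}"
            ) from exc
    return CohortTable(df, roles, domains)
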