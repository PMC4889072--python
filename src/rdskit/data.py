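"""Recruitment-chain data model, validation, and delimited-text I/O.

A respondent-driven sample is a forest of recruitment chains: a handful of
purposively chosen *seeds* (wave 0) each hand a limited number of coupons to
peers, recruits of seeds sit at wave 1, and so on.  Every other module in the
package consumes the :class:`RecruitmentSample` container defined here.

The on-disk format is a plain CSV with one row per participant and a fixed
set of mandatory columns followed by one column per trait::

    participant_id,recruiter_id,seed_id,wave,coupons_issued,degree,<traits...>

Missing values (unknown degree, undisclosed trait) are empty fields.  Seeds
have an empty ``recruiter_id``.  ``wave`` and ``seed_id`` are recomputed from
the recruiter linkage on read and cross-checked against the file.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = (
    "participant_id",
    "recruiter_id",
    "seed_id",
    "wave",
    "coupons_issued",
    "degree",
)

#: trait name -> ordered tuple of category labels
TraitSchema = Mapping[str, Sequence[str]]


class SchemaError(ValueError):
    """A mandatory column is missing or a trait column is undeclared."""


class LinkageError(ValueError):
    """A recruit references a recruiter that is not in the sample."""


class StructureError(ValueError):
    """The recruiter graph is not a forest (cycle or inconsistent waves)."""


class EstimationError(RuntimeError):
    """An estimator could not produce a result on the given data."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One seed or recruit, with linkage, reported degree and trait values.

    ``recruiter_id is None`` iff the participant is a seed (wave 0).
    ``degree`` is the self-reported network size (None when not reported).
    """

    participant_id: str
    recruiter_id: str | None
    seed_id: str
    wave: int
    coupons_issued: int = 0
    degree: int | None = None
    traits: Mapping[str, str | None] = field(default_factory=dict)


def _records_to_frame(records: Sequence[ParticipantRecord], trait_names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "recruiter_id": r.recruiter_id,
            "seed_id": r.seed_id,
            "wave": r.wave,
            "coupons_issued": r.coupons_issued,
            "degree": np.nan if r.degree is None else float(r.degree),
        }
        for t in trait_names:
            row[t] = r.traits.get(t)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + list(trait_names))
    return df


class RecruitmentSample:
    """A validated collection of participant records forming a recruitment forest.

    Parameters
    ----------
    df:
        One row per participant; mandatory columns of :data:`MANDATORY_COLUMNS`
        plus one object column per trait.  Row order is preserved.
    trait_schema:
        Mapping of trait name to its declared category labels.  Values found
        in the data but absent from the declared set raise a SchemaError.
    validate:
        Recompute waves/seed ids from linkage and check all invariants.
    """

    def __init__(self, df: pd.DataFrame, trait_schema: TraitSchema, validate: bool = True):
        self.trait_schema: dict[str, tuple[str, ...]] = {
            t: tuple(cats) for t, cats in trait_schema.items()
        }
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        for t in self.trait_schema:
            if t not in df.columns:
                raise SchemaError(f"declared trait column absent from data: {t}")
        cols = list(MANDATORY_COLUMNS) + sorted(self.trait_schema)
        self.df = df[cols].reset_index(drop=True).copy()
        self.df["participant_id"] = self.df["participant_id"].astype(str)
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Sequence[ParticipantRecord], trait_schema: TraitSchema
    ) -> "RecruitmentSample":
        df = _records_to_frame(records, sorted(trait_schema))
        return cls(df, trait_schema)

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        ids = df["participant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise StructureError(f"duplicate participant ids: {dup[:5]}")
        pos = {pid: i for i, pid in enumerate(ids)}
        rec = df["recruiter_id"]
        is_seed = rec.isna() | (rec == "")
        dangling = sorted(set(rec[~is_seed]) - set(ids))
        if dangling:
            raise LinkageError(f"recruiter id(s) not found in sample: {dangling[:10]}")

        n = len(df)
        parent = np.full(n, -1, dtype=np.int64)
        for i, (seed, r) in enumerate(zip(is_seed, rec)):
            if not seed:
                parent[i] = pos[r]

        wave = np.full(n, -1, dtype=np.int64)
        root = np.full(n, -1, dtype=np.int64)

        def resolve(i: int) -> None:
            path = []
            j = i
            while wave[j] < 0:
                if j in path:
                    cyc = [ids.iloc[k] for k in path]
                    raise StructureError(f"cycle in recruiter graph involving: {cyc}")
                path.append(j)
                if parent[j] < 0:
                    wave[j] = 0
                    root[j] = j
                    break
                if len(path) > n:
                    raise StructureError("recruiter chain longer than the sample")
                j = parent[j]
            for k in reversed(path):
                if wave[k] < 0:
                    wave[k] = wave[parent[k]] + 1
                    root[k] = root[parent[k]]

        for i in range(n):
            resolve(i)

        if df["wave"].notna().any():
            claimed = pd.to_numeric(df["wave"], errors="coerce")
            bad = claimed.notna() & (claimed.astype("Int64") != wave)
            if bad.any():
                offenders = ids[bad].tolist()
                raise StructureError(
                    f"declared wave disagrees with recruiter linkage for: {offenders[:10]}"
                )
        df["wave"] = wave
        computed_seed = ids.to_numpy()[root]
        if df["seed_id"].notna().any():
            declared = df["seed_id"].astype(str)
            known = declared.notna() & (declared != "") & (declared != "nan")
            bad = known & (declared.to_numpy() != computed_seed)
            if bad.any():
                raise StructureError(
                    f"declared seed_id disagrees with linkage for: {ids[bad].tolist()[:10]}"
                )
        df["seed_id"] = computed_seed
        df["coupons_issued"] = (
            pd.to_numeric(df["coupons_issued"], errors="coerce").fillna(0).astype(np.int64)
        )
        df["degree"] = pd.to_numeric(df["degree"], errors="coerce")

        for t, cats in self.trait_schema.items():
            col = df[t]
            observed = set(col.dropna().astype(str)) - {""}
            undeclared = observed - set(cats)
            if undeclared:
                raise SchemaError(
                    f"trait {t!r} has undeclared categories: {sorted(undeclared)}"
                )

    # -- summary properties ----------------------------------------------
    @property
    def is_seed(self) -> pd.Series:
        rec = self.df["recruiter_id"]
        return rec.isna() | (rec == "")

    @property
    def n_seeds(self) -> int:
        return int(self.is_seed.sum())

    @property
    def n_recruits(self) -> int:
        return int((~self.is_seed).sum())

    @property
    def max_wave(self) -> int:
        return int(self.df["wave"].max()) if len(self.df) else 0

    @property
    def coupons_distributed(self) -> int:
        return int(self.df["coupons_issued"].sum())

    @property
    def records(self) -> Iterator[ParticipantRecord]:
        traits = sorted(self.trait_schema)
        for _, row in self.df.iterrows():
            rec = row["recruiter_id"]
            deg = row["degree"]
            yield ParticipantRecord(
                participant_id=str(row["participant_id"]),
                recruiter_id=None if pd.isna(rec) or rec == "" else str(rec),
                seed_id=str(row["seed_id"]),
                wave=int(row["wave"]),
                coupons_issued=int(row["coupons_issued"]),
                degree=None if pd.isna(deg) else int(deg),
                traits={
                    t: (None if pd.isna(row[t]) or row[t] == "" else str(row[t]))
                    for t in traits
                },
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecruitmentSample):
            return NotImplemented
        if self.trait_schema != other.trait_schema:
            return False
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c == "degree":
                if not np.allclose(a[c].fillna(-1), b[c].fillna(-1)):
                    return False
            else:
                if not (a[c].fillna("") .astype(str) == b[c].fillna("").astype(str)).all():
                    return False
        return True


class AnalysisView:
    """Seed-excluded view of a sample used by all estimators.

    Holds the recruit rows only, but keeps each recruit's *recruiter* trait
    values visible (the recruiter of a wave-1 recruit is a seed, and
    recruiter traits are needed to count cross-group recruitments even though
    seeds never enter any estimate).
    """

    def __init__(self, sample: RecruitmentSample):
        self.trait_schema = sample.trait_schema
        full = sample.df
        is_seed = sample.is_seed
        self.df = full[~is_seed].reset_index(drop=True).copy()
        lut = full.set_index("participant_id")
        traits = sorted(sample.trait_schema)
        if len(self.df):
            rec_rows = lut.loc[self.df["recruiter_id"].astype(str), traits]
            self.recruiter_traits = rec_rows.reset_index(drop=True)
        else:
            self.recruiter_traits = pd.DataFrame(columns=traits)
        self.n_seeds = sample.n_seeds

    def __len__(self) -> int:
        return len(self.df)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.trait_schema:
            raise SchemaError(f"trait {trait!r} not declared in schema")
        return self.df[trait]


def exclude_seeds(sample: RecruitmentSample) -> AnalysisView:
    """Return the seed-excluded analysis view of *sample*.

    Seeds are purposively selected and carry no sampling probability, so they
    are excluded from every estimate; their traits remain visible to
    recruiter-side diagnostics through the view.
    """
    return AnalysisView(sample)


def restrict_to_depth(sample: RecruitmentSample, max_depth: int) -> RecruitmentSample:
    """Keep only records recruited at wave <= ``max_depth`` (seeds retained).

    Because waves increase by exactly 1 along every chain, truncating by wave
    removes whole subtree tails and preserves the forest property.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    keep = sample.df["wave"] <= max_depth
    return RecruitmentSample(sample.df[keep], sample.trait_schema, validate=True)


def read_sample(path, schema: TraitSchema | None = None) -> RecruitmentSample:
    """Read a recruitment CSV and validate it.

    When *schema* is None, every non-mandatory column is taken as a trait and
    its category set is inferred from the observed values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.replace({"": np.nan})
    df["wave"] = pd.to_numeric(df["wave"], errors="coerce")
    df["coupons_issued"] = pd.to_numeric(df["coupons_issued"], errors="coerce")
    df["degree"] = pd.to_numeric(df["degree"], errors="coerce")
    if schema is None:
        trait_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
        schema = {
            t: tuple(sorted(set(df[t].dropna().astype(str)))) for t in trait_cols
        }
    return RecruitmentSample(df, schema)


def write_sample(sample: RecruitmentSample, path) -> None:
    """Write the fixed-column CSV representation (missing values empty)."""
    df = sample.df.copy()
    df["degree"] = df["degree"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, na_rep="")


def write_rdsat(sample: RecruitmentSample, path) -> None:
    """Secondary flat export in the style of legacy RDS analysis tools.

    Space-separated: id, degree, recruiter id (0 for seeds), then trait
    values in alphabetical order, missing coded as ``.``.  Write-only.
    """
    traits = sorted(sample.trait_schema)
    with open(path, "w", encoding="utf-8") as fh:
        for r in sample.records:
            vals = [
                r.participant_id,
                "." if r.degree is None else str(r.degree),
                r.recruiter_id if r.recruiter_id is not None else "0",
            ]
            vals += [r.traits.get(t) or "." for t in traits]
            fh.write(" ".join(vals) + "\n")
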