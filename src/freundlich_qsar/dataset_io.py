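"""Tabular inputs and outputs of the adsorption QSAR workflow.

The study relates Freundlich isotherm parameters of 47 organic water
contaminants (the response side) to quantum-chemical molecular descriptors
(the predictor side).  This module holds the packaged 47-compound
Freundlich parameter table, readers/writers for descriptor matrices,
train/test split handling with a canonical compound-name alias map, and a
JSON-serializable analysis report container.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundTable",
    "DescriptorMatrix",
    "SplitSpec",
    "AnalysisReport",
    "load_freundlich_table",
    "load_descriptor_table",
    "make_split",
    "normalize_name",
    "resolve_names",
    "STUDY_TEST_SET_K",
    "STUDY_TEST_SET_ONE_OVER_N",
    "study_split",
    "CANONICAL_ALIASES",
]


def normalize_name(name: str) -> str:
    """Canonical form used for compound-name joins.

    Unicode NFKC normalization, case folding and whitespace collapse, so
    that cosmetic spelling variants compare equal deterministically.
    """
    out = unicodedata.normalize("NFKC", name)
    out = re.sub(r"\s+", " ", out.strip())
    return out.casefold()


# Source-text spelling variants mapped onto the packaged table's canonical
# entries.  "dibromochloroethane" does not occur in the packaged table at
# all; the closest entry is dibromochloromethane and the mapping is
# optional (see resolve_names(allow_ambiguous_aliases=...)).
CANONICAL_ALIASES: dict[str, str] = {
    "cis-1,2-dichloroethene": "cis-1,2-Dichloroethylene",
    "trans-1,2-dichloroethene": "trans-1,2-Dichloroethylene",
    "1,1-dichloroethylene": "1,1-Dichloroethene",
    "methyl tert-butyl ether": "tert-Butyl methyl ether",
    "2,4,5-t": "2,4,5-trichlorophenoxy acetic acid",
}

AMBIGUOUS_ALIASES: dict[str, str] = {
    "dibromochloroethane": "Dibromochloromethane",
}


@dataclass(frozen=True)
class CompoundTable:
    """Per-compound Freundlich parameters: name, K and 1/n.

    K is the Freundlich capacity constant in (mg/g)(L/mg)^(1/n); 1/n is
    the dimensionless adsorption index (exponent of Qe = K*Ce^(1/n)).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["name", "K", "one_over_n"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"CompoundTable missing columns: {missing}")
        names = self.df["name"]
        if names.isna().any() or (names.astype(str).str.strip() == "").any():
            raise ValueError("compound names must be non-empty")
        keys = [normalize_name(n) for n in names]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate compound names: {dupes}")
        if not (self.df["K"] > 0).all():
            raise ValueError("K must be strictly positive for every compound")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float]]
    ) -> "CompoundTable":
        df = pd.DataFrame(records, columns=["name", "K", "one_over_n"])
        return cls(df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundTable":
        df = pd.read_csv(path, dtype={"name": str})
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])

    def __len__(self) -> int:
        return len(self.df)

    def record(self, name: str) -> pd.Series:
        """Row for one compound; name matching is alias-aware."""
        resolved = resolve_names([name], self.names)[0]
        row = self.df[self.df["name"] == resolved]
        return row.iloc[0]

    def response(self, which: Literal["K", "1/n"]) -> np.ndarray:
        if which == "K":
            return self.df["K"].to_numpy(dtype=float)
        if which == "1/n":
            return self.df["one_over_n"].to_numpy(dtype=float)
        raise ValueError(f"unknown response {which!r}; expected 'K' or '1/n'")

    def subset(self, names: Sequence[str]) -> "CompoundTable":
        resolved = set(resolve_names(names, self.names))
        mask = self.df["name"].isin(resolved)
        return CompoundTable(self.df[mask].reset_index(drop=True))


@dataclass(frozen=True)
class DescriptorMatrix:
    """Compounds x quantum-chemical descriptors, dense and fully numeric.

    Wrapped pandas DataFrame: index = compound names, columns = descriptor
    names (charges in e, orbital energies in eV, bond indices
    dimensionless).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            dupes = list(self.df.columns[self.df.columns.duplicated()])
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if self.df.isna().any().any():
            bad = self.df.columns[self.df.isna().any()].tolist()
            raise ValueError(f"missing values in descriptor columns: {bad}")
        if not all(np.issubdtype(dt, np.number) for dt in self.df.dtypes):
            bad = [c for c, dt in self.df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric descriptor columns: {bad}")

    @property
    def compound_names(self) -> list[str]:
        return list(self.df.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def columns(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        return self.df[list(names)].to_numpy(dtype=float)

    def rows(self, names: Sequence[str]) -> "DescriptorMatrix":
        resolved = resolve_names(names, self.compound_names)
        return DescriptorMatrix(self.df.loc[resolved])

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="name")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        return load_descriptor_table(path)


@dataclass(frozen=True)
class SplitSpec:
    """Definition of a train/test partition by test-compound names."""

    response_name: Literal["K", "1/n"]
    test_names: tuple[str, ...]
    allow_ambiguous_aliases: bool = True

    def __post_init__(self) -> None:
        keys = [normalize_name(n) for n in self.test_names]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate names in test set")


def resolve_names(
    query: Sequence[str],
    known: Sequence[str],
    allow_ambiguous_aliases: bool = True,
) -> list[str]:
    """Map query names onto canonical table names.

    Matching is exact after normalization, then via the canonical alias
    map.  Aliases whose intent is ambiguous in the source material (e.g.
    dibromochloroethane -> Dibromochloromethane) are applied only when
    ``allow_ambiguous_aliases`` is true.

    Raises KeyError listing every unresolvable query name.
    """
    lookup = {normalize_name(k): k for k in known}
    alias = {normalize_name(a): c for a, c in CANONICAL_ALIASES.items()}
    if allow_ambiguous_aliases:
        alias.update(
            {normalize_name(a): c for a, c in AMBIGUOUS_ALIASES.items()}
        )
    out: list[str] = []
    unknown: list[str] = []
    for q in query:
        key = normalize_name(q)
        if key in lookup:
            out.append(lookup[key])
            continue
        if key in alias and normalize_name(alias[key]) in lookup:
            out.append(lookup[normalize_name(alias[key])])
            continue
        unknown.append(q)
    if unknown:
        raise KeyError(f"unknown compound names: {unknown}")
    return out


def load_freundlich_table() -> CompoundTable:
    """The packaged 47-compound Freundlich parameter table.

    Rows are in source-table order (first panel top to bottom, then the
    second and third panels).
    """
    with resources.files("freundlich_qsar.data").joinpath(
        "freundlich_table1.csv"
    ).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype={"name": str})
    table = CompoundTable(df)
    if len(table) != 47:
        raise RuntimeError("packaged Freundlich table is corrupt")
    return table


def load_descriptor_table(
    path: str | Path,
    missing_policy: Literal["error", "zero_fill"] = "error",
) -> DescriptorMatrix:
    """Read a compounds x descriptors CSV (first column = compound name).

    ``zero_fill`` replaces blank cells with 0 — appropriate for
    group-charge sums such as sum(q(O+N)) that are empty sums for
    compounds lacking those atoms.  Under ``error`` any missing or
    non-numeric cell aborts with the offending compound and descriptor
    named.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError("descriptor table needs a name column plus data columns")
    name_col = raw.columns[0]
    names = raw[name_col].astype(str)
    data = raw.drop(columns=[name_col])

    numeric = pd.DataFrame(index=range(len(raw)), columns=data.columns, dtype=float)
    for col in data.columns:
        cells = data[col].str.strip()
        blank = cells == ""
        parsed = pd.to_numeric(cells.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell in column {col!r} for compound "
                f"{names.iloc[i]!r}: {cells.iloc[i]!r}"
            )
        if blank.any():
            if missing_policy == "zero_fill":
                parsed = parsed.fillna(0.0)
            else:
                i = int(np.flatnonzero(blank.to_numpy())[0])
                raise ValueError(
                    f"missing value for compound {names.iloc[i]!r}, "
                    f"descriptor {col!r}"
                )
        numeric[col] = parsed
    numeric.index = pd.Index(names, name="name")
    return DescriptorMatrix(numeric)


def make_split(
    table: CompoundTable, spec: SplitSpec
) -> tuple[CompoundTable, CompoundTable]:
    """Partition a compound table into (train, test) per a SplitSpec.

    Table order is preserved inside each part; every compound lands in
    exactly one part.
    """
    test_resolved = resolve_names(
        spec.test_names, table.names, spec.allow_ambiguous_aliases
    )
    test_set = set(test_resolved)
    train_df = table.df[~table.df["name"].isin(test_set)]
    test_df = table.df[table.df["name"].isin(test_set)]
    if len(train_df) == 0:
        raise ValueError("empty training partition")
    train = CompoundTable(train_df.reset_index(drop=True))
    if len(test_df) == 0:
        test = CompoundTable(
            pd.DataFrame({"name": pd.Series(dtype=str),
                          "K": pd.Series(dtype=float),
                          "one_over_n": pd.Series(dtype=float)})
        )
    else:
        test = CompoundTable(test_df.reset_index(drop=True))
    return train, test


# Test-set listings of the source study (9 held-out compounds each; the
# remaining 38 form the training set).  The 1/n list includes
# "dibromochloroethane", resolvable only through the ambiguous alias.
STUDY_TEST_SET_K: tuple[str, ...] = (
    "1,2,3-Trichloropropane",
    "Isophorone",
    "Styrene",
    "cis-1,2-Dichloroethylene",
    "1,2-Dibromoethane",
    "Simazine",
    "Atrazine",
    "Alachlor",
    "Metolachlor",
)

STUDY_TEST_SET_ONE_OVER_N: tuple[str, ...] = (
    "tert-Butyl methyl ether",
    "Benzene",
    "Bromobenzene",
    "1,2-Dibromoethane",
    "dibromochloroethane",
    "cis-1,2-Dichloroethylene",
    "Lindane",
    "Picloram",
    "Alachlor",
)


def study_split(
    response_name: Literal["K", "1/n"],
    allow_ambiguous_aliases: bool = True,
) -> SplitSpec:
    """The study's packaged 38/9 train/test split for either response."""
    if response_name == "K":
        return SplitSpec("K", STUDY_TEST_SET_K, allow_ambiguous_aliases)
    if response_name == "1/n":
        return SplitSpec(
            "1/n", STUDY_TEST_SET_ONE_OVER_N, allow_ambiguous_aliases
        )
    raise ValueError(f"unknown response {response_name!r}")


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return super().default(o)


@dataclass
class AnalysisReport:
    """Self-describing JSON container for one full analysis run.

    ``provenance`` echoes the configuration, seed and any repaired-input
    or alias-resolution events so a run can be reproduced exactly from
    the report alone.
    """

    model_ladder: list[dict] = field(default_factory=list)
    validation: dict = field(default_factory=dict)
    ad: dict = field(default_factory=dict)
    chemspace: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_ladder": self.model_ladder,
            "validation": self.validation,
            "ad": self.ad,
            "chemspace": self.chemspace,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        # repr-round-trip floats: json keeps full double precision
        text = json.dumps(self.to_dict(), indent=2, cls=_ReportEncoder)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisReport":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            model_ladder=d.get("model_ladder", []),
            validation=d.get("validation", {}),
            ad=d.get("ad", {}),
            chemspace=d.get("chemspace", {}),
            provenance=d.get("provenance", {}),
        )
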