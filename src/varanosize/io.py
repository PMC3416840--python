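"""Reading and writing of the measurement tables the pipeline consumes.

All tables are plain UTF-8 CSV with a header row, one record per row,
decimal-point numbers and empty cells for missing values. The package also
bundles the calibration, body-size and fossil tables it was built around,
plus a default group configuration (YAML) mapping calibration-group labels
to specimen ids.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .records import (
    ExtantSizeRecord,
    FossilMeasurement,
    Proxy,
    Sex,
    SpecimenRecord,
    normalize_species,
)

PathLike = Union[str, Path, _io.IOBase]

#: canonical fixture name -> packaged file
_FIXTURES = {
    "specimens": "extant_specimens.csv",
    "sizes": "extant_sizes.csv",
    "fossils": "fossil_measurements.csv",
    "reference_estimates": "reference_estimates.csv",
}
#: accepted aliases for the bundled fixtures
_FIXTURE_ALIASES = {
    "table1": "specimens",
    "table2": "sizes",
    "table3_expected": "reference_estimates",
}


class TableParseError(ValueError):
    """A cell could not be parsed; names the offending row and column."""


class TableValidationError(ValueError):
    """A parsed table violates a record invariant."""


def _read_raw(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


_COLUMN_ALIASES = {
    "specimen_id": {"specimen_id", "specimen #", "specimen", "id"},
    "species": {"species", "varanus sp.", "species/subspecies"},
    "bcl": {"bcl", "bcl_mm", "bcl (mm)"},
    "dvl": {"dvl", "dvl_mm", "dvl (mm)"},
    "pcl": {"pcl", "pcl_mm", "pcl (mm)"},
    "svl": {"svl", "svl_mm", "svl (mm)"},
    "tl": {"tl", "tl_mm", "tl (mm)"},
    "genus": {"genus"},
    "sex": {"sex"},
    "comment": {"comment"},
    "clade_tags": {"clade_tags", "tags"},
    "taxon": {"taxon"},
    "proxy": {"proxy", "proxy_kind", "meas.", "meas"},
    "length": {"length", "length_mm", "l", "l (mm)"},
    "label": {"label"},
}


def _find_column(df: pd.DataFrame, key: str, required: bool = True) -> Optional[str]:
    for col in df.columns:
        if col in _COLUMN_ALIASES[key]:
            return col
    if required:
        raise TableParseError(f"missing required column for {key!r}; have {list(df.columns)}")
    return None


def _parse_float(cell: str, row: int, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"row {row}: column {column!r}: cannot parse {cell!r} as a number"
        ) from None


def read_specimen_table(path: PathLike) -> list[SpecimenRecord]:
    """Read the extant calibration table into :class:`SpecimenRecord` rows.

    Species names are case-normalized to the lowercase epithet; a trailing
    ``?`` sets ``uncertain_id``. Blank measurement cells become ``None``.
    Row order is preserved; duplicate specimen ids are rejected.
    """
    df = _read_raw(path)
    id_col = _find_column(df, "specimen_id")
    sp_col = _find_column(df, "species")
    bcl_col = _find_column(df, "bcl", required=False)
    dvl_col = _find_column(df, "dvl", required=False)
    pcl_col = _find_column(df, "pcl")
    tag_col = _find_column(df, "clade_tags", required=False)

    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is line 1
        species, uncertain = normalize_species(row[sp_col])
        spec_id = row[id_col].strip()
        if spec_id in seen:
            raise TableValidationError(f"duplicate specimen_id {spec_id!r} at row {rownum}")
        seen.add(spec_id)
        tags: set[str] = set()
        if tag_col and row[tag_col].strip():
            tags = {t.strip() for t in row[tag_col].split(";") if t.strip()}
        try:
            records.append(
                SpecimenRecord(
                    specimen_id=spec_id,
                    species=species,
                    pcl=_parse_float(row[pcl_col], rownum, pcl_col),
                    bcl=_parse_float(row[bcl_col], rownum, bcl_col) if bcl_col else None,
                    dvl=_parse_float(row[dvl_col], rownum, dvl_col) if dvl_col else None,
                    clade_tags=tags,
                    uncertain_id=uncertain,
                )
            )
        except TableParseError:
            raise
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"row {rownum}: {exc}") from exc
    return records


def write_specimen_table(records: Iterable[SpecimenRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "species": [r.species + ("?" if r.uncertain_id else "") for r in records],
            "bcl_mm": [r.bcl for r in records],
            "dvl_mm": [r.dvl for r in records],
            "pcl_mm": [r.pcl for r in records],
            "clade_tags": [";".join(sorted(r.clade_tags)) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_extant_size_table(path: PathLike) -> list[ExtantSizeRecord]:
    """Read the extant body-size table. Rows without SVL are retained."""
    df = _read_raw(path)
    genus_col = _find_column(df, "genus")
    sp_col = _find_column(df, "species")
    svl_col = _find_column(df, "svl")
    tl_col = _find_column(df, "tl", required=False)
    sex_col = _find_column(df, "sex", required=False)
    com_col = _find_column(df, "comment", required=False)

    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2
        sex_cell = row[sex_col].strip().upper() if sex_col else ""
        sex = Sex(sex_cell) if sex_cell in ("M", "F") else Sex.UNKNOWN
        try:
            records.append(
                ExtantSizeRecord(
                    genus=row[genus_col].replace("*", "").strip(),
                    species=row[sp_col].replace("*", "").strip().lower(),
                    svl=_parse_float(row[svl_col], rownum, svl_col),
                    tl=_parse_float(row[tl_col], rownum, tl_col) if tl_col else None,
                    sex=sex,
                    comment=row[com_col].strip() if com_col else "",
                )
            )
        except TableParseError:
            raise
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"row {rownum}: {exc}") from exc
    return records


def write_extant_size_table(records: Iterable[ExtantSizeRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "genus": [r.genus for r in records],
            "species": [r.species for r in records],
            "svl_mm": [r.svl for r in records],
            "tl_mm": [r.tl for r in records],
            "sex": [r.sex.value if r.sex is not Sex.UNKNOWN else "" for r in records],
            "comment": [r.comment for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_fossil_table(path: PathLike) -> list[FossilMeasurement]:
    """Read fossil element measurements (one element per row)."""
    df = _read_raw(path)
    taxon_col = _find_column(df, "taxon")
    proxy_col = _find_column(df, "proxy")
    len_col = _find_column(df, "length")
    id_col = _find_column(df, "specimen_id", required=False)
    label_col = _find_column(df, "label", required=False)

    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2
        try:
            records.append(
                FossilMeasurement(
                    taxon=row[taxon_col].replace("*", "").strip(),
                    proxy_kind=Proxy.coerce(row[proxy_col]),
                    length=_parse_float(row[len_col], rownum, len_col),
                    specimen_id=row[id_col].strip() if id_col else "",
                    label=row[label_col].strip() if label_col else "",
                )
            )
        except TableParseError:
            raise
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"row {rownum}: {exc}") from exc
    return records


def write_fossil_table(records: Iterable[FossilMeasurement], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "label": [r.label for r in records],
            "taxon": [r.taxon for r in records],
            "specimen_id": [r.specimen_id for r in records],
            "proxy": [r.proxy_kind.value for r in records],
            "length_mm": [r.length for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundled fixtures


def _data_path(filename: str):
    return resources.files("varanosize.data").joinpath(filename)


def load_bundled_fixture(name: str) -> pd.DataFrame:
    """Return one of the packaged tables as a raw DataFrame.

    Canonical names: ``specimens``, ``sizes``, ``fossils``,
    ``reference_estimates`` (aliases ``table1``/``table2``/``table3_expected``
    are accepted).
    """
    key = _FIXTURE_ALIASES.get(name, name)
    if key not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES) + sorted(_FIXTURE_ALIASES)}"
        )
    with _data_path(_FIXTURES[key]).open("r", encoding="utf-8") as fh:
        return _read_raw(fh)


def bundled_specimens() -> list[SpecimenRecord]:
    with _data_path("extant_specimens.csv").open("r", encoding="utf-8") as fh:
        return read_specimen_table(fh)


def bundled_sizes() -> list[ExtantSizeRecord]:
    with _data_path("extant_sizes.csv").open("r", encoding="utf-8") as fh:
        return read_extant_size_table(fh)


def bundled_fossils() -> list[FossilMeasurement]:
    with _data_path("fossil_measurements.csv").open("r", encoding="utf-8") as fh:
        return read_fossil_table(fh)


# ---------------------------------------------------------------------------
# group configuration


@dataclass
class EstimateSpec:
    """One planned estimate: a fossil element crossed with a calibration group."""

    label: str
    group: str
    proxy: Proxy

    def __post_init__(self) -> None:
        self.proxy = Proxy.coerce(self.proxy)


@dataclass
class GroupConfig:
    """Calibration-group membership plus the default estimate plan.

    ``groups`` maps a group label to a list of specimen ids, or to the
    sentinel string ``"all"`` (every specimen carrying the proxy at hand).
    """

    groups: dict[str, Union[str, list[str]]]
    estimates: list[EstimateSpec] = field(default_factory=list)

    def members(self, label: str) -> Union[str, list[str]]:
        if label not in self.groups:
            raise KeyError(f"unknown calibration group {label!r}")
        return self.groups[label]


def load_group_config(path: PathLike) -> GroupConfig:
    if hasattr(path, "read"):
        raw = yaml.safe_load(path)
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    groups = {}
    for label, spec in raw.get("groups", {}).items():
        members = spec["members"] if isinstance(spec, dict) else spec
        if members != "all" and not isinstance(members, list):
            raise TableValidationError(
                f"group {label!r}: members must be 'all' or a list of specimen ids"
            )
        groups[label] = members
    estimates = [
        EstimateSpec(label=e["label"], group=e["group"], proxy=e["proxy"])
        for e in raw.get("estimates", [])
    ]
    return GroupConfig(groups=groups, estimates=estimates)


def default_group_config() -> GroupConfig:
    with _data_path("groups.yaml").open("r", encoding="utf-8") as fh:
        return load_group_config(fh)


def bundled_example_tree() -> str:
    """Newick text of the small illustrative area-labelled topology."""
    return _data_path("example_tree.nwk").read_text(encoding="utf-8")


def bundled_example_areas() -> dict[str, frozenset[str]]:
    """Tip-area map for the illustrative topology."""
    from .parsimony import read_tip_states

    with _data_path("example_areas.tsv").open("r", encoding="utf-8") as fh:
        return read_tip_states(fh)
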