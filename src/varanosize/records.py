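"""Domain records shared across the package.

Measurements are in millimetres throughout. A *proxy* is a skeletal element
whose length correlates with whole-animal precaudal length (PCL): either the
lateral braincase length (BCL) or the centrum length of a posterior dorsal
vertebra (DVL). PCL — snout tip to last presacral centrum — is the
osteological analogue of snout–vent length (SVL) and is the body-size
currency used everywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Proxy(str, Enum):
    """Skeletal proxy kinds usable for size estimation."""

    BCL = "BCL"
    DVL = "DVL"

    @classmethod
    def coerce(cls, value: "Proxy | str") -> "Proxy":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown proxy kind {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


def _require_positive(name: str, value: Optional[float], allow_none: bool = False):
    if value is None:
        if allow_none:
            return
        raise ValueError(f"{name} is required")
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass
class SpecimenRecord:
    """One extant skeleton: its proxy measurements and reference PCL.

    ``species`` is the normalized (lowercase) specific epithet; a trailing
    ``?`` in the source is stripped and recorded via ``uncertain_id``.
    Missing proxies are ``None``; at least one proxy must be present.
    """

    specimen_id: str
    species: str
    pcl: float
    bcl: Optional[float] = None
    dvl: Optional[float] = None
    clade_tags: set[str] = field(default_factory=set)
    uncertain_id: bool = False

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        _require_positive(f"PCL of {self.specimen_id}", self.pcl)
        _require_positive(f"BCL of {self.specimen_id}", self.bcl, allow_none=True)
        _require_positive(f"DVL of {self.specimen_id}", self.dvl, allow_none=True)
        if self.bcl is None and self.dvl is None:
            raise ValueError(
                f"specimen {self.specimen_id} carries neither BCL nor DVL"
            )

    def proxy_value(self, proxy: Proxy | str) -> Optional[float]:
        proxy = Proxy.coerce(proxy)
        return self.bcl if proxy is Proxy.BCL else self.dvl


@dataclass
class FossilMeasurement:
    """A single measured element of a fossil individual (the length ``L``)."""

    taxon: str
    proxy_kind: Proxy
    length: float
    specimen_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.proxy_kind = Proxy.coerce(self.proxy_kind)
        _require_positive(f"length of {self.taxon}", self.length)
        if not self.label:
            self.label = self.taxon


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "unknown"


@dataclass
class ExtantSizeRecord:
    """One published body-size row for an extant varanid.

    ``species`` keeps the source string (which may include a subspecies,
    e.g. ``"griseus caspius"``); :attr:`epithet` collapses it to the
    species-level epithet. SVL may be missing (some sources report only
    total length); total length is not required to exceed SVL since tail
    proportions vary widely across monitors.
    """

    genus: str
    species: str
    svl: Optional[float] = None
    tl: Optional[float] = None
    sex: Sex = Sex.UNKNOWN
    comment: str = ""

    def __post_init__(self) -> None:
        _require_positive(f"SVL of {self.genus} {self.species}", self.svl, allow_none=True)
        _require_positive(f"TL of {self.genus} {self.species}", self.tl, allow_none=True)

    @property
    def epithet(self) -> str:
        """Species-level epithet with any subspecies part dropped."""
        return self.species.split()[0].lower()


@dataclass
class SpeciesSizeSummary:
    """Maximum reported SVL for one species, over all of its rows."""

    species: str
    max_svl: float
    n_rows: int

    def __post_init__(self) -> None:
        _require_positive(f"max SVL of {self.species}", self.max_svl)
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")


def normalize_species(raw: str) -> tuple[str, bool]:
    """Normalize a species cell to a lowercase epithet.

    Strips markup asterisks and whitespace, lowercases, and pulls off a
    trailing ``?`` (uncertain identification), which is returned as a flag
    rather than silently dropped.
    """
    name = raw.replace("*", "").strip()
    uncertain = name.endswith("?")
    if uncertain:
        name = name[:-1].strip()
    return name.lower(), uncertain
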