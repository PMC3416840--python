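"""Clade-level ratio calibration and OLS trendlines for fossil size prediction.

The estimator at the heart of the package is deliberately simple. For a
calibration group of extant specimens with known precaudal length (PCL) and
a proxy measurement x (BCL or DVL), the group ratio is the *ratio of sums*

    r_hat = (sum of PCL) / (sum of x),

equivalently an x-weighted mean of the per-specimen ratios PCL_i / x_i. A
fossil whose element measures L is then predicted at

    PCL_hat = L * r_hat,

with a normal-approximation 95% interval of half-width

    z * s * L / sqrt(n),    z = 1.96,

where s is the sample standard deviation (n-1 denominator) of the
per-specimen ratios and n the group size. The interval is a confidence
interval on the group mean ratio rescaled by L, not a prediction interval
for a new individual; see the methods note for its calibration properties.

OLS trendlines of PCL on the proxy are fitted alongside (via statsmodels)
as a descriptive cross-check of how tightly each proxy tracks body size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import GroupConfig
from .records import FossilMeasurement, Proxy, SpecimenRecord

__all__ = [
    "RatioModel",
    "RatioCalibration",
    "RatioCalibrationResults",
    "RegressionModel",
    "ProxyTrendline",
    "SizeEstimate",
    "per_specimen_ratios",
    "compute_ratio_model",
    "fit_trendline",
    "estimate_pcl",
    "predict_from_trendline",
    "build_estimate_table",
]


class DegenerateFitError(ValueError):
    """Raised when a trendline is requested for proxy values with no spread."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RatioModel:
    """Fitted parameters of one clade-level ratio calibration.

    ``sd`` is ``None`` when the group has a single member (a warning is
    emitted at fit time; such a model predicts without an interval).
    """

    group_label: str
    proxy_kind: Proxy
    n: int
    mean_ratio: float
    sd: Optional[float]
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.mean_ratio > 0):
            raise ValueError("mean_ratio must be positive")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.sd is not None and self.n < 2:
            raise ValueError("sd requires n >= 2")


@dataclass(frozen=True)
class RegressionModel:
    """OLS trendline of PCL (mm) on a proxy (mm): slope, intercept, R^2."""

    proxy_kind: Proxy
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def predict(self, length: float) -> float:
        return self.slope * length + self.intercept


@dataclass
class SizeEstimate:
    """A fossil's predicted PCL with its interval half-width (both mm)."""

    fossil: FossilMeasurement
    model: RatioModel
    pcl_mm: float
    ci_halfwidth_mm: Optional[float]
    z: float = 1.96


# ---------------------------------------------------------------------------
# functional operations


def per_specimen_ratios(
    specimens: Sequence[SpecimenRecord], proxy_kind: Proxy | str
) -> list[float]:
    """PCL/proxy ratio for each specimen, order preserved.

    Raises if any specimen lacks the proxy (callers select members first).
    """
    proxy = Proxy.coerce(proxy_kind)
    ratios = []
    for s in specimens:
        x = s.proxy_value(proxy)
        if x is None:
            raise ValueError(f"specimen {s.specimen_id} has no {proxy.value} measurement")
        ratios.append(s.pcl / x)
    return ratios


def compute_ratio_model(
    specimens: Sequence[SpecimenRecord],
    proxy_kind: Proxy | str,
    group_label: str = "group",
) -> RatioModel:
    """Fit a clade-level ratio model; see :class:`RatioCalibration`."""
    return RatioCalibration(specimens, proxy_kind, group_label=group_label).fit().model


def fit_trendline(
    specimens: Sequence[SpecimenRecord], proxy_kind: Proxy | str
) -> RegressionModel:
    """Ordinary least squares of PCL on the proxy across the given specimens."""
    return ProxyTrendline(specimens, proxy_kind).fit()


def estimate_pcl(
    model: RatioModel, fossil: FossilMeasurement, z: float = 1.96
) -> SizeEstimate:
    """Predict a fossil's PCL from one measured element.

    ``pcl = L * mean_ratio``; interval half-width ``z * sd * L / sqrt(n)``.
    With a single-specimen calibration the estimate is returned without an
    interval and a warning is emitted.
    """
    if fossil.proxy_kind != model.proxy_kind:
        raise ValueError(
            f"proxy mismatch: fossil measures {fossil.proxy_kind.value}, "
            f"model calibrated on {model.proxy_kind.value}"
        )
    if z <= 0:
        raise ValueError("z must be positive")
    pcl = fossil.length * model.mean_ratio
    if model.sd is None:
        warnings.warn(
            f"group {model.group_label!r} has n=1; no interval for {fossil.label}",
            stacklevel=2,
        )
        half = None
    else:
        half = z * model.sd * fossil.length / math.sqrt(model.n)
    return SizeEstimate(fossil=fossil, model=model, pcl_mm=pcl, ci_halfwidth_mm=half, z=z)


def predict_from_trendline(model: RegressionModel, fossil: FossilMeasurement) -> float:
    """Point prediction (mm) of PCL from the OLS trendline."""
    if fossil.proxy_kind != model.proxy_kind:
        raise ValueError("proxy mismatch between trendline and fossil measurement")
    return model.predict(fossil.length)


# ---------------------------------------------------------------------------
# model objects


class RatioCalibration:
    """Ratio-of-sums calibration of PCL against one skeletal proxy.

    Parameters
    ----------
    specimens
        Extant specimens; all must carry the chosen proxy (pre-filter with
        ``member_ids`` or drop incomplete records first).
    proxy_kind
        ``"BCL"`` or ``"DVL"``.
    group_label
        Name of the calibration set (reported in summaries and errors).
    member_ids
        Optional subset of specimen ids to calibrate on; order follows the
        specimen table, and unknown ids raise.

    Examples
    --------
    >>> from varanosize.io import bundled_specimens
    >>> res = RatioCalibration(bundled_specimens(), "BCL",
    ...                        group_label="all_varanus").fit()
    >>> round(res.mean_ratio, 2), round(res.sd, 3), res.n
    (17.68, 2.322, 21)
    """

    def __init__(
        self,
        specimens: Sequence[SpecimenRecord],
        proxy_kind: Proxy | str,
        group_label: str = "group",
        member_ids: Optional[Iterable[str]] = None,
    ) -> None:
        self.proxy_kind = Proxy.coerce(proxy_kind)
        self.group_label = group_label
        if member_ids is not None:
            wanted = list(member_ids)
            by_id = {s.specimen_id: s for s in specimens}
            missing = [m for m in wanted if m not in by_id]
            if missing:
                raise KeyError(f"group {group_label!r}: unknown specimen ids {missing}")
            # keep table order, not config order, for reproducible ratios
            specimens = [s for s in specimens if s.specimen_id in set(wanted)]
        self.specimens = [
            s for s in specimens if s.proxy_value(self.proxy_kind) is not None
        ]
        dropped = len(list(specimens)) - len(self.specimens)
        if member_ids is not None and dropped:
            raise ValueError(
                f"group {group_label!r}: {dropped} listed specimen(s) lack "
                f"{self.proxy_kind.value}"
            )
        if not self.specimens:
            raise ValueError(
                f"group {group_label!r} has no members carrying {self.proxy_kind.value}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        proxy_kind: Proxy | str,
        group_label: str = "group",
        **kwargs,
    ) -> "RatioCalibration":
        """Build from a DataFrame with ``specimen_id``/``species``/``pcl``
        and proxy columns (mm suffixes accepted)."""
        import io as _io

        from .io import read_specimen_table

        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_specimen_table(buf), proxy_kind, group_label, **kwargs)

    def fit(self) -> "RatioCalibrationResults":
        ratios = per_specimen_ratios(self.specimens, self.proxy_kind)
        pcl_sum = sum(s.pcl for s in self.specimens)
        proxy_sum = sum(s.proxy_value(self.proxy_kind) for s in self.specimens)
        n = len(self.specimens)
        sd = float(np.std(ratios, ddof=1)) if n >= 2 else None
        model = RatioModel(
            group_label=self.group_label,
            proxy_kind=self.proxy_kind,
            n=n,
            mean_ratio=pcl_sum / proxy_sum,
            sd=sd,
            member_ids=tuple(s.specimen_id for s in self.specimens),
        )
        return RatioCalibrationResults(self, model, ratios)


class RatioCalibrationResults:
    """Fitted ratio calibration: parameters, diagnostics, prediction."""

    def __init__(
        self,
        calibration: RatioCalibration,
        model: RatioModel,
        ratios: Sequence[float],
    ) -> None:
        self.calibration = calibration
        self.model = model
        self.ratios = list(ratios)

    # convenience passthroughs
    mean_ratio = property(lambda self: self.model.mean_ratio)
    sd = property(lambda self: self.model.sd)
    n = property(lambda self: self.model.n)
    group_label = property(lambda self: self.model.group_label)
    proxy_kind = property(lambda self: self.model.proxy_kind)

    def se_mean_ratio(self) -> Optional[float]:
        """Naive standard error of the mean ratio, sd / sqrt(n)."""
        if self.model.sd is None:
            return None
        return self.model.sd / math.sqrt(self.model.n)

    def predict(
        self, fossil: Union[FossilMeasurement, float], z: float = 1.96
    ) -> SizeEstimate:
        """Predict PCL for a fossil measurement (or a bare length in mm)."""
        if not isinstance(fossil, FossilMeasurement):
            fossil = FossilMeasurement(
                taxon="query", proxy_kind=self.model.proxy_kind, length=float(fossil)
            )
        return estimate_pcl(self.model, fossil, z=z)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Ratio calibration: PCL/{m.proxy_kind.value} for {m.group_label}",
            "-" * 56,
            f"  n specimens     : {m.n}",
            f"  mean ratio      : {m.mean_ratio:.4f}   (ratio of sums)",
            f"  SD of ratios    : {'n/a (n=1)' if m.sd is None else format(m.sd, '.4f')}",
            f"  ratio range     : {min(self.ratios):.4f} – {max(self.ratios):.4f}",
            f"  members         : {', '.join(m.member_ids)}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        m = self.model
        return (
            f"<RatioCalibrationResults {m.group_label} PCL/{m.proxy_kind.value} "
            f"mean={m.mean_ratio:.3f} n={m.n}>"
        )


class ProxyTrendline:
    """OLS model of PCL on one proxy across a specimen set."""

    def __init__(
        self,
        specimens: Sequence[SpecimenRecord],
        proxy_kind: Proxy | str,
        group_label: str = "group",
    ) -> None:
        self.proxy_kind = Proxy.coerce(proxy_kind)
        self.group_label = group_label
        self.specimens = [s for s in specimens if s.proxy_value(self.proxy_kind) is not None]
        if len(self.specimens) < 2:
            raise ValueError("trendline needs at least two specimens with the proxy")
        xs = [s.proxy_value(self.proxy_kind) for s in self.specimens]
        if max(xs) == min(xs):
            raise DegenerateFitError(
                f"all {self.proxy_kind.value} values identical; trendline undefined"
            )

    def fit(self) -> RegressionModel:
        x = np.array([s.proxy_value(self.proxy_kind) for s in self.specimens])
        y = np.array([s.pcl for s in self.specimens])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        # a 2-point line fits exactly; statsmodels' rsquared is 1 there too,
        # but guard against numerical noise pushing it out of [0, 1]
        r2 = float(min(max(res.rsquared, 0.0), 1.0))
        return RegressionModel(
            proxy_kind=self.proxy_kind,
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
            n=len(self.specimens),
        )


# ---------------------------------------------------------------------------
# the full estimate table


def _resolve_members(
    specimens: Sequence[SpecimenRecord],
    config: GroupConfig,
    group: str,
    proxy: Proxy,
) -> Optional[list[str]]:
    members = config.members(group)
    if members == "all":
        return None  # RatioCalibration keeps everything carrying the proxy
    return list(members)


def build_estimate_table(
    specimens: Sequence[SpecimenRecord],
    fossils: Sequence[FossilMeasurement],
    group_config: GroupConfig,
    z: float = 1.96,
) -> list[SizeEstimate]:
    """Run every estimate in the config plan, in plan order.

    Each plan row names a fossil element (by report label + proxy) and a
    calibration group; the corresponding ratio model is fitted once per
    (group, proxy) pair and reused.
    """
    by_key: dict[tuple[str, Proxy], FossilMeasurement] = {}
    for f in fossils:
        by_key[(f.label, f.proxy_kind)] = f

    cache: dict[tuple[str, Proxy], RatioCalibrationResults] = {}
    out: list[SizeEstimate] = []
    for spec in group_config.estimates:
        key = (spec.label, spec.proxy)
        if key not in by_key:
            raise KeyError(
                f"estimate plan references unknown fossil measurement "
                f"({spec.label!r}, {spec.proxy.value})"
            )
        mkey = (spec.group, spec.proxy)
        if mkey not in cache:
            cache[mkey] = RatioCalibration(
                specimens,
                spec.proxy,
                group_label=spec.group,
                member_ids=_resolve_members(specimens, group_config, spec.group, spec.proxy),
            ).fit()
        out.append(cache[mkey].predict(by_key[key], z=z))
    return out
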