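"""Rendering of the fossil size-estimate table.

Column precision mirrors the conventions of published morphometric tables:
estimates below 1000 mm get one decimal, larger ones round to the
millimetre, and interval half-widths carry four significant figures.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .allometry import SizeEstimate

__all__ = ["estimates_to_frame", "render_estimate_report"]

_FORMATS = ("csv", "markdown", "text")


def _fmt_length(v: float) -> str:
    s = f"{v:.2f}".rstrip("0").rstrip(".")
    return s


def format_pcl(v: float) -> str:
    return f"{v:.0f}" if v >= 1000 else f"{v:.1f}"


def format_ci(v: float) -> str:
    return f"{v:.4g}"


def estimates_to_frame(estimates: Sequence[SizeEstimate]) -> pd.DataFrame:
    """Numeric (unrounded) table of estimates, in input order."""
    return pd.DataFrame(
        {
            "taxon": [e.fossil.label for e in estimates],
            "comparisons": [e.model.group_label for e in estimates],
            "meas.": [e.fossil.proxy_kind.value for e in estimates],
            "L_mm": [e.fossil.length for e in estimates],
            "pcl_est_mm": [e.pcl_mm for e in estimates],
            "ci_mm": [e.ci_halfwidth_mm for e in estimates],
        }
    )


def render_estimate_report(
    estimates: Sequence[SizeEstimate], format: str = "text"
) -> str:
    """Render the estimate table as ``csv``, ``markdown`` or aligned ``text``."""
    if not estimates:
        raise ValueError("no estimates to render")
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")

    df = estimates_to_frame(estimates).copy()
    df["L_mm"] = df["L_mm"].map(_fmt_length)
    df["pcl_est_mm"] = df["pcl_est_mm"].map(format_pcl)
    df["ci_mm"] = df["ci_mm"].map(lambda v: "" if v is None else format_ci(v))
    df.columns = ["taxon", "comparisons", "meas.", "L (mm)", "PCL est. (mm)", "±"]

    if format == "csv":
        return df.to_csv(index=False)
    if format == "markdown":
        header = "| " + " | ".join(df.columns) + " |"
        sep = "| " + " | ".join("---" for _ in df.columns) + " |"
        rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
        return "\n".join([header, sep, *rows]) + "\n"
    return df.to_string(index=False)
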