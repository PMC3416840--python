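"""Rank a predicted fossil size against extant monitor body sizes.

Predicted precaudal lengths are compared directly against maximum reported
snout-vent lengths (the two measures are osteological/external analogues of
the same trunk length; no conversion is applied). Counting is at species
level: subspecies rows collapse onto their species epithet, and a species'
size is its maximum SVL over all of its rows.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

from .records import ExtantSizeRecord, SpeciesSizeSummary

__all__ = ["species_max_svl", "percent_species_below", "project_exceptional"]


def species_max_svl(
    records: Sequence[ExtantSizeRecord], genus_filter: Optional[str] = None
) -> list[SpeciesSizeSummary]:
    """One summary per species: max SVL over its rows (rows lacking SVL drop).

    ``genus_filter`` (case-insensitive) restricts to one genus first.
    Species with no SVL in any row yield no summary. Output is sorted by
    species name for determinism.
    """
    best: dict[str, float] = {}
    counts: dict[str, int] = defaultdict(int)
    for r in records:
        if genus_filter is not None and r.genus.lower() != genus_filter.lower():
            continue
        if r.svl is None:
            continue
        ep = r.epithet
        counts[ep] += 1
        best[ep] = max(best.get(ep, 0.0), r.svl)
    return [
        SpeciesSizeSummary(species=sp, max_svl=best[sp], n_rows=counts[sp])
        for sp in sorted(best)
    ]


def percent_species_below(
    threshold: float, summaries: Sequence[SpeciesSizeSummary]
) -> float:
    """Percentage of species whose maximum SVL is strictly below ``threshold``.

    Ties count as not-below ("larger than" is strict).
    """
    if not summaries:
        raise ValueError("no species summaries to rank against")
    below = sum(1 for s in summaries if s.max_svl < threshold)
    return 100.0 * below / len(summaries)


def project_exceptional(mean_size: float, percent_of_mean: float) -> float:
    """Project an exceptional individual's size from a species mean.

    The largest wild-caught individuals of several monitor species run
    150–225% of the species mean, so ``mean_size * percent_of_mean / 100``
    sketches how large an outlier of a fossil species might have been.
    """
    if mean_size <= 0 or percent_of_mean <= 0:
        raise ValueError("mean_size and percent_of_mean must be positive")
    return mean_size * percent_of_mean / 100.0
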