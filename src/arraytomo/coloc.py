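"""Volumetric colocalization of pathological proteins with synapses.

A synaptic punctum counts as positive for a marker (tau, oligomeric Aβ)
when at least 50% of its voxel volume lies inside that marker's binary
mask — an object-based volumetric rule, not an intensity correlation.
Markers are scored independently; "double positive" means positive for
each marker separately, which is how the rare tau+Aβ synapses are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .puncta import Punctum
from .stacks import BinaryStack

__all__ = ["ColocResult", "overlap_fraction", "classify_positive", "coloc_rates",
           "DEFAULT_OVERLAP_THRESHOLD"]

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass
class ColocResult:
    """Marker-positive counts for one stratum of synaptic puncta.

    ``fractions[m]`` is ``None`` (absent, not zero) when the stratum
    holds no puncta.
    """

    stratum: dict[str, str]
    synaptic_channel: str
    n_puncta: int
    n_positive: dict[str, int]
    n_double_positive: int
    fractions: dict[str, float | None] = field(default_factory=dict)
    double_positive_fraction: float | None = None

    def __post_init__(self) -> None:
        for m, k in self.n_positive.items():
            if not 0 <= k <= self.n_puncta:
                raise ValueError(f"positive count for {m!r} out of range")
        if self.n_positive and self.n_double_positive > min(self.n_positive.values()):
            raise ValueError("double-positive count exceeds a single-marker count")


def overlap_fraction(punctum: Punctum, marker_mask: BinaryStack) -> float:
    """Fraction of the punctum's voxels inside the marker mask, in [0, 1]."""
    if punctum.n_voxels == 0:
        raise ValueError("empty punctum")
    zz, rr, cc = punctum.voxels
    return float(marker_mask.mask[zz, rr, cc].sum() / len(zz))


def classify_positive(fraction: float, threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> bool:
    """Positive iff overlap fraction >= threshold (minimum-50% inclusive)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("overlap fraction must be in [0, 1]")
    return fraction >= threshold


def coloc_rates(
    synaptic_puncta: list[Punctum],
    marker_masks: dict[str, BinaryStack],
    strata: list[dict[str, str]] | None = None,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    report_strata: list[dict[str, str]] | None = None,
) -> list[ColocResult]:
    """Score puncta against every marker mask and summarise per stratum.

    ``strata``, when given, is a per-punctum list of label dicts (e.g.
    ``{"near_far": "near", "animal_id": "m1"}``); results are reported
    for each distinct label combination. ``report_strata`` lists strata
    that must appear in the output even when empty (reported with n=0
    and absent fractions, which is not the same as fraction 0). Puncta
    are scored once and the double-positive call is the conjunction of
    the independent single-marker calls.
    """
    n = len(synaptic_puncta)
    if strata is None:
        strata = [{}] * n
    if len(strata) != n:
        raise ValueError("strata must align with puncta")
    markers = list(marker_masks)
    calls = np.zeros((n, len(markers)), dtype=bool)
    for j, m in enumerate(markers):
        mask = marker_masks[m]
        for i, p in enumerate(synaptic_puncta):
            calls[i, j] = classify_positive(overlap_fraction(p, mask), threshold)

    keys = {tuple(sorted(s.items())) for s in strata}
    if report_strata:
        keys |= {tuple(sorted(s.items())) for s in report_strata}
    keys = sorted(keys)
    channel = synaptic_puncta[0].channel if synaptic_puncta else ""
    results = []
    for key in keys:
        idx = [i for i, s in enumerate(strata) if tuple(sorted(s.items())) == key]
        sub = calls[idx]
        n_sub = len(idx)
        n_pos = {m: int(sub[:, j].sum()) for j, m in enumerate(markers)}
        n_double = int(sub.all(axis=1).sum()) if markers else 0
        res = ColocResult(
            stratum=dict(key),
            synaptic_channel=channel,
            n_puncta=n_sub,
            n_positive=n_pos,
            n_double_positive=n_double,
            fractions={m: (n_pos[m] / n_sub if n_sub else None) for m in markers},
            double_positive_fraction=(n_double / n_sub if n_sub else None),
        )
        results.append(res)
    return results


def coloc_table(results: list[ColocResult]) -> pd.DataFrame:
    """Long-format table: one row per stratum × marker (plus 'double')."""
    rows = []
    for r in results:
        for m in r.n_positive:
            rows.append({**r.stratum, "synaptic_channel": r.synaptic_channel,
                         "marker": m, "n_puncta": r.n_puncta,
                         "n_positive": r.n_positive[m],
                         "fraction": r.fractions.get(m)})
        rows.append({**r.stratum, "synaptic_channel": r.synaptic_channel,
                     "marker": "double", "n_puncta": r.n_puncta,
                     "n_positive": r.n_double_positive,
                     "fraction": r.double_positive_fraction})
    return pd.DataFrame(rows)
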