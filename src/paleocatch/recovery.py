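"""Recovery-bias diagnostics (second-order changes).

Differences in excavation and analysis methods — notably sieve mesh size —
can distort NISP and richness independently of what was deposited. This
module reproduces the standard diagnostics: one-way ANOVA with Tukey HSD
across mesh classes, Pearson correlation of richness against NISP density,
and sensitivity of that correlation to a single extreme endmember site.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

MESH_CLASSES = ("2-3 mm", "4 mm", "5 mm")


def mesh_class(mesh_mm: float) -> str:
    """Pool 2 and 3 mm sieves into one class (both adequate for fish bone);
    4 and 5 mm stand alone."""
    if mesh_mm in (2, 3, 2.0, 3.0):
        return "2-3 mm"
    if mesh_mm in (4, 4.0):
        return "4 mm"
    if mesh_mm in (5, 5.0):
        return "5 mm"
    raise ValueError(f"unsupported mesh size: {mesh_mm!r} (expected 2, 3, 4 or 5 mm)")


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    ci_low: float
    ci_high: float


@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    pairwise: dict[tuple[str, str], TukeyPair]

    def pair(self, a: str, b: str) -> TukeyPair:
        return self.pairwise[tuple(sorted((a, b)))]


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """Classic one-way ANOVA followed by Tukey's HSD (Tukey-Kramer for
    unbalanced groups) at 95% family-wise confidence.

    Pairwise p-values come from the studentized-range distribution; with two
    groups the Tukey p equals the pooled-variance two-sample t-test p.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    labels = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    f, p = stats.f_oneway(*arrays)

    values = np.concatenate(arrays)
    codes = np.concatenate([[g] * len(a) for g, a in zip(labels, arrays)])
    hsd = pairwise_tukeyhsd(values, codes, alpha=0.05)
    pairwise: dict[tuple[str, str], TukeyPair] = {}
    for row in hsd.summary().data[1:]:
        a, b, diff, p_adj, lo, hi, _ = row
        key = tuple(sorted((str(a), str(b))))
        pairwise[key] = TukeyPair(key[0], key[1], float(diff), float(p_adj),
                                  float(lo), float(hi))
    return AnovaTukeyResult(f=float(f), p=float(p), pairwise=pairwise)


@dataclass
class PearsonResult:
    r: float
    p: float
    n: int


def pearson_sr_nisp(points: Sequence[tuple[float, float]]) -> PearsonResult:
    """Pearson correlation (two-sided t-based p) between richness and NISP
    density across sites."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p), n=int(pts.shape[0]))


@dataclass
class EndmemberResult:
    with_point: PearsonResult
    without_point: PearsonResult
    endmember_index: int
    mahalanobis_fallback: bool


def endmember_sensitivity(
    points: Sequence[tuple[float, float]],
    allow_mahalanobis_fallback: bool = True,
) -> EndmemberResult:
    """Correlation with and without the endmember maximal in both variables.

    When no single point is maximal in both coordinates, the point with the
    largest Mahalanobis distance is used instead and flagged. A lone extreme
    site can manufacture an apparent SR ~ NISP/m^3 association; this
    diagnostic quantifies its leverage.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    x, y = pts[:, 0], pts[:, 1]
    ix, iy = int(np.argmax(x)), int(np.argmax(y))
    fallback = False
    if ix == iy:
        idx = ix
    else:
        if not allow_mahalanobis_fallback:
            raise ValueError("no point is maximal in both variables")
        fallback = True
        centred = pts - pts.mean(axis=0)
        cov = np.cov(centred.T)
        inv = np.linalg.pinv(cov)
        d2 = np.einsum("ij,jk,ik->i", centred, inv, centred)
        idx = int(np.argmax(d2))
    keep = np.ones(pts.shape[0], dtype=bool)
    keep[idx] = False
    return EndmemberResult(
        with_point=pearson_sr_nisp(pts),
        without_point=pearson_sr_nisp(pts[keep]),
        endmember_index=idx,
        mahalanobis_fallback=fallback,
    )
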