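"""Richness estimation and the alpha/gamma community-overlap model.

Alpha-diversity per community is estimated with bias-corrected Chao1,
S_obs + F1(F1-1)/(2(F2+1)), from singleton (F1) and doubleton (F2) counts.
Community overlap among N communities treats richness as an effective
number of species and rescales the alpha/gamma ratio:

    overlap = (alpha/gamma - 1/N) / (1 - 1/N)

which is 1 when all communities are identical (alpha = gamma) and 0 when
they are completely distinct (gamma = N * alpha).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger("smdiv")


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RichnessEstimate:
    observed: int
    chao1: float
    F1: int
    F2: int

    @property
    def coverage(self) -> float:
        """Observed/Chao1 ratio; fraction of the estimated richness seen."""
        return self.observed / self.chao1 if self.chao1 > 0 else 0.0

    @property
    def coverage_pct(self) -> int:
        return _round_half_up(100.0 * self.coverage)


def chao1(otu_counts, bias_corrected: bool = True) -> RichnessEstimate:
    """Chao1 richness from a vector of per-OTU counts (zeros ignored).

    The bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) is the default and
    is defined even when no doubletons are present; the classic form
    S_obs + F1^2/(2 F2) is available with ``bias_corrected=False``.
    """
    counts = np.asarray(list(otu_counts), dtype=float)
    if counts.size and (counts < 0).any():
        raise ValueError("negative count in OTU vector")
    counts = counts[counts > 0]
    observed = int(counts.size)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if observed == 0:
        return RichnessEstimate(0, 0.0, 0, 0)
    if bias_corrected:
        est = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        est = observed + (f1 * f1 / (2.0 * f2) if f2 > 0 else 0.0)
    return RichnessEstimate(observed, float(est), f1, f2)


def rarefy_curve(
    otu_counts, depths, iterations: int = 10, seed: int | None = None
) -> pd.DataFrame:
    """Mean observed richness and Chao1 under repeated subsampling.

    At each depth, ``iterations`` subsamples are drawn without replacement
    (multivariate hypergeometric) and the mean observed-OTU count and
    Chao1 are reported.
    """
    counts = np.asarray(list(otu_counts), dtype=int)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total count {total}")
        obs, est = [], []
        for _ in range(iterations):
            sub = rng.multivariate_hypergeometric(counts, int(depth))
            r = chao1(sub)
            obs.append(r.observed)
            est.append(r.chao1)
        rows.append(
            {"depth": int(depth), "observed": float(np.mean(obs)), "chao1": float(np.mean(est))}
        )
    return pd.DataFrame(rows)


def overlap_statistic(alphas, gamma: float, N: int | None = None) -> float:
    """Effective-species overlap of N communities from alpha and gamma richness.

    ``alphas`` are per-community richness values (their arithmetic mean is
    alpha); ``gamma`` is the pooled richness. The result is clipped to
    [0, 1]. A gamma below max(alphas) is estimator noise and warns rather
    than erroring.
    """
    alphas = [float(a) for a in alphas]
    n = len(alphas) if N is None else int(N)
    if n < 2:
        raise ValueError("overlap requires at least two communities")
    if len(alphas) != n:
        raise ValueError(f"expected {n} alpha values, got {len(alphas)}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if gamma < max(alphas):
        warnings.warn(
            "gamma below max(alpha): richness-estimator noise", stacklevel=2
        )
    alpha = float(np.mean(alphas))
    raw = (alpha / gamma - 1.0 / n) / (1.0 - 1.0 / n)
    return float(np.clip(raw, 0.0, 1.0))


def site_overlap_report(
    per_site_counts: dict[str, list], pooled_counts, bias_corrected: bool = True
) -> dict:
    """Per-site and pooled richness plus the overlap of the sites.

    ``per_site_counts`` maps site label to its OTU count vector;
    ``pooled_counts`` is the count vector of all sites combined. Overlap is
    computed on Chao1 richness (observed-OTU overlap reported alongside);
    percentages are rounded half-up for reporting, with raw ratios always
    retained.
    """
    if len(per_site_counts) < 2:
        raise ValueError("overlap requires at least two sites")
    per_site = {s: chao1(c, bias_corrected) for s, c in per_site_counts.items()}
    pooled = chao1(pooled_counts, bias_corrected)
    chao_alphas = [r.chao1 for r in per_site.values()]
    obs_alphas = [r.observed for r in per_site.values()]
    overlap = overlap_statistic(chao_alphas, pooled.chao1)
    overlap_obs = overlap_statistic(obs_alphas, pooled.observed)
    report = {
        "per_site": per_site,
        "pooled": pooled,
        "mean_alpha": _round_half_up(float(np.mean(chao_alphas))),
        "mean_alpha_raw": float(np.mean(chao_alphas)),
        "mean_coverage_pct": _round_half_up(
            100.0 * float(np.mean([r.coverage for r in per_site.values()]))
        ),
        "overlap": overlap,
        "overlap_pct": _round_half_up(100.0 * overlap),
        "overlap_observed": overlap_obs,
    }
    logger.info(
        "site_overlap_report: mean alpha %s, overlap %.3f",
        report["mean_alpha"], overlap,
    )
    return report
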