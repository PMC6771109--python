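"""Per-area posterior summaries, uncertainty statistics and convergence flags.

Point estimates are posterior medians of the ratio-scale draws; uncertainty
is reported as equal-tailed 60% and 80% credible intervals and as the
difference in posterior probabilities DPP = 2 |PP_high - 0.5|, where
PP_high is the posterior probability that the area's ratio exceeds 1.
Convergence per retained chain is screened with the Geweke diagnostic
(early vs late window means) at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AtlasEstimate",
    "summarise",
    "summarise_matrix",
    "dpp",
    "geweke_score",
    "geweke_flags",
    "estimates_table",
]


@dataclass
class AtlasEstimate:
    area_id: object
    point: float
    cri60: tuple
    cri80: tuple
    pp_high: float
    dpp: float

    def __post_init__(self) -> None:
        if not (self.cri80[0] <= self.cri60[0] <= self.point <= self.cri60[1] <= self.cri80[1]):
            raise ValueError("credible intervals must nest around the point estimate")
        if not 0.0 <= self.dpp <= 1.0:
            raise ValueError("dpp must lie in [0, 1]")


def dpp(draws) -> tuple[float, float]:
    """(PP_high, DPP) from ratio-scale draws.

    PP_high is the fraction of draws strictly greater than 1 (draws equal
    to 1 count as not greater); DPP = 2 |PP_high - 0.5|.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("at least one draw required")
    pp_high = float(np.mean(draws > 1.0))
    return pp_high, 2.0 * abs(pp_high - 0.5)


def summarise(draws, area_id=None) -> AtlasEstimate:
    """Posterior median and equal-tailed 60%/80% intervals of one area's draws.

    Quantiles use linear interpolation between order statistics.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("at least two draws required")
    qs = np.quantile(draws, [0.1, 0.2, 0.5, 0.8, 0.9])
    pp_high, d = dpp(draws)
    return AtlasEstimate(
        area_id,
        float(qs[2]),
        (float(qs[1]), float(qs[3])),
        (float(qs[0]), float(qs[4])),
        pp_high,
        d,
    )


def summarise_matrix(draw_matrix, area_ids=None) -> pd.DataFrame:
    """Vectorised summaries for a draws x areas matrix."""
    X = np.asarray(draw_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("draw matrix must be (draws >= 2) x areas")
    ids = list(area_ids) if area_ids is not None else list(range(X.shape[1]))
    q = np.quantile(X, [0.1, 0.2, 0.5, 0.8, 0.9], axis=0)
    pp_high = (X > 1.0).mean(axis=0)
    return pd.DataFrame(
        {
            "area": ids,
            "point": q[2],
            "cri60_lo": q[1],
            "cri60_hi": q[3],
            "cri80_lo": q[0],
            "cri80_hi": q[4],
            "pp_high": pp_high,
            "dpp": 2.0 * np.abs(pp_high - 0.5),
        }
    )


def _long_run_variance(x: np.ndarray) -> float:
    """Bartlett-window (Newey-West) spectral variance estimate at frequency 0."""
    n = x.size
    x = x - x.mean()
    g0 = float(x @ x) / n
    L = max(int(round(n ** (1.0 / 3.0))), 1)
    s = g0
    for l in range(1, min(L, n - 1) + 1):
        gl = float(x[l:] @ x[:-l]) / n
        s += 2.0 * (1.0 - l / (L + 1.0)) * gl
    return max(s, 0.0)


def geweke_score(chain, first: float = 0.1, last: float = 0.5) -> tuple[float, float]:
    """Geweke z-score and two-sided p-value for one retained chain.

    Compares the means of the first 10% and last 50% of the chain, with
    spectral-density estimates of each segment's long-run variance.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for the Geweke diagnostic")
    a = x[: int(np.floor(first * n))]
    b = x[int(np.ceil((1.0 - last) * n)):]
    va = _long_run_variance(a) / a.size
    vb = _long_run_variance(b) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        return np.nan, np.nan
    z = (a.mean() - b.mean()) / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def geweke_flags(chains, alpha: float = 0.01) -> pd.DataFrame:
    """Flag table for an areas x draws chain matrix.

    Zero-variance chains receive a distinct ``degenerate`` status instead of
    a p-value.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    rows = []
    for i, chain in enumerate(chains):
        if np.ptp(chain) == 0:
            rows.append((i, np.nan, np.nan, True, "degenerate"))
            continue
        z, p = geweke_score(chain)
        rows.append((i, z, p, bool(p < alpha), "flagged" if p < alpha else "ok"))
    return pd.DataFrame(rows, columns=["area_index", "z", "p", "flag", "status"])


def estimates_table(draw_matrix, area_ids=None, alpha: float = 0.01) -> pd.DataFrame:
    """Full per-area estimates table: summaries plus Geweke flags."""
    df = summarise_matrix(draw_matrix, area_ids)
    flags = geweke_flags(np.asarray(draw_matrix, dtype=float).T, alpha=alpha)
    df["geweke_flag"] = flags["flag"].to_numpy()
    df["geweke_status"] = flags["status"].to_numpy()
    return df
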