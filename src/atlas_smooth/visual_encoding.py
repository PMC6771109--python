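"""Uncertainty-aware visual mappings: colour, transparency, V-plots,
wave plots and regional summaries.

The diverging colour gradient is linear in log(estimate), anchored at a
ratio of 1.5 (darkest red), its inverse 1/1.5 (darkest blue) and 1
(yellow, the national average).  A pale-yellow mask whose opacity falls
linearly from 100% at DPP = 0 to 0% at DPP = 1 fades out estimates that
are unlikely to differ from the average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "ColourScale",
    "colour_position",
    "opacity_percent",
    "vplot_data",
    "waveplot_data",
    "region_summary",
    "style_properties",
    "write_styled_geojson",
]

UPPER_ANCHOR = 1.5
DEFAULT_STOPS = ("#2166ac", "#ffffbf", "#b2182b")  # blue - yellow - red
DEFAULT_BAND_EDGES = (0.0, 1.0 / UPPER_ANCHOR, 0.95, 1.05, UPPER_ANCHOR, np.inf)
DEFAULT_BAND_LABELS = ("well below", "below", "average", "above", "well above")


def colour_position(v, upper: float = UPPER_ANCHOR):
    """Position in [0, 1] on the log-linear diverging gradient.

    0 is darkest blue (ratio <= 1/upper), 0.5 yellow (ratio 1), 1 darkest
    red (ratio >= upper); clamped outside the anchors.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("ratio-scale estimates must be positive")
    pos = np.clip(0.5 + np.log(v) / (2.0 * np.log(upper)), 0.0, 1.0)
    return float(pos) if pos.ndim == 0 else pos


def opacity_percent(dpp):
    """Opacity of the pale-yellow mask: 100 * (1 - DPP), in percent.

    Linear between the two defined endpoints: 0% at DPP = 1, 100% at
    DPP = 0.
    """
    dpp = np.asarray(dpp, dtype=float)
    if np.any((dpp < 0) | (dpp > 1)):
        raise ValueError("dpp must lie in [0, 1]")
    out = 100.0 * (1.0 - dpp)
    return float(out) if out.ndim == 0 else out


@dataclass
class ColourScale:
    """Diverging gradient with configurable hex stops; positions are the contract."""

    upper: float = UPPER_ANCHOR
    stops: tuple = DEFAULT_STOPS

    @property
    def lower(self) -> float:
        return 1.0 / self.upper

    def position(self, v):
        return colour_position(v, upper=self.upper)

    def rgba(self, v):
        from matplotlib.colors import LinearSegmentedColormap

        cmap = LinearSegmentedColormap.from_list("atlas_diverging", list(self.stops))
        return cmap(self.position(v))

    def hex(self, v) -> str:
        from matplotlib.colors import to_hex

        return to_hex(self.rgba(v))


def vplot_data(estimates: pd.DataFrame) -> pd.DataFrame:
    """One point per area: x = posterior median ratio, y = DPP."""
    return pd.DataFrame(
        {"area": estimates["area"], "x": estimates["point"], "y": estimates["dpp"]}
    )


def waveplot_data(draws, gridsize: int = 256, cri: pd.Series | None = None) -> dict:
    """Kernel density of the log ratio with ratio-scale tick labels.

    Returns grid (log scale), density, tick positions/labels, and the 60/80%
    interval bounds shared with the summary computation.
    """
    from .posterior_summaries import summarise

    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("at least 100 draws required for a wave plot")
    if np.ptp(draws) == 0:
        raise ValueError("degenerate draws: no spread to plot")
    logd = np.log(draws)
    kde = gaussian_kde(logd, bw_method="silverman")
    pad = 0.5
    grid = np.linspace(logd.min() - pad, logd.max() + pad, gridsize)
    density = kde(grid)
    est = summarise(draws)
    ratio_ticks = [0.25, 0.5, 1.0 / UPPER_ANCHOR, 1.0, UPPER_ANCHOR, 2.0, 4.0]
    ticks = [t for t in ratio_ticks if grid.min() <= np.log(t) <= grid.max()]
    return {
        "grid_log": grid.tolist(),
        "density": density.tolist(),
        "tick_positions": [float(np.log(t)) for t in ticks],
        "tick_labels": [f"{t:g}" for t in ticks],
        "cri60": list(est.cri60),
        "cri80": list(est.cri80),
        "median": est.point,
    }


def region_summary(
    estimates: pd.DataFrame,
    grouping: pd.DataFrame,
    band_edges=DEFAULT_BAND_EDGES,
    band_labels=DEFAULT_BAND_LABELS,
) -> pd.DataFrame:
    """Per-group five-number summaries and colour-band percentages.

    ``grouping`` maps every area to exactly one group (columns area, group).
    """
    merged = estimates.merge(grouping, on="area", how="left", validate="one_to_one")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "area"].tolist()
        raise ValueError(f"areas without a group assignment: {missing[:5]}")
    rows = []
    for group, sub in merged.groupby("group"):
        pts = sub["point"].to_numpy()
        q = np.quantile(pts, [0.0, 0.25, 0.5, 0.75, 1.0])
        bands = np.histogram(pts, bins=np.asarray(band_edges, dtype=float))[0]
        pct = 100.0 * bands / pts.size
        row = {
            "group": group,
            "n_areas": pts.size,
            "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
        }
        row.update({f"pct_{lab.replace(' ', '_')}": p for lab, p in zip(band_labels, pct)})
        rows.append(row)
    return pd.DataFrame(rows)


def style_properties(estimates: pd.DataFrame, scale: ColourScale | None = None) -> pd.DataFrame:
    """Map-layer styling per area: estimate, colour position, hex colour, opacity."""
    scale = scale or ColourScale()
    pts = estimates["point"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "area": estimates["area"],
            "estimate": pts,
            "colour_position": scale.position(pts),
            "colour": [scale.hex(v) for v in pts],
            "mask_opacity_pct": opacity_percent(estimates["dpp"].to_numpy(dtype=float)),
        }
    )


def write_styled_geojson(estimates: pd.DataFrame, geojson_path, out_path,
                         scale: ColourScale | None = None) -> None:
    """Attach style properties to a GeoJSON FeatureCollection by feature id."""
    style = style_properties(estimates, scale).set_index("area")
    with open(geojson_path) as fh:
        gj = json.load(fh)
    for feat in gj["features"]:
        fid = feat.get("id", feat.get("properties", {}).get("id"))
        if fid in style.index:
            feat.setdefault("properties", {}).update(
                style.loc[fid].to_dict()
            )
    with open(out_path, "w") as fh:
        json.dump(gj, fh)
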