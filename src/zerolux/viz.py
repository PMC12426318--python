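"""Plot gallery: scaling comparisons, difference plots, histograms, overlays.

Four ways to put zero-inflated lux data on an axis:

* ``linear`` — faithful but dominated by the daylight peak;
* ``log10`` — physiologically sensible but undefined at 0: zeros are
  omitted, and every plotting function *reports* how many points it
  omitted rather than dropping them silently;
* ``hybrid`` — log axis plus a dedicated band at the bottom marking the
  exact-zero samples;
* ``symlog`` / ``pseudolog`` — signed log-like transforms that keep
  zeros (and, for difference series, negatives) on the axis.

All figures are written as vector SVG by default so tests can inspect
the output.  Each plotting function returns the number of points omitted
by the chosen scale (0 except for log10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import DayWindow, LightTimeSeries, split_day_night
from .gam import GamFit, predict
from .scales import (SymlogScale, hybrid_split, pseudo_log, symlog_forward,
                     symlog_ticks)

__all__ = ["PlotSpec", "plot_timeseries", "plot_difference",
           "plot_histograms", "plot_model_overlay"]

SCALES = ("linear", "log10", "hybrid", "symlog", "pseudolog")

GROUP_COLORS = {"participant": "#E8A33D", "environment": "#3D7EE8"}


@dataclass(frozen=True)
class PlotSpec:
    """Axis scale and optional annotation guides for the light plots."""

    scale: str = "symlog"
    symlog: SymlogScale = SymlogScale()
    pseudo_sigma: float = 1.0
    measurement_range: Optional[tuple[float, float]] = None  # lux guides
    zero_band_offset: float = 1.5   # transformed units below the log floor

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; choose from {SCALES}")
        if self.measurement_range is not None:
            lo, hi = self.measurement_range
            if not (lo > 0 and hi > 0):
                raise ValueError("measurement-range guides must be positive lux")


def _transform(values: np.ndarray, spec: PlotSpec) -> tuple[np.ndarray, np.ndarray]:
    """(transformed values, keep mask); log10 drops zeros/negatives."""
    v = np.asarray(values, dtype=float)
    if spec.scale == "linear":
        return v, np.isfinite(v)
    if spec.scale == "log10":
        keep = np.isfinite(v) & (v > 0)
        out = np.full_like(v, np.nan)
        out[keep] = np.log10(v[keep])
        return out, keep
    if spec.scale == "symlog":
        return symlog_forward(np.nan_to_num(v), spec.symlog), np.isfinite(v)
    if spec.scale == "pseudolog":
        return pseudo_log(np.nan_to_num(v), spec.pseudo_sigma), np.isfinite(v)
    # hybrid handled by the callers via hybrid_split
    raise AssertionError(spec.scale)


def _apply_symlog_axis(ax, values, spec: PlotSpec) -> None:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return
    ticks = symlog_ticks(float(finite.min()), float(finite.max()), spec.symlog)
    ax.set_yticks([p for p, _ in ticks])
    ax.set_yticklabels([lab for _, lab in ticks])


def _guides(ax, spec: PlotSpec, transform) -> None:
    if spec.measurement_range:
        for lux in spec.measurement_range:
            ax.axhline(transform(lux), color="red", ls=":", lw=1)


def plot_timeseries(series_list: Sequence[LightTimeSeries], spec: PlotSpec,
                    out) -> int:
    """Time-series panel under the chosen scale; returns omitted-point count.

    On the log10 scale exact zeros have no image and are omitted — the
    count of omitted points is returned and annotated on the figure.  The
    hybrid scale instead keeps every zero visible in a dedicated band at
    the bottom of the axis.
    """
    if not series_list:
        raise ValueError("need at least one series to plot")
    fig, ax = plt.subplots(figsize=(9, 4))
    omitted = 0
    all_tf = []
    for s in series_list:
        for g in s.sources:
            sub = s.for_source(g)
            color = GROUP_COLORS.get(g)
            if spec.scale == "hybrid":
                parts = hybrid_split(np.nan_to_num(sub.medi))
                tf = np.full(len(sub), np.nan)
                pos = ~parts.zero_mask & ~np.isnan(sub.medi)
                tf[pos] = np.log10(sub.medi[pos])
                floor = np.nanmin(tf) if np.any(pos) else 0.0
                band = floor - spec.zero_band_offset
                tf[parts.zero_mask] = band
                ax.plot(sub.timestamps, tf, ".", ms=2, color=color, label=g)
                ax.axhline(band + spec.zero_band_offset / 2, color="gray",
                           lw=0.5, ls="--")
                ax.text(sub.timestamps[0], band, "0 lux", fontsize=7, va="bottom")
                all_tf.append(tf)
            else:
                tf, keep = _transform(sub.medi, spec)
                omitted += int(np.sum(~keep & ~np.isnan(sub.medi)))
                ax.plot(sub.timestamps, tf, ".", ms=2, color=color, label=g)
                all_tf.append(tf)
    all_tf = np.concatenate(all_tf)
    if spec.scale == "symlog":
        _apply_symlog_axis(ax, all_tf, spec)
        _guides(ax, spec, lambda v: symlog_forward(v, spec.symlog))
    elif spec.scale == "log10":
        _guides(ax, spec, np.log10)
        if omitted:
            ax.annotate(f"{omitted} zero-lux points not shown",
                        (0.01, 0.01), xycoords="axes fraction", fontsize=7)
    ax.set_xlabel("local time")
    ax.set_ylabel(f"melanopic EDI ({spec.scale})")
    ax.legend(loc="upper right", fontsize=7)
    fig.autofmt_xdate()
    fig.savefig(out, format=_fmt(out))
    plt.close(fig)
    return omitted


def plot_difference(a: LightTimeSeries, b: LightTimeSeries, spec: PlotSpec,
                    out) -> int:
    """Plot the sample-wise difference a - b; returns omitted-point count.

    Differences are signed and heavy-tailed in both directions.  The
    symlog scale shows negative magnitudes mirrored below zero (log of
    the absolute difference, then a sign flip); the log10 scale can only
    show positive differences and reports the omissions.  A zero-
    difference guide line is always drawn.
    """
    if len(a) != len(b) or not np.array_equal(a.timestamps.asi8, b.timestamps.asi8):
        raise ValueError("difference requires identical time grids")
    diff = a.medi - b.medi
    fig, ax = plt.subplots(figsize=(9, 4))
    omitted = 0
    if spec.scale == "hybrid":
        parts = hybrid_split(np.nan_to_num(diff))
        tf = np.where(parts.magnitude > 0,
                      parts.sign * np.log10(np.maximum(parts.magnitude, 1e-300)),
                      0.0)
        ax.plot(a.timestamps, tf, ".", ms=2)
        zero_line = 0.0
    else:
        tf, keep = _transform(diff, spec)
        omitted = int(np.sum(~keep & ~np.isnan(diff)))
        ax.plot(a.timestamps, tf, ".", ms=2)
        zero_line = {"linear": 0.0, "log10": np.nan, "symlog": 0.0,
                     "pseudolog": 0.0}[spec.scale]
        if spec.scale == "symlog":
            _apply_symlog_axis(ax, tf, spec)
        if spec.scale == "log10" and omitted:
            ax.annotate(f"{omitted} non-positive differences not shown",
                        (0.01, 0.01), xycoords="axes fraction", fontsize=7)
    if np.isfinite(zero_line):
        ax.axhline(zero_line, color="red", ls="--", lw=1)
    ax.set_xlabel("local time")
    ax.set_ylabel(f"difference in melanopic EDI ({spec.scale})")
    fig.autofmt_xdate()
    fig.savefig(out, format=_fmt(out))
    plt.close(fig)
    return omitted


def plot_histograms(series: LightTimeSeries, window: DayWindow,
                    binwidth: float, out,
                    scale: SymlogScale = SymlogScale()
                    ) -> dict[tuple[str, str], np.ndarray]:
    """Day/night x source histogram panel on the symlog-transformed axis.

    ``binwidth`` is in transformed units (0.5 by convention), so each
    decade above the threshold spans two bins and the zero spike occupies
    its own bin at 0.  An empty subset renders as an annotated empty
    panel rather than an error.  Returns the bin counts per
    ``(source, "day"/"night")`` panel.
    """
    if not binwidth > 0:
        raise ValueError(f"binwidth must be > 0, got {binwidth}")
    sources = series.sources
    fig, axes = plt.subplots(2, len(sources), figsize=(4.5 * len(sources), 6),
                             squeeze=False)
    day, night = split_day_night(series, window)
    counts: dict[tuple[str, str], np.ndarray] = {}
    for col, g in enumerate(sources):
        for row, (name, subset) in enumerate([("day", day), ("night", night)]):
            ax = axes[row][col]
            vals = subset.medi[subset.source == g]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                ax.annotate("no samples", (0.5, 0.5), xycoords="axes fraction",
                            ha="center")
                counts[(g, name)] = np.array([])
            else:
                tf = symlog_forward(vals, scale)
                lo = np.floor(tf.min() / binwidth) * binwidth
                hi = np.ceil(tf.max() / binwidth) * binwidth + binwidth
                edges = np.arange(lo - binwidth / 2, hi, binwidth)
                c, _, _ = ax.hist(tf, bins=edges, color=GROUP_COLORS.get(g))
                counts[(g, name)] = c
            ax.set_title(f"{g}, {name}", fontsize=9)
    fig.tight_layout()
    fig.savefig(out, format=_fmt(out))
    plt.close(fig)
    return counts


def plot_model_overlay(series: LightTimeSeries, fits: Sequence[GamFit],
                       zooms=None, out=None,
                       labels: Optional[Sequence[str]] = None,
                       spec: PlotSpec = PlotSpec(scale="symlog")) -> None:
    """Observations with fitted-model curves on a symlog axis.

    One main panel per source overlaying every model's back-adjusted
    predictions; optional zoom facets at the supplied (start, end)
    windows showing behavior around zero transitions; plus a companion
    scaled-residual panel per fit.
    """
    labels = list(labels or [f"fit {i + 1}" for i in range(len(fits))])
    zooms = list(zooms or [])
    nrows = 2 + (1 if zooms else 0)
    fig = plt.figure(figsize=(10, 3.2 * nrows))
    gs = fig.add_gridspec(nrows, max(len(zooms), 1))
    ax = fig.add_subplot(gs[0, :])
    tfobs = symlog_forward(np.nan_to_num(series.medi), spec.symlog)
    for g in series.sources:
        m = series.source == g
        ax.plot(series.timestamps[m], tfobs[m], ".", ms=2,
                color=GROUP_COLORS.get(g), label=g)
    grid = np.arange(0.0, 86400.0, series.interval)
    day0 = series.timestamps[0].normalize()
    grid_ts = day0 + pd.to_timedelta(grid, unit="s")
    for fit_obj, lab in zip(fits, labels):
        for g in fit_obj.groups:
            lux = predict(fit_obj, grid, g, scale="response")
            ax.plot(grid_ts, symlog_forward(lux, spec.symlog), "-", lw=1,
                    label=f"{lab} ({g})")
    _apply_symlog_axis(ax, tfobs, spec)
    ax.legend(fontsize=6, ncol=2)
    ax.set_ylabel("melanopic EDI (symlog)")
    axr = fig.add_subplot(gs[1, :])
    for fit_obj, lab in zip(fits, labels):
        resid = (fit_obj.y - fit_obj.fitted_response) / np.sqrt(
            fit_obj.phi_hat * (fit_obj.fitted_response ** fit_obj.p_hat
                               if fit_obj.family == "tweedie" else 1.0))
        axr.plot(resid, ".", ms=1.5, label=lab)
    axr.axhline(0, color="k", lw=0.5)
    axr.set_ylabel("scaled Pearson residual")
    axr.legend(fontsize=6)
    for i, (lo, hi) in enumerate(zooms):
        axz = fig.add_subplot(gs[2, i])
        m = (series.timestamps >= lo) & (series.timestamps <= hi)
        axz.plot(series.timestamps[m], tfobs[m], ".", ms=3)
        zm = (grid_ts >= lo) & (grid_ts <= hi)
        for fit_obj, lab in zip(fits, labels):
            for g in fit_obj.groups:
                lux = predict(fit_obj, grid, g, scale="response")
                axz.plot(grid_ts[zm], symlog_forward(lux[zm], spec.symlog),
                         "-", lw=1)
        axz.set_title(f"{lo:%H:%M}-{hi:%H:%M}", fontsize=7)
        axz.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(out, format=_fmt(out))
    plt.close(fig)


def _fmt(path) -> str:
    name = str(path)
    return name.rsplit(".", 1)[-1] if "." in name else "svg"
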