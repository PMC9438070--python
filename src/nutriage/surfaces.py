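"""Nutrient-space response surfaces and screen summaries.

A fitted three-dimensional nutrient smooth is visualized as a gridded
two-dimensional surface: predicted (Z-scored) outcome over the observed
ranges of two nutrients, with the third held fixed (population median for
raw intakes, mean for Z-scored screen variables) and covariates at a
reference profile.  Pointwise standard errors accompany every surface —
the SE is a proxy for sample density, flagging sparsely observed corners
of the intake space.  Rendered colours are clipped at +/- a cap (default
0.8 SD, conventionally a large biological effect); clipping is visual
only and never alters stored values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gam import Smooth
from .models import FitSummary, predict_at

__all__ = ["SurfaceGrid", "make_surface", "render_and_export", "load_surface",
           "p_value_summary"]


@dataclass
class SurfaceGrid:
    x_var: str
    y_var: str
    x_values: np.ndarray  # ascending, length = resolution
    y_values: np.ndarray
    predicted: np.ndarray  # shape (len(y_values), len(x_values))
    se: np.ndarray
    fixed_values: dict[str, float]
    profile: dict[str, object]
    cap: float = 0.8

    def transpose(self) -> "SurfaceGrid":
        return SurfaceGrid(
            x_var=self.y_var,
            y_var=self.x_var,
            x_values=self.y_values,
            y_values=self.x_values,
            predicted=self.predicted.T,
            se=self.se.T,
            fixed_values=dict(self.fixed_values),
            profile=dict(self.profile),
            cap=self.cap,
        )


def make_surface(
    fit: FitSummary,
    x_var: str,
    y_var: str,
    fixed_values: dict[str, float] | None = None,
    profile: dict[str, object] | None = None,
    resolution: int = 25,
    extent: tuple[float, float] = (0.01, 0.99),
    fixed_convention: str = "median",
    cap: float = 0.8,
) -> SurfaceGrid:
    """Gridded predictions over two axis nutrients of one smooth block.

    The grid spans the 1st-99th percentile of the observed values on each
    axis (extrapolation into unobserved intake space is avoided); the
    block's remaining nutrient defaults to its population median
    (``fixed_convention="mean"`` for Z-scored variables).
    """
    results = fit.results if isinstance(fit, FitSummary) else fit
    block = None
    for t in results.model.terms:
        if isinstance(t, Smooth) and x_var in t.variables and y_var in t.variables:
            block = t
            break
    if block is None:
        raise ValueError(
            f"{x_var!r} and {y_var!r} are not axis variables of a single smooth block"
        )
    data = results.model.data
    fixed = dict(fixed_values or {})
    for v in block.variables:
        if v in (x_var, y_var) or v in fixed:
            continue
        col = data[v].to_numpy(float)
        fixed[v] = float(np.median(col)) if fixed_convention == "median" else float(col.mean())

    lo, hi = extent
    xs = np.linspace(*np.quantile(data[x_var].to_numpy(float), [lo, hi]), resolution)
    ys = np.linspace(*np.quantile(data[y_var].to_numpy(float), [lo, hi]), resolution)
    pred = np.empty((resolution, resolution))
    se = np.empty((resolution, resolution))
    for i, yv in enumerate(ys):
        for j, xv in enumerate(xs):
            values = {x_var: xv, y_var: yv, **fixed}
            pred[i, j], se[i, j] = predict_at(fit, values, profile)
    return SurfaceGrid(
        x_var=x_var,
        y_var=y_var,
        x_values=xs,
        y_values=ys,
        predicted=pred,
        se=se,
        fixed_values=fixed,
        profile=dict(profile or {}),
        cap=cap,
    )


def render_and_export(surface: SurfaceGrid, out_dir, name: str | None = None) -> dict[str, Path]:
    """Write surface values + SEs (CSV), metadata (YAML) and a raster image
    with a diverging palette clipped at +/- cap.  The CSV round-trips
    losslessly via :func:`load_surface`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or f"surface_{surface.x_var}_{surface.y_var}"
    xg, yg = np.meshgrid(surface.x_values, surface.y_values)
    table = pd.DataFrame(
        {
            surface.x_var: xg.ravel(),
            surface.y_var: yg.ravel(),
            "predicted": surface.predicted.ravel(),
            "se": surface.se.ravel(),
        }
    )
    csv_path = out_dir / f"{name}.csv"
    table.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "x_var": surface.x_var,
        "y_var": surface.y_var,
        "resolution": [len(surface.y_values), len(surface.x_values)],
        "fixed_values": {k: float(v) for k, v in surface.fixed_values.items()},
        "profile": {k: (v if isinstance(v, str) else float(v))
                    for k, v in surface.profile.items()},
        "cap": float(surface.cap),
    }
    meta_path = out_dir / f"{name}.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, grid, title, kw in (
        (axes[0], surface.predicted, "predicted",
         dict(cmap="RdBu_r", vmin=-surface.cap, vmax=surface.cap)),
        (axes[1], surface.se, "standard error", dict(cmap="viridis")),
    ):
        im = ax.pcolormesh(surface.x_values, surface.y_values, grid, shading="auto", **kw)
        ax.set_xlabel(surface.x_var)
        ax.set_ylabel(surface.y_var)
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    png_path = out_dir / f"{name}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "meta": meta_path, "image": png_path}


def load_surface(csv_path, meta_path) -> SurfaceGrid:
    """Rebuild a SurfaceGrid from its exported CSV + metadata."""
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    table = pd.read_csv(csv_path)
    ny, nx = meta["resolution"]
    return SurfaceGrid(
        x_var=meta["x_var"],
        y_var=meta["y_var"],
        x_values=table[meta["x_var"]].to_numpy()[:nx],
        y_values=table[meta["y_var"]].to_numpy()[::nx][:ny],
        predicted=table["predicted"].to_numpy().reshape(ny, nx),
        se=table["se"].to_numpy().reshape(ny, nx),
        fixed_values=meta["fixed_values"],
        profile=meta["profile"],
        cap=meta["cap"],
    )


def p_value_summary(
    screen_table: pd.DataFrame,
    outcome: str,
    cutoff: float = 0.2,
    bins: int = 20,
) -> dict:
    """Histogram of screen p-values for one outcome plus the fraction below
    the cutoff; the expected per-bin count under a uniform null (m / bins)
    is recorded as the reference line."""
    rows = screen_table[screen_table["outcome"] == outcome]
    p = rows["p"].dropna().to_numpy(float)
    if p.size == 0:
        raise ValueError(f"no screen rows for outcome {outcome!r}")
    counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return {
        "outcome": outcome,
        "counts": counts,
        "bin_edges": edges,
        "fraction_below_cutoff": float(np.mean(p < cutoff)),
        "cutoff": cutoff,
        "n": int(p.size),
        "expected_null_per_bin": p.size / bins,
    }
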