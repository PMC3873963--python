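"""CSV/JSON readers and writers for capture data, rasters and fits.

Long (tidy) CSV is the canonical capture format: one row per detection.
Wide count matrices are accepted for trap captures.  Fits are stored as
JSON together with the configuration needed to rebuild the model context,
so chained commands do not re-fit.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .area import AreaCaptures, AreaDesign
from .fitting import FitResult
from .statespace import Raster, Region, build_grid
from .traps import TrapCaptures, TrapDesign

__all__ = [
    "read_trap_layout",
    "write_trap_layout",
    "read_trap_captures",
    "write_trap_captures",
    "read_area_captures",
    "write_area_captures",
    "read_raster",
    "write_raster",
    "save_fit",
    "load_fit",
    "write_chains",
]


def read_trap_layout(path) -> tuple[list, np.ndarray]:
    """Trap layout CSV with columns trap_id, x, y -> (ids, coordinates)."""
    df = pd.read_csv(path)
    required = {"trap_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trap layout needs columns {sorted(required)}")
    return df["trap_id"].tolist(), df[["x", "y"]].to_numpy(dtype=float)


def write_trap_layout(path, trap_ids, coords) -> None:
    pd.DataFrame(
        {"trap_id": trap_ids, "x": np.asarray(coords)[:, 0], "y": np.asarray(coords)[:, 1]}
    ).to_csv(path, index=False)


def read_trap_captures(path, trap_ids: list, J: int | None = None) -> tuple[TrapCaptures, int]:
    """Capture CSV -> (TrapCaptures, J).

    Long format (individual_id, occasion, trap_id) is canonical; duplicate
    (individual, occasion, trap) rows are collapsed with a warning, as when
    multiple same-day detections are treated as a single recapture.  A wide
    matrix whose columns are the trap ids is also accepted.
    """
    df = pd.read_csv(path)
    long_cols = {"individual_id", "occasion", "trap_id"}
    index = {t: k for k, t in enumerate(trap_ids)}
    if long_cols.issubset(df.columns):
        unknown = set(df["trap_id"]) - set(trap_ids)
        if unknown:
            raise ValueError(f"unknown trap_id values: {sorted(map(str, unknown))}")
        if J is None:
            J = int(df["occasion"].max())
        bad = df[(df["occasion"] < 1) | (df["occasion"] > J)]
        if len(bad):
            raise ValueError(f"occasion outside 1..{J} in rows {bad.index.tolist()}")
        dupes = df.duplicated(subset=["individual_id", "occasion", "trap_id"])
        if dupes.any():
            warnings.warn(
                f"collapsed {int(dupes.sum())} duplicate detection(s) per "
                "(individual, occasion, trap) to single recaptures"
            )
            df = df[~dupes]
        ids = sorted(df["individual_id"].unique())
        y = np.zeros((len(ids), len(trap_ids)), dtype=int)
        imap = {v: i for i, v in enumerate(ids)}
        for _, r in df.iterrows():
            y[imap[r["individual_id"]], index[r["trap_id"]]] += 1
    else:  # wide count matrix: one column per trap id
        cols = [c for c in df.columns if c != "individual_id"]
        if set(cols) != set(map(str, trap_ids)) and set(cols) != set(trap_ids):
            raise ValueError("wide capture matrix columns must match trap ids")
        y = df[[str(t) if str(t) in df.columns else t for t in trap_ids]].to_numpy(dtype=int)
        if J is None:
            raise ValueError("J must be given with a wide capture matrix")
    if np.any(y > J):
        raise ValueError("a capture count exceeds the number of occasions")
    return TrapCaptures(y), J


def write_trap_captures(path, captures: TrapCaptures, trap_ids: list) -> None:
    """Write captures in long format (one row per detection)."""
    rows = []
    for i, row in enumerate(captures.y):
        for k, c in enumerate(row):
            # occasion labels are arbitrary for count data; 1..c keeps rows unique
            for occ in range(1, int(c) + 1):
                rows.append(
                    {"individual_id": i + 1, "occasion": occ, "trap_id": trap_ids[k]}
                )
    df = pd.DataFrame(rows, columns=["individual_id", "occasion", "trap_id"])
    df.to_csv(path, index=False)


def read_area_captures(path, design: AreaDesign) -> AreaCaptures:
    """Long CSV individual_id, occasion, x, y -> AreaCaptures."""
    df = pd.read_csv(path)
    required = {"individual_id", "occasion", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"area captures need columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("no detections in file; nothing to fit")
    J = design.J
    bad = df[(df["occasion"] < 1) | (df["occasion"] > J)]
    if len(bad):
        raise ValueError(f"occasion outside 1..{J} in rows {bad.index.tolist()}")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    inside = design.S.contains(pts)
    if not inside.all():
        first = df.index[~inside][0]
        raise ValueError(f"capture location outside the search plot at row {first}")
    ids = sorted(df["individual_id"].unique())
    imap = {v: i for i, v in enumerate(ids)}
    w = np.zeros((len(ids), J), dtype=int)
    u = np.full((len(ids), J, 2), np.nan)
    for _, r in df.iterrows():
        i, j = imap[r["individual_id"]], int(r["occasion"]) - 1
        w[i, j] = 1
        u[i, j] = (r["x"], r["y"])
    return AreaCaptures(w, u)


def write_area_captures(path, captures: AreaCaptures) -> None:
    rows = []
    for i in range(captures.n):
        for j in range(captures.J):
            if captures.w[i, j] == 1:
                rows.append(
                    {
                        "individual_id": i + 1,
                        "occasion": j + 1,
                        "x": captures.u[i, j, 0],
                        "y": captures.u[i, j, 1],
                    }
                )
    pd.DataFrame(rows, columns=["individual_id", "occasion", "x", "y"]).to_csv(
        path, index=False
    )


def read_raster(path) -> Raster:
    """Raster from long CSV (x, y, value) on a regular grid."""
    df = pd.read_csv(path)
    if not {"x", "y", "value"}.issubset(df.columns):
        raise ValueError("raster CSV needs columns x, y, value")
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    grid = df.pivot_table(index="y", columns="x", values="value").reindex(
        index=ys, columns=xs
    )
    if grid.isna().any().any():
        raise ValueError("raster grid is incomplete (missing x,y combinations)")
    return Raster(xs, ys, grid.to_numpy())


def write_raster(path, raster: Raster) -> None:
    gx, gy = np.meshgrid(raster.x, raster.y)
    pd.DataFrame(
        {"x": gx.ravel(), "y": gy.ravel(), "value": raster.values.ravel()}
    ).to_csv(path, index=False)


def save_fit(path, fit: FitResult, config: dict) -> None:
    """Persist a fit as JSON: estimates, vcov and the rebuild config."""
    payload = {
        "names": fit.names,
        "transforms": fit.transforms,
        "theta": fit.theta.tolist(),
        "loglik": fit.loglik,
        "vcov": None if fit.vcov is None else fit.vcov.tolist(),
        "converged": fit.converged,
        "params": fit.params,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _rebuild_context(config: dict):
    from .area import AreaContext
    from .traps import TrapsContext

    model = config["model"]
    if model == "traps":
        trap_ids, coords = read_trap_layout(config["traps"])
        region = Region(*config["region"])
        raster = read_raster(config["habitat"]) if config.get("habitat") else None
        ss = build_grid(
            region, config["pixel_width"], raster, degree=config.get("degree", 1)
        )
        design = TrapDesign(coords, config["occasions"])
        captures, _ = read_trap_captures(config["captures"], trap_ids, config["occasions"])
        return TrapsContext(ss, design, captures)
    if model == "area":
        region = Region(*config["region"])
        plot = Region(*config["plot"])
        ss = build_grid(region, config["pixel_width"])
        design = AreaDesign(plot, config["occasions"])
        captures = read_area_captures(config["captures"], design)
        return AreaContext(ss, design, captures)
    raise ValueError(f"unknown model kind: {model!r}")


def load_fit(path) -> FitResult:
    """Load a fit JSON and rebuild its model context from the stored config."""
    payload = json.loads(Path(path).read_text())
    ctx = _rebuild_context(payload["config"])
    return FitResult(
        names=payload["names"],
        transforms=payload["transforms"],
        theta=np.asarray(payload["theta"], dtype=float),
        loglik=payload["loglik"],
        vcov=None if payload["vcov"] is None else np.asarray(payload["vcov"]),
        converged=payload["converged"],
        context=ctx,
    )


def write_chains(path, chains) -> None:
    """Posterior draws as CSV with one column per parameter plus n0."""
    df = pd.DataFrame(chains.theta, columns=chains.names)
    df["n0"] = chains.n0
    df["mu_pi0"] = chains.mu_pi0
    df.to_csv(path, index=False)
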