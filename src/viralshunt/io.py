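"""CSV / JSON / YAML input-output and configuration helpers.

Canonical on-disk dialects:

* growth curves, long format (canonical): ``mix,time_h,replicate,od``;
  wide format ``mix,time_h,rep1..repN`` is auto-detected on read but never
  written,
* single-cell tracks: ``track_id,condition,replicate,time_min,length_um,x_um``,
* trajectories: ``time_h,C_g,C_l,B_WT,B_TS_total,od``,
* reports: JSON with the seed and a config hash embedded.

Mix composition is parsed from the mix label ("100WT", "73WT-27TS",
"19WT-81TS", "100TS", plus WT-only controls like "73WT" whose number refers
to the reduced inoculum, not a TS admixture).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams, Trajectory
from .inference import DataError, FitResult, GrowthCurveDataset, ThreeStageFit
from .single_cell import CellTrack, GrowthRateRecord, records_frame

_MIX_RE = re.compile(r"^(\d+)WT(?:[-–](\d+)TS)?$|^(\d+)TS$", re.IGNORECASE)


def parse_mix_label(label: str) -> tuple[float, float]:
    """(wt_fraction, ts_fraction) from a mix label.

    ``"100TS"`` -> (0, 1); ``"73WT-27TS"`` -> (0.73, 0.27); a bare WT label
    such as ``"73WT"`` is a WT-only control -> (1, 0).
    """
    m = _MIX_RE.match(label.strip())
    if not m:
        raise DataError(f"cannot parse mix label '{label}'")
    if m.group(3) is not None:  # pure TS
        return 0.0, 1.0
    if m.group(2) is None:  # WT-only control
        return 1.0, 0.0
    wt, ts = int(m.group(1)), int(m.group(2))
    if wt + ts != 100:
        raise DataError(f"mix label '{label}' fractions do not sum to 100")
    return wt / 100.0, ts / 100.0


def read_growth_curves(path: str | Path) -> dict[str, GrowthCurveDataset]:
    """Read a growth-curve CSV (long or wide) into per-mix datasets."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    out: dict[str, GrowthCurveDataset] = {}
    if {"mix", "time_h", "replicate", "od"} <= cols:
        for mix, g in df.groupby("mix", sort=False):
            wide = g.pivot_table(index="time_h", columns="replicate", values="od")
            if wide.isna().any().any():
                bad = int(g.index[g["od"].isna()].min()) + 2 if g["od"].isna().any() else "?"
                raise DataError(f"{path}: incomplete replicate grid for mix '{mix}' (near line {bad})")
            out[str(mix)] = _dataset_from_wide(str(mix), wide)
    elif "mix" in cols and "time_h" in cols:
        rep_cols = [c for c in df.columns if re.fullmatch(r"rep\d+", c)]
        if not rep_cols:
            raise DataError(f"{path}: no replicate columns (rep1..repN) found")
        for mix, g in df.groupby("mix", sort=False):
            wide = g.set_index("time_h")[rep_cols]
            out[str(mix)] = _dataset_from_wide(str(mix), wide)
    else:
        raise DataError(
            f"{path}: expected columns mix,time_h,replicate,od (long) or "
            "mix,time_h,rep1..repN (wide)"
        )
    return out


def _dataset_from_wide(mix: str, wide: pd.DataFrame) -> GrowthCurveDataset:
    wt, ts = parse_mix_label(mix)
    times = wide.index.to_numpy(dtype=float)
    order = np.argsort(times)
    reps = wide.to_numpy(dtype=float)[order]
    times = times[order]
    return GrowthCurveDataset(
        mix_label=mix,
        wt_fraction=wt,
        ts_fraction=ts,
        initial_od=float(reps[0].mean()),
        times=times,
        replicates=reps,
    )


def write_growth_curves(
    datasets: Iterable[GrowthCurveDataset] | Mapping[str, GrowthCurveDataset],
    path: str | Path,
) -> None:
    """Write datasets as the canonical long-format CSV."""
    if isinstance(datasets, Mapping):
        datasets = list(datasets.values())
    rows = []
    for ds in datasets:
        for j in range(ds.n_replicates):
            for i, t in enumerate(ds.times):
                rows.append(
                    {"mix": ds.mix_label, "time_h": t, "replicate": f"rep{j + 1}",
                     "od": ds.replicates[i, j]}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[CellTrack]:
    df = pd.read_csv(path)
    required = {"track_id", "condition", "replicate", "time_min", "length_um", "x_um"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: track CSV needs columns {sorted(required)}")
    tracks = []
    for (tid, cond, rep), g in df.groupby(
        ["track_id", "condition", "replicate"], sort=False
    ):
        g = g.sort_values("time_min")
        tracks.append(
            CellTrack(
                track_id=str(tid),
                condition=str(cond),
                replicate=str(rep),
                times_min=g["time_min"].to_numpy(float),
                lengths_um=g["length_um"].to_numpy(float),
                x_um=g["x_um"].to_numpy(float),
            )
        )
    return tracks


def write_tracks(tracks: Iterable[CellTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, ln, x in zip(tr.times_min, tr.lengths_um, tr.x_um):
            rows.append(
                {"track_id": tr.track_id, "condition": tr.condition,
                 "replicate": tr.replicate, "time_min": t,
                 "length_um": ln, "x_um": x}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_records(records: Iterable[GrowthRateRecord], path: str | Path) -> None:
    records_frame(records).to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def config_hash(config: Mapping[str, Any] | None) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def params_from_config(config: Mapping[str, Any]) -> ModelParams:
    """Build ModelParams from flat config keys named after the symbols."""
    from .dynamics import DEFAULT_PARAMS

    allowed = {
        "mu_g_max", "K_S_g", "mu_l_max", "K_S_l", "delta", "k", "epsilon",
        "ts_lysate_growth",
    }
    fields = {k: v for k, v in config.items() if k in allowed}
    base = {
        "mu_g_max": DEFAULT_PARAMS.mu_g_max, "K_S_g": DEFAULT_PARAMS.K_S_g,
        "mu_l_max": DEFAULT_PARAMS.mu_l_max, "K_S_l": DEFAULT_PARAMS.K_S_l,
        "delta": DEFAULT_PARAMS.delta, "k": DEFAULT_PARAMS.k,
        "epsilon": DEFAULT_PARAMS.epsilon,
        "ts_lysate_growth": DEFAULT_PARAMS.ts_lysate_growth,
    }
    base.update(fields)
    return ModelParams(**base)


def _fit_result_dict(res: FitResult) -> dict[str, Any]:
    return {
        "stage": res.stage,
        "estimates": res.estimates,
        "bounds": {k: list(v) for k, v in res.bounds.items()},
        "fixed": res.fixed,
        "rss": res.rss,
        "aic": res.aic,
        "bic": res.bic,
        "n_obs": res.n_obs,
        "n_params": res.n_params,
        "ci95": {k: list(v) for k, v in res.ci95.items()} if res.ci95 else None,
    }


def write_fit_report(
    fit: ThreeStageFit,
    path: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> None:
    """JSON fit report: per-stage estimates, diagnostics, CIs, seed, config hash."""
    report = {
        "seed": seed,
        "config_hash": config_hash(config),
        "stages": [_fit_result_dict(res) for res in fit],
    }
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")


def write_json(obj: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
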