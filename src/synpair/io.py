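"""File formats and run configuration.

Tables travel as CSV (spikes, summary statistics, MAPs), traces and
training sets as HDF5, parameter vectors and reports as JSON, run
configuration as YAML.  Times are milliseconds at 0.01 ms precision; z
coordinates are um along the channel axis with the presynaptic soma base
at the origin.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .model_core import MembraneParams
from .sbi import PriorBox, TrainingSet
from .simulator import PairParameters, SimulationConfig, SimulationResult
from .summary import SummaryStats, TEConfig, STAT_NAMES

SPIKE_COLUMNS = ("pair_id", "unit_id", "site", "time_ms")


# ----------------------------------------------------------------------
# spike tables
# ----------------------------------------------------------------------

def write_spike_csv(path, trains: dict) -> None:
    """Write {(pair_id, unit_id, site): times} to a sorted spike table."""
    rows = []
    for (pair_id, unit_id, site), times in trains.items():
        for t in np.asarray(times, dtype=float):
            rows.append((pair_id, unit_id, site, round(float(t), 2)))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df = df.sort_values(list(SPIKE_COLUMNS)).reset_index(drop=True)
    df.to_csv(path, index=False)


def read_spike_csv(path) -> dict:
    """Read a spike table back into {(pair_id, unit_id, site): times}.

    Validates columns and times; collapses duplicate (unit, time) rows
    with a warning; reports the offending line on bad rows.
    """
    df = pd.read_csv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    times = pd.to_numeric(df["time_ms"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(times.to_numpy()))
    if bad.size:
        raise ValueError(f"unparsable time_ms on line {bad[0] + 2}")
    neg = np.flatnonzero(times.to_numpy() < 0)
    if neg.size:
        raise ValueError(f"negative time_ms on line {neg[0] + 2}")
    df["time_ms"] = times
    out: dict = {}
    for key, g in df.groupby(["pair_id", "unit_id", "site"], sort=True):
        t = np.sort(g["time_ms"].to_numpy(dtype=float))
        uniq = np.unique(np.round(t, 2))
        if uniq.size < t.size:
            import warnings
            warnings.warn(
                f"collapsed {t.size - uniq.size} duplicate spike(s) for {key}"
            )
        out[key] = uniq
    return out


def write_result(result: SimulationResult, out_dir) -> None:
    """Serialize one simulation: spikes CSV, parameters JSON, traces HDF5."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trains = {("pair0", name.split("_")[0], name): times
              for name, times in result.spikes.items()}
    write_spike_csv(out / "spikes.csv", trains)
    payload = {
        "parameters": result.parameters.to_dict(),
        "valid": result.valid,
        "diagnostics": result.diagnostics,
        "synapse_events": [round(float(t), 2)
                           for t in result.synapse_events],
    }
    (out / "parameters.json").write_text(json.dumps(payload, indent=2))
    if result.traces is not None:
        with h5py.File(out / "traces.h5", "w") as f:
            f.create_dataset("V_pre", data=result.traces["V_pre"])
            f.create_dataset("V_post", data=result.traces["V_post"])
            f.create_dataset("phi", data=result.traces["phi"])
            f.attrs["dt"] = result.traces["dt"]
            f.attrs["duration"] = result.config.duration


# ----------------------------------------------------------------------
# summary-statistic tables and MAP tables
# ----------------------------------------------------------------------

def write_stats_csv(path, rows: list) -> None:
    """rows: (pair_id, SummaryStats | None); invalid rows get valid=False."""
    recs = []
    for pair_id, s in rows:
        if s is None:
            recs.append({"pair_id": pair_id, "valid": False,
                         **{k: np.nan for k in STAT_NAMES}})
        else:
            rec = {"pair_id": pair_id, "valid": True}
            rec.update(dict(zip(STAT_NAMES, s.to_array())))
            recs.append(rec)
    cols = ["pair_id", *STAT_NAMES, "valid"]
    pd.DataFrame(recs)[cols].rename(columns={"lag": "lag_ms"}).to_csv(
        path, index=False)


def read_stats_csv(path) -> list:
    df = pd.read_csv(path).rename(columns={"lag_ms": "lag"})
    out = []
    for _, row in df.iterrows():
        if not bool(row.get("valid", True)):
            out.append((row["pair_id"], None))
        else:
            out.append((row["pair_id"],
                        SummaryStats(**{k: float(row[k])
                                        for k in STAT_NAMES})))
    return out


def write_maps_csv(path, maps: np.ndarray, pair_ids=None) -> None:
    df = pd.DataFrame(maps, columns=list(C.PARAM_NAMES))
    df.insert(0, "pair_id", pair_ids if pair_ids is not None
              else np.arange(len(df)))
    df.to_csv(path, index=False)


def read_maps_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[list(C.PARAM_NAMES)].to_numpy(dtype=float)


# ----------------------------------------------------------------------
# training sets and models
# ----------------------------------------------------------------------

def write_training_set(path, ts: TrainingSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("theta", data=ts.thetas)
        f.create_dataset("x", data=ts.stats)
        f.attrs["n_attempted"] = ts.n_attempted
        f.attrs["n_valid"] = ts.n_valid
        f.attrs["provenance"] = json.dumps(ts.provenance)


def read_training_set(path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        return TrainingSet(
            thetas=f["theta"][:], stats=f["x"][:],
            n_attempted=int(f.attrs["n_attempted"]),
            n_valid=int(f.attrs["n_valid"]),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )


def save_posterior(path, model) -> None:
    """Persist a fitted posterior (MDN weights + scalers + prior) as .npz."""
    est = model.estimator
    arrays = {f"param_{k}": v for k, v in est.params_.items()}
    arrays.update(x_mean=est.x_mean_, x_scale=est.x_scale_,
                  y_mean=est.y_mean_, y_scale=est.y_scale_,
                  prior_lows=model.prior.lows, prior_highs=model.prior.highs,
                  meta=np.array([est.n_components, est.hidden, est._ydim,
                                 est.n_features_in_]))
    np.savez(path, **arrays)


def load_posterior(path):
    from .sbi import MixtureDensityNetwork, PosteriorModel
    data = np.load(path)
    meta = data["meta"]
    est = MixtureDensityNetwork(n_components=int(meta[0]),
                                hidden=int(meta[1]))
    est._ydim = int(meta[2])
    est.n_features_in_ = int(meta[3])
    est.params_ = {k[len("param_"):]: data[k] for k in data.files
                   if k.startswith("param_")}
    est.x_mean_, est.x_scale_ = data["x_mean"], data["x_scale"]
    est.y_mean_, est.y_scale_ = data["y_mean"], data["y_scale"]
    est.loss_curve_ = []
    ndim = int(meta[2])
    names = C.PARAM_NAMES if ndim == len(C.PARAM_NAMES) else tuple(
        f"p{i}" for i in range(ndim))
    prior = PriorBox(names=names, lows=data["prior_lows"],
                     highs=data["prior_highs"])
    return PosteriorModel(est, prior)


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully defaulted, validated run configuration.

    The default object's model section reproduces the reference parameter
    table field for field.
    """

    model: MembraneParams = MembraneParams()
    prior: PriorBox = field(default_factory=PriorBox)
    simulation: SimulationConfig = SimulationConfig()
    te: TEConfig = TEConfig()
    stats_delta_t_model: float = 0.5
    stats_delta_t_experimental: float = 1.0
    sbi_n_train: int = 2000
    sbi_n_components: int = 10
    sbi_hidden: int = 64


_SECTIONS = {
    "model": MembraneParams,
    "simulation": SimulationConfig,
    "te": TEConfig,
}


def validate_config(raw: dict | str | None) -> RunConfig:
    """Build a RunConfig from a YAML string/dict, rejecting unknown keys."""
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    known = {f.name for f in fields(RunConfig)}
    for key, val in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            allowed = {f.name for f in fields(cls)}
            unknown = set(val) - allowed
            if unknown:
                raise ValueError(f"unknown keys in {key}: {sorted(unknown)}")
            kwargs[key] = cls(**val)
        elif key == "prior":
            names = tuple(C.PARAM_NAMES)
            unknown = set(val) - set(names)
            if unknown:
                raise ValueError(f"unknown prior parameters: {sorted(unknown)}")
            lows = np.array([val.get(k, C.PRIOR_RANGES[k])[0] for k in names],
                            dtype=float)
            highs = np.array([val.get(k, C.PRIOR_RANGES[k])[1] for k in names],
                             dtype=float)
            kwargs["prior"] = PriorBox(names, lows, highs)
        elif key in known:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config section {key!r}")
    return RunConfig(**kwargs)


def config_defaults_dict() -> dict:
    cfg = RunConfig()
    return {
        "model": asdict(cfg.model),
        "prior": {k: list(v) for k, v in C.PRIOR_RANGES.items()},
        "simulation": asdict(cfg.simulation),
        "te": asdict(cfg.te),
    }
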