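"""Delimited-text formats, configuration and the end-to-end pipeline.

Attenuation tables are comma-separated with ms/um units in the headers
(columns ``tm_ms, tau_ms, b_per_m2_s, E_over_E0``) plus a YAML sidecar
carrying the protocol, the generating truth (when synthetic) and the seed.
``run_pipeline`` chains the stages synth -> fit -> tddc -> theory and writes
the series, a compartment summary and a structure table together with a run
log (seed, config hash, versions, stage timings).
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, fitting, geometry, synthetic
from .physics import GAMMA_1H, SSEProtocol, b_value

__all__ = [
    "StageError",
    "RunConfig",
    "read_attenuation_table",
    "write_attenuation_table",
    "protocol_to_dict",
    "protocol_from_dict",
    "series_to_frame",
    "run_pipeline",
]

TABLE_COLUMNS = ["tm_ms", "tau_ms", "b_per_m2_s", "E_over_E0"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def protocol_to_dict(protocol: SSEProtocol) -> dict:
    """Protocol as a YAML/JSON-ready mapping (ms units)."""
    return {
        "G_T_per_m": float(protocol.G),
        "gamma_rad_per_sT": float(protocol.gamma),
        "tau_ms": [float(t) * 1e3 for t in protocol.tau_grid],
        "tm_ms": [float(t) * 1e3 for t in protocol.tm_grid],
        "T1_ms": float(protocol.T1) * 1e3,
        "T2_ms": float(protocol.T2) * 1e3,
    }


def protocol_from_dict(cfg: dict) -> SSEProtocol:
    return SSEProtocol(
        G=float(cfg["G_T_per_m"]),
        gamma=float(cfg.get("gamma_rad_per_sT", GAMMA_1H)),
        tau_grid=np.asarray(cfg["tau_ms"], dtype=float) * 1e-3,
        tm_grid=np.asarray(cfg["tm_ms"], dtype=float) * 1e-3,
        T1=float(cfg["T1_ms"]) * 1e-3,
        T2=float(cfg["T2_ms"]) * 1e-3,
    )


def write_attenuation_table(dataset: synthetic.AttenuationDataset, path) -> None:
    """Write records as CSV plus a ``<path>.yaml`` sidecar with provenance."""
    path = Path(path)
    df = pd.DataFrame({
        "tm_ms": dataset.records["tm"] * 1e3,
        "tau_ms": dataset.records["tau"] * 1e3,
        "b_per_m2_s": dataset.records["b"],
        "E_over_E0": dataset.records["E"],
    })
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round trip
    sidecar = {"protocol": protocol_to_dict(dataset.protocol),
               "seed": dataset.seed,
               "generator_version": dataset.generator_version}
    if dataset.truth is not None:
        sidecar["truth"] = _truth_to_dict(dataset.truth)
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False)
    )


def _truth_to_dict(truth: synthetic.TruthModel) -> dict:
    pools = []
    for p in truth.pools:
        pools.append({
            "label": int(p.label), "D0_m2s": float(p.D0),
            "p0": [float(x) for x in p.p0],
            "tau_s": [float(x) for x in p.tau],
            "SV_per_m": None if p.SV is None else float(p.SV),
            "W": int(p.W),
            "R_m": None if p.R is None else float(p.R),
            "d": int(p.d),
            "transition_s": [float(x) for x in p.transition]
            if p.transition else None,
        })
    return {"pools": pools, "y0": float(truth.y0),
            "noise_sigma": float(truth.noise_sigma), "seed": int(truth.seed)}


def read_attenuation_table(path, protocol: SSEProtocol | None = None
                           ) -> synthetic.AttenuationDataset:
    """Read a delimited attenuation table, validating values and grids.

    Requires columns ``tm_ms, tau_ms, E_over_E0`` (b is recomputed from the
    protocol).  The protocol comes from the explicit argument or from the
    ``<path>.yaml`` sidecar.  Malformed cells and out-of-range attenuations
    are reported with their row; non-monotone grids are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("tm_ms", "tau_ms", "E_over_E0"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() \
            | df[col].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"non-numeric or missing value in column {col!r}, "
                             f"row {row}")
        df[col] = pd.to_numeric(df[col])
    # normalized magnitudes: slightly above 1 is measurement noise at the
    # reference point, far above 1 is a unit or normalization error
    if (df["E_over_E0"] <= 0).any() or (df["E_over_E0"] > 1.25).any():
        row = int(df.index[(df["E_over_E0"] <= 0) | (df["E_over_E0"] > 1.25)][0])
        raise ValueError(f"E/E0 out of range (0, 1.25] at row {row}")

    if protocol is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if not sidecar.exists():
            raise ValueError("no protocol given and no sidecar found")
        protocol = protocol_from_dict(
            yaml.safe_load(sidecar.read_text())["protocol"]
        )

    tm = df["tm_ms"].to_numpy() * 1e-3
    tau = df["tau_ms"].to_numpy() * 1e-3
    for name, grid, ref in (("tm", tm, protocol.tm_grid),
                            ("tau", tau, protocol.tau_grid)):
        vals = np.unique(grid)
        if len(vals) != len(ref) or not np.allclose(np.sort(vals), ref,
                                                    rtol=1e-6):
            raise ValueError(f"{name} grid does not match the protocol")
    # snap to the protocol grids: the protocol is authoritative for timings,
    # which makes write -> read round trips value-exact
    tm = protocol.tm_grid[np.abs(tm[:, None] - protocol.tm_grid).argmin(1)]
    tau = protocol.tau_grid[np.abs(tau[:, None] - protocol.tau_grid).argmin(1)]
    records = pd.DataFrame({
        "tm": tm, "tau": tau,
        "b": b_value(tau, tm, protocol.G, protocol.gamma),
        "E": df["E_over_E0"].to_numpy(),
    })
    return synthetic.AttenuationDataset(protocol, records)


def series_to_frame(series: fitting.TDDCSeries) -> pd.DataFrame:
    """TDDC series as a delimited-ready table with unit-bearing headers."""
    t = series.table
    return pd.DataFrame({
        "tm_ms": t["tm"] * 1e3, "comp": t["comp"],
        "D_m2s": t["D"], "D_se_m2s": t["D_se"],
        "p": t["p"], "p_se": t["p_se"], "y0": t["y0"],
        "RSS": t["RSS"], "AIC": t["AIC"], "BIC": t["BIC"],
        "model_id": t["model_id"], "converged": t["converged"],
    })


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    ``stages`` toggles pipeline steps; ``dataset_path`` loads measured data
    instead of synthesizing (the synth stage then just records provenance).
    """

    out_dir: str
    seed: int = 0
    noise_sigma: float = 0.005
    epsilon: float = 0.02
    tm_break_s: float = 2e-3
    stages: tuple[str, ...] = ("synth", "fit", "tddc", "theory")
    dataset_path: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and persist their outputs.

    Returns a bundle with the dataset, series, summary and structure tables.
    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are already on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    log: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                 "generator_version": synthetic.GENERATOR_VERSION,
                 "stages": {}}

    def stage(name):
        return name in config.stages

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # persist the log, then surface the stage
            log["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        log["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }

    if stage("synth"):
        def _synth():
            if config.dataset_path is not None:
                bundle["dataset"] = read_attenuation_table(config.dataset_path)
            else:
                truth = synthetic.yeast_truth(noise_sigma=config.noise_sigma,
                                              seed=config.seed)
                bundle["dataset"] = synthetic.generate(
                    truth, synthetic.default_protocol()
                )
            write_attenuation_table(bundle["dataset"], out / "dataset.csv")
        run_stage("synth", _synth)

    if stage("fit"):
        def _fit():
            bundle["series"] = fitting.interval_strategy_series(
                bundle["dataset"], tm_break=config.tm_break_s,
                epsilon=config.epsilon,
            )
            series_to_frame(bundle["series"]).to_csv(
                out / "series.csv", index=False, float_format="%.8g"
            )
        run_stage("fit", _fit)

    if stage("tddc"):
        def _tddc():
            summary = analysis.characterize(
                bundle["series"], analysis.default_yeast_plan()
            )
            bundle["summary"] = summary
            summary.to_frame().to_csv(out / "summary.csv", index=False,
                                      float_format="%.6g")
        run_stage("tddc", _tddc)

    if stage("theory"):
        def _theory():
            table = geometry.structure_table()
            bundle["structures"] = table
            table.to_csv(out / "structures.csv", float_format="%.6g")
        run_stage("theory", _theory)

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    bundle["log"] = log
    return bundle
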