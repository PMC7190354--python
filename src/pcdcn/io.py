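"""File formats, configuration, and the end-to-end pipeline driver.

Conventions enforced at the I/O boundary: time in seconds with t = 0 at sweep
start, current in pA, voltages in mV, conductance in nS, kinetic constants in
ms. Stimulus times are stored explicitly, never inferred from artifacts.

The sweep container is HDF5::

    /sweeps/<k>/current_pA      float array
    /sweeps/<k>/stim_times_s    float array (may be empty)
    attrs: sample_rate_hz, v_hold_mV, e_rev_mV, seed, params (JSON string)

Single sweeps can also round-trip through two-column CSV (time_s,current_pA).
All writes are atomic (temp file + rename), so an interrupted run never
leaves a truncated output behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from . import detect as _detect
from . import evoked as _evoked
from . import perievent as _perievent
from . import stats as _stats
from . import synthgen as _synth
from .synthgen import MiniParams, StimProtocol, Trace

__all__ = [
    "write_sweeps",
    "read_traces",
    "write_trace_csv",
    "read_source_data",
    "PipelineConfig",
    "run_pipeline",
    "atomic_write_text",
    "config_hash",
]

log = logging.getLogger("pcdcn")

GROUP_ALIASES = {
    "WT": ("wt", "wildtype", "wild-type", "wild type", "control", "+/+"),
    "KO": ("ko", "knockout", "knock-out", "-/-", "mutant"),
}


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------


def atomic_write_text(path: Union[str, Path], text: str) -> None:
    """Write text via a temp file and rename; never leaves partial files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_dataframe(path: Union[str, Path], df: pd.DataFrame) -> None:
    atomic_write_text(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# Sweep containers
# ---------------------------------------------------------------------------


def write_sweeps(
    path: Union[str, Path],
    sweeps: Sequence[Trace],
    seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> None:
    """Write sweeps to the HDF5 container (atomic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            first = sweeps[0]
            f.attrs["sample_rate_hz"] = first.sample_rate_hz
            f.attrs["v_hold_mV"] = first.v_hold_mV
            f.attrs["e_rev_mV"] = first.e_rev_mV
            if seed is not None:
                f.attrs["seed"] = int(seed)
            if params is not None:
                f.attrs["params"] = json.dumps(params, sort_keys=True)
            grp = f.create_group("sweeps")
            for k, tr in enumerate(sweeps):
                g = grp.create_group(str(k))
                g.create_dataset("current_pA", data=tr.samples)
                stims = tr.stim_times_s if tr.stim_times_s is not None else np.empty(0)
                g.create_dataset("stim_times_s", data=stims)
                g.attrs["t0_s"] = tr.t0_s
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_traces(path: Union[str, Path]) -> list[Trace]:
    """Read sweeps from the HDF5 container or a two-column CSV.

    Missing metadata is an error with an actionable message, never a silent
    default.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt"):
        return [_read_trace_csv(path)]
    with h5py.File(path, "r") as f:
        if "sample_rate_hz" not in f.attrs:
            raise ValueError(
                f"{path}: missing required attribute 'sample_rate_hz'; "
                "write the container with pcdcn.io.write_sweeps"
            )
        fs = float(f.attrs["sample_rate_hz"])
        v_hold = float(f.attrs.get("v_hold_mV", -35.0))
        e_rev = float(f.attrs.get("e_rev_mV", 0.0))
        if "sweeps" not in f:
            raise ValueError(f"{path}: no /sweeps group")
        out = []
        keys = sorted(f["sweeps"].keys(), key=int)
        for k in keys:
            g = f["sweeps"][k]
            stims = np.asarray(g["stim_times_s"])
            out.append(
                Trace(
                    np.asarray(g["current_pA"], dtype=float),
                    fs,
                    t0_s=float(g.attrs.get("t0_s", 0.0)),
                    v_hold_mV=v_hold,
                    e_rev_mV=e_rev,
                    stim_times_s=stims if stims.size else None,
                    meta={"source": str(path), "sweep": int(k)},
                )
            )
    return out


def write_trace_csv(path: Union[str, Path], trace: Trace) -> None:
    """Write one sweep as two-column CSV (time_s,current_pA)."""
    df = pd.DataFrame({"time_s": trace.times_s, "current_pA": trace.samples})
    _atomic_dataframe(path, df)


def _read_trace_csv(path: Path) -> Trace:
    df = pd.read_csv(path)
    expected = {"time_s", "current_pA"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, found {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: samples are not uniformly spaced")
    return Trace(
        df["current_pA"].to_numpy(dtype=float),
        sample_rate_hz=1.0 / float(dt[0]),
        t0_s=float(t[0]),
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Source-data tables
# ---------------------------------------------------------------------------


def _canonical_group(name: str) -> Optional[str]:
    s = str(name).strip().lower()
    for canon, aliases in GROUP_ALIASES.items():
        if s == canon.lower() or s in aliases:
            return canon
    return None


def read_source_data(
    path: Union[str, Path],
    measurement: Optional[str] = None,
    units: str = "",
    aliases: Optional[dict] = None,
) -> pd.DataFrame:
    """Parse a deposited summary table into tidy rows.

    Accepts CSV or XLSX laid out either tidily (columns group/value) or as one
    column per group (headers matched against WT/KO aliases). Blank lines are
    tolerated; non-numeric cells are excluded with a log entry. Returns a
    DataFrame with columns (group, measurement, value, units).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        try:
            raw = pd.read_csv(path, skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            raw = pd.DataFrame()
    if raw.empty and raw.columns.size == 0:
        log.warning("%s: empty source-data file", path)
        return pd.DataFrame(columns=["group", "measurement", "value", "units"])

    alias_map = dict(GROUP_ALIASES)
    if aliases:
        alias_map.update({k: tuple(v) for k, v in aliases.items()})

    def canon(name: str) -> Optional[str]:
        s = str(name).strip().lower()
        for c, al in alias_map.items():
            if s == c.lower() or s in al:
                return c
        return None

    rows = []
    lowered = {str(c).strip().lower(): c for c in raw.columns}
    if "group" in lowered and "value" in lowered:
        meas_col = lowered.get("measurement")
        unit_col = lowered.get("units")
        for i, r in raw.iterrows():
            g = canon(r[lowered["group"]])
            v = pd.to_numeric(r[lowered["value"]], errors="coerce")
            if g is None or not np.isfinite(v):
                log.warning("%s row %d: skipped (group=%r value=%r)", path, i, r[lowered["group"]], r[lowered["value"]])
                continue
            rows.append(
                (
                    g,
                    str(r[meas_col]) if meas_col else (measurement or path.stem),
                    float(v),
                    str(r[unit_col]) if unit_col else units,
                )
            )
    else:
        for col in raw.columns:
            g = canon(col)
            if g is None:
                log.warning("%s: column %r matches no group alias, skipped", path, col)
                continue
            vals = pd.to_numeric(raw[col], errors="coerce")
            n_bad = int(raw[col].notna().sum() - vals.notna().sum())
            if n_bad:
                log.warning("%s: %d non-numeric cells in column %r excluded", path, n_bad, col)
            for v in vals.dropna():
                rows.append((g, measurement or path.stem, float(v), units))
    return pd.DataFrame(rows, columns=["group", "measurement", "value", "units"])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a full synthetic-study run needs; fully determines outputs.

    The two genotype groups share every generator parameter by default (the
    null configuration): group differences then reflect sampling alone.
    """

    seed: int = 0
    out_dir: str = "pcdcn_out"
    # spontaneous-release study
    n_cells_per_group: int = 8
    mini_rate_wt_hz: float = 2.0
    mini_rate_ko_hz: float = 2.0
    mini_amp_pA: float = 50.0
    mini_duration_s: float = 30.0
    mini_snr: float = 8.0
    # train study
    train_frequencies_hz: tuple = (10.0, 20.0, 50.0, 100.0)
    train_n_stim: int = 50
    stp_preset: str = "juvenile"  # or "adult"
    train_snr: float = 20.0
    # peri-stimulus study
    peri_base_rate_hz: float = 75.0
    peri_dip_depth: float = 0.8
    peri_dip_tau_s: float = 0.02
    peri_n_trials: int = 60

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: Union[PipelineConfig, dict]) -> str:
    """Stable hash of a config: key order never changes it."""
    d = config.to_dict() if isinstance(config, PipelineConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: Union[str, Path]) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return PipelineConfig(**data)


def _stp_preset(name: str) -> _synth.STPParams:
    presets = {"juvenile": _synth.JUVENILE_STP, "adult": _synth.ADULT_STP}
    try:
        return presets[name]
    except KeyError:
        raise ValueError(f"unknown STP preset {name!r}; choose from {sorted(presets)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run synth → detect → evoked → perievent → stats and write all outputs.

    Returns the manifest (also written to ``manifest.json``). Identical
    config + seed give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    noise_sd = _synth.noise_sd_for_snr(config.mini_amp_pA, config.mini_snr)

    # --- spontaneous release: per-cell mini frequency and amplitude
    cfg_det = _detect.DetectConfig()
    summary_rows = []
    event_frames = []
    for gi, (group, rate) in enumerate(
        [("WT", config.mini_rate_wt_hz), ("KO", config.mini_rate_ko_hz)]
    ):
        for cell in range(config.n_cells_per_group):
            params = MiniParams(
                rate_hz=rate,
                amp_mean_pA=config.mini_amp_pA,
                noise_sd_pA=noise_sd,
                duration_s=config.mini_duration_s,
            )
            cell_seed = config.seed + 1000 * gi + cell
            trace, _ = _synth.generate_mini_trace(params, seed=cell_seed)
            ev = _detect.detect_events(trace, cfg_det)
            ev = _detect.measure_amplitudes(trace, ev, cfg_det)
            freq = _detect.event_frequency(ev, trace.duration_s)
            mean_amp = float(np.nanmean(ev.amplitudes_pA)) if len(ev) else math.nan
            summary_rows.append(
                {
                    "cell_id": f"{group}{cell}",
                    "genotype": group,
                    "mipsc_frequency_hz": freq,
                    "mipsc_amplitude_pA": mean_amp,
                }
            )
            event_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": f"{group}{cell}",
                        "time_s": ev.times_s,
                        "amplitude_pA": ev.amplitudes_pA,
                        "area_pA_ms": ev.areas_pA_ms,
                    }
                )
            )
    summary = pd.DataFrame(summary_rows)
    _atomic_dataframe(out / "mini_summary.csv", summary)
    _atomic_dataframe(out / "mini_events.csv", pd.concat(event_frames, ignore_index=True))

    stats_out = {}
    for metric in ("mipsc_frequency_hz", "mipsc_amplitude_pA"):
        wt = summary.loc[summary.genotype == "WT", metric].dropna()
        ko = summary.loc[summary.genotype == "KO", metric].dropna()
        if len(wt) < 3 or len(ko) < 3:
            stats_out[metric] = {"error": "fewer than 3 cells per group; gate not applicable"}
        else:
            stats_out[metric] = asdict(_stats.compare_groups(wt, ko))

    # --- trains: measured STP metrics per frequency
    stp = _stp_preset(config.stp_preset)
    train_noise = stp.a1_pA / config.train_snr / 5.0  # averaged-trace noise
    train_rows = []
    for f in config.train_frequencies_hz:
        protocol = StimProtocol.regular(float(f), config.train_n_stim)
        trace, truth = _synth.generate_train_trace(
            stp, protocol, noise_sd_pA=train_noise, seed=config.seed + int(f)
        )
        res = _evoked.analyze_train(trace, protocol)
        for i, (amp, normed, mode) in enumerate(
            zip(res.amplitudes_pA, res.normalized, res.baseline_mode)
        ):
            train_rows.append(
                {
                    "frequency_hz": f,
                    "stim_index": i + 1,
                    "amplitude_pA": amp,
                    "normalized": normed,
                    "baseline_mode": mode,
                    "true_amplitude_pA": truth.per_stimulus_amps_pA[i],
                }
            )
        stats_out.setdefault("train_metrics", {})[str(f)] = {
            "ppr": res.ppr,
            "ss_norm": res.ss_norm,
            "lambda_stim": res.lambda_stim,
            "lambda_s": res.lambda_s,
        }
    _atomic_dataframe(out / "train_amplitudes.csv", pd.DataFrame(train_rows))

    # --- peri-stimulus suppression
    stim_times = 0.5 + np.arange(config.peri_n_trials) * 0.5
    trace, truth = _synth.generate_perievent_trace(
        base_rate_hz=config.peri_base_rate_hz,
        dip_depth=config.peri_dip_depth,
        dip_tau_s=config.peri_dip_tau_s,
        stim_times_s=stim_times,
        duration_s=float(stim_times[-1] + 0.5),
        seed=config.seed + 77,
    )
    hists = _perievent.perievent_rate(truth.event_times_s, stim_times)
    hist = hists["all"]
    metrics = _perievent.suppression_metrics(hist)
    psth = pd.DataFrame(
        {
            "bin_start_s": hist.bin_edges_s[:-1],
            "bin_end_s": hist.bin_edges_s[1:],
            "rate_hz": hist.rate_hz,
            "class": hist.trial_class,
        }
    )
    _atomic_dataframe(out / "psth.csv", psth)
    stats_out["perievent"] = metrics

    atomic_write_text(out / "stats.json", json.dumps(stats_out, indent=2, default=float))

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "outputs": sorted(
            {p.name for p in out.iterdir() if not p.name.startswith(".")} | {"manifest.json"}
        ),
        "mini_stats": {
            k: {"test": v["test_used"], "p": v["p_value"]}
            for k, v in stats_out.items()
            if isinstance(v, dict) and "test_used" in v
        },
    }
    atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2, default=float))
    return manifest
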