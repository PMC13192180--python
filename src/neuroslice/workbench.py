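"""Run configuration, experiment dispatch and condition-level summaries.

Ties the analysis modules together the way the study's figure panels
are assembled: a manifest lists input files by kind (lfp | ic | image |
plate) with a condition label; :func:`run_experiment` dispatches each
input to the matching module and assembles per-record results plus a
per-condition summary table (state distributions, gamma peak medians,
cell densities).  Every output row carries the configuration hash and
the input checksum so any number can be traced to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, classify, counting, intracellular, spectral
from .synth.ic import IcStep
from .trace import read_trace

__all__ = ["RunConfig", "run_experiment", "compare_conditions", "activity_table"]

STATES = ("Gamma", "LowActivity", "Bursts", "NoActivity")


@dataclass(frozen=True)
class RunConfig:
    """All module thresholds and defaults, serialized with every output."""

    gamma_freq_min: float = 23.0
    power_min: float = 1e-4
    silence_rms: float = 2e-3
    min_burst_events: int = 3
    burst_crest_min: float = 4.0
    prominence_frac: float = 0.85
    refractory_s: float = 0.2
    corner_hz: float = 200.0
    window_len: int = 8192
    segment: tuple[float, float] | None = None  # (start_s, end_s) or full trace
    min_particle_px: int = 400
    min_soma_px: int = 300
    dilation_px: float = 100.0
    pixel_um: float = 0.31
    roi_um: float = 200.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file with typed validation."""
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key == "segment":
                values[key] = None if raw in ("none", "") else tuple(float(x) for x in raw.split(":"))
            elif types[key] == "int":
                values[key] = int(raw)
            else:
                values[key] = float(raw)
        return cls.from_dict(values)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def thresholds(self) -> classify.ClassifyThresholds:
        return classify.ClassifyThresholds(
            gamma_freq_min=self.gamma_freq_min,
            power_min=self.power_min,
            silence_rms=self.silence_rms,
            min_burst_events=self.min_burst_events,
            burst_crest_min=self.burst_crest_min,
        )


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def analyze_lfp_file(path: str | Path, config: RunConfig) -> dict:
    """Filter, spectral-analyze and classify one LFP trace file."""
    trace = read_trace(path)
    if config.segment is not None:
        trace = spectral.extract_segment(trace, *config.segment)
    filtered = spectral.lowpass_butterworth(trace, corner_hz=config.corner_hz)
    psd = spectral.welch_psd(filtered, window_len_samples=min(config.window_len, filtered.n))
    peak = spectral.find_spectral_peak(psd)
    bursts = classify.detect_bursts(
        filtered, prominence_frac=config.prominence_frac, refractory_s=config.refractory_s
    )
    call = classify.classify_state(filtered, peak, bursts, thresholds=config.thresholds)
    return {
        "kind": "lfp",
        "state": call.state,
        "peak_freq_hz": peak.peak_freq,
        "peak_power_mv2_hz": peak.peak_power,
        "n_bursts": len(call.burst_events),
        "burst_subtype": call.burst_subtype,
    }


def analyze_ic_file(path: str | Path, protocol_path: str | Path, config: RunConfig) -> dict:
    """Per-cell intracellular metrics for the steps of a protocol JSON."""
    trace = read_trace(path)
    steps = [IcStep(**s) for s in json.loads(Path(protocol_path).read_text())]
    rows = []
    for step in steps:
        m = intracellular.step_metrics(trace, step)
        rows.append(
            {
                "amp_na": step.amp_na,
                "latency_ms": m.latency_first_ms,
                "n_aps": m.n_aps_total,
                "n_aps_100ms": m.n_aps_first_100ms,
                "mahp_mv": m.mahp_mv,
                "sahp_mv": m.sahp_mv,
            }
        )
    return {"kind": "ic", "steps": rows}


def analyze_image_pair(dapi_path, iba1_path, config: RunConfig) -> dict:
    import tifffile

    dapi = counting.ChannelImage(tifffile.imread(dapi_path), config.pixel_um, "DAPI")
    iba1 = counting.ChannelImage(tifffile.imread(iba1_path), config.pixel_um, "Iba1")
    res = counting.count_microglia(
        dapi, iba1, roi_um=config.roi_um, min_particle_px=config.min_particle_px
    )
    return {"kind": "image", "n_somata": res.n_somata, "density_per_mm2": res.density_per_mm2}


def analyze_plate_file(path: str | Path, config: RunConfig, fit_kind: str = "linear") -> dict:
    table = pd.read_csv(path)
    od = table["od"].to_numpy(dtype=float)
    if "od_ref" in table.columns:
        od = assays.correct_reference(od, table["od_ref"].to_numpy(dtype=float))
    std = table["role"] == "standard"
    n_std = int(std.sum())
    concs = assays.dilution_series(float(table.attrs.get("high_standard", 80.0)), n_std)
    curve = assays.fit_standard_curve(concs, od[std.to_numpy()], fit_kind=fit_kind)
    samples = [
        assays.invert_curve(curve, o, extrapolate=True)
        for o in od[(table["role"] == "sample").to_numpy()]
    ]
    return {"kind": "plate", "fit_kind": curve.fit_kind, "concentrations": samples}


def run_experiment(
    manifest: list[dict] | str | Path,
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, list[dict]]:
    """Dispatch every manifest entry and assemble the summary table.

    Manifest entries: ``{"kind": "lfp"|"ic"|"image"|"plate",
    "condition": str, "path": ..., [extra paths per kind]}``.
    Returns (summary per condition, per-record results).
    """
    if isinstance(manifest, (str, Path)):
        manifest = json.loads(Path(manifest).read_text())
    records = []
    cfg_hash = config.digest()
    for entry in manifest:
        kind = entry.get("kind")
        condition = entry.get("condition", "")
        if kind == "lfp":
            rec = analyze_lfp_file(entry["path"], config)
        elif kind == "ic":
            rec = analyze_ic_file(entry["path"], entry["protocol"], config)
        elif kind == "image":
            rec = analyze_image_pair(entry["dapi"], entry["iba1"], config)
        elif kind == "plate":
            rec = analyze_plate_file(entry["path"], config)
        else:
            raise ValueError(f"unknown manifest kind: {kind!r}")
        rec["condition"] = condition
        rec["config_hash"] = cfg_hash
        rec["input_checksum"] = _checksum(entry.get("path", entry.get("dapi")))
        records.append(rec)

    rows = []
    for condition in sorted({r["condition"] for r in records}):
        sub = [r for r in records if r["condition"] == condition]
        lfp = [r for r in sub if r["kind"] == "lfp"]
        img = [r for r in sub if r["kind"] == "image"]
        row: dict = {"condition": condition, "n_records": len(sub)}
        for state in STATES:
            row[f"n_{state}"] = sum(1 for r in lfp if r["state"] == state)
        gammas = [r for r in lfp if r["state"] == "Gamma"]
        row["median_peak_freq_hz"] = (
            float(np.median([r["peak_freq_hz"] for r in gammas])) if gammas else np.nan
        )
        row["median_peak_power_mv2_hz"] = (
            float(np.median([r["peak_power_mv2_hz"] for r in gammas])) if gammas else np.nan
        )
        row["mean_density_per_mm2"] = (
            float(np.mean([r["density_per_mm2"] for r in img])) if img else np.nan
        )
        row["config_hash"] = cfg_hash
        rows.append(row)
    summary = pd.DataFrame(rows)
    return summary, records


def activity_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Condition x state contingency counts from a summary table."""
    t = summary.set_index("condition")[[f"n_{s}" for s in STATES]]
    t.columns = list(STATES)
    return t


def compare_conditions(table: pd.DataFrame, state: str) -> pd.DataFrame:
    """Pairwise Fisher's exact tests of one state vs its absence.

    For each condition pair the table collapses to 2x2 (state vs
    not-state); raw per-pair p-values are reported, matching the
    per-pair testing of the original analysis (no correction).
    """
    if state not in table.columns:
        raise ValueError(f"state {state!r} not in table")
    if len(table) < 2:
        raise ValueError("need at least two conditions")
    conditions = list(table.index)
    rows = []
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            na, nb = int(table.loc[a].sum()), int(table.loc[b].sum())
            ka, kb = int(table.loc[a, state]), int(table.loc[b, state])
            t2 = np.array([[ka, na - ka], [kb, nb - kb]])
            if na == 0 or nb == 0:
                import warnings

                warnings.warn(f"degenerate margins for pair ({a}, {b}); p = 1")
                p = 1.0
            else:
                p = classify.fisher_exact_2x2(t2)
            rows.append({"condition_a": a, "condition_b": b, "state": state, "p_value": p})
    return pd.DataFrame(rows)
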