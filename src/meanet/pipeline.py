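"""Pipeline orchestration: simulate -> detect -> parameterize -> test -> barcode.

`run_pipeline` drives the whole analysis from a single config and writes
a deterministic output bundle of delimited-text tables plus a provenance
file (all configs + seed), so a rerun with the same config and seed is
reproducible row for row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bursts import BurstDetectionConfig, detect_bursts_recording, write_burst_table
from .model import MEALayout, Recording, read_spike_table, standard_layout, \
    write_spike_table
from .netparams import CorrelationConfig, PARAMETER_NAMES, compute_all
from .simulate import Trajectory, condition_preset, default_trajectory, \
    simulate_experiment
from .stats import BarcodeEntry, DegenerateDataError, barcode_matrix, \
    build_barcode, fishers_plsd, one_way_anova, GroupData, _cell_groups

__all__ = [
    "PipelineConfig",
    "parameter_table",
    "stats_report",
    "run_pipeline",
    "load_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, serialized into provenance."""

    conditions: tuple[str, ...] = ("control", "ntc", "dctn5_kd")
    n_cultures: int = 8
    divs: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 12)
    seed: int = 0
    burst: BurstDetectionConfig = field(default_factory=BurstDetectionConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    alpha: float = 0.05
    protected: bool = True
    epoch_duration: float = 900.0
    grid_rows: int = 8
    grid_cols: int = 8
    write_spike_tables: bool = False

    def layout(self) -> MEALayout:
        return standard_layout(self.grid_rows, self.grid_cols)

    def trajectory(self) -> Trajectory:
        return default_trajectory(self.layout(), self.epoch_duration)


def parameter_table(recordings: Sequence[Recording],
                    burst_config: BurstDetectionConfig = BurstDetectionConfig(),
                    correlation_config: CorrelationConfig = CorrelationConfig()
                    ) -> pd.DataFrame:
    """Long table: one row per recording, the seven parameters as columns."""
    rows = []
    for rec in recordings:
        params = compute_all(rec, burst_config, correlation_config)
        rows.append({"condition": rec.condition, "culture": rec.culture_id,
                     "div": rec.div, **params.as_dict()})
    return pd.DataFrame(rows)


def stats_report(table: pd.DataFrame, kd_condition: str, *,
                 ut_condition: str = "control", ntc_condition: str = "ntc",
                 alpha: float = 0.05, protected: bool = True) -> pd.DataFrame:
    """Per-(parameter, DIV) ANOVA/PLSD report with the barcode call."""
    conditions = (ut_condition, ntc_condition, kd_condition)
    entries = build_barcode(table, kd_condition, ut_condition=ut_condition,
                            ntc_condition=ntc_condition, alpha=alpha,
                            protected=protected)
    calls = {(e.parameter, e.div): e.call for e in entries}
    rows = []
    for parameter in PARAMETER_NAMES:
        for div in sorted(table["div"].unique()):
            groups = _cell_groups(table, parameter, div, conditions)
            row = {"parameter": parameter, "div": div, "F": None, "df_between": None,
                   "df_within": None, "p": None, "p_kd_vs_ut": None,
                   "p_kd_vs_ntc": None, "p_ut_vs_ntc": None,
                   "call": calls[(parameter, div)]}
            if groups.testable():
                try:
                    anova = one_way_anova(groups)
                except DegenerateDataError:
                    pass
                else:
                    plsd = fishers_plsd(groups, anova, alpha)
                    row.update(F=anova.F, df_between=anova.df_between,
                               df_within=anova.df_within, p=anova.p,
                               p_kd_vs_ut=plsd.p(kd_condition, ut_condition),
                               p_kd_vs_ntc=plsd.p(kd_condition, ntc_condition),
                               p_ut_vs_ntc=plsd.p(ut_condition, ntc_condition))
            rows.append(row)
    return pd.DataFrame(rows)


def load_experiment(manifest_path: str | Path, layout: MEALayout,
                    epoch_duration: float) -> list[Recording]:
    """Load recordings listed in a manifest (condition, culture, div, file)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"empty manifest: {manifest_path}")
    recordings = []
    for row in manifest.itertuples():
        path = manifest_path.parent / str(row.file)
        if not path.exists():
            raise FileNotFoundError(f"missing spike table: {path}")
        recordings.append(read_spike_table(
            str(path), layout, epoch_duration, div=int(row.div),
            condition=str(row.condition), culture_id=str(row.culture)))
    return recordings


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulate -> detect -> parameterize -> test -> barcode
    pipeline and write the output bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    recordings = simulate_experiment(list(config.conditions), config.n_cultures,
                                     list(config.divs), config.trajectory(),
                                     seed=config.seed)
    logger.info("simulated %d recordings", len(recordings))

    if config.write_spike_tables:
        spikes_dir = outdir / "spike_tables"
        spikes_dir.mkdir(exist_ok=True)
        manifest_rows = []
        for rec in recordings:
            name = f"{rec.condition}_{rec.culture_id}_div{rec.div}.csv"
            write_spike_table(rec, str(spikes_dir / name))
            manifest_rows.append({"condition": rec.condition,
                                  "culture": rec.culture_id, "div": rec.div,
                                  "file": f"spike_tables/{name}"})
        manifest = outdir / "manifest.csv"
        pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
        written["manifest"] = manifest

    burst_rows = []
    for rec in recordings:
        bursts = detect_bursts_recording(rec, config.burst)
        for eid in rec.layout.electrode_ids:
            for b in bursts[eid]:
                burst_rows.append({"condition": rec.condition,
                                   "culture": rec.culture_id, "div": rec.div,
                                   "electrode_id": eid, "start_s": b.start,
                                   "end_s": b.end, "n_spikes": b.n_spikes})
    bursts_path = outdir / "bursts.csv"
    pd.DataFrame(burst_rows).to_csv(bursts_path, index=False,
                                    float_format="%.6f")
    written["bursts"] = bursts_path

    table = parameter_table(recordings, config.burst, config.correlation)
    params_path = outdir / "network_parameters.csv"
    table.to_csv(params_path, index=False)
    written["parameters"] = params_path

    kd_conditions = [c for c in config.conditions if c not in ("control", "ntc")]
    for kd in kd_conditions:
        report = stats_report(table, kd, alpha=config.alpha,
                              protected=config.protected)
        stats_path = outdir / f"stats_{kd}.csv"
        report.to_csv(stats_path, index=False)
        written[f"stats_{kd}"] = stats_path
        entries = build_barcode(table, kd, alpha=config.alpha,
                                protected=config.protected)
        barcode_path = outdir / f"barcode_{kd}.csv"
        barcode_matrix(entries).to_csv(barcode_path)
        written[f"barcode_{kd}"] = barcode_path

    provenance = {
        "meanet_version": __version__,
        "seed": config.seed,
        "config": _as_jsonable(config),
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    written["provenance"] = prov_path
    return written


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
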