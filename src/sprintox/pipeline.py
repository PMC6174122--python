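"""Pipeline orchestration: generate -> process -> summarize -> infer.

Thin, deterministic glue over the library modules: generates (or loads) a
study, produces the per-test performance / neuromuscular / NIRS summary
tables, then runs the mixed-model inference over the resulting endpoint
tables.  All outputs are tidy CSVs; a fixed seed makes the whole chain
byte-identical between runs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ChannelTrace, SprintTimeline
from . import nirs as nirs_mod
from . import performance as perf_mod
from . import neuromuscular as nm_mod
from . import inference as inf_mod
from .synthetic import (ProtocolConfig, StudyDataset, NirsTraces,
                        NeuromuscularRecording, generate_study, write_study,
                        GroundTruth, TestRecord)

__all__ = ["RunConfig", "run_generate", "run_analyze", "run_report",
           "run_selftest", "read_study"]

CSV_FLOAT_FORMAT = "%.8g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run; YAML-serializable, seed-determined."""

    seed: int = 42
    n_participants: int = 11
    output_dir: str = "results"
    effects: dict = field(default_factory=dict)
    filter_cutoff_hz: float = 0.2
    detect_sprints_from_signal: bool = True
    skip_stats: bool = False
    protocol: dict = field(default_factory=dict)

    def make_protocol(self) -> ProtocolConfig:
        return ProtocolConfig(**self.protocol)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_generate(config: RunConfig, write: bool = True) -> StudyDataset:
    """Generate the synthetic study; optionally write it to disk with a
    provenance record (config hash + seed, no timestamps)."""
    dataset = generate_study(config.make_protocol(), config.n_participants,
                             effects=config.effects or None, seed=config.seed)
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_study(dataset, out / "dataset")
        (out / "provenance.json").write_text(json.dumps(
            {"seed": config.seed, "config_hash": config.config_hash(),
             "n_participants": config.n_participants}, indent=1, sort_keys=True))
    return dataset


# ---------------------------------------------------------------------------
# loading a written study
# ---------------------------------------------------------------------------

def _read_channel(path: Path, fs: float, channel: str, site: str = "",
                  units: str = "") -> ChannelTrace:
    df = pd.read_csv(path)
    return ChannelTrace(df["value"].to_numpy(), fs=fs, channel=channel,
                        site=site, units=units,
                        start_time=float(df["time_s"].iloc[0]))


def read_study(dataset_dir: str | Path,
               protocol: ProtocolConfig | None = None) -> StudyDataset:
    """Reconstruct a StudyDataset from the tidy-CSV layout of write_study."""
    protocol = protocol or ProtocolConfig()
    root = Path(dataset_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    records, truth = [], GroundTruth()
    for (pid, cond), _ in manifest.groupby(["participant", "condition"]):
        d = root / f"{pid}_c{cond}"
        side = json.loads((d / "sidecar.json").read_text())
        timeline = SprintTimeline(
            starts=np.array(side["timeline"]["starts"]),
            ends=np.array(side["timeline"]["ends"]),
            recovery_duration_s=protocol.recovery_duration_s)
        gt = {k: (np.array(v) if isinstance(v, list) else v)
              for k, v in side["ground_truth"].items()}
        truth.entries[(pid, int(cond))] = gt

        def ch(name, fs, site="", units=""):
            return _read_channel(d / f"{name}.csv", fs, name, site, units)

        def nirs_site(prefix, site):
            return NirsTraces(
                o2hb=ch(f"{prefix}_o2hb", protocol.fs_nirs, site, "uM"),
                hhb=ch(f"{prefix}_hhb", protocol.fs_nirs, site, "uM"),
                tsi=ch(f"{prefix}_tsi", protocol.fs_nirs, site, "%"),
                clean={}, true_deltas={}, true_tsi_max=np.empty(0),
                timeline=timeline)

        breaths = pd.read_csv(d / "vo2_breaths.csv")
        records.append(TestRecord(
            participant=pid, condition=int(cond), timeline=timeline,
            power=ch("power", protocol.fs_power, units="W"),
            cadence=ch("cadence", protocol.fs_power, units="rpm"),
            nirs_muscle=nirs_site("muscle", "vastus_lateralis"),
            nirs_cerebral=nirs_site("cerebral", "prefrontal_cortex"),
            hr=ch("hr", protocol.fs_hr, units="bpm"),
            spo2=ch("spo2", protocol.fs_spo2, units="%"),
            breath_times=breaths["time_s"].to_numpy(),
            breath_vo2=breaths["value"].to_numpy(),
            scalars=side["scalars"],
            nm_pre=NeuromuscularRecording(
                force=ch("force_pre", protocol.fs_force, units="N"),
                emg=ch("emg_pre", protocol.fs_emg, units="mV"),
                markers=side["markers_pre"], truth={}),
            nm_post=NeuromuscularRecording(
                force=ch("force_post", protocol.fs_force, units="N"),
                emg=ch("emg_post", protocol.fs_emg, units="mV"),
                markers=side["markers_post"], truth={})))
    return StudyDataset(protocol=protocol, records=records,
                        ground_truth=truth, seed=-1)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _nirs_rows(rec, summary: "nirs_mod.NirsSprintSummary", site_label: str):
    sprint_rows, norm_rows = [], []
    if not summary.deltas or next(iter(summary.deltas.values())).size == 0:
        return sprint_rows, norm_rows
    base = {"participant": rec.participant, "condition": rec.condition,
            "site": site_label}
    n = next(iter(summary.deltas.values())).size
    for k in range(n):
        row = dict(base, sprint=k + 1, tsi_max=summary.tsi_max[k])
        for c, d in summary.deltas.items():
            row[f"delta_{c}"] = d[k]
        sprint_rows.append(row)
    for meas, vals in summary.normalized.items():
        for f, v in zip(summary.fractions, vals):
            norm_rows.append(dict(base, measure=meas, fraction=f, value=v))
    return sprint_rows, norm_rows


def run_analyze(config: RunConfig, dataset: StudyDataset | str | Path,
                write: bool = True) -> dict[str, pd.DataFrame]:
    """Process every test and, unless disabled, run the group inference.

    Returns (and writes) the summary tables: Table-1-style performance rows,
    Table-2-style neuromuscular rows, per-sprint NIRS deltas, set-duration
    normalized NIRS values, effects (LRT per endpoint and factor), Tukey
    contrasts, and per-subject percent changes versus the 0 % condition.
    """
    if not isinstance(dataset, StudyDataset):
        dataset = read_study(dataset, config.make_protocol())

    issues: list[dict] = []
    perf_rows, nm_rows, nirs_sprint_rows, nirs_norm_rows = [], [], [], []
    for rec in dataset.records:
        perf = perf_mod.summarize_performance(
            rec.power, rec.timeline, cadence=rec.cadence,
            breath_times=rec.breath_times, breath_vo2=rec.breath_vo2,
            hr=rec.hr, spo2=rec.spo2, scalars=rec.scalars)
        perf_rows.append({"participant": rec.participant,
                          "condition": rec.condition, **perf.to_row()})

        for phase, nm in (("pre", rec.nm_pre), ("post", rec.nm_post)):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                ass = nm_mod.analyze_assessment(nm.force, nm.emg, nm.markers,
                                                phase=phase)
            for w in caught:
                issues.append({"participant": rec.participant,
                               "condition": rec.condition, "stage": f"nm_{phase}",
                               "message": str(w.message)})
            nm_rows.append({"participant": rec.participant,
                            "condition": rec.condition, **ass.to_row()})

        for site_label, bundle in (("muscle", rec.nirs_muscle),
                                   ("cerebral", rec.nirs_cerebral)):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    summary = nirs_mod.summarize_nirs(
                        bundle.o2hb, bundle.hhb, bundle.tsi,
                        timeline_hint=rec.timeline,
                        cutoff=config.filter_cutoff_hz,
                        detect_from_signal=config.detect_sprints_from_signal)
                except ValueError as err:
                    issues.append({"participant": rec.participant,
                                   "condition": rec.condition,
                                   "stage": f"nirs_{site_label}",
                                   "message": str(err)})
                    continue
            for w in caught:
                issues.append({"participant": rec.participant,
                               "condition": rec.condition,
                               "stage": f"nirs_{site_label}",
                               "message": str(w.message)})
            s_rows, n_rows = _nirs_rows(rec, summary, site_label)
            if not s_rows:
                issues.append({"participant": rec.participant,
                               "condition": rec.condition,
                               "stage": f"nirs_{site_label}",
                               "message": "no sprints detected; test skipped"})
            nirs_sprint_rows += s_rows
            nirs_norm_rows += n_rows

    tables = {
        "performance_summary": pd.DataFrame(perf_rows),
        "neuromuscular_summary": pd.DataFrame(nm_rows),
        "nirs_sprint_deltas": pd.DataFrame(nirs_sprint_rows),
        "nirs_normalized": pd.DataFrame(nirs_norm_rows),
    }

    if not config.skip_stats:
        effects, contrasts = _run_inference(tables)
        tables["effects"] = effects
        tables["contrasts"] = contrasts
        pct_frames = []
        for ep in ("n_sprints", "total_work_kJ", "vo2_Lmin"):
            pct = inf_mod.percent_change_summary(
                tables["performance_summary"].rename(columns={ep: "value"}),
                value_col="value")
            pct.insert(0, "endpoint", ep)
            pct_frames.append(pct)
        tables["percent_changes"] = pd.concat(pct_frames, ignore_index=True)

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False,
                      float_format=CSV_FLOAT_FORMAT)
        (out / "warnings.json").write_text(json.dumps(issues, indent=1,
                                                      sort_keys=True))
    return tables


def _run_inference(tables: dict[str, pd.DataFrame]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    effect_rows, contrast_rows = [], []

    def record(endpoint, table, fixed, factors_to_test):
        for eff in factors_to_test:
            try:
                res = inf_mod.test_effect(table, eff, fixed=fixed)
            except Exception as err:  # singular designs in degenerate inputs
                effect_rows.append({"endpoint": endpoint, "effect": eff,
                                    "statistic": np.nan, "df": np.nan,
                                    "p": np.nan, "note": str(err)})
                continue
            effect_rows.append({"endpoint": endpoint, "effect": eff,
                                "statistic": res.statistic, "df": res.df,
                                "p": res.p_value,
                                "significant_at_0.05": res.p_value < 0.05})
        if len(fixed) > 1:
            full = inf_mod.fit_mixed_model(table, fixed=fixed, interaction=True)
            add = inf_mod.fit_mixed_model(table, fixed=fixed, interaction=False)
            res = inf_mod.lrt_effect(full, add)
            effect_rows.append({"endpoint": endpoint,
                                "effect": ":".join(fixed),
                                "statistic": res.statistic, "df": res.df,
                                "p": res.p_value,
                                "significant_at_0.05": res.p_value < 0.05})
        fit = inf_mod.fit_mixed_model(table, fixed=fixed,
                                      interaction=len(fixed) > 1)
        con = inf_mod.tukey_contrasts(fit, fixed[0])
        con.insert(0, "endpoint", endpoint)
        con.attrs = {}  # drop the ls_means attachment before concatenation
        contrast_rows.append(con)

    perf = tables["performance_summary"]
    for ep in ("n_sprints", "mean_power_W", "fatigue_index_pct",
               "total_work_kJ", "hr_max_bpm", "spo2_pct", "vo2_Lmin",
               "lactate", "rpe_legs", "rpe_breathing", "ve", "rr", "rer"):
        if ep not in perf.columns:
            continue
        t = perf[["participant", "condition", ep]].rename(columns={ep: "value"})
        record(ep, t, ["condition"], ["condition"])

    nm = tables["neuromuscular_summary"]
    for ep in ("mvc_N", "val_pct", "p10_p100", "rms_mwave"):
        t = nm[["participant", "condition", "phase", ep]].rename(
            columns={ep: "value"})
        record(ep, t, ["condition", "phase"], ["condition", "phase"])

    norm = tables["nirs_normalized"]
    if len(norm):
        for site in norm["site"].unique():
            for meas in norm["measure"].unique():
                t = norm[(norm.site == site) & (norm.measure == meas)][
                    ["participant", "condition", "fraction", "value"]]
                if t["participant"].nunique() < 2:
                    continue
                record(f"{site}_{meas}", t, ["condition", "fraction"],
                       ["condition", "fraction"])

    effects = pd.DataFrame(effect_rows)
    contrasts = (pd.concat(contrast_rows, ignore_index=True)
                 if contrast_rows else pd.DataFrame())
    return effects, contrasts


def run_report(config: RunConfig) -> str:
    """Human-readable digest of the tables a previous analyze run wrote."""
    out = Path(config.output_dir)
    lines = []
    for name in ("performance_summary", "neuromuscular_summary",
                 "percent_changes", "effects"):
        path = out / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        lines.append(f"== {name} ({len(df)} rows) ==")
        if name == "performance_summary":
            g = df.groupby("condition")[["n_sprints", "mean_power_W",
                                         "fatigue_index_pct", "total_work_kJ"]]
            lines.append(g.mean().round(2).to_string())
        elif name == "neuromuscular_summary":
            g = df.groupby(["condition", "phase"])[["mvc_N", "val_pct",
                                                    "p10_p100", "rms_mwave"]]
            lines.append(g.mean().round(3).to_string())
        else:
            lines.append(df.round(4).to_string(index=False))
        lines.append("")
    return "\n".join(lines)


def run_selftest(verbose: bool = True) -> bool:
    """Fast internal consistency checks of the full chain."""
    from .synthetic import generate_power_profile, generate_neuromuscular_traces
    checks = []

    trace, tl = generate_power_profile(4, 600.0, 0.1, 0.0, seed=0)
    means, _ = perf_mod.per_sprint_power(trace, tl)
    checks.append(("geometric sprint means recovered",
                   np.allclose(means, 600.0 * 0.9 ** np.arange(4), atol=1e-6)))
    checks.append(("S_dec matches closed form",
                   abs(perf_mod.fatigue_index(means)
                       - (1 - np.mean(0.9 ** np.arange(4))) * 100) < 1e-9))

    const = ChannelTrace(np.full(600, 7.5), fs=10.0)
    checks.append(("filter DC gain is 1",
                   np.allclose(nirs_mod.lowpass_zero_phase(const).values, 7.5)))
    checks.append(("set-duration normalization identity at n=5",
                   np.allclose(nirs_mod.normalize_set_duration([10, 9, 8, 7, 6]),
                               [10, 9, 8, 7, 6])))

    rec = generate_neuromuscular_traces(300.0, 85.0, 60.0, 54.0, 30.0)
    ass = nm_mod.analyze_assessment(rec.force, rec.emg, rec.markers)
    checks.append(("VAL round trip", abs(ass.val - 85.0) < 0.1))
    checks.append(("P10/P100 round trip", abs(ass.p10_p100 - 0.9) < 1e-3))

    cfg = RunConfig(seed=7, n_participants=2, skip_stats=True,
                    output_dir="unused")
    d1 = run_generate(cfg, write=False)
    d2 = run_generate(cfg, write=False)
    checks.append(("determinism under fixed seed",
                   np.array_equal(d1.records[0].power.values,
                                  d2.records[0].power.values)))

    ok = all(flag for _, flag in checks)
    if verbose:
        for name, flag in checks:
            print(f"[{'ok' if flag else 'FAIL'}] {name}")
    return ok
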