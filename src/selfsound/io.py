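"""Session tables, configuration and the end-to-end analysis report.

All on-disk formats are delimited text with headers, one directory per
session: ``units.csv`` (unit_id, animal_id, genotype, depth_um),
``spikes.csv`` (unit_id, time_s), ``events.csv`` (time_s, event_type,
duration_s) and ``waveforms.csv`` (unit_id, sample_index, amplitude).
Times are seconds, depths micrometres, rates Hz; genotype labels are
``WT`` and ``DF16A``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import celltypes, evoked, modulation, opto
from .events import SelectionConfig, select_preparatory_presses, select_sounds, split_blocks
from .types import EventLog, UnitRecord

logger = logging.getLogger("selfsound")

GENOTYPES = ("WT", "DF16A")
FLOAT_FMT = "%.6f"


def fraction_percent(count: int, total: int) -> float:
    """Percentage at the report's printed precision (two decimals)."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 2)


def format_fraction(count: int, total: int) -> str:
    return f"{fraction_percent(count, total):.2f}% ({count}/{total})"


# ---------------------------------------------------------------------------
# tables


def write_session(path: Path, units: Sequence[UnitRecord], log: EventLog) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "animal_id": u.animal_id,
                "genotype": u.genotype,
                "depth_um": u.depth_um,
            }
            for u in units
        ]
    ).to_csv(path / "units.csv", index=False, float_format=FLOAT_FMT)
    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate([[u.unit_id] * len(u.spike_times) for u in units])
            if units
            else [],
            "time_s": np.concatenate([u.spike_times for u in units]) if units else [],
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False, float_format=FLOAT_FMT)
    log.to_frame().to_csv(path / "events.csv", index=False, float_format=FLOAT_FMT)
    wf_rows = []
    for u in units:
        if u.waveform is not None:
            wf_rows.append(
                pd.DataFrame(
                    {
                        "unit_id": u.unit_id,
                        "sample_index": np.arange(len(u.waveform)),
                        "amplitude": u.waveform,
                    }
                )
            )
    (pd.concat(wf_rows, ignore_index=True) if wf_rows else pd.DataFrame(
        columns=["unit_id", "sample_index", "amplitude"]
    )).to_csv(path / "waveforms.csv", index=False, float_format=FLOAT_FMT)


def _require_columns(frame: pd.DataFrame, cols: set[str], name: str) -> None:
    missing = cols - set(frame.columns)
    if missing:
        raise ValueError(f"{name} is missing columns: {sorted(missing)}")


def read_session(path: Path, fs: float = 30000.0) -> tuple[list[UnitRecord], EventLog]:
    """Load and validate one session directory.

    Hard errors: missing columns, unsorted event times (reported with the
    first offending row) and spikes referencing unknown unit ids.
    """
    path = Path(path)
    units_df = pd.read_csv(path / "units.csv")
    spikes_df = pd.read_csv(path / "spikes.csv")
    events_df = pd.read_csv(path / "events.csv")
    _require_columns(units_df, {"unit_id", "animal_id", "genotype", "depth_um"}, "units.csv")
    _require_columns(spikes_df, {"unit_id", "time_s"}, "spikes.csv")
    _require_columns(events_df, {"time_s", "event_type", "duration_s"}, "events.csv")

    known = set(units_df["unit_id"])
    orphans = set(spikes_df["unit_id"]) - known
    if orphans:
        raise ValueError(f"spikes.csv references unknown unit_id(s): {sorted(orphans)[:5]}")

    log = EventLog.from_frame(events_df)  # raises with row number if unsorted

    wf_path = path / "waveforms.csv"
    waveforms: dict[str, np.ndarray] = {}
    if wf_path.exists():
        wf_df = pd.read_csv(wf_path)
        if len(wf_df):
            _require_columns(wf_df, {"unit_id", "sample_index", "amplitude"}, "waveforms.csv")
            for uid, grp in wf_df.groupby("unit_id"):
                waveforms[uid] = grp.sort_values("sample_index")["amplitude"].to_numpy()

    by_unit = {uid: grp["time_s"].to_numpy() for uid, grp in spikes_df.groupby("unit_id")}
    units = []
    for row in units_df.itertuples():
        st = np.sort(by_unit.get(row.unit_id, np.empty(0)))
        units.append(
            UnitRecord(
                unit_id=str(row.unit_id),
                animal_id=str(row.animal_id),
                genotype=str(row.genotype),
                depth_um=float(row.depth_um),
                spike_times=st,
                waveform=waveforms.get(row.unit_id),
                fs=fs,
            )
        )
    return units, log


def write_cohort(root: Path, sessions: dict[str, tuple[list[UnitRecord], EventLog]]) -> None:
    for animal_id, (units, log) in sessions.items():
        write_session(Path(root) / animal_id, units, log)


def read_cohort(root: Path) -> dict[str, tuple[list[UnitRecord], EventLog]]:
    root = Path(root)
    out = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if (sub / "units.csv").exists():
            out[sub.name] = read_session(sub)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Toggles and parameters for a full analysis run."""

    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    min_trials_per_class: int = 10  # below this a unit is skipped
    run_modulation: bool = True
    run_blocks: bool = True
    run_depth: bool = True
    run_celltype: bool = True
    run_preparatory: bool = True
    alpha: float = 0.05
    bootstrap_reps: int = 1000

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("configuration file must set a seed")
        sel = SelectionConfig(**raw.pop("selection", {}))
        return cls(selection=sel, **raw)


def _config_hash(cfg: RunConfig) -> str:
    text = json.dumps(
        {**cfg.__dict__, "selection": cfg.selection.__dict__}, sort_keys=True, default=str
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# full analysis


def unit_table(
    sessions: dict[str, tuple[list[UnitRecord], EventLog]],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Per-unit profile + modulation table across sessions."""
    rows = []
    for animal_id, (units, log) in sessions.items():
        self_t, rand_t = select_sounds(log, cfg.selection)
        if min(len(self_t), len(rand_t)) < cfg.min_trials_per_class:
            logger.warning("session %s: too few retained sounds; units skipped", animal_id)
            continue
        for u in units:
            prof = evoked.compute_profile(u.unit_id, u.spike_times, self_t, rand_t)
            res = modulation.analyze_unit(prof, alpha=cfg.alpha)
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "animal_id": u.animal_id,
                    "genotype": u.genotype,
                    "depth_um": u.depth_um,
                    "baseline_mean": prof.baseline_mean,
                    "baseline_sd": prof.baseline_sd,
                    "amp_random": prof.amp_random,
                    "amp_self": prof.amp_self,
                    "z_random": prof.z_random,
                    "z_self": prof.z_self,
                    "is_responsive": prof.is_responsive,
                    "n_trials_random": prof.n_trials_random,
                    "n_trials_self": prof.n_trials_self,
                    "mi": res.mi,
                    "sig_class": res.sig_class,
                    "mi_flagged": res.flagged,
                    "depth_bin": modulation.depth_bin_label(u.depth_um),
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(
    sessions_by_genotype: dict[str, dict[str, tuple[list[UnitRecord], EventLog]]],
    cfg: Optional[RunConfig] = None,
) -> dict:
    """Run every enabled stage and assemble the summary report.

    A failing stage is recorded as failed and the others proceed.
    """
    cfg = cfg or RunConfig()
    report: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    all_sessions: dict[str, tuple[list[UnitRecord], EventLog]] = {}
    for geno, sess in sessions_by_genotype.items():
        all_sessions.update(sess)
    if not all_sessions:
        report["stages"]["all"] = "skipped: no sessions"
        return report

    try:
        table = unit_table(all_sessions, cfg)
        report["stages"]["profiles"] = "ok"
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        logger.exception("profile stage failed")
        report["stages"]["profiles"] = f"failed: {exc}"
        return report

    if len(table) == 0:
        report["stages"]["profiles"] = "skipped: no analyzable units"
        return report

    genos = sorted(table["genotype"].unique())
    resp = table[table["is_responsive"]]
    report["responsiveness"] = {
        g: {
            "n_total": int((table["genotype"] == g).sum()),
            "n_responsive": int((resp["genotype"] == g).sum()),
            "percent_responsive": fraction_percent(
                int((resp["genotype"] == g).sum()), int((table["genotype"] == g).sum())
            ),
        }
        for g in genos
    }

    if cfg.run_modulation:
        try:
            mod: dict = {}
            for g in genos:
                sub = resp[resp["genotype"] == g]
                n = len(sub)
                mod[g] = {
                    "n": n,
                    "percent_attenuated": fraction_percent(int((sub["sig_class"] == "attenuated").sum()), n),
                    "percent_enhanced": fraction_percent(int((sub["sig_class"] == "enhanced").sum()), n),
                    "n_flagged_mi": int(sub["mi_flagged"].sum()),
                }
            if len(genos) == 2:
                mod["contrast"] = modulation.genotype_summary(
                    resp[["mi", "genotype", "animal_id"]], seed=cfg.seed, n_reps=cfg.bootstrap_reps
                )
            report["modulation"] = mod
            report["stages"]["modulation"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.exception("modulation stage failed")
            report["stages"]["modulation"] = f"failed: {exc}"

    if cfg.run_depth:
        try:
            report["depth_profile"] = {
                g: modulation.depth_profile(
                    resp[resp["genotype"] == g]["mi"].to_numpy(),
                    resp[resp["genotype"] == g]["depth_um"].to_numpy(),
                ).to_dict(orient="records")
                for g in genos
            }
            report["stages"]["depth"] = "ok"
        except Exception as exc:  # noqa: BLE001
            report["stages"]["depth"] = f"failed: {exc}"

    if cfg.run_celltype:
        try:
            units_flat = [u for units, _ in all_sessions.values() for u in units]
            if any(u.waveform is not None for u in units_flat):
                ct = celltypes.classify_units(units_flat, random_state=cfg.seed)
                counts = ct["cell_class"].value_counts()
                n_units = len(ct)
                n_classified = int((ct["cell_class"] != "unclassified").sum())
                report["cell_types"] = {
                    "n_units": n_units,
                    "percent_classified": fraction_percent(n_classified, n_units),
                    "percent_pin_of_classified": fraction_percent(
                        int(counts.get("pIN", 0)), n_classified
                    ),
                }
                report["stages"]["celltype"] = "ok"
            else:
                report["stages"]["celltype"] = "skipped: no waveforms"
        except Exception as exc:  # noqa: BLE001
            report["stages"]["celltype"] = f"failed: {exc}"

    if cfg.run_blocks:
        try:
            blocks_out: dict = {}
            for g in genos:
                mi_e, mi_l, n_sessions = [], [], 0
                for animal_id, (units, log) in sessions_by_genotype.get(g, {}).items():
                    split = split_blocks(log, cfg.selection)
                    if split.excluded:
                        continue
                    n_sessions += 1
                    for u in units:
                        e, l = modulation.block_modulation(u.spike_times, split)
                        if np.isfinite(e) and np.isfinite(l):
                            mi_e.append(e)
                            mi_l.append(l)
                blocks_out[g] = {
                    "n_sessions": n_sessions,
                    "n_units": len(mi_e),
                    "mean_mi_early": float(np.mean(mi_e)) if mi_e else np.nan,
                    "mean_mi_late": float(np.mean(mi_l)) if mi_l else np.nan,
                }
            report["blocks"] = blocks_out
            report["stages"]["blocks"] = "ok"
        except Exception as exc:  # noqa: BLE001
            report["stages"]["blocks"] = f"failed: {exc}"

    if cfg.run_preparatory:
        try:
            prep: dict = {}
            for g in genos:
                deltas = []
                for animal_id, (units, log) in sessions_by_genotype.get(g, {}).items():
                    presses = select_preparatory_presses(log, cfg.selection)
                    if len(presses) < cfg.min_trials_per_class:
                        continue
                    for u in units:
                        _, summary = evoked.preparatory_activity(u.spike_times, presses)
                        deltas.append(summary)
                prep[g] = {
                    "n_units": len(deltas),
                    "mean_delta_hz": float(np.mean(deltas)) if deltas else np.nan,
                    "sem_delta_hz": float(np.std(deltas, ddof=1) / np.sqrt(len(deltas)))
                    if len(deltas) > 1
                    else np.nan,
                }
            report["preparatory"] = prep
            report["stages"]["preparatory"] = "ok"
        except Exception as exc:  # noqa: BLE001
            report["stages"]["preparatory"] = f"failed: {exc}"

    return report


def analyze_opto_cohort(
    sessions: dict[str, tuple[list[UnitRecord], EventLog]],
    mode: str = "terminal",
    n_surrogates: int = 1000,
    seed: int = 0,
) -> dict:
    """Opto labels and layer fractions across sessions."""
    tables = []
    for i, (animal_id, (units, log)) in enumerate(sorted(sessions.items())):
        lights = log.of_type("light_on")
        tables.append(
            opto.analyze_opto_session(
                units,
                lights,
                duration=log.session_duration,
                mode=mode,
                n_surrogates=n_surrogates,
                seed=seed + 1000 * i,
            )
        )
    table = pd.concat(tables, ignore_index=True)
    return {
        "n_units": len(table),
        "n_excitatory": int((table["label"] == "excitatory_short_latency").sum()),
        "n_inhibitory": int((table["label"] == "inhibitory").sum()),
        "fractions_by_layer": opto.population_fractions(
            table["label"].to_numpy(), table["depth_um"].to_numpy()
        ),
        "table": table,
    }


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return None if np.isnan(obj) else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_report(report: dict, path: Path) -> None:
    """Deterministic JSON: keys sorted, floats at fixed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clean = _round_floats({k: v for k, v in report.items() if k != "table"})
    with open(path, "w") as fh:
        json.dump(clean, fh, sort_keys=True, indent=2)
        fh.write("\n")
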