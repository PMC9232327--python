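"""Run configuration and pipeline orchestration: simulate → analyze → report.

``simulate`` writes a synthetic cohort file set (trajectory/EMG/MVIC CSVs plus
a JSON manifest echoing the configuration).  ``analyze`` runs kinematics and
EMG per subject and combination, then the two-group statistics, writing
per-subject metrics CSVs and group-level stats CSVs.  ``report`` renders the
stats CSVs as a deterministic markdown report (no value is computed at render
time).  A failing subject file never aborts the run: the subject is skipped
for that stage and the problem is recorded in the analysis manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import emg as emg_mod
from . import io as io_mod
from . import kinematics as kin
from . import stats as stats_mod
from .errors import ConfigurationError, InvalidArgumentError
from .synthetic import CHANNELS, COMBO_BEATS, ArmGeometry, CohortConfig, generate_cohort

__all__ = [
    "KinematicsOptions",
    "EMGOptions",
    "StatsOptions",
    "RunConfig",
    "simulate",
    "analyze",
    "report",
]

PLANES = ("XY", "XZ", "YZ", "3D")


@dataclasses.dataclass(frozen=True)
class KinematicsOptions:
    zero_speed_threshold: float = 1e-3  # m/s, braking endpoint detection
    smoothing_window: int = 0  # frames; 0 disables position smoothing


@dataclasses.dataclass(frozen=True)
class EMGOptions:
    filter_enabled: bool = False  # synthetic carrier is already band-limited
    band: tuple[float, float] = (20.0, 450.0)
    mvic_window_s: float = 1.0
    iemg_rule: str = "left"


@dataclasses.dataclass(frozen=True)
class StatsOptions:
    t_variant: str = "student"
    grade_bands: stats_mod.GradeBands = dataclasses.field(
        default_factory=stats_mod.GradeBands
    )
    holm: bool = False


@dataclasses.dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    kinematics: KinematicsOptions = dataclasses.field(default_factory=KinematicsOptions)
    emg: EMGOptions = dataclasses.field(default_factory=EMGOptions)
    stats: StatsOptions = dataclasses.field(default_factory=StatsOptions)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        cohort_d = dict(d.get("cohort", {}))
        if "geometry" in cohort_d:
            geo = dict(cohort_d["geometry"])
            if "chest_cross_offset_m" in geo:
                geo["chest_cross_offset_m"] = tuple(geo["chest_cross_offset_m"])
            cohort_d["geometry"] = ArmGeometry(**geo)
        if "emg_carrier_band" in cohort_d:
            cohort_d["emg_carrier_band"] = tuple(cohort_d["emg_carrier_band"])
        emg_d = dict(d.get("emg", {}))
        if "band" in emg_d:
            emg_d["band"] = tuple(emg_d["band"])
        stats_d = dict(d.get("stats", {}))
        if "grade_bands" in stats_d:
            stats_d["grade_bands"] = stats_mod.GradeBands(**stats_d["grade_bands"])
        return cls(
            cohort=CohortConfig(**cohort_d),
            kinematics=KinematicsOptions(**dict(d.get("kinematics", {}))),
            emg=EMGOptions(**emg_d),
            stats=StatsOptions(**stats_d),
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_json(path: Path, obj: Mapping[str, Any]) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x: Any) -> Any:
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# simulate


def simulate(config: RunConfig, out_dir: Path | str) -> Path:
    """Generate and write the synthetic cohort file set; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_cohort(config.cohort)
    files: dict[str, str] = {}
    for profile in bundle.profiles:
        sid = profile.subject_id
        mvic_name = f"{sid}_mvic.csv"
        io_mod.write_mvic_csv(out / mvic_name, bundle.mvic[sid])
        files[f"{sid}:mvic"] = mvic_name
        for combo in (1, 2):
            tname = f"{sid}_combo{combo}_trajectory.csv"
            ename = f"{sid}_combo{combo}_emg.csv"
            io_mod.write_trajectory_csv(out / tname, bundle.motion[(sid, combo)])
            io_mod.write_emg_csv(out / ename, bundle.emg[(sid, combo)])
            files[f"{sid}:combo{combo}:trajectory"] = tname
            files[f"{sid}:combo{combo}:emg"] = ename
    manifest = {
        "software_version": __version__,
        "seed": config.cohort.seed,
        "config": config.to_dict(),
        "combos": {str(c): n for c, n in COMBO_BEATS.items()},
        "subjects": [
            {
                "subject_id": p.subject_id,
                "group": p.group,
                "height_m": p.height,
                "handedness": p.handedness,
            }
            for p in bundle.profiles
        ],
        "files": files,
        "warnings": [],
    }
    path = out / "manifest.json"
    _write_json(path, manifest)
    return path


# ---------------------------------------------------------------------------
# analyze


def _braking_rows(
    trial_hands: Mapping[str, kin.TrajectorySeries],
    tempo: float,
    n_beats: int,
    opts: KinematicsOptions,
    warnings: list[str],
    context: str,
) -> tuple[list[dict[str, Any]], dict[int, dict[str, list[float]]]]:
    """Per-hand braking rows plus per-beat values for hand averaging."""
    rows: list[dict[str, Any]] = []
    per_beat: dict[int, dict[str, list[float]]] = {}
    for side, traj in sorted(trial_hands.items()):
        smoothed = kin.smooth_positions(traj, opts.smoothing_window)
        speed = kin.linear_speed(smoothed)
        boundaries = kin.segment_beats(len(traj) - 1, tempo, traj.frame_rate, n_beats)
        records = kin.braking_metrics(speed, boundaries, opts.zero_speed_threshold)
        if len(records) < n_beats:
            missing = sorted(
                set(range(1, n_beats + 1)) - {r.beat_index for r in records}
            )
            warnings.append(f"{context}:{side}: degenerate beats {missing} excluded")
        for r in records:
            rows.append(
                {
                    "hand": side,
                    "beat": r.beat_index,
                    "v_peak_ms": r.v_peak,
                    "v_end_ms": r.v_end,
                    "delta_v_ms": r.delta_v,
                    "delta_t_s": r.delta_t,
                    "a_bar_ms2": r.a_bar,
                }
            )
            slot = per_beat.setdefault(r.beat_index, {"delta_v": [], "a_bar": []})
            slot["delta_v"].append(r.delta_v)
            slot["a_bar"].append(r.a_bar)
    return rows, per_beat


def _stat_row(
    label: dict[str, Any],
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str,
    warnings: list[str],
) -> dict[str, Any]:
    """One group-comparison row; degrades gracefully when a group is thin."""
    row = dict(label)
    for g, vals in (("a", values_a), ("b", values_b)):
        v = np.asarray(vals, float)
        row[f"mean_{g}"] = float(v.mean()) if v.size else np.nan
        row[f"sd_{g}"] = float(v.std(ddof=1)) if v.size >= 2 else np.nan
        row[f"n_{g}"] = int(v.size)
    row["diff_ab"] = row["mean_a"] - row["mean_b"]
    if len(values_a) >= 2 and len(values_b) >= 2:
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            t = stats_mod.independent_t_test(values_a, values_b, variant=variant)
        for c in caught:
            warnings.append(f"{label}: {c.message}")
        row.update(t=t.t, df=t.df, p=t.p, sig_05=t.significant_05, sig_01=t.significant_01)
    else:
        warnings.append(f"{label}: insufficient group sizes for t-test")
        row.update(t=np.nan, df=np.nan, p=np.nan, sig_05=False, sig_01=False)
    return row


def analyze(config: RunConfig, in_dir: Path | str, out_dir: Path | str) -> Path:
    """Run kinematics + EMG per subject, then group statistics.

    Returns the path of the analysis manifest.  Requires a simulate-style
    input directory with ``manifest.json``.
    """
    in_path = Path(in_dir)
    manifest_file = in_path / "manifest.json"
    if not manifest_file.exists():
        raise InvalidArgumentError(f"no manifest.json in {in_path}")
    with open(manifest_file) as fh:
        manifest = json.load(fh)
    subjects = manifest["subjects"]
    if not subjects:
        raise InvalidArgumentError("manifest lists no subjects")
    combos = {int(c): int(n) for c, n in manifest["combos"].items()}
    tempo = float(manifest["config"]["cohort"]["tempo"])
    groups = {s["subject_id"]: s["group"] for s in subjects}
    heights = {s["subject_id"]: float(s["height_m"]) for s in subjects}

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    track_rows: list[dict[str, Any]] = []
    braking_rows: list[dict[str, Any]] = []
    emg_rows: list[dict[str, Any]] = []

    for s in subjects:
        sid = s["subject_id"]
        for combo, n_beats in combos.items():
            base = {"subject": sid, "group": groups[sid], "combo": combo}
            # --- kinematics (per-subject isolation) ---
            try:
                hands = io_mod.read_trajectory_csv(
                    in_path / f"{sid}_combo{combo}_trajectory.csv"
                )
                summaries = {
                    side: kin.summarize_track(traj, heights[sid], side, sid)
                    for side, traj in hands.items()
                }
                if {"left", "right"} <= set(summaries):
                    summaries["averaged"] = kin.hand_average(
                        summaries["left"], summaries["right"]
                    )
                for hand_label, summ in sorted(summaries.items()):
                    lengths = {"3D": summ.length_3d}
                    lengths.update(
                        {p.value: v for p, v in summ.plane_lengths.items()}
                    )
                    for plane in PLANES:
                        track_rows.append(
                            {
                                **base,
                                "hand": hand_label,
                                "plane": plane,
                                "length_m": lengths[plane],
                                "relative": lengths[plane] / heights[sid],
                            }
                        )
                hand_rows, per_beat = _braking_rows(
                    hands, tempo, n_beats, config.kinematics, warnings,
                    f"{sid}:combo{combo}",
                )
                for r in hand_rows:
                    braking_rows.append({**base, **r})
                for beat in sorted(per_beat):
                    vals = per_beat[beat]
                    braking_rows.append(
                        {
                            **base,
                            "hand": "averaged",
                            "beat": beat,
                            "v_peak_ms": np.nan,
                            "v_end_ms": np.nan,
                            "delta_v_ms": float(np.mean(vals["delta_v"])),
                            "delta_t_s": np.nan,
                            "a_bar_ms2": float(np.mean(vals["a_bar"])),
                        }
                    )
            except Exception as exc:  # per-subject isolation
                warnings.append(f"{sid}:combo{combo}:kinematics: {exc}")

            # --- EMG (independent isolation) ---
            try:
                channels, rate = io_mod.read_emg_csv(in_path / f"{sid}_combo{combo}_emg.csv")
                mvic = io_mod.read_mvic_csv(in_path / f"{sid}_mvic.csv")
                if config.emg.filter_enabled:
                    channels = {
                        name: emg_mod.preprocess(
                            emg_mod.EMGSeries(name, rate, v),
                            enabled=True,
                            band=config.emg.band,
                        ).values
                        for name, v in channels.items()
                    }
                beat_s = 60.0 / tempo
                boundaries_s = [b * beat_s for b in range(n_beats + 1)]
                metrics = emg_mod.per_beat_emg(
                    channels, rate, boundaries_s, mvic, iemg_rule=config.emg.iemg_rule
                )
                for m in metrics:
                    emg_rows.append(
                        {
                            **base,
                            "channel": m.channel,
                            "window": str(m.window),
                            "rms_mv": m.rms,
                            "iemg_mvs": m.iemg,
                            "rms_pct": m.rms_pct,
                            "iemg_pct": m.iemg_pct,
                        }
                    )
            except Exception as exc:
                warnings.append(f"{sid}:combo{combo}:emg: {exc}")

    track_df = pd.DataFrame(track_rows)
    braking_df = pd.DataFrame(braking_rows)
    emg_df = pd.DataFrame(emg_rows)
    track_df.to_csv(out / "track_lengths.csv", index=False, float_format="%.12g")
    braking_df.to_csv(out / "braking.csv", index=False, float_format="%.12g")
    emg_df.to_csv(out / "emg_metrics.csv", index=False, float_format="%.12g")

    variant = config.stats.t_variant
    # --- group stats: track length ---
    stats_track = []
    for combo in sorted(combos):
        for measure in ("length_m", "relative"):
            for plane in PLANES:
                sel = track_df[
                    (track_df.get("combo") == combo)
                    & (track_df.get("hand") == "averaged")
                    & (track_df.get("plane") == plane)
                ] if len(track_df) else track_df
                va = sel[sel["group"] == "A"][measure].tolist() if len(sel) else []
                vb = sel[sel["group"] == "B"][measure].tolist() if len(sel) else []
                stats_track.append(
                    _stat_row(
                        {"combo": combo, "measure": measure, "plane": plane},
                        va, vb, variant, warnings,
                    )
                )
    pd.DataFrame(stats_track).to_csv(out / "stats_track.csv", index=False, float_format="%.12g")

    # --- group stats: braking ---
    stats_braking = []
    for combo in sorted(combos):
        for beat in range(1, combos[combo] + 1):
            for measure in ("delta_v_ms", "a_bar_ms2"):
                sel = braking_df[
                    (braking_df.get("combo") == combo)
                    & (braking_df.get("hand") == "averaged")
                    & (braking_df.get("beat") == beat)
                ] if len(braking_df) else braking_df
                va = sel[sel["group"] == "A"][measure].tolist() if len(sel) else []
                vb = sel[sel["group"] == "B"][measure].tolist() if len(sel) else []
                stats_braking.append(
                    _stat_row(
                        {"combo": combo, "beat": beat, "measure": measure},
                        va, vb, variant, warnings,
                    )
                )
    pd.DataFrame(stats_braking).to_csv(
        out / "stats_braking.csv", index=False, float_format="%.12g"
    )

    # --- group stats: standardized EMG (figure data) ---
    stats_emg = []
    for combo in sorted(combos):
        for channel in CHANNELS:
            for measure in ("rms_pct", "iemg_pct"):
                sel = emg_df[
                    (emg_df.get("combo") == combo)
                    & (emg_df.get("channel") == channel)
                    & (emg_df.get("window") == "trial")
                ] if len(emg_df) else emg_df
                va = sel[sel["group"] == "A"][measure].tolist() if len(sel) else []
                vb = sel[sel["group"] == "B"][measure].tolist() if len(sel) else []
                stats_emg.append(
                    _stat_row(
                        {"combo": combo, "channel": channel, "measure": measure},
                        va, vb, variant, warnings,
                    )
                )
    pd.DataFrame(stats_emg).to_csv(out / "stats_emg.csv", index=False, float_format="%.12g")

    # --- correlations: track length vs standardized RMS / iEMG per group ---
    corr_rows = []
    for combo in sorted(combos):
        data_by_group: dict[str, dict[str, list[float]]] = {}
        for group in ("A", "B"):
            sids = sorted(s for s, g in groups.items() if g == group)
            track_vals, rms_vals, iemg_vals = [], [], []
            for sid in sids:
                tl = track_df[
                    (track_df.get("subject") == sid)
                    & (track_df.get("combo") == combo)
                    & (track_df.get("hand") == "averaged")
                    & (track_df.get("plane") == "3D")
                ] if len(track_df) else track_df
                em = emg_df[
                    (emg_df.get("subject") == sid)
                    & (emg_df.get("combo") == combo)
                    & (emg_df.get("window") == "trial")
                ] if len(emg_df) else emg_df
                if len(tl) == 1 and len(em) == len(CHANNELS):
                    track_vals.append(float(tl["length_m"].iloc[0]))
                    rms_vals.append(float(em["rms_pct"].mean()))
                    iemg_vals.append(float(em["iemg_pct"].mean()))
            data_by_group[group] = {
                "track_length": track_vals,
                "rms_pct": rms_vals,
                "iemg_pct": iemg_vals,
            }
        panel = stats_mod.correlation_panel(data_by_group, config.stats.grade_bands)
        for (group, x, y), res in sorted(panel.results.items()):
            corr_rows.append(
                {
                    "combo": combo, "group": group, "var_x": x, "var_y": y,
                    "r": res.r, "p": res.p, "grade": res.grade, "note": "",
                }
            )
        for (group, x, y), msg in sorted(panel.errors.items()):
            corr_rows.append(
                {
                    "combo": combo, "group": group, "var_x": x, "var_y": y,
                    "r": np.nan, "p": np.nan, "grade": "undefined", "note": msg,
                }
            )
            warnings.append(f"combo{combo}:{group}:corr({x},{y}): {msg}")
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False, float_format="%.12g")

    analysis_manifest = {
        "software_version": __version__,
        "seed": manifest["seed"],
        "config": config.to_dict(),
        "row_counts": {
            "track_lengths": len(track_df),
            "braking": len(braking_df),
            "emg_metrics": len(emg_df),
        },
        "warnings": sorted(warnings),
    }
    path = out / "analysis_manifest.json"
    _write_json(path, analysis_manifest)
    return path


# ---------------------------------------------------------------------------
# report


def _fmt(x: Any, nd: int = 3) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "—"
    if isinstance(x, (bool, np.bool_)):
        return "yes" if x else "no"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.{nd}f}"


def _stars(p: Any) -> str:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _group_table(df: pd.DataFrame, key_cols: list[str]) -> list[str]:
    header = key_cols + ["A mean±SD", "B mean±SD", "diff (A−B)", "t", "p", "sig"]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for _, row in df.iterrows():
        cells = [str(row[c]) for c in key_cols]
        cells.append(f"{_fmt(row['mean_a'])} ± {_fmt(row['sd_a'])} (n={_fmt(row['n_a'])})")
        cells.append(f"{_fmt(row['mean_b'])} ± {_fmt(row['sd_b'])} (n={_fmt(row['n_b'])})")
        cells.append(_fmt(row["diff_ab"]))
        cells.append(_fmt(row["t"]))
        cells.append(_fmt(row["p"]))
        cells.append(_stars(row["p"]))
        lines.append("| " + " | ".join(cells) + " |")
    return lines


def report(metrics_dir: Path | str, out_path: Path | str | None = None) -> Path:
    """Render the group-stats CSVs as a deterministic markdown report.

    Fixed column order and 3-decimal formatting; significance is flagged with
    ``*`` (P < 0.05) and ``**`` (P < 0.01).  Values are taken verbatim from the
    stage CSVs — nothing is recomputed at render time.
    """
    mdir = Path(metrics_dir)
    required = ["stats_track.csv", "stats_braking.csv", "stats_emg.csv", "correlations.csv"]
    for name in required:
        if not (mdir / name).exists():
            raise InvalidArgumentError(f"missing metrics file {name}")
    track = pd.read_csv(mdir / "stats_track.csv")
    braking = pd.read_csv(mdir / "stats_braking.csv")
    emg = pd.read_csv(mdir / "stats_emg.csv")
    corr = pd.read_csv(mdir / "correlations.csv")
    for df, cols in (
        (track, {"combo", "measure", "plane", "mean_a", "mean_b", "diff_ab", "t", "p"}),
        (braking, {"combo", "beat", "measure", "mean_a", "mean_b"}),
        (emg, {"combo", "channel", "measure", "mean_a", "mean_b"}),
        (corr, {"combo", "group", "var_x", "var_y", "r", "p", "grade"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise InvalidArgumentError(f"metrics schema mismatch: missing {sorted(missing)}")

    lines: list[str] = ["# Arm-manipulation biomechanics report", ""]
    manifest_path = mdir / "analysis_manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            warnings = json.load(fh).get("warnings", [])
        if warnings:
            lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]

    measure_names = {
        "length_m": "track length (m)",
        "relative": "relative track length",
        "delta_v_ms": "Δv (m/s)",
        "a_bar_ms2": "ā (m/s²)",
        "rms_pct": "standardized RMS (%)",
        "iemg_pct": "standardized iEMG (%)",
    }
    for combo in sorted(track["combo"].unique()):
        lines += [f"## Combination {combo}", ""]
        for measure in ("length_m", "relative"):
            sub = track[(track["combo"] == combo) & (track["measure"] == measure)]
            lines += [f"### {measure_names[measure].capitalize()}", ""]
            lines += _group_table(sub, ["plane"]) + [""]
        sub = braking[braking["combo"] == combo].copy()
        sub["measure"] = sub["measure"].map(measure_names)
        lines += ["### Per-beat braking (hand-averaged)", ""]
        lines += _group_table(sub, ["beat", "measure"]) + [""]
        sub = emg[emg["combo"] == combo].copy()
        sub["measure"] = sub["measure"].map(measure_names)
        lines += ["### Standardized EMG by channel", ""]
        lines += _group_table(sub, ["channel", "measure"]) + [""]
        sub = corr[corr["combo"] == combo]
        lines += ["### Correlations (per group)", ""]
        header = ["group", "pair", "r", "p", "grade"]
        lines += ["| " + " | ".join(header) + " |",
                  "|" + "|".join(["---"] * len(header)) + "|"]
        for _, row in sub.iterrows():
            lines.append(
                "| "
                + " | ".join(
                    [
                        str(row["group"]),
                        f"{row['var_x']} vs {row['var_y']}",
                        _fmt(row["r"]),
                        _fmt(row["p"]),
                        str(row["grade"]),
                    ]
                )
                + " |"
            )
        lines.append("")
    lines.append("Significance: * P < 0.05, ** P < 0.01 (independent-samples t-test).")
    lines.append("")

    out_file = Path(out_path) if out_path else mdir / "report.md"
    out_file.write_text("\n".join(lines))
    return out_file
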