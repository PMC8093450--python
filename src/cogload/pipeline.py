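"""Study-level orchestration: metric extraction, condition comparison, and
rank-correlation conformance.

``extract_metrics`` walks a study directory (participant/condition/recording
CSVs), computes every workload metric per recording, and returns a long-form
MetricTable. ``compare_conditions`` applies, per metric: outer-fence outlier
removal, an Anderson-Darling normality gate, then either the nonparametric
path (Friedman omnibus + pairwise Wilcoxon signed-rank) or the parametric
path (repeated-measures ANOVA + pairwise paired t), flagging each condition
pair at the 0.1 / 0.05 / 0.01 levels. ``conformance`` computes Spearman rank
correlations between metric pairs, pooling all participant x condition
values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from cogload import eeg_metrics, flight_metrics, gaze_metrics, pupil_metrics, stats
from cogload.errors import CogloadError, DegenerateInputError
from cogload.flight_metrics import FlightReference, InceptorTrace
from cogload.signal_io import outer_fence_filter, read_recording, segment_by_events

logger = logging.getLogger("cogload.pipeline")

__all__ = [
    "AnalysisReport",
    "DEFAULT_CONFORMANCE_PAIRS",
    "extract_metrics",
    "compare_conditions",
    "conformance",
    "analyze_study",
]

#: default rank-correlation pairs: EEG-EEG, ocular-ocular, cross-modality
DEFAULT_CONFORMANCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("power_lb", "power_theta"),
    ("power_lb", "power_hb"),
    ("nni", "l1ns_right"),
    ("l1ns_right", "power_lb"),
    ("duty_cycle", "l1ns_right"),
    ("duty_cycle", "power_theta"),
)

#: significance levels used for pairwise flags
ALPHA_LEVELS = (0.1, 0.05, 0.01)


@dataclass
class AnalysisReport:
    """Everything the analysis produces for one study."""

    metrics: pd.DataFrame  # long form: participant, condition, metric, value
    omnibus: dict[str, stats.TestReport]
    pairwise: pd.DataFrame  # metric, pair, statistic, p_value, flag
    conformance: pd.DataFrame  # metric_a, metric_b, rho, p_value, n
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the report; written to ``path`` when given."""
        payload = {
            "provenance": self.provenance,
            "omnibus": {
                m: {
                    "test": r.test,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "effect_size": r.effect_size,
                    "n": r.n,
                }
                for m, r in self.omnibus.items()
            },
            "pairwise": self.pairwise.to_dict(orient="records"),
            "conformance": self.conformance.to_dict(orient="records"),
            "skipped": self.skipped,
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _flag(p: float, alphas: Sequence[float] = ALPHA_LEVELS) -> str:
    for a in sorted(alphas):
        if p < a:
            return f"p<{a:g}"
    return ""


def _pupil_and_gaze_metrics(cell_dir: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    events = read_recording(cell_dir / "events.csv", "events")
    gaze = read_recording(cell_dir / "gaze.csv", "gaze")
    segs = segment_by_events(gaze, events, "task")
    gaze = segs[0] if segs else gaze
    duration = gaze.duration

    for eye, epoch in pupil_metrics.epochs_from_gaze(gaze).items():
        res = pupil_metrics.compute_pupil_metrics(epoch)
        if res is not None:
            out[f"l1ns_{eye}"] = res.l1ns
            out[f"stdp_{eye}"] = res.stdp
            out[f"lpf_{eye}"] = res.lpf

    fixations, saccades = gaze_metrics.ivt_classify(gaze)
    if fixations.n >= 2:
        out["nni"] = gaze_metrics.nni(fixations).nni
    out["fixation_rate"] = gaze_metrics.fixation_rate(fixations, duration)
    out["saccade_rate"] = gaze_metrics.saccade_rate(saccades, duration)
    si = gaze_metrics.detect_si(gaze)
    out["median_si_velocity"] = gaze_metrics.median_si_velocity(si)
    return out


def _eeg_band_metrics(cell_dir: Path) -> dict[str, float]:
    eeg = read_recording(cell_dir / "eeg.csv", "eeg")
    fs_eeg = 1.0 / float(np.median(np.diff(eeg.t)))
    summary = eeg_metrics.band_power_summary(eeg, fs=fs_eeg)
    short = {"theta": "theta", "alpha": "alpha", "low_beta": "lb", "high_beta": "hb"}
    return {f"power_{short.get(b, b)}": v for b, v in summary.median.items()}


def _inceptor_flight_metrics(cell_dir: Path) -> dict[str, float]:
    out: dict[str, float] = {}
    inceptor = read_recording(cell_dir / "inceptor.csv", "inceptor")
    trace = InceptorTrace.from_timeseries(inceptor)
    out["duty_cycle"] = flight_metrics.duty_cycle(trace)
    out["aggressiveness"] = flight_metrics.aggressiveness(trace)
    flight = read_recording(cell_dir / "flight.csv", "flight")
    ref = FlightReference()
    out["rmse_altitude_pct"] = flight_metrics.rmse_percent(flight, ref, "altitude")
    out["rmse_airspeed_pct"] = flight_metrics.rmse_percent(flight, ref, "airspeed")
    return out


def _metrics_for_cell(cell_dir: Path) -> dict[str, float]:
    """All workload metrics for one recording set, with per-modality isolation.

    A failure in one modality (say a corrupt EEG file) drops only that
    modality's metrics for the cell, logged with the cause; the others still
    report.
    """
    out: dict[str, float] = {}
    for group in (_pupil_and_gaze_metrics, _eeg_band_metrics, _inceptor_flight_metrics):
        try:
            out.update(group(cell_dir))
        except Exception:
            logger.exception("%s failed for %s", group.__name__, cell_dir)
    return out


def extract_metrics(study_dir: str | Path) -> pd.DataFrame:
    """Compute the MetricTable for a study directory.

    One row per participant x condition x metric. A failing recording set
    loses only its own metrics (logged, not fatal); an empty or non-study
    directory is an error.
    """
    study_dir = Path(study_dir)
    cells = sorted(
        d for p in sorted(study_dir.iterdir()) if p.is_dir()
        for d in sorted(p.iterdir()) if d.is_dir()
    ) if study_dir.is_dir() else []
    if not cells:
        raise CogloadError(f"{study_dir} contains no participant/condition cells")
    rows: list[dict[str, Any]] = []
    for cell in cells:
        participant, condition = cell.parent.name, cell.name
        try:
            metrics = _metrics_for_cell(cell)
        except Exception:
            logger.exception("metrics failed for %s/%s", participant, condition)
            continue
        for metric, value in metrics.items():
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["participant", "condition", "metric", "value"])


def _fence_within_conditions(wide: pd.DataFrame) -> pd.DataFrame:
    """Outer-fence each condition column; removed values become NaN."""
    out = wide.copy()
    for col in out.columns:
        vals = out[col].to_numpy(float)
        try:
            _, removed = outer_fence_filter(vals)
        except DegenerateInputError:
            continue
        out.loc[removed, col] = np.nan
    return out


def compare_conditions(
    table: pd.DataFrame,
    gate_alpha: float = 0.05,
    alphas: Sequence[float] = ALPHA_LEVELS,
    apply_outer_fence: bool = True,
    min_participants: int = 5,
) -> tuple[dict[str, stats.TestReport], pd.DataFrame, dict[str, str]]:
    """Omnibus + pairwise tests for every metric in a MetricTable.

    Per metric the participants x conditions table is outer-fenced within
    conditions, gated through Anderson-Darling on the within-condition
    residuals, then tested with Friedman + pairwise Wilcoxon (non-normal) or
    RM-ANOVA + pairwise paired t (normal). Metrics with fewer than
    ``min_participants`` complete rows are skipped with a reason.

    Returns (omnibus reports, pairwise long-form DataFrame, skipped reasons).
    """
    omnibus: dict[str, stats.TestReport] = {}
    skipped: dict[str, str] = {}
    pair_rows: list[dict[str, Any]] = []
    conditions = sorted(table["condition"].unique())
    if len(conditions) < 2:
        return omnibus, pd.DataFrame(
            columns=["metric", "pair", "test", "statistic", "p_value", "flag"]
        ), skipped
    for metric, sub in table.groupby("metric"):
        wide = sub.pivot_table(
            index="participant", columns="condition", values="value", aggfunc="mean"
        ).reindex(columns=conditions)
        if apply_outer_fence:
            wide = _fence_within_conditions(wide)
        complete = wide.dropna()
        if len(complete) < min_participants:
            skipped[str(metric)] = (
                f"only {len(complete)} complete participants (<{min_participants})"
            )
            continue
        arr = complete.to_numpy(float)
        resid = arr - arr.mean(axis=0, keepdims=True)
        try:
            gate = stats.anderson_darling_normal(resid.ravel())
            normal = gate.p_value >= gate_alpha
        except DegenerateInputError:
            normal = False
        if normal:
            omnibus[str(metric)] = stats.rm_anova_oneway(arr)
        else:
            omnibus[str(metric)] = stats.friedman(arr)
        for i, j in combinations(range(len(conditions)), 2):
            a, b = arr[:, i], arr[:, j]
            try:
                if normal:
                    t_stat, p = sstats.ttest_rel(a, b)
                    rep_stat, test_name = float(t_stat), "paired_t"
                else:
                    rep = stats.wilcoxon_signed_rank(a, b)
                    rep_stat, p, test_name = rep.statistic, rep.p_value, rep.test
            except DegenerateInputError as exc:
                skipped[f"{metric}:{conditions[i]}-{conditions[j]}"] = str(exc)
                continue
            pair_rows.append(
                {
                    "metric": metric,
                    "pair": f"{conditions[i]}-{conditions[j]}",
                    "test": test_name,
                    "statistic": rep_stat,
                    "p_value": float(p),
                    "flag": _flag(float(p), alphas),
                }
            )
    pairwise = pd.DataFrame(
        pair_rows, columns=["metric", "pair", "test", "statistic", "p_value", "flag"]
    )
    return omnibus, pairwise, skipped


def conformance(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_CONFORMANCE_PAIRS,
    min_n: int = 10,
) -> pd.DataFrame:
    """Spearman rank correlation for each metric pair.

    All participant x condition values are pooled (each recording contributes
    one point per metric). Pairs with fewer than ``min_n`` complete
    observations are reported with NaN correlation.
    """
    wide = table.pivot_table(
        index=["participant", "condition"], columns="metric", values="value",
        aggfunc="mean",
    )
    rows: list[dict[str, Any]] = []
    for ma, mb in pairs:
        if ma not in wide.columns or mb not in wide.columns:
            rows.append({"metric_a": ma, "metric_b": mb, "rho": np.nan,
                         "p_value": np.nan, "n": 0})
            continue
        sub = wide[[ma, mb]].dropna()
        if len(sub) < min_n:
            rows.append({"metric_a": ma, "metric_b": mb, "rho": np.nan,
                         "p_value": np.nan, "n": len(sub)})
            continue
        rep = stats.spearman(sub[ma].to_numpy(), sub[mb].to_numpy())
        rows.append({"metric_a": ma, "metric_b": mb, "rho": rep.statistic,
                     "p_value": rep.p_value, "n": rep.n})
    return pd.DataFrame(rows, columns=["metric_a", "metric_b", "rho", "p_value", "n"])


def analyze_study(
    table: pd.DataFrame,
    gate_alpha: float = 0.05,
    alphas: Sequence[float] = ALPHA_LEVELS,
    pairs: Sequence[tuple[str, str]] = DEFAULT_CONFORMANCE_PAIRS,
    provenance: dict[str, Any] | None = None,
) -> AnalysisReport:
    """Run the full comparison + conformance analysis on a MetricTable."""
    omnibus, pairwise, skipped = compare_conditions(
        table, gate_alpha=gate_alpha, alphas=alphas
    )
    conf = conformance(table, pairs=pairs)
    import cogload

    prov = dict(provenance or {})
    prov.setdefault("package_version", cogload.__version__)
    prov.setdefault(
        "metrics_sha256",
        hashlib.sha256(
            table.to_csv(index=False).encode()
        ).hexdigest(),
    )
    return AnalysisReport(
        metrics=table,
        omnibus=omnibus,
        pairwise=pairwise,
        conformance=conf,
        skipped=skipped,
        provenance=prov,
    )
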