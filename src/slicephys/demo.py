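"""End-to-end synthetic experiment: wild-type versus knockout slices.

The demo emulates the study design on fully synthetic data with known
ground truth:

- **Washdown assay** — ramp recordings from "knockout-like" cells with an
  initially open K_ATP conductance that decays after break-in, versus
  control cells with no excess K_ATP conductance; analyzed as normalized
  slope-conductance time courses.
- **Excitability assay** — current-clamp F–I curves from model neurons
  with and without an added K_ATP leak.
- **Slice imaging assay** — per-slice ΔF/F traces in which the knockout
  group's SLE rate is programmed to halve the plateau-window occupancy;
  analyzed with the full detection pipeline and compared by t-test /
  one-way ANOVA.

All randomness derives from one seed; the same seed reproduces every
table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from slicephys import io as sio
from slicephys.synthetic import (
    CalciumSimConfig, MembraneSimConfig, SpikingSimConfig,
    generate_dff_trace, generate_ramp_recording, generate_current_clamp,
)
from slicephys.sle import (
    DetectionParams, detrend, estimate_noise, detect_events, time_in_sle,
    interval_overlap,
)
from slicephys.ephys import washdown_timecourse, fi_curve
from slicephys.stats import two_tailed_t, one_way_anova, summarize, significance_stars

# Programmed study conditions: the knockout group's plateau SLE rate is half
# the wild-type rate, which halves plateau-window occupancy to first order.
WT_SLE_RATE = 0.75    # events/min at plateau
KO_SLE_RATE = 0.375   # events/min at plateau
N_SLICES = 8          # slices per group
KO_KATP_LEAK_NS = 0.75   # nS added K_ATP leak in knockout model neurons
KO_WASHDOWN_G0_NS = 3.0  # nS initial K_ATP conductance (washdown group)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def plateau_truth_percent(truth, params: DetectionParams) -> float:
    """Ground-truth percent time in SLEs over the plateau window."""
    lo, hi = params.plateau_window
    return 100.0 * interval_overlap(truth.event_intervals, lo, hi) / (hi - lo)


def detect_plateau_percent(trace, params: DetectionParams) -> float:
    """Full pipeline on one trace; returns detected plateau percent."""
    flat = detrend(trace, params)
    train = detect_events(flat, params)
    return time_in_sle(train, trace.duration, params).plateau_percent


def sle_group_experiment(
    seed: int,
    n_slices: int = N_SLICES,
    rate_wt: float = WT_SLE_RATE,
    rate_ko: float = KO_SLE_RATE,
    params: Optional[DetectionParams] = None,
    duration: float = 4800.0,
) -> pd.DataFrame:
    """Generate and analyze one WT-vs-knockout slice-imaging experiment.

    Returns one row per slice: condition, slice index, detected and
    ground-truth plateau percent.
    """
    params = params or DetectionParams()
    rng = np.random.default_rng(seed)
    rows = []
    for condition, rate in (("wildtype", rate_wt), ("knockout", rate_ko)):
        for i in range(n_slices):
            cfg = CalciumSimConfig(duration=duration, sle_rate_profile=rate,
                                   seed=_sub_seed(rng))
            trace, truth = generate_dff_trace(cfg)
            trace.condition = condition
            trace.trace_id = f"{condition}_{i}"
            rows.append({
                "condition": condition, "slice": i,
                "plateau_detected": detect_plateau_percent(trace, params),
                "plateau_truth": plateau_truth_percent(truth, params),
            })
    return pd.DataFrame(rows)


def power_analysis(
    seed: int,
    n_reps: int = 300,
    n_slices: int = N_SLICES,
    alpha: float = 0.05,
    duration: float = 4800.0,
) -> Dict[str, float]:
    """Replicate the slice experiment and measure detection power.

    For each replicate the WT and knockout groups are regenerated, the
    detection pipeline estimates per-slice plateau percentages, and a
    two-tailed t-test compares the groups.  Returns the rejection rate at
    ``alpha``, the mean detected and true reductions (percentage points),
    and the mean relative reduction.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    det_reductions = []
    truth_reductions = []
    wt_means = []
    for _ in range(n_reps):
        df = sle_group_experiment(_sub_seed(rng), n_slices=n_slices,
                                  duration=duration)
        wt = df[df.condition == "wildtype"]["plateau_detected"].to_numpy()
        ko = df[df.condition == "knockout"]["plateau_detected"].to_numpy()
        res = two_tailed_t(wt, ko)
        if res.p_value < alpha:
            rejections += 1
        det_reductions.append(wt.mean() - ko.mean())
        wt_means.append(wt.mean())
        wt_t = df[df.condition == "wildtype"]["plateau_truth"].to_numpy()
        ko_t = df[df.condition == "knockout"]["plateau_truth"].to_numpy()
        truth_reductions.append(wt_t.mean() - ko_t.mean())
    det = float(np.mean(det_reductions))
    tru = float(np.mean(truth_reductions))
    wt_mean = float(np.mean(wt_means))
    return {
        "power": rejections / n_reps,
        "n_reps": n_reps,
        "mean_detected_reduction_points": det,
        "mean_truth_reduction_points": tru,
        "mean_wt_plateau_percent": wt_mean,
        "mean_relative_reduction": det / wt_mean if wt_mean else float("nan"),
    }


def washdown_experiment(seed: int, n_cells: int = 6) -> pd.DataFrame:
    """Normalized conductance time courses: washdown vs control cells."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = (
        ("knockout", dict(katp_mode="washdown",
                          katp_conductance_t0=KO_WASHDOWN_G0_NS)),
        ("wildtype", dict(katp_mode="constant", katp_conductance_t0=0.0)),
    )
    for condition, kw in groups:
        for c in range(n_cells):
            cfg = MembraneSimConfig(noise_sd=2.0, seed=_sub_seed(rng), **kw)
            rec, _ = generate_ramp_recording(cfg, n_sweeps=30, sweep_interval=10.0)
            tc = washdown_timecourse(rec)
            for t, g, gn in zip(tc.times, tc.conductance, tc.normalized):
                rows.append({"condition": condition, "cell": c,
                             "time_s": t, "conductance_ns": g,
                             "normalized": gn})
    return pd.DataFrame(rows)


def fi_experiment(seed: int, n_cells: int = 8) -> pd.DataFrame:
    """F–I curves for model neurons with and without added K_ATP leak."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = (("wildtype", 0.0), ("knockout", KO_KATP_LEAK_NS))
    for condition, g_k in groups:
        for c in range(n_cells):
            cfg = SpikingSimConfig(katp_leak=g_k, noise_sd=10.0,
                                   seed=_sub_seed(rng))
            rec, _ = generate_current_clamp(cfg)
            curve = fi_curve(rec)
            for amp, cnt in zip(curve.amplitudes, curve.ap_counts):
                rows.append({"condition": condition, "cell": c,
                             "amplitude_pa": amp, "ap_count": int(cnt)})
    return pd.DataFrame(rows)


def run_demo(seed: int, outdir: Optional[Path] = None,
             n_power_reps: int = 0) -> Dict[str, object]:
    """Run the full synthetic WT-vs-knockout experiment.

    Returns a dict with the three assay tables, the group statistics, and
    (if ``n_power_reps > 0``) the power analysis.  If ``outdir`` is given,
    tables are written as TSV, figures as PNG, and a JSON summary records
    the headline numbers.
    """
    rng = np.random.default_rng(seed)
    s_wash, s_fi, s_sle, s_pow = (_sub_seed(rng) for _ in range(4))

    wash = washdown_experiment(s_wash)
    fi = fi_experiment(s_fi)
    sle = sle_group_experiment(s_sle)

    wt = sle[sle.condition == "wildtype"]["plateau_detected"].to_numpy()
    ko = sle[sle.condition == "knockout"]["plateau_detected"].to_numpy()
    ttest = two_tailed_t(wt, ko)
    anova = one_way_anova({"wildtype": wt, "knockout": ko})
    summaries = summarize({"wildtype": wt, "knockout": ko})
    wt_truth = sle[sle.condition == "wildtype"]["plateau_truth"].mean()
    ko_truth = sle[sle.condition == "knockout"]["plateau_truth"].mean()

    result: Dict[str, object] = {
        "washdown": wash, "fi": fi, "sle": sle,
        "sle_ttest": ttest, "sle_anova": anova, "sle_summaries": summaries,
        "wt_plateau_percent": float(wt.mean()),
        "ko_plateau_percent": float(ko.mean()),
        "detected_reduction_points": float(wt.mean() - ko.mean()),
        "truth_reduction_points": float(wt_truth - ko_truth),
        "seed": seed,
    }
    if n_power_reps > 0:
        result["power"] = power_analysis(s_pow, n_reps=n_power_reps)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wash.to_csv(outdir / "washdown_timecourse.tsv", sep="\t", index=False)
        fi.to_csv(outdir / "fi_curves.tsv", sep="\t", index=False)
        sle.to_csv(outdir / "sle_plateau.tsv", sep="\t", index=False)
        sio.write_json(outdir / "summary.json", {
            k: v for k, v in result.items()
            if not isinstance(v, pd.DataFrame)})
        _demo_figures(wash, fi, sle, outdir)
    return result


def _demo_figures(wash: pd.DataFrame, fi: pd.DataFrame, sle: pd.DataFrame,
                  outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"wildtype": "k", "knockout": "g"}

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, sub in wash.groupby("condition"):
        agg = sub.groupby("time_s")["normalized"].agg(["mean", "sem"])
        ax.errorbar(agg.index / 60, agg["mean"], yerr=agg["sem"],
                    fmt="o-", ms=3, color=colors[cond], label=cond)
    ax.set(xlabel="time from break-in (min)",
           ylabel="normalized slope conductance")
    ax.legend()
    fig.savefig(outdir / "washdown.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, sub in fi.groupby("condition"):
        agg = sub.groupby("amplitude_pa")["ap_count"].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], fmt="o-",
                    color=colors[cond], label=cond)
    ax.set(xlabel="injected current (pA)", ylabel="APs per 1-s pulse")
    ax.legend()
    fig.savefig(outdir / "fi_curve.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    data = [sle[sle.condition == c]["plateau_detected"].to_numpy()
            for c in ("wildtype", "knockout")]
    ax.boxplot(data, tick_labels=["wildtype", "knockout"], whis=1.5)
    ax.set(ylabel="% time in SLEs (40–80 min)")
    fig.savefig(outdir / "sle_plateau.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
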