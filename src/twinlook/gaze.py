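"""Extraction of preferential-looking phenotypes from raw gaze samples.

Turns 120 Hz gaze streams over five-object displays into three per-infant
phenotypes — face orienting (proportion of valid trials with the face
looked at first), face preference (face share of total AOI looking time)
and efficiency of visual exploration (distinct objects looked at in the
first 10 s) — plus two gaze-quality covariates (mean proportion of missing
samples, number of valid trials).

Trial validity follows three independent exclusion criteria: a valid-sample
proportion below 0.25, under 5 s of summed valid-sample time, or no look at
any AOI.  Phenotypes are averaged over valid trials and an infant is
retained only with at least four valid trials.  All thresholds are
configurable through :class:`ExtractionParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenes import GazeScene

__all__ = [
    "GazeTrial",
    "Look",
    "TrialMeasures",
    "ExtractionParams",
    "assign_aoi",
    "detect_looks",
    "trial_validity",
    "trial_measures",
    "aggregate_participant",
    "process_cohort",
    "regress_out_quality",
]


@dataclass(frozen=True)
class ExtractionParams:
    min_valid_proportion: float = 0.25
    min_valid_seconds: float = 5.0
    min_valid_trials: int = 4
    exploration_window_ms: float = 10_000.0
    min_look_samples: int = 3     # ~25 ms at 120 Hz
    max_gap_samples: int = 1      # invalid samples tolerated inside a look
    target_aoi: str = "face"      # any AOI can be designated the target

    def __post_init__(self) -> None:
        if (self.min_valid_proportion <= 0 or self.min_valid_seconds <= 0
                or self.min_valid_trials < 1):
            raise ValueError("validity thresholds must be positive")


@dataclass
class GazeTrial:
    """One trial's timestamped samples plus the AOI layout shown."""

    infant_id: str
    trial_index: int
    stimulus_id: int
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    scene: GazeScene

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid).astype(bool)
        if len(self.t_ms) and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def sample_period_ms(self) -> float:
        if len(self.t_ms) > 1:
            return float(np.median(np.diff(self.t_ms)))
        return 1000.0 / 120.0


@dataclass(frozen=True)
class Look:
    aoi: str
    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("look offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class TrialMeasures:
    infant_id: str
    trial_index: int
    valid: bool
    reasons: tuple[str, ...]
    first_aoi: str | None
    prop_target: float
    n_objects_window: float
    prop_missing: float


def assign_aoi(x: float, y: float, scene: GazeScene) -> str | None:
    """AOI containing (x, y) under half-open [x0,x1) x [y0,y1) rectangles,
    or None (off-screen coordinates and NaN also map to None)."""
    if not (np.isfinite(x) and np.isfinite(y)):
        return None
    for label, (x0, y0, x1, y1) in scene.aois.items():
        if x0 <= x < x1 and y0 <= y < y1:
            return label
    return None


def _sample_labels(trial: GazeTrial) -> list[str | None]:
    return [
        assign_aoi(x, y, trial.scene) if v else None
        for x, y, v in zip(trial.x_px, trial.y_px, trial.valid)
    ]


def detect_looks(trial: GazeTrial, params: ExtractionParams | None = None) -> list[Look]:
    """Segment the stream into looks: maximal runs of same-AOI samples.

    A run must span at least ``min_look_samples`` samples; invalid samples
    inside a run are tolerated up to ``max_gap_samples`` consecutive ones
    (a lightweight stand-in for gap interpolation).  A valid sample outside
    every AOI always terminates the run.
    """
    params = params or ExtractionParams()
    labels = _sample_labels(trial)
    looks: list[Look] = []
    period = trial.sample_period_ms
    cur: str | None = None
    start = end = -1
    count = 0
    pending_gap = 0

    def close() -> None:
        nonlocal cur, count
        if cur is not None and count >= params.min_look_samples:
            looks.append(Look(cur, trial.t_ms[start], trial.t_ms[end] + period))
        cur = None
        count = 0

    for i, lab in enumerate(labels):
        is_invalid = not trial.valid[i]
        if cur is not None:
            if lab == cur:
                count += 1 + pending_gap  # bridged invalids count into the run
                pending_gap = 0
                end = i
                continue
            if is_invalid and pending_gap < params.max_gap_samples:
                pending_gap += 1
                continue
            close()
            pending_gap = 0
        if lab is not None:
            cur = lab
            start = end = i
            count = 1
            pending_gap = 0
    close()
    return looks


def trial_validity(
    trial: GazeTrial,
    params: ExtractionParams | None = None,
    looks: list[Look] | None = None,
) -> tuple[bool, tuple[str, ...]]:
    """Apply the three exclusion criteria; reasons list every failure.

    The duration criterion is summed valid-sample time (elapsed trial time
    is constant by design, so only valid data can be meant by 'total
    duration of data').
    """
    params = params or ExtractionParams()
    reasons = []
    n = len(trial.t_ms)
    prop_valid = trial.valid.mean() if n else 0.0
    if prop_valid < params.min_valid_proportion:
        reasons.append(f"proportion<{params.min_valid_proportion}")
    valid_seconds = trial.valid.sum() * trial.sample_period_ms / 1000.0
    if valid_seconds < params.min_valid_seconds:
        reasons.append(f"duration<{params.min_valid_seconds}s")
    if looks is None:
        looks = detect_looks(trial, params)
    if not looks:
        reasons.append("no AOI look")
    return (not reasons), tuple(reasons)


def trial_measures(trial: GazeTrial, params: ExtractionParams | None = None) -> TrialMeasures:
    """Per-trial constituents of the three phenotypes.

    first AOI = AOI of the earliest-onset look; target (face) proportion =
    target look time over total AOI look time across the whole trial;
    exploration = number of distinct AOIs among looks starting inside the
    exploration window; missing = 1 - valid-sample proportion.
    """
    params = params or ExtractionParams()
    looks = detect_looks(trial, params)
    valid, reasons = trial_validity(trial, params, looks)
    n = len(trial.t_ms)
    prop_missing = 1.0 - (trial.valid.mean() if n else 0.0)
    if not valid:
        return TrialMeasures(trial.infant_id, trial.trial_index, False, reasons,
                             None, np.nan, np.nan, prop_missing)
    total = sum(lk.duration_ms for lk in looks)
    target = sum(lk.duration_ms for lk in looks if lk.aoi == params.target_aoi)
    first = min(looks, key=lambda lk: lk.onset_ms)
    explored = {lk.aoi for lk in looks if lk.onset_ms < params.exploration_window_ms}
    return TrialMeasures(
        trial.infant_id, trial.trial_index, True, (),
        first_aoi=first.aoi, prop_target=target / total,
        n_objects_window=float(len(explored)), prop_missing=prop_missing,
    )


def aggregate_participant(
    measures: list[TrialMeasures],
    params: ExtractionParams | None = None,
) -> dict | None:
    """Unweighted means over valid trials; None below the trial minimum."""
    params = params or ExtractionParams()
    if not 1 <= len(measures) <= 7:
        raise ValueError("expected 1-7 trials per infant")
    valid = [m for m in measures if m.valid]
    if len(valid) < params.min_valid_trials:
        return None
    # the missing-data covariate is averaged over valid trials only
    mean_missing = float(np.mean([m.prop_missing for m in valid]))
    return {
        "infant_id": measures[0].infant_id,
        "face_orienting": float(np.mean(
            [m.first_aoi == params.target_aoi for m in valid])),
        "face_preference": float(np.mean([m.prop_target for m in valid])),
        "exploration": float(np.mean([m.n_objects_window for m in valid])),
        "n_valid_trials": len(valid),
        "mean_prop_missing": mean_missing,
    }


def process_cohort(
    gaze: pd.DataFrame,
    scenes: dict[int, GazeScene] | list[GazeScene],
    params: ExtractionParams | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full extraction over a tidy gaze-sample table.

    ``gaze`` needs columns infant_id, trial_index, stimulus_id, t_ms, x_px,
    y_px, valid (plus optional pair_id / zygosity carried through).
    ``meta`` may supply per-infant age_days / sex / pair_id / zygosity.
    Returns (phenotypes, trial_qc); infants below the valid-trial minimum
    appear only in the QC table.
    """
    params = params or ExtractionParams()
    scene_map = ({s.stimulus_id: s for s in scenes}
                 if isinstance(scenes, list) else scenes)
    pheno_rows, qc_rows = [], []
    carry = [c for c in ("pair_id", "zygosity") if c in gaze.columns]
    for infant_id, g in gaze.groupby("infant_id", sort=True):
        measures = []
        for trial_idx, tg in g.groupby("trial_index", sort=True):
            stim = int(tg["stimulus_id"].iloc[0])
            trial = GazeTrial(
                infant_id=str(infant_id), trial_index=int(trial_idx),
                stimulus_id=stim,
                t_ms=tg["t_ms"].to_numpy(), x_px=tg["x_px"].to_numpy(),
                y_px=tg["y_px"].to_numpy(), valid=tg["valid"].to_numpy(),
                scene=scene_map[stim],
            )
            m = trial_measures(trial, params)
            measures.append(m)
            qc_rows.append({
                "infant_id": m.infant_id, "trial_index": m.trial_index,
                "valid": m.valid, "reasons": ";".join(m.reasons),
                "first_aoi": m.first_aoi, "prop_face": m.prop_target,
                "n_objects_10s": m.n_objects_window,
                "prop_missing": m.prop_missing,
            })
        agg = aggregate_participant(measures, params)
        if agg is not None:
            for c in carry:
                agg[c] = g[c].iloc[0]
            pheno_rows.append(agg)
    pheno = pd.DataFrame(pheno_rows)
    if meta is not None and len(pheno):
        keep = [c for c in meta.columns
                if c == "infant_id" or c not in pheno.columns]
        pheno = pheno.merge(meta[keep], on="infant_id", how="left")
    return pheno, pd.DataFrame(qc_rows)


def regress_out_quality(
    phenotypes: pd.DataFrame,
    traits: list[str],
    quality_cols: tuple[str, str] = ("mean_prop_missing", "n_valid_trials"),
    cluster: str = "pair_id",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residualize phenotypes that show a significant gaze-quality association.

    Each trait is tested (cluster-robust linear model on both quality
    covariates together); traits with p < alpha on either covariate are
    replaced by residuals from an ordinary least-squares fit on both, with
    the grand mean added back so chance-level comparisons stay meaningful.
    Returns (adjusted table, adjustment log).
    """
    from .assoc import gee_fit

    df = phenotypes.copy()
    log_rows = []
    # a quality covariate that is constant in this cohort carries no signal
    quality_cols = tuple(c for c in quality_cols if df[c].nunique() > 1)
    if not quality_cols:
        return df, pd.DataFrame(
            [{"trait": t, "min_quality_p": np.nan, "adjusted": False}
             for t in traits])
    for trait in traits:
        res = gee_fit(df, outcome=trait, predictors=list(quality_cols),
                      covariates=(), cluster=cluster, standardize=True)
        pmin = float(res.table.loc[
            res.table["predictor"].isin(quality_cols), "p"].min())
        adjusted = pmin < alpha
        if adjusted:
            X = np.column_stack([np.ones(len(df))]
                                + [df[c].to_numpy(dtype=float) for c in quality_cols])
            y = df[trait].to_numpy(dtype=float)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            df[trait] = y - X @ coef + y.mean()
        log_rows.append({"trait": trait, "min_quality_p": pmin,
                         "adjusted": adjusted})
    return df, pd.DataFrame(log_rows)
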