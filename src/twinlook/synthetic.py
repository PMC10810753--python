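"""Synthetic twin cohorts: ACE-structured latent traits, raw gaze streams,
and longitudinal outcomes.

This module is the generative mirror of the analysis chain.  A
:class:`GenerativeSpec` declares Cholesky path matrices for the additive
genetic (A), shared environment (C), optional dominance (D) and non-shared
environment (E) components of one or two standardized latent looking
traits.  Twin pairs inherit factor scores with the classical sharing
pattern (MZ share A and D fully, DZ with correlation 0.5 and 0.25; C is
fully shared regardless of zygosity; E is individual).  Latent traits can
then be rendered as 120 Hz gaze-sample streams over 20-s five-object
trials, and parent-report outcomes can be simulated with a configurable
standardized association to any phenotype.

Default cohort dimensions emulate a twin study of ~155 MZ and ~130 DZ
same-sex pairs of five-month-olds with ~12% incomplete pairs, six trials
per infant, and gaze-quality characteristics (mean ~28% missing samples)
matching published descriptives for this paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scenes import AOI_LABELS, GazeScene, default_scenes
from .twinmodels import TwinPairDataset

__all__ = [
    "GenerativeSpec",
    "TwinPedigree",
    "GazeParams",
    "simulate_twin_pedigree",
    "simulate_twin_phenotypes",
    "simulate_gaze_cohort",
    "simulate_outcomes",
    "probit_link_params",
]

# factor-sharing correlations per component and zygosity
_SHARING = {"A": {"MZ": 1.0, "DZ": 0.5},
            "C": {"MZ": 1.0, "DZ": 1.0},
            "D": {"MZ": 1.0, "DZ": 0.25}}


@dataclass(frozen=True)
class GenerativeSpec:
    """Path-coefficient specification of the latent twin-trait model.

    Paths are lower-triangular (Cholesky) matrices; for a standardized spec
    the implied total variance of each trait (row sums of squared paths
    across components) must be 1.  E must contribute positive variance to
    every trait so the observed-data likelihood is proper.
    """

    n_traits: int = 1
    path_A: tuple = ((0.0,),)
    path_C: tuple = ((0.0,),)
    path_E: tuple = ((1.0,),)
    path_D: tuple | None = None
    trait_means: tuple = (0.0,)
    beta_age: tuple = (0.0,)   # per scaled-age unit
    beta_sex: tuple = (0.0,)
    standardized: bool = True

    @classmethod
    def univariate(cls, a2: float, c2: float = 0.0, d2: float = 0.0,
                   mean: float = 0.0, beta_age: float = 0.0,
                   beta_sex: float = 0.0) -> "GenerativeSpec":
        """Standardized one-trait spec from variance proportions."""
        e2 = 1.0 - a2 - c2 - d2
        if e2 <= 0:
            raise ValueError("E must contribute positive variance")
        return cls(
            n_traits=1,
            path_A=((np.sqrt(a2),),), path_C=((np.sqrt(c2),),),
            path_D=((np.sqrt(d2),),) if d2 > 0 else None,
            path_E=((np.sqrt(e2),),),
            trait_means=(mean,), beta_age=(beta_age,), beta_sex=(beta_sex,),
        )

    @classmethod
    def bivariate_ae(cls, a11_2: float, shared_a2: float, unique_a2: float,
                     unique_e_share: float) -> "GenerativeSpec":
        """Standardized two-trait AE Cholesky spec from reported shares.

        ``a11_2`` is trait 1's heritability; ``shared_a2``/``unique_a2`` are
        trait 2's genetic variance shares transmitted through and specific
        to trait 1's genetic factor; ``unique_e_share`` is the fraction of
        trait 2's E variance that is trait-2 specific.
        """
        e11_2 = 1.0 - a11_2
        e2_total = 1.0 - shared_a2 - unique_a2
        e22_2 = unique_e_share * e2_total
        e21_2 = (1.0 - unique_e_share) * e2_total
        if min(e11_2, e22_2) <= 0 or e2_total <= 0:
            raise ValueError("E must contribute positive variance to both traits")
        return cls(
            n_traits=2,
            path_A=((np.sqrt(a11_2), 0.0), (np.sqrt(shared_a2), np.sqrt(unique_a2))),
            path_C=((0.0, 0.0), (0.0, 0.0)),
            path_E=((np.sqrt(e11_2), 0.0), (np.sqrt(e21_2), np.sqrt(e22_2))),
            trait_means=(0.0, 0.0), beta_age=(0.0, 0.0), beta_sex=(0.0, 0.0),
        )

    def _mats(self) -> dict[str, np.ndarray]:
        k = self.n_traits
        mats = {"A": np.asarray(self.path_A, dtype=float).reshape(k, k),
                "C": np.asarray(self.path_C, dtype=float).reshape(k, k),
                "E": np.asarray(self.path_E, dtype=float).reshape(k, k)}
        if self.path_D is not None:
            mats["D"] = np.asarray(self.path_D, dtype=float).reshape(k, k)
        return mats

    def validate(self) -> None:
        mats = self._mats()
        for name, L in mats.items():
            if np.any(np.triu(L, 1) != 0):
                raise ValueError(f"path_{name} must be lower triangular")
        total = sum(L @ L.T for L in mats.values())
        if self.standardized and not np.allclose(np.diag(total), 1.0, atol=1e-8):
            raise ValueError("standardized spec must imply unit trait variances")
        E = mats["E"]
        if np.any(np.diag(E @ E.T) <= 0):
            raise ValueError("E must contribute positive variance to every trait")
        for zyg in ("MZ", "DZ"):
            sigma = self.implied_covariance(zyg)
            try:
                np.linalg.cholesky(sigma + 1e-12 * np.eye(len(sigma)))
            except np.linalg.LinAlgError:
                raise ValueError(f"implied {zyg} pair covariance is not positive definite")

    def implied_covariance(self, zygosity: str) -> np.ndarray:
        """Closed-form 2k x 2k within-pair covariance for one zygosity."""
        mats = self._mats()
        cov = {name: L @ L.T for name, L in mats.items()}
        k = self.n_traits
        within = sum(cov.values())
        cross = np.zeros((k, k))
        for name, M in cov.items():
            if name != "E":
                cross = cross + _SHARING[name][zygosity] * M
        return np.block([[within, cross], [cross.T, within]])


@dataclass
class TwinPedigree:
    """One row per infant: pair structure, demographics, latent traits.

    Columns: infant_id, pair_id, zygosity, twin_order, sex (0/1, shared
    within pair), age_days (shared within pair), present (bool), and
    ``trait_1`` .. ``trait_k`` latent trait values (centered, covariate
    effects included).
    """

    table: pd.DataFrame
    spec: GenerativeSpec

    @property
    def n_traits(self) -> int:
        return self.spec.n_traits

    def present_infants(self) -> pd.DataFrame:
        return self.table[self.table["present"]].reset_index(drop=True)


def _truncated_age(rng: np.random.Generator, n: int, mean: float = 168.0,
                   sd: float = 9.0, lo: float = 145.0, hi: float = 203.0) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def simulate_twin_pedigree(
    spec: GenerativeSpec,
    n_mz: int = 155,
    n_dz: int = 130,
    incomplete_rate: float = 0.12,
    seed: int = 0,
) -> TwinPedigree:
    """Draw a twin pedigree with ACE(/D)-structured latent traits.

    Factor scores per component are standard normal; co-twins' scores share
    the classical correlations (see module docstring).  Sex and age are
    shared within a pair.  With ``incomplete_rate`` > 0 a random subset of
    pairs has exactly one present twin.
    """
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair per zygosity")
    if not 0.0 <= incomplete_rate < 1.0:
        raise ValueError("incomplete_rate must be in [0, 1)")
    spec.validate()
    rng = np.random.default_rng(seed)
    k = spec.n_traits
    mats = spec._mats()
    rows = []
    infant = 0
    for zyg, n_pairs in (("MZ", n_mz), ("DZ", n_dz)):
        sex = rng.integers(0, 2, size=n_pairs)
        age = _truncated_age(rng, n_pairs)
        age_s = (age - 168.0) / 9.0
        latents = {1: np.zeros((n_pairs, k)), 2: np.zeros((n_pairs, k))}
        for name, L in mats.items():
            rho = _SHARING.get(name, {}).get(zyg, 0.0)
            shared = rng.standard_normal((n_pairs, k))
            for t in (1, 2):
                own = rng.standard_normal((n_pairs, k))
                f = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
                latents[t] += f @ L.T
        incomplete = rng.random(n_pairs) < incomplete_rate
        drop_first = rng.integers(0, 2, size=n_pairs).astype(bool)
        beta_age = np.asarray(spec.beta_age, dtype=float)
        beta_sex = np.asarray(spec.beta_sex, dtype=float)
        for p in range(n_pairs):
            pid = f"{zyg}{p:04d}"
            for t in (1, 2):
                present = not (incomplete[p] and (drop_first[p] == (t == 1)))
                z = latents[t][p] + beta_age * age_s[p] + beta_sex * sex[p]
                row = {"infant_id": f"{pid}_{t}", "pair_id": pid, "zygosity": zyg,
                       "twin_order": t, "sex": int(sex[p]),
                       "age_days": float(age[p]), "present": present}
                for j in range(k):
                    row[f"trait_{j + 1}"] = float(z[j])
                rows.append(row)
            infant += 2
    return TwinPedigree(table=pd.DataFrame(rows), spec=spec)


def pedigree_to_dataset(pedigree: TwinPedigree) -> TwinPairDataset:
    """Pair up the pedigree's latent traits as an analyzable phenotype set."""
    df = pedigree.table
    k = pedigree.n_traits
    trait_cols = [f"trait_{j + 1}" for j in range(k)]
    pairs = []
    for pid, g in df.groupby("pair_id", sort=True):
        g = g.set_index("twin_order")
        y = {}
        for t in (1, 2):
            r = g.loc[t]
            y[t] = (np.array([r[c] for c in trait_cols], dtype=float)
                    + np.asarray(pedigree.spec.trait_means, dtype=float)
                    if r["present"] else np.full(k, np.nan))
        if np.isnan(y[1]).all() and np.isnan(y[2]).all():
            continue
        pairs.append((pid, g.loc[1, "zygosity"], g.loc[1, "age_days"],
                      g.loc[1, "sex"], y[1], y[2]))
    return TwinPairDataset(
        y1=np.array([p[4] for p in pairs]),
        y2=np.array([p[5] for p in pairs]),
        zygosity=np.array([p[1] for p in pairs]),
        age_days=np.array([p[2] for p in pairs], dtype=float),
        sex=np.array([p[3] for p in pairs], dtype=float),
        trait_names=tuple(trait_cols[: k]),
        pair_id=np.array([p[0] for p in pairs]),
    )


def simulate_twin_phenotypes(
    spec: GenerativeSpec,
    n_mz: int = 155,
    n_dz: int = 130,
    incomplete_rate: float = 0.12,
    seed: int = 0,
) -> TwinPairDataset:
    """Pair-structured phenotype dataset drawn directly at the trait level."""
    pedigree = simulate_twin_pedigree(spec, n_mz, n_dz, incomplete_rate, seed)
    return pedigree_to_dataset(pedigree)


# ---------------------------------------------------------------------------
# Latent-to-rate link
# ---------------------------------------------------------------------------

def probit_link_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Solve (m, s) so that p = Phi(m + s Z), Z ~ N(0,1), has the target
    mean and s.d.

    E[p] = Phi(h) with h = m / sqrt(1 + s^2); E[p^2] is the orthant
    probability Phi2(h, h; rho) with rho = s^2 / (1 + s^2), so both moments
    are available in closed form and s is found by 1-D root bracketing.
    """
    if not 0 < target_mean < 1:
        raise ValueError("target mean must be in (0, 1)")
    max_sd = np.sqrt(target_mean * (1 - target_mean))
    if not 0 < target_sd < max_sd:
        raise ValueError(f"target sd must be in (0, {max_sd:.3f}) for this mean")
    h = stats.norm.ppf(target_mean)

    def sd_at(s: float) -> float:
        rho = s * s / (1.0 + s * s)
        m2 = stats.multivariate_normal.cdf(
            [h, h], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        return np.sqrt(max(m2 - target_mean ** 2, 0.0))

    sol = optimize.brentq(lambda s: sd_at(s) - target_sd, 1e-6, 50.0)
    m = h * np.sqrt(1.0 + sol * sol)
    return float(m), float(sol)


# ---------------------------------------------------------------------------
# Gaze rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeParams:
    """Tunable settings of the gaze renderer.

    Rates and spreads default to the published cohort descriptives for this
    paradigm: face orienting mean 0.30, face preference mean 0.44 (s.d.
    0.14), ~28% missing samples.  The orienting latent spread on the
    probability scale defaults to 0.10 — the observed 6-trial proportion
    adds binomial noise (~0.19 s.d.) on top of it.
    """

    sampling_rate: float = 120.0
    trial_s: float = 20.0
    n_trials: int = 6
    orient_mean: float = 0.30
    orient_sd: float = 0.10
    pref_mean: float = 0.44
    pref_sd: float = 0.14
    missing_mean: float = 0.28
    missing_sd: float = 0.13
    missing_max: float = 0.61
    p_bad_trial: float = 0.04  # look-away trials with extreme missingness
    blink_mean_samples: float = 10.0
    latency_median_ms: float = 350.0
    latency_log_sd: float = 0.45
    mean_dwell_ms: float = 850.0
    p_revisit: float = 0.70   # bias toward returning to the previous AOI
    p_elsewhere: float = 0.06
    elsewhere_dwell_ms: float = 250.0
    deterministic_dwell: bool = False
    force_face_share: float | None = None
    force_missing_rate: float | None = None
    orient_trait: int = 0   # which latent trait drives first looks
    pref_trait: int = -1    # which latent trait drives dwell share


def _render_trial(
    rng: np.random.Generator,
    scene: GazeScene,
    p_orient: float,
    p_face: float,
    missing_rate: float,
    params: GazeParams,
) -> pd.DataFrame:
    # face dwell scaled so the stationary face share of AOI time is p_face
    # (uniform visit frequencies over the 5 AOIs; duration carries the bias)
    d_face = params.mean_dwell_ms * 5.0 * p_face
    d_other = params.mean_dwell_ms * 5.0 * (1.0 - p_face) / 4.0
    others = [l for l in AOI_LABELS if l != "face"]
    latency = params.latency_median_ms * np.exp(
        0.0 if params.deterministic_dwell
        else rng.normal(0.0, params.latency_log_sd))
    segments: list[tuple[float, str]] = [(latency, "centre")]
    total = latency
    if params.deterministic_dwell:
        # noise-free render: cycle the five AOIs with exact dwell shares so
        # the trial's face time share equals p_face up to end truncation
        first_face = rng.random() < p_orient
        cycle = ["face"] + others if first_face else [others[0], "face"] + others[1:]
        i = 0
        while total < params.trial_s * 1000.0:
            aoi = cycle[i % 5]
            dwell = d_face if aoi == "face" else d_other
            if dwell > 0:
                segments.append((dwell, aoi))
                total += dwell
            i += 1
        return _paint_segments(segments, scene, rng, params, missing_rate,
                               jitter=0.0)
    current: str | None = None
    prev: str | None = None
    first = True
    zero_streak = 0
    while total < params.trial_s * 1000.0:
        if rng.random() < params.p_elsewhere and not first:
            aoi = "elsewhere"
            dwell = params.elsewhere_dwell_ms
        else:
            if first:
                aoi = "face" if rng.random() < p_orient else others[rng.integers(4)]
                first = False
            elif (prev is not None and prev != current
                    and rng.random() < params.p_revisit):
                # back-and-forth looking: revisit the previous object; the
                # rule is label-symmetric, so AOI visit frequencies stay
                # uniform and the face time share is still set by dwell
                aoi = prev
            else:
                choices = [l for l in AOI_LABELS if l != current]
                aoi = choices[rng.integers(len(choices))]
            dwell = d_face if aoi == "face" else d_other
        # a degenerate dwell share zeroes some dwells; bail out of the walk
        # to the non-zero-dwell state so the segment clock always advances
        if dwell <= 0:
            current = aoi
            zero_streak += 1
            if zero_streak > 20:
                aoi = "face" if d_face > 0 else "elsewhere"
                dwell = d_face if d_face > 0 else params.elsewhere_dwell_ms
            else:
                continue
        zero_streak = 0
        if not params.deterministic_dwell and dwell > 0:
            dwell = rng.exponential(dwell)
        if dwell > 0:
            segments.append((dwell, aoi))
            if aoi in AOI_LABELS and current in AOI_LABELS:
                prev = current
            current = aoi
            total += dwell
    return _paint_segments(segments, scene, rng, params, missing_rate,
                           jitter=8.0)


def _paint_segments(
    segments: list[tuple[float, str]],
    scene: GazeScene,
    rng: np.random.Generator,
    params: GazeParams,
    missing_rate: float,
    jitter: float,
) -> pd.DataFrame:
    dt = 1000.0 / params.sampling_rate
    n = int(round(params.trial_s * 1000.0 / dt))
    t = np.arange(n) * dt
    labels = np.empty(n, dtype=object)
    edges = np.cumsum([s[0] for s in segments])
    starts = np.concatenate([[0.0], edges[:-1]])
    for (dwell, aoi), s0, s1 in zip(segments, starts, edges):
        sel = (t >= s0) & (t < s1)
        labels[sel] = aoi
    labels[t >= edges[-1]] = segments[-1][1]
    x = np.empty(n)
    y = np.empty(n)
    cx, cy = scene.centre()
    for lab in set(labels):
        sel = labels == lab
        m = int(sel.sum())
        if lab == "centre":
            px, py = cx, cy
        elif lab == "elsewhere":
            # screen corner: far from the AOI ring even with sample jitter
            px, py = scene.screen[0] * 0.03, scene.screen[1] * 0.03
        else:
            px, py = scene.aoi_centre(lab)
        x[sel] = px + (rng.normal(0, jitter, m) if jitter else 0.0)
        y[sel] = py + (rng.normal(0, jitter, m) if jitter else 0.0)
    # bursty missingness: alternating geometric valid / invalid (blink) runs
    # whose mean lengths give the target stationary invalid rate
    valid = np.ones(n, dtype=bool)
    r = missing_rate
    if r > 0:
        L = params.blink_mean_samples
        p_exit = 1.0 / L
        p_enter = min(r / (L * (1.0 - r)), 1.0)
        n_runs = max(8, int(2 * n * (p_enter + p_exit)) + 8)
        invalid_runs = rng.geometric(p_exit, n_runs)
        valid_runs = rng.geometric(p_enter, n_runs)
        start_invalid = rng.random() < r
        lengths = np.empty(2 * n_runs, dtype=int)
        lengths[0::2] = invalid_runs if start_invalid else valid_runs
        lengths[1::2] = valid_runs if start_invalid else invalid_runs
        while lengths.sum() < n:
            lengths = np.concatenate([lengths, lengths])
        flags = np.repeat(
            (np.arange(len(lengths)) % 2 == 0) == start_invalid, lengths)[:n]
        valid = ~flags
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y,
                         "valid": valid.astype(int)})


def simulate_gaze_cohort(
    pedigree: TwinPedigree,
    params: GazeParams | None = None,
    scenes: list[GazeScene] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render raw 120 Hz gaze streams for every present infant.

    Returns ``(gaze, truth)``: a tidy sample table (infant_id, pair_id,
    zygosity, trial_index, stimulus_id, t_ms, x_px, y_px, valid) and a
    per-infant ground-truth table with the generating first-look and
    dwell-share rates for round-trip checks.

    Each trial starts with gaze at the screen centre (the gaze-contingent
    start), a lognormal latency to the first look, a first-look AOI that is
    the face with the infant's orienting probability, and thereafter a
    random walk over AOIs whose face dwell duration is scaled so the
    expected face share of AOI looking time equals the infant's preference
    rate.  Missingness is a bursty two-state process at the infant's rate.
    """
    params = params or GazeParams()
    scenes = scenes if scenes is not None else default_scenes()
    rng = np.random.default_rng(seed)
    m_o, s_o = probit_link_params(params.orient_mean, params.orient_sd)
    m_p, s_p = probit_link_params(params.pref_mean, params.pref_sd)
    infants = pedigree.present_infants()
    k = pedigree.n_traits
    gaze_parts = []
    truth_rows = []
    for _, inf in infants.iterrows():
        z_o = inf[f"trait_{params.orient_trait % k + 1}"]
        z_p = inf[f"trait_{params.pref_trait % k + 1}"]
        p_orient = float(stats.norm.cdf(m_o + s_o * z_o))
        p_face = float(stats.norm.cdf(m_p + s_p * z_p))
        if params.force_face_share is not None:
            p_face = params.force_face_share
        if params.force_missing_rate is not None:
            miss = params.force_missing_rate
        else:
            miss = float(np.clip(rng.normal(params.missing_mean, params.missing_sd),
                                 0.0, params.missing_max))
        for trial in range(1, params.n_trials + 1):
            scene = scenes[(trial - 1) % len(scenes)]
            trial_miss = miss
            if rng.random() < params.p_bad_trial:
                trial_miss = rng.uniform(0.78, 0.97)  # fails the 25% criterion
            tr = _render_trial(rng, scene, p_orient, p_face, trial_miss, params)
            tr.insert(0, "infant_id", inf["infant_id"])
            tr.insert(1, "pair_id", inf["pair_id"])
            tr.insert(2, "zygosity", inf["zygosity"])
            tr.insert(3, "trial_index", trial)
            tr.insert(4, "stimulus_id", scene.stimulus_id)
            gaze_parts.append(tr)
        truth_rows.append({"infant_id": inf["infant_id"],
                           "p_orient": p_orient, "p_face": p_face,
                           "missing_rate": miss})
    return pd.concat(gaze_parts, ignore_index=True), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Longitudinal outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(
    phenotypes: pd.DataFrame,
    beta: float,
    predictor: str,
    seed: int = 0,
    pair_corr: float = 0.0,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Standardized outcome with a configurable association to a phenotype.

    ``outcome = beta * z(predictor) + covariate effects + noise`` with noise
    variance 1 - beta^2, so the outcome is (marginally) standardized when
    covariate effects are zero.  With ``pair_corr`` > 0 the noise is
    exchangeable within twin pairs, exercising the clustered-error machinery
    downstream.
    """
    if abs(beta) >= 1.0:
        raise ValueError("|beta| must be < 1 under the standardized construction")
    if not 0.0 <= pair_corr < 1.0:
        raise ValueError("pair_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = phenotypes.copy()
    x = df[predictor].to_numpy(dtype=float)
    xz = (x - np.nanmean(x)) / np.nanstd(x)
    pair_ids = df["pair_id"].to_numpy()
    uniq, inv = np.unique(pair_ids, return_inverse=True)
    shared = rng.standard_normal(len(uniq))[inv]
    own = rng.standard_normal(len(df))
    noise = np.sqrt(pair_corr) * shared + np.sqrt(1.0 - pair_corr) * own
    out = beta * xz + np.sqrt(1.0 - beta * beta) * noise
    if beta_age and "age_days" in df:
        a = df["age_days"].to_numpy(dtype=float)
        out = out + beta_age * (a - a.mean()) / a.std()
    if beta_sex and "sex" in df:
        out = out + beta_sex * df["sex"].to_numpy(dtype=float)
    df[outcome_name] = out
    return df
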