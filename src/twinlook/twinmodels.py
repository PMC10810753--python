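"""Full-information maximum-likelihood engine for classical twin models.

Implements saturated and ACE-family (ACE / ADE / AE / CE / E) models for
one or two traits measured on MZ and DZ twin pairs, with the bivariate case
parameterized as a Cholesky decomposition.  The likelihood is the standard
multivariate-normal FIML over pairs: an absent co-twin simply drops their
rows from the implied mean vector and covariance matrix, so partially
complete pairs contribute their marginal density.

Model structure
---------------
Each variance component X in {A, C, D, E} is parameterized by a free
lower-triangular path matrix ``L_X`` (k x k for k traits), so the component
covariance ``X = L_X @ L_X.T`` is positive semi-definite by construction.
The within-twin covariance is ``A + C + D + E``; the cross-twin covariance
is ``A + C + D`` for MZ pairs and ``0.5 A + C + 0.25 D`` for DZ pairs,
reflecting the expected sharing of additive-genetic (100% / 50%) and
dominance (100% / 25%) effects, and full sharing of the common environment.
Age (scaled) and sex enter the mean model only, with effects equated across
twins and zygosity.

Conventions
-----------
* degrees of freedom = (number of non-missing observed trait values) minus
  (number of free parameters);
* AIC = -2LL - 2 * df;
* nested-model p-values use the naive chi-square reference, the standard
  reporting convention in the twin literature (no boundary mixture).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinPairDataset",
    "ModelSpec",
    "ModelFit",
    "ComparisonResult",
    "VarianceDecomposition",
    "SaturatedConstraints",
    "implied_moments",
    "fiml_minus2ll",
    "fit_model",
    "fit_saturated",
    "compare_models",
    "select_best",
    "twin_correlations",
    "standardize_components",
    "profile_ci",
    "fit_statistics",
]

_CHI2_95_DF1 = stats.chi2.ppf(0.95, 1)  # 3.841...
_PENALTY = 1e10


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class TwinPairDataset:
    """Pair-structured phenotypes: one row per twin pair.

    ``y1``/``y2`` are (n_pairs, n_traits) arrays; an absent co-twin is an
    all-NaN row (a present twin must have every trait observed).  Age and
    sex are shared within a pair (same-sex twins assessed together).
    """

    y1: np.ndarray
    y2: np.ndarray
    zygosity: np.ndarray  # "MZ" / "DZ"
    age_days: np.ndarray
    sex: np.ndarray  # 0 = female, 1 = male
    trait_names: tuple[str, ...] = ("trait",)
    pair_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y1 = np.atleast_2d(np.asarray(self.y1, dtype=float))
        self.y2 = np.atleast_2d(np.asarray(self.y2, dtype=float))
        if self.y1.shape[0] == 1 and len(self.zygosity) != 1:
            self.y1 = self.y1.T
            self.y2 = self.y2.T
        self.zygosity = np.asarray(self.zygosity)
        self.age_days = np.asarray(self.age_days, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        if self.pair_id is None:
            self.pair_id = np.arange(self.y1.shape[0])
        for y in (self.y1, self.y2):
            row_nan = np.isnan(y)
            bad = row_nan.any(axis=1) & ~row_nan.all(axis=1)
            if bad.any():
                raise ValueError(
                    "a present twin must have all traits observed; "
                    f"pairs with partial traits: {np.flatnonzero(bad)[:5]}"
                )
        present = self.present1 | self.present2
        if not present.all():
            raise ValueError("every retained pair needs at least one present twin")

    @property
    def n_pairs(self) -> int:
        return self.y1.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y1.shape[1]

    @property
    def present1(self) -> np.ndarray:
        return ~np.isnan(self.y1).any(axis=1)

    @property
    def present2(self) -> np.ndarray:
        return ~np.isnan(self.y2).any(axis=1)

    @property
    def n_individuals(self) -> int:
        return int(self.present1.sum() + self.present2.sum())

    @property
    def n_obs_values(self) -> int:
        """Total non-missing observed trait values (the df numerator)."""
        return self.n_individuals * self.n_traits

    @property
    def age_scaled(self) -> np.ndarray:
        a = self.age_days
        s = a.std(ddof=0)
        return (a - a.mean()) / (s if s > 0 else 1.0)

    def select_traits(self, idx: Sequence[int]) -> "TwinPairDataset":
        idx = list(idx)
        return replace(
            self,
            y1=self.y1[:, idx],
            y2=self.y2[:, idx],
            trait_names=tuple(self.trait_names[i] for i in idx),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, traits: Sequence[str]) -> "TwinPairDataset":
        """Build from a long table with one row per infant.

        Requires columns ``pair_id``, ``zygosity``, ``twin_order`` (1/2),
        ``age_days``, ``sex`` plus one column per trait.
        """
        need = {"pair_id", "zygosity", "twin_order", "age_days", "sex", *traits}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        k = len(traits)
        pairs = []
        for pid, g in df.groupby("pair_id", sort=True):
            row = {"pair_id": pid, "zygosity": g["zygosity"].iloc[0],
                   "age_days": g["age_days"].iloc[0], "sex": g["sex"].iloc[0]}
            y = {1: np.full(k, np.nan), 2: np.full(k, np.nan)}
            for _, r in g.iterrows():
                y[int(r["twin_order"])] = np.array([r[t] for t in traits], dtype=float)
            row["y1"], row["y2"] = y[1], y[2]
            pairs.append(row)
        keep = [p for p in pairs
                if not (np.isnan(p["y1"]).all() and np.isnan(p["y2"]).all())]
        return cls(
            y1=np.array([p["y1"] for p in keep]),
            y2=np.array([p["y2"] for p in keep]),
            zygosity=np.array([p["zygosity"] for p in keep]),
            age_days=np.array([p["age_days"] for p in keep]),
            sex=np.array([p["sex"] for p in keep]),
            trait_names=tuple(traits),
            pair_id=np.array([p["pair_id"] for p in keep]),
        )


# ---------------------------------------------------------------------------
# Genetic model specification and parameter packing
# ---------------------------------------------------------------------------

def _tril_slots(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1)]


@dataclass(frozen=True)
class ModelSpec:
    """A genetic twin model: which components are free, which paths are fixed.

    ``components`` is a subset of "ACDE"; E is mandatory (the likelihood is
    improper without residual variance) and C and D cannot be combined (not
    jointly identified from MZ/DZ data alone).  ``fixed_zero`` pins named
    Cholesky paths to zero, e.g. ``(("A", 1, 0),)`` drops the cross-trait
    genetic path in a bivariate model.
    """

    n_traits: int = 1
    components: str = "ACE"
    fixed_zero: tuple[tuple[str, int, int], ...] = ()
    covariates: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if "E" not in self.components:
            raise ValueError("E is mandatory")
        if "C" in self.components and "D" in self.components:
            raise ValueError("C and D are not jointly identified with MZ/DZ data")
        if any(c not in "ACDE" for c in self.components):
            raise ValueError(f"unknown components in {self.components!r}")
        for comp, i, j in self.fixed_zero:
            if comp not in self.components or j > i or i >= self.n_traits:
                raise ValueError(f"invalid fixed path {(comp, i, j)}")

    @property
    def label(self) -> str:
        return self.name or self.components

    def free_slots(self) -> list[tuple[str, int, int]]:
        fixed = set(self.fixed_zero)
        return [
            (comp, i, j)
            for comp in self.components
            for (i, j) in _tril_slots(self.n_traits)
            if (comp, i, j) not in fixed
        ]

    @property
    def n_params(self) -> int:
        k = self.n_traits
        n = len(self.free_slots()) + k  # paths + means
        if self.covariates:
            n += 2 * k  # age and sex effects per trait
        return n

    def unpack(self, x: np.ndarray) -> dict:
        k = self.n_traits
        slots = self.free_slots()
        paths = {comp: np.zeros((k, k)) for comp in self.components}
        for val, (comp, i, j) in zip(x[: len(slots)], slots):
            paths[comp][i, j] = val
        pos = len(slots)
        means = x[pos : pos + k]
        pos += k
        if self.covariates:
            beta_age = x[pos : pos + k]
            beta_sex = x[pos + k : pos + 2 * k]
        else:
            beta_age = np.zeros(k)
            beta_sex = np.zeros(k)
        return {"paths": paths, "means": means, "beta_age": beta_age, "beta_sex": beta_sex}

    def pack(self, params: dict) -> np.ndarray:
        """Inverse of :meth:`unpack` (fixed-zero slots are dropped)."""
        slots = self.free_slots()
        x = [params["paths"][comp][i, j] for (comp, i, j) in slots]
        x.extend(params["means"])
        if self.covariates:
            x.extend(params["beta_age"])
            x.extend(params["beta_sex"])
        return np.asarray(x, dtype=float)


def _component_covariances(paths: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {comp: L @ L.T for comp, L in paths.items()}


def implied_moments(spec: ModelSpec, params: dict) -> dict:
    """Per-zygosity implied moments from unpacked parameters.

    Returns ``{"MZ": (mu, Sigma), "DZ": (mu, Sigma)}`` where ``mu`` is the
    baseline 2k mean vector (covariates at zero) and ``Sigma`` the 2k x 2k
    pair covariance.
    """
    cov = _component_covariances(params["paths"])
    k = spec.n_traits
    zero = np.zeros((k, k))
    A = cov.get("A", zero)
    C = cov.get("C", zero)
    D = cov.get("D", zero)
    E = cov.get("E", zero)
    within = A + C + D + E
    out = {}
    for zyg, (wa, wd) in (("MZ", (1.0, 1.0)), ("DZ", (0.5, 0.25))):
        cross = wa * A + C + wd * D
        sigma = np.block([[within, cross], [cross.T, within]])
        mu = np.concatenate([params["means"], params["means"]])
        out[zyg] = (mu, sigma)
    return out


# ---------------------------------------------------------------------------
# FIML likelihood
# ---------------------------------------------------------------------------

_LN2PI = np.log(2.0 * np.pi)


def _group_m2ll(resid: np.ndarray, sigma: np.ndarray) -> float:
    """Sum of -2 log N(resid; 0, sigma) over rows; penalty if sigma not PD."""
    if resid.shape[0] == 0:
        return 0.0
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY
    logdet = 2.0 * np.log(np.diag(L)).sum()
    z = np.linalg.solve(L, resid.T)  # (dim, n)
    quad = (z * z).sum()
    n, dim = resid.shape
    return n * (dim * _LN2PI + logdet) + quad


class _FimlEngine:
    """Precomputes pair groupings so repeated -2LL evaluations are vectorized."""

    def __init__(self, spec: ModelSpec, data: TwinPairDataset):
        if spec.n_traits != data.n_traits:
            raise ValueError("spec/data trait dimension mismatch")
        self.spec = spec
        self.data = data
        p1, p2 = data.present1, data.present2
        mz = data.zygosity == "MZ"
        self.idx = {
            "MZ_full": np.flatnonzero(mz & p1 & p2),
            "DZ_full": np.flatnonzero(~mz & p1 & p2),
            "single1": np.flatnonzero(p1 & ~p2),
            "single2": np.flatnonzero(~p1 & p2),
        }
        self.age_s = data.age_scaled
        self.sex = data.sex

    def _pair_mu(self, params: dict) -> np.ndarray:
        """(n_pairs, k) per-twin mean (identical for both twins of a pair)."""
        return (
            params["means"][None, :]
            + np.outer(self.age_s, params["beta_age"])
            + np.outer(self.sex, params["beta_sex"])
        )

    def minus2ll(self, x: np.ndarray) -> float:
        params = self.spec.unpack(np.asarray(x, dtype=float))
        moments = implied_moments(self.spec, params)
        mu_tw = self._pair_mu(params)
        d = self.data
        total = 0.0
        for zyg in ("MZ", "DZ"):
            idx = self.idx[f"{zyg}_full"]
            _, sigma = moments[zyg]
            resid = np.hstack([d.y1[idx] - mu_tw[idx], d.y2[idx] - mu_tw[idx]])
            total += _group_m2ll(resid, sigma)
            if total >= _PENALTY:
                return total
        k = d.n_traits
        sigma_within = moments["MZ"][1][:k, :k]
        i1, i2 = self.idx["single1"], self.idx["single2"]
        resid_single = np.vstack([d.y1[i1] - mu_tw[i1], d.y2[i2] - mu_tw[i2]])
        total += _group_m2ll(resid_single, sigma_within)
        return total

    def start_values(self, rng: np.random.Generator | None = None) -> np.ndarray:
        d = self.data
        k = d.n_traits
        stacked = np.vstack([d.y1[d.present1], d.y2[d.present2]])
        mean = stacked.mean(axis=0)
        cov = np.cov(stacked.T).reshape(k, k)
        n_comp = len(self.spec.components)
        share = cov / n_comp
        try:
            L = np.linalg.cholesky(share + 1e-6 * np.eye(k))
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.maximum(np.diag(share), 1e-3)))
        slots = self.spec.free_slots()
        x0 = np.array([L[i, j] for (_, i, j) in slots])
        x0 = np.concatenate([x0, mean])
        if self.spec.covariates:
            x0 = np.concatenate([x0, np.zeros(2 * k)])
        if rng is not None:
            x0 = x0 + rng.normal(scale=0.1 * (np.abs(x0) + 0.05))
        return x0


def fiml_minus2ll(spec: ModelSpec, x: np.ndarray, data: TwinPairDataset) -> float:
    """-2 log-likelihood of ``data`` under ``spec`` at packed parameters ``x``."""
    return _FimlEngine(spec, data).minus2ll(x)


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    spec: object
    x: np.ndarray | None
    params: dict | None
    minus2ll: float
    n_params: int
    n_obs_values: int
    converged: bool = True
    label: str = ""
    implied: dict | None = None
    data: TwinPairDataset | None = None

    @property
    def df(self) -> int:
        return self.n_obs_values - self.n_params

    @property
    def aic(self) -> float:
        return self.minus2ll - 2.0 * self.df

    def summary_row(self) -> dict:
        return {
            "model": self.label,
            "n_params": self.n_params,
            "minus2LL": self.minus2ll,
            "df": self.df,
            "AIC": self.aic,
            "converged": self.converged,
        }

    def to_json(self) -> str:
        payload = self.summary_row()
        if self.params is not None:
            payload["estimates"] = {
                "paths": {c: L.tolist() for c, L in self.params["paths"].items()},
                "means": self.params["means"].tolist(),
                "beta_age": self.params["beta_age"].tolist(),
                "beta_sex": self.params["beta_sex"].tolist(),
            }
        return json.dumps(payload, indent=2)


def fit_statistics(minus2ll: float, n_params: int, n_obs_values: int,
                   label: str = "") -> ModelFit:
    """A ModelFit shell holding externally supplied fit statistics.

    Useful for applying the df / AIC / nested-comparison conventions to fit
    statistics produced elsewhere (e.g. a published model-fitting table).
    """
    return ModelFit(spec=None, x=None, params=None, minus2ll=minus2ll,
                    n_params=n_params, n_obs_values=n_obs_values, label=label)


def _minimize_multistart(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    extra_starts: list[np.ndarray],
    tol_agree: float = 1e-4,
) -> tuple[np.ndarray, float, bool]:
    results = []
    for start in [x0, *extra_starts]:
        res = optimize.minimize(fun, start, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    agree = len(results) == 1 or (results[1].fun - best.fun) < tol_agree
    converged = bool(best.fun < _PENALTY / 2) and agree
    return best.x, float(best.fun), converged


def fit_model(
    spec: ModelSpec,
    data: TwinPairDataset,
    n_restarts: int = 3,
    seed: int = 0,
) -> ModelFit:
    """Fit a genetic twin model by FIML with multi-start quasi-Newton search.

    Non-convergence (restart optima disagreeing beyond 1e-4 in -2LL, or a
    penalized optimum) is reported through the ``converged`` flag rather
    than raised.
    """
    engine = _FimlEngine(spec, data)
    rng = np.random.default_rng(seed)
    x0 = engine.start_values()
    extras = [engine.start_values(rng) for _ in range(n_restarts)]
    x, m2ll, converged = _minimize_multistart(engine.minus2ll, x0, extras)
    params = spec.unpack(x)
    # sign convention: diagonal Cholesky paths non-negative (flip column signs)
    for L in params["paths"].values():
        for j in range(spec.n_traits):
            if L[j, j] < 0:
                L[:, j] *= -1.0
    return ModelFit(
        spec=spec, x=x, params=params, minus2ll=m2ll,
        n_params=spec.n_params, n_obs_values=data.n_obs_values,
        converged=converged, label=spec.label,
        implied=implied_moments(spec, params), data=data,
    )


# ---------------------------------------------------------------------------
# Saturated models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturatedConstraints:
    """Equality constraints applied to the saturated (unrestricted) model.

    The fully saturated model frees means, variances and all correlations
    per twin-order x zygosity cell.  The constrained saturated model used
    for twin correlations equates means, variances and phenotypic
    correlations across twin order and zygosity, and equates the two CTCT
    directions within each zygosity group, leaving the per-zygosity twin and
    CTCT correlations free.
    """

    equal_means_order: bool = False
    equal_means_zygosity: bool = False
    equal_vars_order: bool = False
    equal_vars_zygosity: bool = False
    equal_pheno_corr: bool = False   # phenotypic corr across order and zygosity
    equal_ctct_direction: bool = False  # r(X1,Y2) == r(Y1,X2) within zygosity
    equal_twin_corr_zygosity: bool = False  # MZ == DZ twin/CTCT correlations
    covariates: bool = True

    @classmethod
    def free(cls, covariates: bool = True) -> "SaturatedConstraints":
        return cls(covariates=covariates)

    @classmethod
    def correlations(cls, covariates: bool = True) -> "SaturatedConstraints":
        return cls(equal_means_order=True, equal_means_zygosity=True,
                   equal_vars_order=True, equal_vars_zygosity=True,
                   equal_pheno_corr=True, equal_ctct_direction=True,
                   covariates=covariates)


class _SaturatedEngine:
    """Label-tied parameterization of per-cell means, s.d.s and correlations.

    Every structural slot (a mean for twin t of zygosity z, an s.d., or an
    entry of the 2k x 2k correlation matrix) carries a label; slots with
    equal labels share one free parameter, mirroring how equality
    constraints are declared in structural-equation twin software.
    """

    def __init__(self, data: TwinPairDataset, con: SaturatedConstraints):
        self.data = data
        self.con = con
        self.k = data.n_traits
        self.labels: list[str] = []
        self._index: dict[str, int] = {}
        self.slots: dict[tuple, str] = {}
        self._build_labels()
        self.age_s = data.age_scaled
        p1, p2 = data.present1, data.present2
        mz = data.zygosity == "MZ"
        self.idx = {
            ("MZ", "full"): np.flatnonzero(mz & p1 & p2),
            ("DZ", "full"): np.flatnonzero(~mz & p1 & p2),
            ("MZ", "s1"): np.flatnonzero(mz & p1 & ~p2),
            ("MZ", "s2"): np.flatnonzero(mz & ~p1 & p2),
            ("DZ", "s1"): np.flatnonzero(~mz & p1 & ~p2),
            ("DZ", "s2"): np.flatnonzero(~mz & ~p1 & p2),
        }

    def _lab(self, key: tuple, label: str) -> None:
        self.slots[key] = label
        if label not in self._index:
            self._index[label] = len(self.labels)
            self.labels.append(label)

    def _build_labels(self) -> None:
        k, con = self.k, self.con
        for z in ("MZ", "DZ"):
            zm = "all" if con.equal_means_zygosity else z
            zv = "all" if con.equal_vars_zygosity else z
            for t in (1, 2):
                tm = "x" if con.equal_means_order else t
                tv = "x" if con.equal_vars_order else t
                for j in range(k):
                    self._lab(("mean", z, t, j), f"m|{zm}|{tm}|{j}")
                    self._lab(("sd", z, t, j), f"s|{zv}|{tv}|{j}")
            # within-twin cross-trait correlations
            for t in (1, 2):
                for j in range(k):
                    for l in range(j + 1, k):
                        zp = "all" if con.equal_pheno_corr else z
                        tp = "x" if con.equal_pheno_corr else t
                        self._lab(("rph", z, t, j, l), f"rph|{zp}|{tp}|{j}{l}")
            zc = "all" if con.equal_twin_corr_zygosity else z
            # cross-twin same-trait (twin) correlations
            for j in range(k):
                self._lab(("rtw", z, j), f"rtw|{zc}|{j}")
            # cross-twin cross-trait (CTCT) correlations, both directions
            for j in range(k):
                for l in range(k):
                    if j == l:
                        continue
                    direction = "sym" if con.equal_ctct_direction else f"{j}->{l}"
                    pair = f"{min(j, l)}{max(j, l)}" if con.equal_ctct_direction else f"{j}{l}"
                    self._lab(("rct", z, j, l), f"rct|{zc}|{pair}|{direction}")
        if con.covariates:
            for j in range(self.k):
                self._lab(("bage", j), f"bage|{j}")
                self._lab(("bsex", j), f"bsex|{j}")

    @property
    def n_params(self) -> int:
        return len(self.labels)

    def _get(self, x: np.ndarray, key: tuple) -> float:
        return x[self._index[self.slots[key]]]

    def cell_moments(self, x: np.ndarray, z: str) -> tuple[np.ndarray, np.ndarray]:
        """(2k mean vector, 2k x 2k covariance) for zygosity z, covariates at 0."""
        k = self.k
        mu = np.array([self._get(x, ("mean", z, t, j)) for t in (1, 2) for j in range(k)])
        sd = np.array([self._get(x, ("sd", z, t, j)) for t in (1, 2) for j in range(k)])
        R = np.eye(2 * k)
        for t, off in ((1, 0), (2, k)):
            for j in range(k):
                for l in range(j + 1, k):
                    r = self._get(x, ("rph", z, t, j, l))
                    R[off + j, off + l] = R[off + l, off + j] = r
        for j in range(k):
            r = self._get(x, ("rtw", z, j))
            R[j, k + j] = R[k + j, j] = r
        for j in range(k):
            for l in range(k):
                if j == l:
                    continue
                r = self._get(x, ("rct", z, j, l))
                R[j, k + l] = R[k + l, j] = r
        sigma = R * np.outer(sd, sd)
        return mu, sigma

    def covariate_shift(self, x: np.ndarray) -> np.ndarray:
        """(n_pairs, k) mean shift from age and sex (shared across twins)."""
        if not self.con.covariates:
            return np.zeros((self.data.n_pairs, self.k))
        bage = np.array([self._get(x, ("bage", j)) for j in range(self.k)])
        bsex = np.array([self._get(x, ("bsex", j)) for j in range(self.k)])
        return np.outer(self.age_s, bage) + np.outer(self.data.sex, bsex)

    def minus2ll(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        d, k = self.data, self.k
        shift = self.covariate_shift(x)
        total = 0.0
        for z in ("MZ", "DZ"):
            mu, sigma = self.cell_moments(x, z)
            idx = self.idx[(z, "full")]
            if idx.size:
                resid = np.hstack([d.y1[idx] - shift[idx], d.y2[idx] - shift[idx]]) - mu
                total += _group_m2ll(resid, sigma)
            for key, sl, yarr in ((("s1"), slice(0, k), d.y1), (("s2"), slice(k, 2 * k), d.y2)):
                idx = self.idx[(z, key)]
                if idx.size:
                    resid = yarr[idx] - shift[idx] - mu[sl]
                    total += _group_m2ll(resid, sigma[sl, sl])
            if total >= _PENALTY:
                return total
        return total

    def start_values(self, rng: np.random.Generator | None = None) -> np.ndarray:
        d, k = self.data, self.k
        stacked = np.vstack([d.y1[d.present1], d.y2[d.present2]])
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0, ddof=1)
        x = np.zeros(self.n_params)
        for key, label in self.slots.items():
            i = self._index[label]
            if key[0] == "mean":
                x[i] = mean[key[3]]
            elif key[0] == "sd":
                x[i] = sd[key[3]]
            elif key[0] in ("rph", "rtw", "rct"):
                x[i] = 0.1
        if rng is not None:
            x = x + rng.normal(scale=0.05 * (np.abs(x) + 0.05))
        return x


def fit_saturated(
    data: TwinPairDataset,
    constraints: SaturatedConstraints | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    label: str = "saturated",
) -> ModelFit:
    """Fit a (possibly constraint-reduced) saturated normal model by FIML."""
    con = constraints or SaturatedConstraints.free()
    engine = _SaturatedEngine(data, con)
    rng = np.random.default_rng(seed)
    x0 = engine.start_values()
    extras = [engine.start_values(rng) for _ in range(n_restarts)]
    x, m2ll, converged = _minimize_multistart(engine.minus2ll, x0, extras)
    implied = {z: engine.cell_moments(x, z) for z in ("MZ", "DZ")}
    fit = ModelFit(
        spec=con, x=x, params=None, minus2ll=m2ll,
        n_params=engine.n_params, n_obs_values=data.n_obs_values,
        converged=converged, label=label, implied=implied, data=data,
    )
    fit._engine = engine  # kept for correlation extraction / profiling
    return fit


# ---------------------------------------------------------------------------
# Model comparison and selection
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    full: ModelFit
    nested: ModelFit
    delta_chi2: float
    delta_df: int
    p_value: float

    @property
    def aic_difference(self) -> float:
        return self.nested.aic - self.full.aic

    @property
    def retain_nested(self) -> bool:
        return self.p_value >= 0.05

    def summary_row(self) -> dict:
        return {
            "model": self.nested.label,
            "comparison": self.full.label,
            "delta_chi2": self.delta_chi2,
            "delta_df": self.delta_df,
            "p_value": self.p_value,
            "AIC": self.nested.aic,
            "retained": self.retain_nested,
        }


def compare_models(full: ModelFit, nested: ModelFit, tol: float = 1e-6) -> ComparisonResult:
    """Likelihood-ratio comparison of a nested model against the full model."""
    if nested.n_params >= full.n_params:
        raise ValueError("nested model must have fewer free parameters")
    delta = nested.minus2ll - full.minus2ll
    if delta < -tol:
        raise ValueError(
            f"nested -2LL ({nested.minus2ll:.4f}) below full ({full.minus2ll:.4f}); "
            "models are mis-ordered or the full fit did not converge"
        )
    delta = max(delta, 0.0)
    ddf = full.n_params - nested.n_params
    p = float(stats.chi2.sf(delta, ddf)) if delta > 0 else 1.0
    return ComparisonResult(full=full, nested=nested, delta_chi2=delta,
                            delta_df=ddf, p_value=p)


def select_best(comparisons: Sequence[ComparisonResult]) -> ModelFit:
    """Best-fitting model: the retained (p >= 0.05) nested model with lowest
    AIC; ties break to fewest parameters; the full model if none retained."""
    if not comparisons:
        raise ValueError("no candidate comparisons supplied")
    full = comparisons[0].full
    if any(c.full is not full and c.full.label != full.label for c in comparisons):
        raise ValueError("all comparisons must share the same full model")
    retained = [c for c in comparisons if c.retain_nested]
    if not retained:
        return full
    retained.sort(key=lambda c: (c.nested.aic, c.nested.n_params))
    return retained[0].nested


# ---------------------------------------------------------------------------
# Twin correlations from the constrained saturated model
# ---------------------------------------------------------------------------

def _profile_scan(refit: Callable[[float], float], m2ll_min: float, mle: float,
                  lo: float, hi: float, side: str, tol: float = 5e-4) -> float:
    """Bisection for the parameter value where the profile -2LL crosses
    m2ll_min + chi2_95(1); ``side`` is 'lower' or 'upper'."""
    target = m2ll_min + _CHI2_95_DF1
    bound = lo if side == "lower" else hi
    if refit(bound) <= target:
        return bound
    inner, outer = mle, bound
    for _ in range(60):
        mid = 0.5 * (inner + outer)
        if refit(mid) <= target:
            inner = mid
        else:
            outer = mid
        if abs(outer - inner) < tol:
            break
    return 0.5 * (inner + outer)


def twin_correlations(
    data: TwinPairDataset,
    compute_ci: bool = True,
    seed: int = 0,
    covariates: bool = True,
) -> pd.DataFrame:
    """Per-zygosity twin correlations (and CTCT for two traits) with 95% CIs.

    Derived from the constrained saturated model: means, variances and
    phenotypic correlations equated across twin order and zygosity; CTCT
    directions equated within zygosity; twin and CTCT correlations free per
    zygosity.  CIs are profile-likelihood based.
    """
    con = SaturatedConstraints.correlations(covariates=covariates)
    fit = fit_saturated(data, con, seed=seed, label="constrained saturated")
    engine: _SaturatedEngine = fit._engine
    rows = []
    corr_labels = []
    for z in ("MZ", "DZ"):
        for j in range(data.n_traits):
            corr_labels.append((f"r_{z}", z, data.trait_names[j],
                                engine.slots[("rtw", z, j)]))
        if data.n_traits == 2:
            corr_labels.append((f"r_CTCT_{z}", z, "cross-trait",
                                engine.slots[("rct", z, 0, 1)]))
    for name, z, trait, label in corr_labels:
        i = engine._index[label]
        est = float(fit.x[i])
        lo = hi = np.nan
        if compute_ci:
            def refit(v: float, i=i) -> float:
                x0 = fit.x.copy()
                x0[i] = v
                free = [j for j in range(len(x0)) if j != i]

                def obj(sub: np.ndarray) -> float:
                    xx = x0.copy()
                    xx[free] = sub
                    return engine.minus2ll(xx)

                res = optimize.minimize(obj, x0[free], method="L-BFGS-B",
                                        options={"maxiter": 500, "ftol": 1e-10})
                return float(res.fun)

            lo = _profile_scan(refit, fit.minus2ll, est, -0.999, 0.999, "lower")
            hi = _profile_scan(refit, fit.minus2ll, est, -0.999, 0.999, "upper")
        rows.append({"correlation": name, "zygosity": z, "trait": trait,
                     "estimate": est, "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardized components and profile CIs
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    trait_names: tuple[str, ...]
    components: pd.DataFrame       # rows: trait x component, standardized
    bivariate: dict | None = None  # shared/unique splits, r_A, r_Ph
    cis: pd.DataFrame | None = None


def standardize_components(fit: ModelFit) -> VarianceDecomposition:
    """Standardize fitted paths to proportions of phenotypic variance.

    Per trait, each component's standardized share is its implied variance
    over the total.  For a bivariate Cholesky, the trait-2 additive-genetic
    variance is split into the part transmitted through the trait-1 factor
    (shared, a21^2 / V2) and the trait-2-specific part (unique, a22^2 / V2),
    with the analogous split for E (and C/D when present); the genetic
    correlation and the implied phenotypic correlation are also reported.
    """
    if fit.params is None:
        raise ValueError("standardize_components requires a parameterized fit")
    spec: ModelSpec = fit.spec
    cov = _component_covariances(fit.params["paths"])
    k = spec.n_traits
    totals = sum(cov.values())
    tv = np.diag(totals)
    if np.any(tv <= 0):
        raise ValueError("zero total implied variance")
    rows = []
    for j in range(k):
        for comp, M in cov.items():
            rows.append({"trait": fit.data.trait_names[j] if fit.data is not None
                         else f"trait{j + 1}",
                         "component": comp, "standardized": M[j, j] / tv[j]})
    comp_df = pd.DataFrame(rows)
    bivar = None
    if k == 2:
        bivar = {}
        for comp, L in fit.params["paths"].items():
            bivar[f"shared_{comp}"] = L[1, 0] ** 2 / tv[1]
            bivar[f"unique_{comp}"] = L[1, 1] ** 2 / tv[1]
        A = cov.get("A")
        if A is not None and A[0, 0] > 0 and A[1, 1] > 0:
            bivar["r_A"] = A[0, 1] / np.sqrt(A[0, 0] * A[1, 1])
        bivar["r_Ph"] = totals[0, 1] / np.sqrt(tv[0] * tv[1])
    return VarianceDecomposition(
        trait_names=fit.data.trait_names if fit.data is not None
        else tuple(f"trait{j + 1}" for j in range(k)),
        components=comp_df, bivariate=bivar,
    )


def _standardized_value(spec: ModelSpec, x: np.ndarray, component: str,
                        trait: int) -> float:
    params = spec.unpack(x)
    cov = _component_covariances(params["paths"])
    tv = sum(M[trait, trait] for M in cov.values())
    return cov[component][trait, trait] / tv


def profile_ci(
    fit: ModelFit,
    component: str,
    trait: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """95% profile-likelihood CI for a standardized variance component.

    The interval is the set of values v for which refitting all other
    parameters subject to (component share for this trait) == v raises the
    -2LL by at most the chi-square(1) 95% critical value.  Bounds are
    clipped to [0, 1].
    """
    if fit.params is None or fit.data is None:
        raise ValueError("profile_ci requires a fitted parameterized model")
    spec: ModelSpec = fit.spec
    engine = _FimlEngine(spec, fit.data)
    mle = _standardized_value(spec, fit.x, component, trait)

    def feasible_start(v: float) -> np.ndarray:
        """Rescale the component's paths for this trait so the standardized
        share equals v (the constraint gradient vanishes at a zero path, so
        the constrained search must not start on that boundary)."""
        params = spec.unpack(fit.x.copy())
        cov = _component_covariances(params["paths"])
        c_cur = cov[component][trait, trait]
        other = sum(M[trait, trait] for M in cov.values()) - c_cur
        c_new = v / (1.0 - v) * other if v < 1.0 else other * 1e6
        L = params["paths"][component]
        if c_cur > 1e-12:
            L[trait, : trait + 1] *= np.sqrt(c_new / c_cur)
        else:
            L[trait, trait] = np.sqrt(c_new)
        return spec.pack(params)

    def refit(v: float) -> float:
        cons = {"type": "eq",
                "fun": lambda x: _standardized_value(spec, x, component, trait) - v}
        res = optimize.minimize(engine.minus2ll, feasible_start(v),
                                method="SLSQP", constraints=[cons],
                                options={"maxiter": 400, "ftol": 1e-10})
        if not np.isfinite(res.fun):
            return _PENALTY
        if abs(_standardized_value(spec, res.x, component, trait) - v) > 1e-4:
            return _PENALTY  # constraint not met: treat as outside the region
        return float(res.fun)

    lo = _profile_scan(refit, fit.minus2ll, mle, 0.0, 1.0, "lower", tol=1e-3)
    hi = _profile_scan(refit, fit.minus2ll, mle, 0.0, 1.0, "upper", tol=1e-3)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
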