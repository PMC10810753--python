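"""FIML twin-model engine: moments, likelihood, fitting, comparison, CIs."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.stats import multivariate_normal

import twinlook as tl
from twinlook.twinmodels import ModelSpec, SaturatedConstraints, _FimlEngine

LN2PI = np.log(2 * np.pi)


def _std_component(fit, comp, trait=0):
    df = tl.standardize_components(fit).components
    sel = (df["component"] == comp) & (df["trait"] == df["trait"].unique()[trait])
    return float(df.loc[sel, "standardized"].iloc[0])


# ---------------------------------------------------------------------------
# Implied moments
# ---------------------------------------------------------------------------

def test_univariate_ae_implied_moments():
    spec = ModelSpec(1, "AE", covariates=False)
    x = np.array([np.sqrt(0.46), np.sqrt(0.54), 0.0])  # a, e, mean
    mom = tl.implied_moments(spec, spec.unpack(x))
    assert mom["MZ"][1][0, 1] == pytest.approx(0.46)
    assert mom["DZ"][1][0, 1] == pytest.approx(0.23)
    assert mom["MZ"][1][0, 0] == pytest.approx(1.0)


def test_e_only_moments_are_block_diagonal():
    spec = ModelSpec(1, "E", covariates=False)
    mom = tl.implied_moments(spec, spec.unpack(np.array([1.3, 0.0])))
    for zyg in ("MZ", "DZ"):
        assert mom[zyg][1][0, 1] == 0.0


def test_bivariate_moments_match_independent_assembly():
    spec = ModelSpec(2, "ACE", covariates=False)
    rng = np.random.default_rng(0)
    x = rng.normal(0.3, 0.3, spec.n_params)
    params = spec.unpack(x)
    mom = tl.implied_moments(spec, params)
    w = {"MZ": {"A": 1.0, "C": 1.0}, "DZ": {"A": 0.5, "C": 1.0}}
    for zyg in ("MZ", "DZ"):
        cov = {c: params["paths"][c] @ params["paths"][c].T for c in "ACE"}
        within = cov["A"] + cov["C"] + cov["E"]
        cross = w[zyg]["A"] * cov["A"] + w[zyg]["C"] * cov["C"]
        expected = np.block([[within, cross], [cross.T, within]])
        np.testing.assert_allclose(mom[zyg][1], expected, atol=1e-12)


@pytest.mark.parametrize("components", ["ACE", "ADE", "AE", "E"])
def test_implied_covariances_are_psd_for_random_paths(components):
    spec = ModelSpec(2, components, covariates=False)
    rng = np.random.default_rng(1)
    for _ in range(50):
        params = spec.unpack(rng.normal(0, 1, spec.n_params))
        mom = tl.implied_moments(spec, params)
        for zyg in ("MZ", "DZ"):
            assert np.linalg.eigvalsh(mom[zyg][1]).min() >= -1e-10


def test_spec_rejects_c_and_d_together():
    with pytest.raises(ValueError, match="not jointly identified"):
        ModelSpec(1, "ACDE")
    with pytest.raises(ValueError, match="mandatory"):
        ModelSpec(1, "AC")


# ---------------------------------------------------------------------------
# FIML likelihood
# ---------------------------------------------------------------------------

def test_single_pair_identity_covariance_closed_form():
    spec = ModelSpec(1, "E", covariates=False)
    ds = tl.TwinPairDataset(y1=[[0.0]], y2=[[0.0]], zygosity=["MZ"],
                            age_days=[168.0], sex=[0.0])
    x = np.array([1.0, 0.0])  # unit E path, zero mean -> Sigma = I2
    assert tl.fiml_minus2ll(spec, x, ds) == pytest.approx(2 * LN2PI)


def test_fiml_matches_density_oracle_with_absent_twin():
    spec = ModelSpec(2, "ACE")
    rng = np.random.default_rng(4)
    x = rng.normal(0.3, 0.4, spec.n_params)
    ds = tl.TwinPairDataset(
        y1=rng.normal(0, 1, (5, 2)),
        y2=np.vstack([rng.normal(0, 1, (4, 2)), [np.nan, np.nan]]),
        zygosity=np.array(["MZ", "DZ", "MZ", "DZ", "MZ"]),
        age_days=rng.normal(168, 9, 5), sex=np.array([0, 1, 1, 0, 1.0]))
    params = spec.unpack(x)
    mom = tl.implied_moments(spec, params)
    age_s = ds.age_scaled
    total = 0.0
    for i in range(5):
        mu_t = (params["means"] + params["beta_age"] * age_s[i]
                + params["beta_sex"] * ds.sex[i])
        mu = np.concatenate([mu_t, mu_t])
        sigma = mom[ds.zygosity[i]][1]
        if np.isnan(ds.y2[i]).all():
            # marginalizing the absent twin = dropping their rows/columns
            total += -2 * multivariate_normal.logpdf(ds.y1[i], mu[:2],
                                                     sigma[:2, :2])
        else:
            obs = np.concatenate([ds.y1[i], ds.y2[i]])
            total += -2 * multivariate_normal.logpdf(obs, mu, sigma)
    assert tl.fiml_minus2ll(spec, x, ds) == pytest.approx(total, abs=1e-8)


def test_fit_optimum_matches_grid_oracle_on_toy_data():
    """On a 6-pair toy dataset the AE optimum equals a dense profile grid
    over (a, e) with the mean concentrated out in closed form (GLS)."""
    spec = ModelSpec(1, "AE", covariates=False)
    rng = np.random.default_rng(6)
    ds = tl.TwinPairDataset(
        y1=rng.normal(0.2, 1, (6, 1)), y2=rng.normal(0.2, 1, (6, 1)),
        zygosity=np.array(["MZ"] * 3 + ["DZ"] * 3),
        age_days=np.full(6, 168.0), sex=np.zeros(6))
    fit = tl.fit_model(spec, ds)

    def oracle(a, e):
        m2 = 0.0
        ys = np.hstack([ds.y1, ds.y2])
        num = den = 0.0
        sigmas = {}
        for zyg, wa in (("MZ", 1.0), ("DZ", 0.5)):
            v = a * a + e * e
            c = wa * a * a
            sigmas[zyg] = np.array([[v, c], [c, v]])
        for i in range(6):
            si = np.linalg.inv(sigmas[ds.zygosity[i]])
            one = np.ones(2)
            num += one @ si @ ys[i]
            den += one @ si @ one
        mu = num / den
        for i in range(6):
            s = sigmas[ds.zygosity[i]]
            r = ys[i] - mu
            m2 += (2 * LN2PI + np.log(np.linalg.det(s))
                   + r @ np.linalg.inv(s) @ r)
        return m2

    grid_a = np.linspace(0.0, 1.5, 120)
    grid_e = np.linspace(0.05, 1.5, 120)
    vals = np.array([[oracle(a, e) for e in grid_e] for a in grid_a])
    ia, ie = np.unravel_index(np.argmin(vals), vals.shape)
    # refine around the coarse grid minimum
    res = optimize.minimize(lambda p: oracle(*p), [grid_a[ia], grid_e[ie]],
                            method="Nelder-Mead", options={"xatol": 1e-8})
    assert fit.minus2ll == pytest.approx(res.fun, abs=1e-3)


# ---------------------------------------------------------------------------
# Model fitting and recovery
# ---------------------------------------------------------------------------

def test_fit_recovers_generating_heritability(ae_dataset):
    fit = tl.fit_model(ModelSpec(1, "AE", name="AE"), ae_dataset)
    assert fit.converged
    assert _std_component(fit, "A") == pytest.approx(0.46, abs=0.05)


def test_null_data_yield_near_zero_a_and_c():
    spec = tl.GenerativeSpec.univariate(a2=0.0, c2=0.0)
    ds = tl.simulate_twin_phenotypes(spec, 2000, 2000, 0.0, seed=8)
    fit = tl.fit_model(ModelSpec(1, "ACE"), ds)
    assert _std_component(fit, "A") < 0.05
    assert _std_component(fit, "C") < 0.05


@pytest.mark.parametrize("a2,c2", [(0.46, 0.0), (0.2, 0.3), (0.0, 0.4)])
def test_parameter_recovery_across_ace_grid(a2, c2):
    spec = tl.GenerativeSpec.univariate(a2=a2, c2=c2)
    ds = tl.simulate_twin_phenotypes(spec, 4000, 4000, 0.0, seed=9)
    fit = tl.fit_model(ModelSpec(1, "ACE"), ds)
    err = (abs(_std_component(fit, "A") - a2)
           + abs(_std_component(fit, "C") - c2)
           + abs(_std_component(fit, "E") - (1 - a2 - c2))) / 3
    assert err < 0.03


def test_c_only_data_give_equal_mz_dz_and_a_only_double(small_mixed_dataset):
    c_spec = tl.GenerativeSpec.univariate(a2=0.0, c2=0.5)
    ds = tl.simulate_twin_phenotypes(c_spec, 3000, 3000, 0.0, seed=10)
    mz = np.corrcoef(ds.y1[ds.zygosity == "MZ", 0], ds.y2[ds.zygosity == "MZ", 0])[0, 1]
    dz = np.corrcoef(ds.y1[ds.zygosity == "DZ", 0], ds.y2[ds.zygosity == "DZ", 0])[0, 1]
    assert mz == pytest.approx(dz, abs=0.05)
    a_spec = tl.GenerativeSpec.univariate(a2=0.5, c2=0.0)
    ds = tl.simulate_twin_phenotypes(a_spec, 3000, 3000, 0.0, seed=11)
    mz = np.corrcoef(ds.y1[ds.zygosity == "MZ", 0], ds.y2[ds.zygosity == "MZ", 0])[0, 1]
    dz = np.corrcoef(ds.y1[ds.zygosity == "DZ", 0], ds.y2[ds.zygosity == "DZ", 0])[0, 1]
    assert mz == pytest.approx(2 * dz, abs=0.06)


def test_nesting_monotonicity_and_fit_identities(small_mixed_dataset):
    ds = small_mixed_dataset
    chain = [ModelSpec(1, "ACE", name="ACE"), ModelSpec(1, "AE", name="AE"),
             ModelSpec(1, "E", name="E")]
    fits = [tl.fit_model(s, ds) for s in chain]
    m2lls = [f.minus2ll for f in fits]
    assert m2lls == sorted(m2lls)  # dropping parameters never improves fit
    for f in fits:
        assert len(f.x) == f.n_params
        assert f.df == ds.n_obs_values - f.n_params
        assert f.aic == pytest.approx(f.minus2ll - 2 * f.df)


def test_fiml_estimates_unaffected_by_how_missing_twin_is_encoded():
    """Dropping an absent co-twin's rows must equal analytic marginalization:
    fitting with singles present equals fitting where those singles'
    contribution is the univariate marginal density."""
    spec_g = tl.GenerativeSpec.univariate(a2=0.4, c2=0.1)
    ds = tl.simulate_twin_phenotypes(spec_g, 400, 400, 0.25, seed=12)
    spec = ModelSpec(1, "ACE", covariates=False)
    engine = _FimlEngine(spec, ds)
    x = np.array([0.6, 0.3, 0.7, 0.1])

    mom = tl.implied_moments(spec, spec.unpack(x))
    total = 0.0
    for i in range(ds.n_pairs):
        sigma = mom[ds.zygosity[i]][1]
        mu = mom[ds.zygosity[i]][0]
        p1, p2 = ds.present1[i], ds.present2[i]
        if p1 and p2:
            obs = np.array([ds.y1[i, 0], ds.y2[i, 0]])
            total += -2 * multivariate_normal.logpdf(obs, mu, sigma)
        else:
            yv = ds.y1[i, 0] if p1 else ds.y2[i, 0]
            total += -2 * stats.norm.logpdf(yv, mu[0], np.sqrt(sigma[0, 0]))
    assert engine.minus2ll(x) == pytest.approx(total, abs=1e-8)


# ---------------------------------------------------------------------------
# Saturated models
# ---------------------------------------------------------------------------

def test_saturated_reproduces_sample_moments_exactly():
    spec_g = tl.GenerativeSpec.bivariate_ae(0.3, 0.1, 0.2, 0.9)
    ds = tl.simulate_twin_phenotypes(spec_g, 120, 110, 0.0, seed=13)
    fit = tl.fit_saturated(ds, SaturatedConstraints.free(covariates=False))
    for zyg in ("MZ", "DZ"):
        sel = ds.zygosity == zyg
        y = np.hstack([ds.y1[sel], ds.y2[sel]])
        mu_hat, sigma_hat = fit.implied[zyg]
        np.testing.assert_allclose(mu_hat, y.mean(axis=0), atol=5e-3)
        np.testing.assert_allclose(sigma_hat, np.cov(y.T, ddof=0), atol=2e-2)


def test_fully_saturated_bivariate_parameter_count_and_df():
    # two traits on 536 infants: 1072 data points, 32 free parameters
    spec_g = tl.GenerativeSpec.bivariate_ae(0.2, 0.1, 0.3, 0.9)
    ds = tl.simulate_twin_phenotypes(spec_g, 150, 118, 0.0, seed=14)
    assert ds.n_obs_values == 1072
    fit = tl.fit_saturated(ds, SaturatedConstraints.free(covariates=True))
    assert fit.n_params == 32
    assert fit.df == 1040


def test_injected_twin_order_effect_detected_by_constraint():
    spec_g = tl.GenerativeSpec.univariate(a2=0.3)
    ds = tl.simulate_twin_phenotypes(spec_g, 150, 150, 0.0, seed=15)
    ds.y2 = ds.y2 + 0.5  # twin-order mean shift
    free = tl.fit_saturated(ds, SaturatedConstraints.free(covariates=False))
    con = tl.fit_saturated(
        ds, SaturatedConstraints(equal_means_order=True, covariates=False))
    cmp = tl.compare_models(free, con)
    assert cmp.delta_chi2 > 10
    assert cmp.p_value < 0.001


# ---------------------------------------------------------------------------
# Model comparison and selection
# ---------------------------------------------------------------------------

def test_comparison_requires_fewer_parameters_and_ordering():
    full = tl.fit_statistics(100.0, 10, 500)
    nested = tl.fit_statistics(99.0, 8, 500)
    with pytest.raises(ValueError, match="mis-ordered"):
        tl.compare_models(full, nested)
    with pytest.raises(ValueError, match="fewer"):
        tl.compare_models(nested, full)


def test_identical_fits_compare_as_null():
    full = tl.fit_statistics(100.0, 10, 500, "full")
    nested = tl.fit_statistics(100.0, 8, 500, "nested")
    cmp = tl.compare_models(full, nested)
    assert cmp.delta_chi2 == 0.0
    assert cmp.p_value == 1.0


def test_select_best_reproduces_published_style_selection():
    ace = tl.fit_statistics(1167.82, 15, 1072, "ACE")
    ae = tl.fit_statistics(1169.33, 12, 1072, "AE")
    ce = tl.fit_statistics(1175.34, 12, 1072, "CE")
    e = tl.fit_statistics(1211.82, 9, 1072, "E")
    comps = [tl.compare_models(ace, m) for m in (ae, ce, e)]
    assert comps[0].p_value == pytest.approx(0.680, abs=0.001)
    assert comps[1].p_value == pytest.approx(0.057, abs=0.001)
    assert comps[2].p_value < 0.001
    assert tl.select_best(comps).label == "AE"


def test_select_best_falls_back_to_full_and_breaks_ties():
    full = tl.fit_statistics(100.0, 10, 500, "full")
    bad = tl.fit_statistics(150.0, 8, 500, "bad")
    assert tl.select_best([tl.compare_models(full, bad)]).label == "full"
    # equal AIC: fewer parameters wins
    n1 = tl.fit_statistics(102.0, 9, 500, "n1")   # AIC = 102 - 2*491
    n2 = tl.fit_statistics(100.0, 8, 500, "n2")   # AIC = 100 - 2*492 (lower)
    picked = tl.select_best([tl.compare_models(full, n) for n in (n1, n2)])
    assert picked.label == "n2"
    with pytest.raises(ValueError, match="candidate"):
        tl.select_best([])


# ---------------------------------------------------------------------------
# Twin correlations
# ---------------------------------------------------------------------------

def test_duplicate_twin_data_give_mz_correlation_near_one():
    rng = np.random.default_rng(16)
    y = rng.normal(0, 1, (60, 1))
    ds = tl.TwinPairDataset(y1=y, y2=y.copy(),
                            zygosity=np.array(["MZ"] * 30 + ["DZ"] * 30),
                            age_days=np.full(60, 168.0),
                            sex=np.zeros(60))
    tc = tl.twin_correlations(ds, compute_ci=False)
    r_mz = tc.loc[tc["zygosity"] == "MZ", "estimate"].iloc[0]
    assert r_mz > 0.97


def test_twin_correlations_match_double_entry_pearson(ae_dataset):
    # pooled-variance ML and per-group double entry agree to O(1/sqrt(n))
    sub = ae_dataset
    tc = tl.twin_correlations(sub, compute_ci=False, covariates=False)
    for zyg in ("MZ", "DZ"):
        sel = sub.zygosity == zyg
        a, b = sub.y1[sel, 0], sub.y2[sel, 0]
        double_entry = np.corrcoef(np.concatenate([a, b]),
                                   np.concatenate([b, a]))[0, 1]
        est = tc.loc[tc["zygosity"] == zyg, "estimate"].iloc[0]
        assert est == pytest.approx(double_entry, abs=0.01)


# ---------------------------------------------------------------------------
# Standardized components and profile CIs
# ---------------------------------------------------------------------------

def test_standardized_share_from_raw_paths():
    spec = ModelSpec(1, "AE", covariates=False)
    x = np.array([0.6, 0.8, 0.0])
    fit = tl.ModelFit(spec=spec, x=x, params=spec.unpack(x), minus2ll=0.0,
                      n_params=3, n_obs_values=10)
    dec = tl.standardize_components(fit)
    a2 = dec.components.loc[dec.components["component"] == "A",
                            "standardized"].iloc[0]
    assert a2 == pytest.approx(0.36)


def test_bivariate_split_identity_for_random_fits():
    spec = ModelSpec(2, "AE", covariates=False)
    rng = np.random.default_rng(17)
    for _ in range(20):
        x = rng.normal(0.4, 0.3, spec.n_params)
        fit = tl.ModelFit(spec=spec, x=x, params=spec.unpack(x), minus2ll=0.0,
                          n_params=spec.n_params, n_obs_values=10)
        dec = tl.standardize_components(fit)
        a2_t2 = dec.components.loc[
            (dec.components["component"] == "A")
            & (dec.components["trait"] == "trait2"), "standardized"].iloc[0]
        assert dec.bivariate["shared_A"] + dec.bivariate["unique_A"] == \
            pytest.approx(a2_t2, abs=1e-6)


def test_implied_phenotypic_correlation_from_printed_components():
    gen = tl.GenerativeSpec.bivariate_ae(0.19, 0.16, 0.29, 0.97)
    r_ph = gen.implied_covariance("MZ")[0, 1]
    assert r_ph == pytest.approx(0.30, abs=0.02)


def test_profile_ci_matches_grid_scan_and_covers_truth():
    spec_g = tl.GenerativeSpec.univariate(a2=0.46)
    ds = tl.simulate_twin_phenotypes(spec_g, 120, 100, 0.0, seed=18)
    fit = tl.fit_model(ModelSpec(1, "AE", covariates=False), ds)
    lo, hi = tl.profile_ci(fit, "A")
    assert lo <= 0.46 <= hi
    assert 0.0 <= lo < hi <= 1.0

    # independent grid oracle: refit (total variance, mean) at fixed a2 = v
    def constrained_m2ll(v):
        engine = _FimlEngine(ModelSpec(1, "AE", covariates=False), ds)

        def obj(p):
            logv, mu = p
            V = np.exp(logv)
            a = np.sqrt(v * V)
            e = np.sqrt((1 - v) * V)
            return engine.minus2ll(np.array([a, e, mu]))

        return optimize.minimize(obj, [0.0, 0.0], method="Nelder-Mead",
                                 options={"xatol": 1e-7, "fatol": 1e-9}).fun

    target = fit.minus2ll + stats.chi2.ppf(0.95, 1)
    grid = np.linspace(0.01, 0.99, 197)
    prof = np.array([constrained_m2ll(v) for v in grid])
    inside = grid[prof <= target]
    assert lo == pytest.approx(inside.min(), abs=0.02)
    assert hi == pytest.approx(inside.max(), abs=0.02)


def test_profile_ci_component_at_zero_hits_boundary():
    spec_g = tl.GenerativeSpec.univariate(a2=0.0, c2=0.0)
    ds = tl.simulate_twin_phenotypes(spec_g, 150, 150, 0.0, seed=19)
    fit = tl.fit_model(ModelSpec(1, "AE", covariates=False), ds)
    lo, hi = tl.profile_ci(fit, "A")
    assert lo == pytest.approx(0.0, abs=1e-6)
    assert hi < 0.35
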