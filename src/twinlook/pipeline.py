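"""End-to-end orchestration: simulate -> extract -> adjust -> describe ->
twin models -> associations, with per-stage artifacts on disk."""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, gaze, io, synthetic, twinmodels
from .config import PipelineConfig
from .scenes import default_scenes, scenes_to_yaml

log = logging.getLogger("twinlook")

TRAITS = ["face_orienting", "face_preference", "exploration"]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent per-stage substreams below 2**31, derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _descriptives(pheno: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in ["age_days", "n_valid_trials", "mean_prop_missing", *TRAITS]:
        v = pheno[col].dropna().to_numpy(dtype=float)
        rows.append({
            "measure": col, "n": len(v), "mean": v.mean(),
            "sd": v.std(ddof=1), "min": v.min(), "max": v.max(),
            "skewness": assoc.skewness(v),
        })
    return pd.DataFrame(rows)


def _univariate_stage(dataset: twinmodels.TwinPairDataset, seed: int,
                      compute_cis: bool) -> dict:
    full = twinmodels.fit_model(
        twinmodels.ModelSpec(1, "ACE", name="ACE"), dataset, seed=seed)
    nested = {
        "AE": twinmodels.ModelSpec(1, "ACE", fixed_zero=(("C", 0, 0),), name="AE"),
        "CE": twinmodels.ModelSpec(1, "ACE", fixed_zero=(("A", 0, 0),), name="CE"),
        "E": twinmodels.ModelSpec(1, "ACE", fixed_zero=(("A", 0, 0), ("C", 0, 0)),
                                  name="E"),
    }
    fits = {"ACE": full}
    comparisons = []
    for name, spec in nested.items():
        fit = twinmodels.fit_model(spec, dataset, seed=seed)
        fits[name] = fit
        comparisons.append(twinmodels.compare_models(full, fit))
    best = twinmodels.select_best(comparisons)
    decomp = twinmodels.standardize_components(best)
    cis = {}
    if compute_cis:
        for comp in best.spec.components:
            free = {c for (c, _, _) in getattr(best.spec, "fixed_zero", ())}
            if comp in free:
                continue
            cis[comp] = twinmodels.profile_ci(best, comp)
    return {"fits": fits, "comparisons": comparisons, "best": best,
            "decomposition": decomp, "cis": cis}


def _bivariate_stage(dataset: twinmodels.TwinPairDataset, seed: int) -> dict:
    sat = twinmodels.fit_saturated(
        dataset, twinmodels.SaturatedConstraints.free(), seed=seed,
        label="fully saturated")
    full = twinmodels.fit_model(
        twinmodels.ModelSpec(2, "ACE", name="ACE"), dataset, seed=seed)
    nested_specs = {
        "AE": twinmodels.ModelSpec(
            2, "ACE", fixed_zero=(("C", 0, 0), ("C", 1, 0), ("C", 1, 1)),
            name="AE"),
        "CE": twinmodels.ModelSpec(
            2, "ACE", fixed_zero=(("A", 0, 0), ("A", 1, 0), ("A", 1, 1)),
            name="CE"),
        "E": twinmodels.ModelSpec(
            2, "ACE", fixed_zero=(("A", 0, 0), ("A", 1, 0), ("A", 1, 1),
                                  ("C", 0, 0), ("C", 1, 0), ("C", 1, 1)),
            name="E"),
    }
    fits = {"fully saturated": sat, "ACE": full}
    comparisons = []
    for name, spec in nested_specs.items():
        fit = twinmodels.fit_model(spec, dataset, seed=seed)
        fits[name] = fit
        comparisons.append(twinmodels.compare_models(full, fit))
    best = twinmodels.select_best(comparisons)
    decomp = twinmodels.standardize_components(best)
    return {"fits": fits, "comparisons": comparisons, "best": best,
            "decomposition": decomp}


def run_pipeline(config: PipelineConfig, compute_cis: bool = False) -> dict:
    """Execute the full chain and write per-stage CSV/JSON artifacts plus a
    human-readable report under ``config.out_dir``.

    Any stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict = {"seeds": seeds}
    stage = "configure"
    try:
        config.to_yaml(out / "config.yaml")

        stage = "simulate"
        spec = synthetic.GenerativeSpec.bivariate_ae(
            config.gen_a11_sq, config.gen_shared_a_sq,
            config.gen_unique_a_sq, config.gen_unique_e_share)
        pedigree = synthetic.simulate_twin_pedigree(
            spec, config.n_mz, config.n_dz, config.incomplete_rate, seeds[0])
        scenes = default_scenes()
        scenes_to_yaml(scenes, out / "scenes.yaml")
        gaze_df, truth = synthetic.simulate_gaze_cohort(
            pedigree, config.gaze, scenes, seeds[1])
        io.write_gaze_csv(gaze_df, out / "gaze.csv")
        io.write_table_csv(truth, out / "truth.csv")
        n_present = int(pedigree.table["present"].sum())
        log.info("simulated %d infants (%d MZ + %d DZ pairs)",
                 n_present, config.n_mz, config.n_dz)

        stage = "extract"
        meta = pedigree.present_infants()[
            ["infant_id", "pair_id", "zygosity", "twin_order", "sex", "age_days"]]
        pheno, qc = gaze.process_cohort(gaze_df, scenes, config.extraction,
                                        meta=meta)
        io.write_table_csv(qc, out / "trial_qc.csv")
        n_invalid = int((~qc["valid"]).sum())
        log.info("extraction: %d/%d trials invalid; %d of %d infants retained "
                 "(>=%d valid trials)", n_invalid, len(qc), len(pheno),
                 qc["infant_id"].nunique(), config.extraction.min_valid_trials)

        stage = "quality-adjust"
        pheno, adj_log = gaze.regress_out_quality(pheno, TRAITS)
        io.write_phenotypes_csv(pheno, out / "phenotypes.csv")
        io.write_table_csv(adj_log, out / "quality_adjustment.csv")
        for _, row in adj_log.iterrows():
            log.info("quality adjustment: %s %s (min p = %.3g)", row["trait"],
                     "residualized" if row["adjusted"] else "unchanged",
                     row["min_quality_p"])

        stage = "descriptives"
        desc = _descriptives(pheno)
        io.write_table_csv(desc, out / "descriptives.csv")
        chance_rows = []
        for trait in ("face_orienting", "face_preference"):
            for order in (1, 2):
                vals = pheno.loc[pheno["twin_order"] == order, trait].dropna()
                res = assoc.test_against_chance(vals, config.chance_level)
                chance_rows.append({"measure": trait, "twin_order": order,
                                    **asdict(res)})
        chance = pd.DataFrame(chance_rows)
        io.write_table_csv(chance, out / "chance_tests.csv")

        stage = "twin-datasets"
        df = pheno.copy()
        if config.standardize_phenotypes:
            for t in TRAITS:
                df[t] = (df[t] - df[t].mean()) / df[t].std(ddof=0)
        dataset3 = twinmodels.TwinPairDataset.from_dataframe(df, TRAITS)

        stage = "twin-correlations"
        corr_parts = []
        for j, trait in enumerate(TRAITS):
            tc = twinmodels.twin_correlations(
                dataset3.select_traits([j]), compute_ci=compute_cis,
                seed=seeds[2])
            corr_parts.append(tc.assign(measure=trait))
        corr = pd.concat(corr_parts, ignore_index=True)
        io.write_table_csv(corr, out / "twin_correlations.csv")

        stage = "fit-univariate"
        uni = {}
        for j, trait in enumerate(TRAITS):
            uni[trait] = _univariate_stage(dataset3.select_traits([j]),
                                           seeds[3], compute_cis)
            io.write_table_csv(
                pd.DataFrame([c.summary_row() for c in uni[trait]["comparisons"]]),
                out / f"univariate_{trait}_comparisons.csv")
        artifacts["univariate"] = uni

        stage = "fit-bivariate"
        dataset2 = dataset3.select_traits([0, 1])
        biv = _bivariate_stage(dataset2, seeds[4])
        rows = [f.summary_row() for f in biv["fits"].values()]
        rows_cmp = [c.summary_row() for c in biv["comparisons"]]
        io.write_table_csv(pd.DataFrame(rows), out / "bivariate_fits.csv")
        io.write_table_csv(pd.DataFrame(rows_cmp),
                           out / "bivariate_comparisons.csv")
        io.write_fit_json(biv["best"], out / "bivariate_best.json")
        artifacts["bivariate"] = biv

        stage = "associate"
        outcome_df = synthetic.simulate_outcomes(
            pheno.dropna(subset=TRAITS), beta=config.outcome_beta,
            predictor="face_preference", seed=seeds[5],
            pair_corr=config.outcome_pair_corr, outcome_name="outcome")
        gee = assoc.gee_fit(outcome_df, "outcome", TRAITS,
                            covariates=("age_days", "sex"), cluster="pair_id")
        fam = gee.table[gee.table["predictor"] != "intercept"].copy()
        flags = assoc.fdr_stepup(fam["p"].to_numpy(), config.fdr_q)
        fam["fdr_threshold"] = flags["fdr_threshold"].to_numpy()
        fam["significant"] = flags["significant"].to_numpy()
        io.write_table_csv(fam, out / "associations.csv")
        artifacts["gee"] = gee

        stage = "report"
        artifacts.update({"pheno": pheno, "descriptives": desc,
                          "chance": chance, "correlations": corr,
                          "associations": fam})
        _write_report(out / "report.txt", config, desc, chance, corr, uni,
                      biv, fam, gee)
    except Exception as err:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return artifacts


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def _write_report(path, config, desc, chance, corr, uni, biv, fam, gee) -> None:
    lines = []
    w = lines.append
    w("twin analysis of infant preferential looking — pipeline report")
    w(f"seed: {config.seed}; pairs: {config.n_mz} MZ + {config.n_dz} DZ; "
      f"chance level: {_fmt(config.chance_level)}")
    w("")
    w("== descriptives (per measure) ==")
    w(desc.to_string(index=False, float_format=_fmt))
    w("")
    w("== tests against chance ==")
    w(chance[["measure", "twin_order", "test", "statistic", "p", "d",
              "ci_lower", "ci_upper"]].to_string(index=False, float_format=_fmt))
    w("")
    w("== twin correlations (constrained saturated) ==")
    w(corr.to_string(index=False, float_format=_fmt))
    w("")
    for trait, res in uni.items():
        w(f"== univariate model comparison: {trait} ==")
        w(pd.DataFrame([c.summary_row() for c in res["comparisons"]])
          .to_string(index=False, float_format=_fmt))
        w(f"selected: {res['best'].label}")
        w(res["decomposition"].components.to_string(index=False,
                                                    float_format=_fmt))
        for comp, (lo, hi) in res.get("cis", {}).items():
            w(f"  95% CI {comp}: [{_fmt(lo)}, {_fmt(hi)}]")
        w("")
    w("== bivariate Cholesky (orienting, preference) ==")
    w(pd.DataFrame([f.summary_row() for f in biv["fits"].values()])
      .to_string(index=False, float_format=_fmt))
    w(pd.DataFrame([c.summary_row() for c in biv["comparisons"]])
      .to_string(index=False, float_format=_fmt))
    w(f"selected: {biv['best'].label}")
    d = biv["decomposition"]
    w(d.components.to_string(index=False, float_format=_fmt))
    if d.bivariate:
        for key, val in d.bivariate.items():
            w(f"  {key} = {_fmt(val)}")
    w("")
    w("== longitudinal association (cluster-robust linear model) ==")
    w(fam.to_string(index=False, float_format=_fmt))
    w(f"delta R^2 vs covariate-only null: {_fmt(gee.delta_r2)}")
    w("")
    Path(path).write_text("\n".join(lines))
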