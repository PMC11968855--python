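"""End-to-end pipeline driver.

Wires the stages in dependency order on synthetic inputs, with every
default printed into a manifest so a run is fully determined by its config
and master seed.  Stage defaults mirror the published parameterization
(burn-in 5000 / thin 5, alpha 0.5 / 10 folds, thresholds 3.6e-8 / 1e-5 /
5e-8, DoC 2 / 0.99 quantile / 40 samples / 10 or 5 reads, 12-month
matching window); the bundled demo scales the sizes down, not the rules.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bayes, biomarker, evaluate, gwas, marginal, matching
from . import phenotype as phen
from . import seqfilters, synthetic

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": [
        "cohort",
        "phenotype",
        "bayes_ewas",
        "marginal_ewas",
        "seq_filters",
        "matching",
        "biomarker",
        "evaluate",
        "gwas",
    ],
    "cohort": {
        "n_individuals": 400,
        "n_cpgs": 600,
        "target_h2": 0.5,
        "spike_fraction": 0.95,
        "n_causal": 20,
    },
    "bayes_ewas": {
        "burn_in": 5000,
        "post_burn_iterations": 10000,
        "thin": 5,
        "pip_thresholds": [0.80, 0.95],
    },
    "marginal_ewas": {
        "genome_wide_p": 3.6e-8,
        "suggestive_p": 1e-5,
        "phenotype_mode": "binary",
    },
    "seq_filters": {
        "n_samples": 46,
        "n_sites": 300,
        "platform": "short_read_panel",
        "mean_depth": 15.0,
        "min_doc": 2,
        "high_coverage_quantile": 0.99,
        "min_samples": 40,
        "min_reads_platform": 10,
        "n_effect_sites": 5,
        "effect_shift": 0.3,
    },
    "matching": {
        "n_questionnaire": 400,
        "never_fraction": 0.5,
        "n_per_sex": 12,
        "max_age_diff_days": 365,
    },
    "biomarker": {"alpha": 0.5, "n_folds": 10, "n_lambda": 60, "path_decades": 3.0},
    "evaluate": {"current_fraction": 0.2, "former_fraction": 0.3},
    "gwas": {
        "n_individuals": 500,
        "n_snps": 800,
        "maf_low": 0.05,
        "maf_high": 0.5,
        "h2_snp": 0.4,
        "n_causal": 50,
        "n_pcs": 10,
        "genome_wide_p": 5e-8,
        "suggestive_p": 1e-5,
    },
}


def load_config(path=None) -> dict:
    """Deep-merge a plain key:value (YAML subset) config over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.12g", lineterminator="\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = list(config["stages"])
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "outputs": {},
    }

    state: dict = {}

    def need(name: str, stage: str):
        if name not in state:
            raise RuntimeError(f"stage {stage!r} requires upstream artifact {name!r}; "
                               f"is its producing stage enabled?")
        return state[name]

    def record(stage: str, info: dict, files: dict[str, pd.DataFrame] | None = None):
        manifest["stages"][stage] = info
        for fname, frame in (files or {}).items():
            path = out / fname
            _write_tsv(frame, path, index=fname.startswith("methylation"))
            manifest["outputs"][fname] = _sha256(path)
        logger.info("stage %-13s %s", stage, info)

    if "cohort" in stages:
        c = config["cohort"]
        sim_cfg = synthetic.SimulationConfig(
            n_individuals=int(c["n_individuals"]),
            n_cpgs=int(c["n_cpgs"]),
            target_h2=float(c["target_h2"]),
            spike_fraction=float(c["spike_fraction"]),
            n_causal=(int(c["n_causal"]) if c.get("n_causal") is not None else None),
            seed=seed,
        )
        methylation, phenotypes, truth = synthetic.simulate_methylation_cohort(sim_cfg)
        state.update(methylation=methylation, phenotypes=phenotypes, truth=truth)
        record(
            "cohort",
            {"n": len(phenotypes), "p": methylation.shape[1],
             "realized_h2": truth.realized_h2},
            {
                "methylation.tsv": methylation,
                "phenotypes.tsv": phenotypes,
                "truth.tsv": truth.to_frame(),
            },
        )

    if "phenotype" in stages:
        ph = need("phenotypes", "phenotype")
        methylation = need("methylation", "phenotype")
        y = ph["trait"].to_numpy()
        y_std = (y - y.mean()) / y.std()
        resid = phen.residualize_methylation(
            methylation, ph["age"], ph["sex"], ph["batch"]
        )
        state.update(y_processed=y_std, methylation_resid=resid)
        record("phenotype", {"n": len(y_std), "p_resid": resid.shape[1]},
               {"phenotype_processed.tsv": pd.DataFrame(
                   {"sample_id": ph["sample_id"], "value": y_std})})

    if "bayes_ewas" in stages:
        b = config["bayes_ewas"]
        resid = need("methylation_resid", "bayes_ewas")
        y_std = need("y_processed", "bayes_ewas")
        chain = bayes.ChainConfig(
            burn_in=int(b["burn_in"]),
            post_burn_iterations=int(b["post_burn_iterations"]),
            thin=int(b["thin"]),
            seed=seed,
        )
        summary = bayes.run_gibbs(resid.to_numpy(), y_std, chain=chain,
                                  cpg_ids=list(resid.columns))
        mean_v, lo, hi = bayes.variance_explained(summary)
        tiers = bayes.call_significant(summary.pip, summary.cpg_ids,
                                       tuple(b["pip_thresholds"]))
        per_cpg = pd.DataFrame(
            {"cpg_id": summary.cpg_ids, "pip": summary.pip,
             "post_mean_beta": summary.post_mean}
        )
        chain_tab = pd.DataFrame(
            {"v": summary.v_samples, "sigma2_beta": summary.sigma2_beta_samples,
             "sigma2_e": summary.sigma2_e_samples}
        )
        state["bayes_summary"] = summary
        record(
            "bayes_ewas",
            {"var_explained_mean": mean_v, "ci_low": lo, "ci_high": hi,
             **{f"n_pip_gt_{t:g}": len(ids) for t, ids in tiers.items()}},
            {"bayes_per_cpg.tsv": per_cpg, "bayes_chain.tsv": chain_tab},
        )

    if "marginal_ewas" in stages:
        m = config["marginal_ewas"]
        methylation = need("methylation", "marginal_ewas")
        ph = need("phenotypes", "marginal_ewas")
        y = ph["trait"].to_numpy()
        if m["phenotype_mode"] == "binary":
            pheno = (y > np.median(y)).astype(float)
        else:
            pheno = y
        result = marginal.ewas_lm(methylation, pheno, ph["age"], ph["sex"])
        tiers = marginal.tier_hits(
            result,
            marginal.SignificanceTiers(float(m["genome_wide_p"]), float(m["suggestive_p"])),
        )
        lam = marginal.genomic_inflation(result["p"].dropna())
        state["marginal_result"] = result
        record(
            "marginal_ewas",
            {"lambda": lam, "n_genome_wide": len(tiers["genome_wide"]),
             "n_suggestive": len(tiers["suggestive"])},
            {"marginal_ewas.tsv": result},
        )

    if "seq_filters" in stages:
        s = config["seq_filters"]
        table, cov_truth = synthetic.simulate_coverage(
            n_samples=int(s["n_samples"]),
            n_sites=int(s["n_sites"]),
            platform=s["platform"],
            mean_depth=float(s["mean_depth"]),
            seed=seed,
            n_effect_sites=int(s["n_effect_sites"]),
            effect_shift=float(s["effect_shift"]),
        )
        policy = seqfilters.FilterPolicy(
            min_doc=int(s["min_doc"]),
            high_coverage_quantile=float(s["high_coverage_quantile"]),
            min_samples=int(s["min_samples"]),
            min_reads_platform=int(s["min_reads_platform"]),
        )
        filtered, audit = seqfilters.apply_filters(table, policy)
        fractions = seqfilters.methylation_fraction(filtered)
        group = np.array([1.0 if sid.startswith("case") else 0.0
                          for sid in fractions.index])
        seq_result = marginal.ewas_lm(fractions, group)
        state["seq_result"] = seq_result
        record(
            "seq_filters",
            {"n_input_sites": table.n_sites, "n_surviving": filtered.n_sites},
            {"seqfilter_audit.tsv": audit, "seq_ewas.tsv": seq_result},
        )

    if "matching" in stages:
        mt = config["matching"]
        questionnaire = synthetic.simulate_smoking_phenotype(
            n=int(mt["n_questionnaire"]),
            never_fraction=float(mt["never_fraction"]),
            seed=seed,
        )
        mask, _ = phen.flag_inconsistent_records(questionnaire)
        clean = questionnaire[~mask].reset_index(drop=True)
        clean = clean.rename(columns={"current_age": "age"})
        case_ids = matching.select_cases(clean, n_per_sex=int(mt["n_per_sex"]))
        cases = clean[clean["sample_id"].isin(case_ids)]
        pool = clean[clean["smoking_status"] == "never"]
        result = matching.match_controls(
            cases, pool, max_age_diff_days=float(mt["max_age_diff_days"])
        )
        ok, violations, pairs = matching.validate_pairs(
            result.pairs, clean, max_age_diff_days=float(mt["max_age_diff_days"])
        )
        record(
            "matching",
            {"n_cases": len(cases), "n_pairs": len(pairs),
             "n_unmatched": len(result.unmatched), "n_violations": len(violations)},
            {"matched_pairs.tsv": pairs},
        )

    if "biomarker" in stages:
        bm = config["biomarker"]
        methylation = need("methylation", "biomarker")
        y_std = need("y_processed", "biomarker")
        model = biomarker.train_elastic_net(
            methylation, y_std,
            alpha=float(bm["alpha"]), n_folds=int(bm["n_folds"]),
            seed=seed, n_lambda=int(bm["n_lambda"]),
            path_decades=float(bm["path_decades"]),
        )
        weights_path = out / "biomarker_weights.tsv"
        model.to_tsv(weights_path)
        manifest["outputs"]["biomarker_weights.tsv"] = _sha256(weights_path)
        state["biomarker_model"] = model
        record("biomarker",
               {"lambda_selected": model.lambda_selected,
                "n_nonzero": int(len(model.weights))})

    if "evaluate" in stages:
        ev = config["evaluate"]
        model = need("biomarker_model", "evaluate")
        c = config["cohort"]
        test_cfg = synthetic.SimulationConfig(
            n_individuals=int(c["n_individuals"]),
            n_cpgs=int(c["n_cpgs"]),
            target_h2=float(c["target_h2"]),
            spike_fraction=float(c["spike_fraction"]),
            n_causal=(int(c["n_causal"]) if c.get("n_causal") is not None else None),
            seed=seed,
            population_seed=seed + 1,  # same truth, fresh individuals
        )
        m_test, ph_test, truth_test = synthetic.simulate_methylation_cohort(test_cfg)
        scores = biomarker.score(model, m_test)
        # derive smoking categories from the true signal ranks for the demo
        ranks = pd.Series(truth_test.score).rank(pct=True)
        status = np.where(
            ranks > 1 - float(ev["current_fraction"]), "current",
            np.where(ranks > 1 - float(ev["current_fraction"]) - float(ev["former_fraction"]),
                     "former", "never"),
        )
        report = evaluate.evaluation_report(
            status, ph_test["trait"], scores, ph_test["age"], ph_test["sex"]
        )
        report_frame = pd.DataFrame(
            sorted(report.items()), columns=["metric", "value"]
        )
        record("evaluate", {k: report[k] for k in ("incremental_r2", "pearson_r")},
               {"evaluation_report.tsv": report_frame})

    if "gwas" in stages:
        g = config["gwas"]
        geno, pheno_g, truth_g = synthetic.simulate_genotypes(
            n_individuals=int(g["n_individuals"]),
            n_snps=int(g["n_snps"]),
            maf_range=(float(g["maf_low"]), float(g["maf_high"])),
            h2_snp=float(g["h2_snp"]),
            n_causal=int(g["n_causal"]),
            seed=seed,
        )
        pcs = gwas.compute_pcs(geno, k=int(g["n_pcs"]))
        scan_self = gwas.gwas_scan(geno, pheno_g["trait"], pcs)
        # proxy phenotype: the true polygenic signal plus fresh noise, mimicking
        # a methylation-derived estimator of the same exposure
        rng = np.random.default_rng(seed + 10_000)
        proxy = truth_g.score + rng.standard_normal(len(pheno_g)) * np.sqrt(
            max(1.0 - float(g["h2_snp"]), 1e-6)
        )
        scan_proxy = gwas.gwas_scan(geno, proxy, pcs)
        h2, h2_se = gwas.he_regression(geno, pheno_g["trait"])
        comparison = gwas.compare_phenotype_scans(scan_self, scan_proxy)
        record(
            "gwas",
            {"lambda_self": scan_self.attrs["lambda"],
             "lambda_proxy": scan_proxy.attrs["lambda"],
             "h2_estimate": h2, "h2_se": h2_se,
             "n_overlap_gw": comparison[f"tier_{gwas.GWAS_GENOME_WIDE_P:g}"]["n_overlap"]},
            {"gwas_self.tsv": scan_self, "gwas_proxy.tsv": scan_proxy},
        )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2,
                                        default=str) + "\n")
    return manifest
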