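"""Self-contained evaluation runs over synthetic data with planted truth.

These functions regenerate their inputs from a seed, run the pipeline, and
score the results against the planted truth: recovery of planted increased
GPs in the candidate set, ANOVA power on planted fold changes, type-I error
of the clinical chi-square under a null cohort, and the glyco-PSM rejection
rate under a known contaminant fraction.
"""

from __future__ import annotations

import numpy as np

from secretomics import glyco, synthetic
from secretomics.clinical import pearson_chi2
from secretomics.design import StudyDesign
from secretomics.pipeline import PipelineConfig, run_from_tables, simulate_inputs


def recovery_benchmark(seed: int = 1, n_proteins: int = 300) -> dict:
    """End-to-end parameter recovery on the default study conditions.

    Simulates the full input set (four cell lines, three secretome replicates,
    fold step 2, log-scale replicate noise 0.2), runs the pipeline, and scores:

    * ``increased_recovery`` — fraction of GPs planted "increased" and present
      in both arms (quantified in the secretome matrix and the glyco table)
      that the candidate set recovers;
    * ``anova_power`` — fraction of planted fold-changed (non-flat) GPs in the
      abundance matrix that the ANOVA screen flags at alpha = 0.05;
    * ``nsaf5_column_sum_error`` — maximum relative deviation of the NSAF5
      column sums from 1e5.
    """
    cfg = PipelineConfig(seed=seed)
    cfg.sim.n_proteins = n_proteins
    (proteome, truth, psms, glyco_psms, predictors, gene_map,
     design, glyco_design) = simulate_inputs(cfg)
    result = run_from_tables(
        proteome, psms, glyco_psms, predictors, gene_map,
        design, glyco_design, cfg.params, seed,
    )

    by_trend = truth.groupby("trend")["gene_id"].agg(set)
    increased = by_trend.get("increased", set())
    changed = increased | by_trend.get("decreased", set())

    glyco_genes = {
        gene_map.get(acc, acc)
        for acc, _site in result.glyco_table.index
    }
    quantified = set(result.matrix.index)
    denom = increased & glyco_genes & quantified
    recovered = denom & set(result.candidates)

    tested_changed = changed & quantified
    significant = set(result.anova.index[result.anova["significant"]])
    power = len(tested_changed & significant) / len(tested_changed)

    col_sums = result.matrix.sum(axis=0).to_numpy()
    sum_err = float(np.abs(col_sums / 1e5 - 1.0).max())

    return {
        "increased_recovery": len(recovered) / len(denom),
        "n_increased_in_both_arms": len(denom),
        "anova_power": power,
        "n_changed_tested": len(tested_changed),
        "nsaf5_column_sum_error": sum_err,
        "n_candidates": len(result.candidates),
        "result": result,
        "truth": truth,
    }


def clinical_type_i_error(
    seed: int = 1, n_sims: int = 500, n_patients: int = 75, alpha: float = 0.05
) -> dict:
    """Rejection rate of the plain chi-square under a null clinical cohort.

    Simulates ``n_sims`` cohorts with association 1.0 (marker independent of
    the covariate) and tests each 2x2 table at ``alpha``; under the null the
    rejection rate should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    tested = 0
    for _ in range(n_sims):
        cohort = synthetic.simulate_clinical_cohort(
            n_patients, positive_rate=0.3, association=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        table = synthetic.contingency_from_cohort(cohort, "covariate")
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            continue
        _, _, p = pearson_chi2(table, continuity_correction=False)
        tested += 1
        rejections += p < alpha
    return {
        "type_i_error": rejections / tested,
        "n_sims": tested,
        "binomial_3se": 3 * np.sqrt(alpha * (1 - alpha) / tested),
    }


def glyco_rejection_benchmark(
    seed: int = 1,
    n_proteins: int = 80,
    contaminant_fraction: float = 0.2,
) -> dict:
    """Glyco validation under a planted contaminant fraction.

    Simulates glyco-PSMs where ``contaminant_fraction`` of records carry
    deamidation at non-sequon asparagines, validates them, and reports the
    rejected fraction (expected: the contaminant fraction) plus a full
    re-verification of the sequon invariant for every accepted site.
    """
    proteome, truth = synthetic.generate_proteome(n_proteins, seed=seed)
    design = StudyDesign(n_replicates=2, n_fractions=1, seed=seed)
    psms = synthetic.simulate_glyco_psms(
        proteome, truth, design, seed=seed + 1,
        contaminant_fraction=contaminant_fraction,
    )
    accepted, rejected = glyco.validate_glyco_table(psms, proteome)

    by_acc = {p.accession: p.sequence for p in proteome}
    sequon_ok = all(
        (rec["site_position"], rec["sequon"])
        in glyco.find_sequons(by_acc[rec["accession"]])
        for _, rec in accepted.iterrows()
    )
    n = len(psms)
    frac = len(rejected) / n
    return {
        "rejected_fraction": frac,
        "n_psms": n,
        "binomial_3se": 3 * np.sqrt(
            contaminant_fraction * (1 - contaminant_fraction) / n
        ),
        "all_accepted_sites_on_sequons": sequon_ok,
        "n_accepted_records": len(accepted),
    }
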