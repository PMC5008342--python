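"""End-to-end orchestration: simulate -> QC -> inference -> quant -> trends -> candidates.

`run_from_tables` is the in-memory pipeline over already-loaded inputs;
`run_pipeline` wraps it with config validation, file I/O and a JSON run
report, so the command-line subcommands and the one-shot `all` command share
one code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from secretomics import __version__
from secretomics.design import DEFAULT_CELL_LINES, StudyDesign
from secretomics import cluster, glyco, inference, io, qc, quant, secretion, synthetic

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Knobs of the synthetic study (defaults are the study conditions)."""

    n_proteins: int = 300
    length_range: tuple[int, int] = (200, 400)
    sequon_rate: float = 1.0
    frac_increased: float = 0.1
    frac_decreased: float = 0.1
    fold_step: float = 2.0
    depth: float = 2.0
    decoy_fraction: float = 0.1
    rep_sigma: float = 0.2
    area_sigma: float = 0.25
    glyco_depth: float = 3.0
    contaminant_fraction: float = 0.1


@dataclass
class PipelineParams:
    """Analysis parameters with the documented defaults."""

    tiers: tuple[tuple[float, float], ...] = ((30.0, 0.01), (40.0, 0.05))
    min_peptide_length: int = 7
    alpha: float = 0.05
    k_secretome: int = 3
    k_glyco: int = 2
    n_restarts: int = 20
    mass_shift: float = glyco.O18_DEAMIDATION_SHIFT
    mass_tol: float = glyco.MASS_TOL
    reference_line: str | None = None

    def qc_tiers(self) -> tuple[qc.QcTier, ...]:
        return tuple(qc.QcTier(s, q) for s, q in self.tiers)


@dataclass
class PipelineConfig:
    """File-level configuration for the CLI pipeline."""

    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    proteome_fasta: str | None = None
    psm_table: str | None = None
    glyco_table: str | None = None
    predictor_table: str | None = None
    gene_map: str | None = None
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    n_replicates: int = 3
    n_replicates_glyco: int = 2
    n_fractions: int = 12
    sim: SimulationParams = field(default_factory=SimulationParams)
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationParams(**raw.pop("sim", {}))
        params = PipelineParams(**raw.pop("params", {}))
        cfg = cls(**raw, sim=sim, params=params)
        sim.length_range = tuple(sim.length_range)
        params.tiers = tuple(tuple(t) for t in params.tiers)
        cfg.cell_lines = tuple(cfg.cell_lines)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for name in ("proteome_fasta", "psm_table", "glyco_table",
                         "predictor_table", "gene_map"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"config path {name}={path!r} missing")


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    design: StudyDesign
    glyco_design: StudyDesign
    qc_psms: pd.DataFrame
    gp_groups: list
    quantifiable: list
    counts: pd.DataFrame
    matrix: pd.DataFrame
    correlations: pd.DataFrame
    anova: pd.DataFrame
    secretome_clusters: cluster.ClusterAssignment | None
    glyco_sites: pd.DataFrame
    glyco_rejected: pd.DataFrame
    glyco_table: pd.DataFrame
    glyco_clusters: cluster.ClusterAssignment | None
    categories: pd.Series
    category_summary: pd.DataFrame
    secretome_increased: set
    glyco_increased: set
    candidates: list
    report: dict


def run_from_tables(
    proteome: list[io.ProteinRecord],
    psms: pd.DataFrame,
    glyco_psms: pd.DataFrame,
    predictors: pd.DataFrame,
    gene_map: dict[str, str],
    design: StudyDesign,
    glyco_design: StudyDesign,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run QC through candidate selection on in-memory inputs."""
    params = params or PipelineParams()
    sequences = {p.accession: p.sequence for p in proteome}

    # --- QC
    scored = qc.compute_peptide_fdr(psms)
    passed = qc.stepwise_qc_filter(
        scored, params.qc_tiers(), params.min_peptide_length
    )
    logger.info("qc: %d/%d PSMs retained", len(passed), len(psms))

    # --- inference
    pmap = inference.build_peptide_protein_map(passed["peptide"], proteome)
    psm_counts = passed["peptide"].value_counts().to_dict()
    groups = inference.parsimony_group(pmap, psm_counts, sequences)
    gps = inference.collapse_to_gp(groups, gene_map, sequences)
    quantifiable = inference.select_quantifiable(gps)
    logger.info(
        "inference: %d groups -> %d GPs (%d quantifiable)",
        len(groups), len(gps), len(quantifiable),
    )

    # --- quantification and differential screen
    counts = quant.psm_count_matrix(passed, quantifiable, design)
    matrix = quant.abundance_matrix(counts, quantifiable, sequences,
                                    params.min_peptide_length)
    correlations = quant.replicate_correlation(matrix)
    anova = quant.anova_screen(matrix, design, params.alpha)
    significant = anova.index[anova["significant"]]
    logger.info("quant: %d/%d GPs significant at alpha=%g",
                len(significant), len(matrix), params.alpha)

    # --- secretome trend clustering
    secretome_clusters = None
    secretome_increased: set = set()
    if len(significant) >= params.k_secretome:
        secretome_clusters = cluster.kmeans_profiles(
            matrix.loc[significant], design,
            k=params.k_secretome, seed=seed, n_restarts=params.n_restarts,
        )
        secretome_increased = secretome_clusters.gps_with_trend("increased")

    # --- glyco arm
    accepted, rejected = glyco.validate_glyco_table(
        glyco_psms, proteome, shift=params.mass_shift, tol=params.mass_tol
    )
    logger.info("glyco: %d site records accepted, %d PSMs rejected",
                len(accepted), len(rejected))
    glyco_clusters = None
    glyco_increased: set = set()
    gtable = pd.DataFrame()
    if len(accepted):
        gtable = glyco.normalize_glyco_areas(
            accepted, glyco_psms, glyco_design, params.reference_line
        )
        # cluster only differentially expressed sites (same ANOVA screen as
        # the secretome arm); flat-site noise would otherwise wash out the
        # cluster centroids
        site_anova = quant.anova_screen(gtable, glyco_design, params.alpha)
        sig_sites = site_anova.index[site_anova["significant"]]
        cluster_table = gtable.loc[sig_sites] if len(sig_sites) >= params.k_glyco else gtable
        if len(cluster_table) >= params.k_glyco:
            glyco_clusters = glyco.glyco_trend(
                cluster_table, glyco_design, k=params.k_glyco, seed=seed,
                n_restarts=params.n_restarts,
            )
            increased_sites = glyco_clusters.gps_with_trend("increased")
            glyco_increased = {
                gene_map.get(acc, acc) for acc, _site in increased_sites
            }

    # --- secretion categories over the significant set
    categories = secretion.classify_table(predictors)
    acc_to_gene = pd.Series(
        [gene_map.get(a, a) for a in categories.index], index=categories.index
    )
    gene_categories = categories.groupby(acc_to_gene).first()
    sig_categories = gene_categories.reindex(significant).dropna()
    category_summary = (
        secretion.summarize_categories(sig_categories)
        if len(sig_categories)
        else secretion.summarize_categories(gene_categories)
    )

    # --- candidates
    candidates = cluster.intersect_candidates(secretome_increased, glyco_increased)

    report = {
        "version": __version__,
        "seed": seed,
        "n_psms_in": int(len(psms)),
        "n_psms_qc": int(len(passed)),
        "n_groups": len(groups),
        "n_gps": len(gps),
        "n_quantifiable": len(quantifiable),
        "n_significant": int(len(significant)),
        "cluster_sizes": (
            secretome_clusters.labels.value_counts().sort_index().tolist()
            if secretome_clusters else []
        ),
        "n_glycosites": int(
            accepted[~accepted["ambiguous"]]
            .groupby(["accession", "site_position"]).ngroups
        ) if len(accepted) else 0,
        "n_glyco_rejected": int(len(rejected)),
        "category_fractions": category_summary["fraction"].round(4).to_dict(),
        "n_candidates": len(candidates),
        "candidates": list(map(str, candidates)),
    }
    return PipelineResult(
        design=design, glyco_design=glyco_design, qc_psms=passed,
        gp_groups=gps, quantifiable=quantifiable, counts=counts, matrix=matrix,
        correlations=correlations, anova=anova,
        secretome_clusters=secretome_clusters, glyco_sites=accepted,
        glyco_rejected=rejected, glyco_table=gtable,
        glyco_clusters=glyco_clusters, categories=categories,
        category_summary=category_summary,
        secretome_increased=secretome_increased,
        glyco_increased=glyco_increased, candidates=candidates, report=report,
    )


def simulate_inputs(config: PipelineConfig):
    """Generate the full synthetic input set for a config (seeded)."""
    design = StudyDesign(config.cell_lines, config.n_replicates,
                         config.n_fractions, config.seed)
    glyco_design = StudyDesign(config.cell_lines, config.n_replicates_glyco,
                               1, config.seed)
    s = config.sim
    proteome, truth = synthetic.generate_proteome(
        s.n_proteins, s.length_range, s.sequon_rate, seed=config.seed,
        frac_increased=s.frac_increased, frac_decreased=s.frac_decreased,
        fold_step=s.fold_step,
    )
    psms = synthetic.simulate_psm_tables(
        proteome, truth, design, depth=s.depth,
        decoy_fraction=s.decoy_fraction, seed=config.seed + 1,
        rep_sigma=s.rep_sigma, area_sigma=s.area_sigma,
    )
    glyco_psms = synthetic.simulate_glyco_psms(
        proteome, truth, glyco_design, seed=config.seed + 2,
        depth=s.glyco_depth, contaminant_fraction=s.contaminant_fraction,
        rep_sigma=s.rep_sigma, area_sigma=s.area_sigma,
    )
    predictors = synthetic.simulate_predictor_scores(
        proteome, truth, seed=config.seed + 3
    )
    gene_map = {p.accession: p.gene_id for p in proteome}
    return proteome, truth, psms, glyco_psms, predictors, gene_map, design, glyco_design


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Config-driven pipeline: (optionally) simulate, run all stages, write outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        (proteome, truth, psms, glyco_psms, predictors, gene_map,
         design, glyco_design) = simulate_inputs(config)
        io.write_fasta(proteome, out / "proteome.fasta")
        io.write_truth(truth, out / "truth.json")
        io.write_psm_table(psms, out / "psms.tsv")
        io.write_psm_table(glyco_psms, out / "glyco_psms.tsv")
        predictors.to_csv(out / "predictors.tsv", sep="\t", index=False)
        io.write_gene_map(gene_map, out / "gene_map.tsv")
    else:
        proteome = io.read_fasta(config.proteome_fasta)
        psms = io.read_psm_table(config.psm_table)
        glyco_psms = io.read_psm_table(config.glyco_table)
        predictors = pd.read_csv(config.predictor_table, sep="\t")
        gene_map = io.read_gene_map(config.gene_map)
        design = StudyDesign(config.cell_lines, config.n_replicates,
                             config.n_fractions, config.seed)
        glyco_design = StudyDesign(config.cell_lines, config.n_replicates_glyco,
                                   1, config.seed)

    result = run_from_tables(
        proteome, psms, glyco_psms, predictors, gene_map,
        design, glyco_design, config.params, config.seed,
    )
    write_outputs(result, out)
    return result


def write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    inference.groups_table(result.gp_groups).to_csv(
        out / "groups.tsv", sep="\t", index=False
    )
    result.matrix.to_csv(out / "abundance_nsaf5.tsv", sep="\t")
    anova = result.anova.copy()
    anova.to_csv(out / "anova.tsv", sep="\t")
    if result.secretome_clusters is not None:
        cluster.clusters_table(result.secretome_clusters).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
    glyco.site_summary(result.glyco_sites).to_csv(
        out / "glycosites.tsv", sep="\t", index=False
    )
    result.category_summary.to_csv(out / "secretion_classes.tsv", sep="\t")
    pd.DataFrame({"gp_id": result.candidates}).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    (out / "report.json").write_text(json.dumps(result.report, indent=1, sort_keys=True))
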