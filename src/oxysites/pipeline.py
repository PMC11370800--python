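"""Per-gene end-to-end analysis, the random-site control, the BUSTED
evidence-ratio support filter, and the chi-square proportion comparison.

One analysis = sanitize -> (optional) truncation filter -> z-scale encoding
of the selected codons -> PCA -> group inference -> DAPC -> per temperature
and lambda mode: PGLS of standardized P_crit on the LD scores with backward
ANOVA reduction. Every paralog row of a species receives that species'
P_crit, so species with several gene copies contribute several points.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .dapc import DAPCResult, run_dapc
from .io_model import (
    Alignment,
    GeneTree,
    PhenotypeTable,
    SiteRecord,
    SiteSource,
    read_alignment,
    read_phenotypes,
    read_sites,
    read_tree,
    sanitize_alignment,
)
from .pgls import PGLSFit, anova_reduce, build_covariance, gls_fit, lambda_transform
from .site_encoding import (
    encode_sites,
    filter_truncated,
    load_zscales,
    select_random_control_sites,
)

__all__ = [
    "AnalysisConfig",
    "GeneReport",
    "load_reference_sites",
    "run_gene_analysis",
    "run_gene_analysis_data",
    "run_random_control",
    "support_filter",
    "proportion_chi2",
]

logger = logging.getLogger(__name__)

REFERENCE_SITES_FILE = "selected_sites_hif_egln.tsv"


@dataclass
class AnalysisConfig:
    gene_family: str
    alignment: str
    tree: str
    sites: str
    phenotypes: str
    id_map: str
    temperatures: tuple[float, ...] = (15.0, 24.0, 28.0)
    var_target: float = 0.90
    percentile: float = 90.0
    alpha: float = 0.1
    lambda_modes: tuple[str, ...] = ("fixed", "ml")
    fixed_lambda: float = 0.001
    truncation_filter: bool = False
    truncation_fraction: float = 0.5
    k_max: int | None = None
    n_starts: int = 25
    strip_regex: str | None = None
    seed: int = 0
    outdir: str | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("temperatures", "lambda_modes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GeneReport:
    gene_family: str
    dapc: DAPCResult
    pgls: dict[tuple[float, str], PGLSFit]    # (temperature, lambda_mode) -> fit
    n_rows_used: dict[float, int]
    config_digest: str
    seed: int
    notes: list[str] = field(default_factory=list)

    def dapc_table(self) -> pd.DataFrame:
        """One row per homology group analysis: k and per-LD variance
        proportions (the published summary shape)."""
        row: dict[str, object] = {"homolog": self.gene_family, "DAPC_groups": self.dapc.k}
        for j, p in enumerate(self.dapc.ld_var_prop, start=1):
            row[f"LD{j}"] = round(float(p), 2)
        return pd.DataFrame([row])

    def pgls_table(self, temperature: float, lambda_mode: str) -> pd.DataFrame:
        fit = self.pgls[(temperature, lambda_mode)]
        df = pd.DataFrame(fit.summary_rows())
        df.attrs.update(
            lambda_=fit.lam, R2=fit.r2, n=fit.n,
            formula="pcrit ~ " + " + ".join(t for t in fit.terms if t != "(Intercept)"),
        )
        return df


def load_reference_sites() -> list[SiteRecord]:
    """The shipped census of positively selected codons in the fish HIFA /
    EGLN families (episodic and pervasive), with ER-support indicator values."""
    ref = resources.files("oxysites.data") / REFERENCE_SITES_FILE
    with resources.as_file(ref) as p:
        return read_sites(p)


def _join_phenotype(
    aln_ids: list[str],
    species_of: dict[str, str],
    ld_scores: np.ndarray,
    phen: PhenotypeTable,
    temperature: float,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Rows (paralogs) joined to their species' P_crit at one temperature;
    rows without phenotype are dropped with a logged count."""
    keep, y = [], []
    for i, sid in enumerate(aln_ids):
        p = phen.pcrit(species_of.get(sid, sid), temperature)
        if p is not None:
            keep.append(i)
            y.append(p)
    dropped = len(aln_ids) - len(keep)
    if dropped:
        logger.info("dropped %d rows without P_crit at %g C", dropped, temperature)
    if not keep:
        raise ValueError("no rows after phenotype join")
    ids = [aln_ids[i] for i in keep]
    return ids, ld_scores[keep], np.asarray(y)


def _pgls_for_modes(
    cfg: AnalysisConfig,
    tree: GeneTree,
    dapc: DAPCResult,
    species_of: dict[str, str],
    phen: PhenotypeTable,
    reduce_models: bool = True,
) -> tuple[dict[tuple[float, str], PGLSFit], dict[float, int]]:
    fits: dict[tuple[float, str], PGLSFit] = {}
    n_used: dict[float, int] = {}
    for temp in cfg.temperatures:
        ids, lds, y = _join_phenotype(dapc.row_ids, species_of, dapc.ld_scores, phen, temp)
        n_used[temp] = len(ids)
        stripped = {}
        for label in tree.tip_labels:
            key = re.sub(cfg.strip_regex, "", label) if cfg.strip_regex else label
            stripped[key] = label
        unmatched = [i for i in ids if i not in stripped]
        if unmatched:
            raise ValueError(f"rows without a matching tree tip: {unmatched}")
        cov = build_covariance(tree, ids, tip_of_row={i: stripped[i] for i in ids})
        X = np.column_stack([np.ones(len(ids)), lds])
        terms = ["(Intercept)"] + [f"LD{j + 1}" for j in range(lds.shape[1])]
        for mode in cfg.lambda_modes:
            if reduce_models:
                fit = anova_reduce(
                    y, X, terms, cov.C,
                    lambda_mode=mode, fixed_lambda=cfg.fixed_lambda, alpha=cfg.alpha,
                )
            else:
                if mode == "ml":
                    from .pgls import fit_lambda_ml

                    fit = fit_lambda_ml(y, X, cov.C, terms=terms)
                else:
                    fit = gls_fit(
                        y, X, lambda_transform(cov.C, cfg.fixed_lambda),
                        terms=terms, lam=cfg.fixed_lambda,
                    )
                    fit.lambda_mode = "fixed"
            fits[(temp, mode)] = fit
    return fits, n_used


def run_gene_analysis_data(
    cfg: AnalysisConfig,
    aln: Alignment,
    tree: GeneTree,
    sites: list[SiteRecord],
    phen: PhenotypeTable,
    reduce_models: bool = True,
) -> GeneReport:
    """In-memory variant of `run_gene_analysis` (the file-based entry point
    parses the five inputs and delegates here)."""
    if not sites:
        raise ValueError("empty site list: nothing to analyze")
    notes: list[str] = []
    aln, n_repl = sanitize_alignment(aln)
    if n_repl:
        notes.append(f"sanitize: masked {n_repl} frameshift/stop/unknown characters")
    if cfg.truncation_filter:
        aln, removed = filter_truncated(aln, cfg.truncation_fraction)
        if removed:
            notes.append(f"truncation filter removed {len(removed)} sequences: {removed}")
    X = encode_sites(aln, sites, load_zscales())
    dapc = run_dapc(
        X,
        var_target=cfg.var_target,
        k_max=cfg.k_max,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        percentile=cfg.percentile,
    )
    fits, n_used = _pgls_for_modes(cfg, tree, dapc, aln.species_of, phen, reduce_models)
    return GeneReport(
        gene_family=cfg.gene_family,
        dapc=dapc,
        pgls=fits,
        n_rows_used=n_used,
        config_digest=cfg.digest(),
        seed=cfg.seed,
        notes=notes,
    )


def run_gene_analysis(cfg: AnalysisConfig) -> GeneReport:
    """File-based end-to-end analysis for one gene family."""
    aln = read_alignment(cfg.alignment, cfg.id_map)
    tree = read_tree(cfg.tree)
    sites = read_sites(cfg.sites, alignment_length=aln.length)
    phen = read_phenotypes(cfg.phenotypes, aln.species_of)
    return run_gene_analysis_data(cfg, aln, tree, sites, phen)


def run_random_control(
    cfg: AnalysisConfig,
    n_sites: int = 52,
    aln: Alignment | None = None,
    tree: GeneTree | None = None,
    sites: list[SiteRecord] | None = None,
    phen: PhenotypeTable | None = None,
) -> GeneReport:
    """Identical pipeline on `n_sites` random non-selected columns.

    PGLS models are reported FULL (no ANOVA reduction): reducing a null
    model would simply empty it.
    """
    if aln is None:
        aln = read_alignment(cfg.alignment, cfg.id_map)
        tree = read_tree(cfg.tree)
        sites = read_sites(cfg.sites, alignment_length=aln.length)
        phen = read_phenotypes(cfg.phenotypes, aln.species_of)
    control = select_random_control_sites(
        aln, sites, n_sites, seed=cfg.seed, gene_family=cfg.gene_family
    )
    report = run_gene_analysis_data(cfg, aln, tree, control, phen, reduce_models=False)
    report.notes.append(f"random-site control: {n_sites} non-selected columns, unreduced models")
    return report


def support_filter(
    sites: list[SiteRecord], er_threshold: float = 2.0
) -> tuple[list[tuple[SiteRecord, bool]], float]:
    """Flag sites whose BUSTED evidence ratio strictly exceeds the threshold.

    Returns (site, supported) pairs and the supported fraction among sites
    with an ER value. All-missing ER yields an empty annotation and a warning.
    """
    with_er = [s for s in sites if s.busted_er is not None]
    if not with_er:
        import warnings

        warnings.warn("no BUSTED evidence ratios present; support filter is empty")
        return [], float("nan")
    annotated = [(s, s.busted_er is not None and s.busted_er > er_threshold) for s in sites]
    supported = sum(1 for s in with_er if s.busted_er > er_threshold)
    return annotated, supported / len(with_er)


def proportion_chi2(
    selected_counts: dict[str, int],
    total_codons: dict[str, int],
    focal: str | None = None,
) -> dict:
    """Pearson chi-square on the 2 x g table of selected vs non-selected
    codons per gene (no continuity correction), plus an optional focal-gene
    vs pooled-others 2 x 2 variant."""
    genes = sorted(selected_counts)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to compare proportions")
    for g in genes:
        if not 0 <= selected_counts[g] <= total_codons[g]:
            raise ValueError(f"counts inconsistent for {g}")
    table = np.array(
        [[selected_counts[g] for g in genes],
         [total_codons[g] - selected_counts[g] for g in genes]]
    )
    out = {"genes": genes, "table": table}
    out.update(_pearson_chi2(table))
    if focal is not None:
        others = [g for g in genes if g != focal]
        t2 = np.array(
            [
                [selected_counts[focal], sum(selected_counts[g] for g in others)],
                [
                    total_codons[focal] - selected_counts[focal],
                    sum(total_codons[g] - selected_counts[g] for g in others),
                ],
            ]
        )
        res2 = _pearson_chi2(t2)
        out["focal"] = focal
        out["focal_chi2"], out["focal_df"], out["focal_p"] = (
            res2["chi2"], res2["df"], res2["p"],
        )
    return out


def _pearson_chi2(table: np.ndarray) -> dict:
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected < 1):
        import warnings

        warnings.warn("expected cell count < 1; consider an exact test")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return {"chi2": chi2, "df": df, "p": float(scipy.stats.chi2.sf(chi2, df))}
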