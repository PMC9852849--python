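"""End-to-end screening: panel -> variance components -> index -> analytics."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as csio
from .index import IndexCoefficients, cti_table, smith_hazel_coefficients
from .panel import PanelConfig, generate_panel, validate_panel
from .traits import CorrelationResult, PCAResult, correlation_with_stars, pca_traits, stress_ratios
from .variance import DEFAULT_INDEX_TRAITS, IndexMatrices, build_index_matrices, trait_stats_table

log = logging.getLogger(__name__)

__all__ = ["ScreeningReport", "run_screening", "write_tables"]


@dataclass
class ScreeningReport:
    """All artifacts of one screening run, plus reproducibility metadata."""

    seed: int | None
    config_hash: str
    timestamp: str
    stats: pd.DataFrame
    matrices: IndexMatrices
    coefficients: IndexCoefficients
    cti: pd.DataFrame
    ratios: pd.DataFrame
    correlations: CorrelationResult
    pca: PCAResult
    categories: dict = field(default_factory=dict)


def run_screening(panel: pd.DataFrame | None = None,
                  config: PanelConfig | None = None,
                  index_traits: list[str] | None = None,
                  treatment: str = "cold",
                  coeffs: IndexCoefficients | None = None,
                  economic_weights=None,
                  scheme: str = "equal-width",
                  pca_traits_subset: list[str] | None = None) -> ScreeningReport:
    """Run the full screening pipeline on a panel (or simulate one from config).

    Stages: validation -> per-trait variance components under ``treatment``
    -> P/G matrices over the index traits -> Smith-Hazel coefficients
    (unless ``coeffs`` supplies them) -> CTI ranking and categorization ->
    cold/control stress ratios -> ratio correlation matrix -> ratio PCA.
    """
    if panel is None:
        if config is None:
            raise ValueError("either a panel or a config is required")
        log.info("simulating panel: %d genotypes x %d trials x %d replicates",
                 config.n_genotypes, config.n_trials, config.n_replicates)
        panel = generate_panel(config)
    validate_panel(panel)
    index_traits = list(index_traits) if index_traits else list(DEFAULT_INDEX_TRAITS)

    n_geno = panel["genotype"].nunique()
    log.info("panel: %d genotypes, %d traits, treatments %s",
             n_geno, panel["trait"].nunique(), sorted(panel["treatment"].unique()))

    stats = trait_stats_table(panel, treatment=treatment)
    matrices = build_index_matrices(panel, index_traits, treatment=treatment)
    if coeffs is None:
        coeffs = smith_hazel_coefficients(matrices, a=economic_weights)
    log.info("index coefficients b = %s over traits %s",
             np.round(coeffs.b, 4).tolist(), coeffs.traits)

    cti = cti_table(panel, coeffs, treatment=treatment, scheme=scheme)
    ratios = stress_ratios(panel)
    corr = correlation_with_stars(ratios)
    ratio_table = ratios
    if pca_traits_subset:
        keep = [f"{t}_ratio" for t in pca_traits_subset]
        ratio_table = ratios[[c for c in keep if c in ratios.columns]]
    pca = pca_traits(ratio_table)

    categories = {cat: cti.loc[cti["category"] == cat, "genotype"].tolist()
                  for cat in cti["category"].cat.categories}
    counts = {cat: len(v) for cat, v in categories.items()}
    log.info("category counts: %s", counts)

    config_hash = config.fingerprint() if config is not None else \
        hashlib.sha256(pd.util.hash_pandas_object(panel, index=False).values.tobytes()).hexdigest()
    return ScreeningReport(
        seed=config.seed if config is not None else None,
        config_hash=config_hash,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        stats=stats, matrices=matrices, coefficients=coeffs, cti=cti,
        ratios=ratios, correlations=corr, pca=pca, categories=categories,
    )


def write_tables(report: ScreeningReport, outdir) -> list[Path]:
    """Write every report table to ``outdir`` at full numeric precision."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str, **kw):
        p = out / name
        df.to_csv(p, **kw)
        written.append(p)

    _csv(report.stats, "stats.csv", index=False)
    csio.write_matrices_json(report.matrices, out / "matrices.json")
    written.append(out / "matrices.json")
    (out / "coefficients.json").write_text(json.dumps({
        "traits": report.coefficients.traits,
        "b": report.coefficients.b.tolist(),
        "a": report.coefficients.a.tolist(),
        "solve_residual": report.coefficients.solve_residual,
    }, indent=2))
    written.append(out / "coefficients.json")
    _csv(report.cti, "cti.csv", index=False)
    _csv(report.ratios, "ratios.csv")
    _csv(report.correlations.r, "corr.csv")
    _csv(report.correlations.long, "corr_long.csv", index=False)
    pca_dir = out / "pca"
    pca_dir.mkdir(exist_ok=True)
    var = pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(report.pca.component_variance_percent))],
        "variance_percent": report.pca.component_variance_percent,
        "cumulative_percent": report.pca.cumulative_percent,
    })
    var.to_csv(pca_dir / "variance.csv", index=False)
    report.pca.loadings.to_csv(pca_dir / "loadings.csv")
    report.pca.scores.to_csv(pca_dir / "scores.csv")
    written += [pca_dir / "variance.csv", pca_dir / "loadings.csv", pca_dir / "scores.csv"]

    (out / "report.md").write_text(_summary_md(report))
    written.append(out / "report.md")
    return written


def _summary_md(report: ScreeningReport) -> str:
    counts = {cat: len(v) for cat, v in report.categories.items()}
    top = report.cti.nsmallest(5, "CTI")[["genotype", "CTI", "category"]]
    lines = [
        "# Cold-tolerance screening report",
        "",
        f"- run: {report.timestamp}  seed: {report.seed}  config: {report.config_hash[:12]}",
        f"- genotypes: {len(report.cti)}",
        f"- index traits: {', '.join(report.coefficients.traits)}",
        f"- Smith-Hazel b: {np.round(report.coefficients.b, 4).tolist()}",
        f"- category counts (T/MT/MS/S/SS): "
        f"{[counts.get(c, 0) for c in ('T', 'MT', 'MS', 'S', 'SS')]}",
        f"- PC1/PC2 variance: {report.pca.component_variance_percent[0]:.1f}% / "
        f"{report.pca.component_variance_percent[1]:.1f}%"
        if len(report.pca.component_variance_percent) > 1 else "",
        "",
        "Most tolerant genotypes (lowest CTI):",
        "",
        top.to_string(index=False),
        "",
    ]
    return "\n".join(lines)
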