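"""Full-study orchestration: subsets -> ordination -> EMS -> classification
-> co-occurrence -> gradient tests, with deterministic CSV output.

`analyse_metacommunity` runs the three-metric EMS analysis on one study;
`run_full_analysis` maps it (plus co-occurrence and gradient tests) over a
configurable list of metadata-defined subsets, reporting subsets with too
few sites or taxa as "insufficient" rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import StructureLabel, classify
from .cooccur import analyze_pairs, pairs_to_frame, summarize
from .ems import (
    BoundaryClumpResult,
    MetricResult,
    boundary_counts,
    embedded_absences,
    metric_significance,
    morisita_boundary_clumping,
    null_metric_distributions,
    range_fill,
    turnover_replacements,
)
from .gradients import kruskal_wallis, spearman
from .incidence import (
    IncidenceError,
    IncidenceStudy,
    drop_degenerate,
    drop_singletons,
    load_incidence,
    subset_study,
)
from .ordination import OrdinationError, order_matrix, reciprocal_averaging

__all__ = [
    "EmsAnalysis",
    "AnalysisConfig",
    "ResultBundle",
    "analyse_metacommunity",
    "default_subsets",
    "run_full_analysis",
]


@dataclass(frozen=True)
class EmsAnalysis:
    """EMS metrics, classification and ordination for one metacommunity."""

    coherence: MetricResult
    turnover: MetricResult
    boundary: BoundaryClumpResult
    label: StructureLabel
    ordination: object
    n_sites: int
    n_taxa: int


def analyse_metacommunity(
    study: IncidenceStudy,
    *,
    n_sims: int = 1000,
    method: str = "r1",
    alpha: float = 0.05,
    seed: int | None = None,
    axis: str = "both",
    singleton_filter: bool = False,
) -> EmsAnalysis:
    """Ordinate one study, compute the three EMS metrics against a shared
    null, and classify the structure.

    ``singleton_filter=True`` removes single-site taxa before the EMS
    metrics (both conventions are seen in the literature; the default
    keeps them).
    """
    if singleton_filter:
        study = drop_singletons(study)
    study = drop_degenerate(study)
    ordn = reciprocal_averaging(study)
    om = order_matrix(study, ordn)

    obs_coh = embedded_absences(om, axis=axis)
    obs_turn = turnover_replacements(range_fill(om))
    nulls = null_metric_distributions(
        study, method=method, n_sims=n_sims, seed=seed, axis=axis
    )
    coh = metric_significance(obs_coh, nulls["coherence"])
    turn = metric_significance(obs_turn, nulls["turnover"])
    clump = morisita_boundary_clumping(boundary_counts(om), alpha=alpha)

    if coh.significant_at(alpha) and coh.observed <= coh.sim_mean:
        label = classify(coh, turn, clump, alpha=alpha)
    else:
        label = classify(coh, alpha=alpha)
    return EmsAnalysis(
        coherence=coh,
        turnover=turn,
        boundary=clump,
        label=label,
        ordination=ordn,
        n_sites=study.n_sites,
        n_taxa=study.n_taxa,
    )


@dataclass(frozen=True)
class SubsetSpec:
    name: str
    filters: dict | None  # None selects every site


def default_subsets(study: IncidenceStudy, min_sites: int = 5) -> list[SubsetSpec]:
    """The study's analysis plan, derived from the metadata.

    Total set; each assemblage with enough sites (the Doushantuo and
    indeterminate groups are excluded from assemblage-level analyses);
    palaeoenvironmental and geographic subsets within each assemblage
    where enough localities exist.
    """
    subsets = [SubsetSpec("total", None)]
    meta = study.sites
    for assem in ("Avalon", "White Sea", "Nama"):
        in_a = meta["assemblage"] == assem
        if in_a.sum() == 0:
            continue
        subsets.append(SubsetSpec(assem, {"assemblage": assem}))
        for col, kind in (("palaeoenvironment", ""), ("region", "")):
            for value, count in meta.loc[in_a, col].value_counts().items():
                if count >= min_sites and count < in_a.sum():
                    subsets.append(
                        SubsetSpec(
                            f"{assem} ({value})",
                            {"assemblage": assem, col: value},
                        )
                    )
    # groups explicitly excluded from assemblage-level analyses still get a
    # row so their insufficiency is reported, not silently dropped
    for assem in ("Doushantuo",):
        if (meta["assemblage"] == assem).any():
            subsets.append(SubsetSpec(assem, {"assemblage": assem}))
    return subsets


@dataclass
class AnalysisConfig:
    matrix_path: str | None = None
    metadata_path: str | None = None
    subsets: list[SubsetSpec] | None = None  # None -> default_subsets
    n_sims: int = 1000
    alpha: float = 0.05
    expected_threshold: float = 1.0
    seed: int = 0
    min_sites: int = 5
    min_taxa: int = 3
    null_method: str = "r1"
    axis: str = "both"
    outdir: str | None = None
    run_robustness: bool = False
    robustness_reps: int = 1000

    def __post_init__(self) -> None:
        if self.n_sims < 2:
            raise ValueError("n_sims must be >= 2")


@dataclass
class ResultBundle:
    ems_table: pd.DataFrame
    gradient_table: pd.DataFrame
    cooccur_tables: dict[str, pd.DataFrame]
    cooccur_summaries: pd.DataFrame
    robustness_table: pd.DataFrame | None
    log: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.ems_table.to_csv(out / "ems_results.csv", index=False)
        self.gradient_table.to_csv(out / "gradient_tests.csv", index=False)
        self.cooccur_summaries.to_csv(out / "cooccurrence_summary.csv", index=False)
        for name, table in self.cooccur_tables.items():
            safe = name.replace(" ", "_").replace("(", "").replace(")", "")
            table.to_csv(out / f"cooccurrence_{safe}.csv", index=False)
        if self.robustness_table is not None:
            self.robustness_table.to_csv(out / "robustness.csv", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _ems_row(name: str, res: EmsAnalysis) -> dict:
    sign = lambda d: "+" if d == "positive" else "-"
    return {
        "group": name,
        "n_sites": res.n_sites,
        "n_taxa": res.n_taxa,
        "coherence": res.coherence.observed,
        "coherence_z": res.coherence.z,
        "coherence_p": res.coherence.p,
        "coherence_simMean": res.coherence.sim_mean,
        "coherence_sign": sign(res.coherence.direction),
        "turnover": res.turnover.observed,
        "turnover_z": res.turnover.z,
        "turnover_p": res.turnover.p,
        "turnover_simMean": res.turnover.sim_mean,
        "turnover_sign": sign(res.turnover.direction),
        "morisita": res.boundary.morisita_index,
        "morisita_p": res.boundary.p,
        "morisita_sign": "+" if res.boundary.morisita_index >= 1 else "-",
        "interpretation": res.label.label,
    }


def _insufficient_row(name: str, n_sites: int, n_taxa: int, why: str) -> dict:
    return {
        "group": name,
        "n_sites": n_sites,
        "n_taxa": n_taxa,
        "interpretation": f"insufficient ({why})",
    }


def run_full_analysis(
    config: AnalysisConfig, study: IncidenceStudy | None = None
) -> ResultBundle:
    """Execute the whole analysis plan and return the result tables.

    ``study`` may be passed directly (e.g. a synthetic metacommunity);
    otherwise it is loaded from the configured CSV paths.  Identical
    config + seed reproduce identical tables.
    """
    if study is None:
        if not config.matrix_path or not config.metadata_path:
            raise ValueError("config needs matrix_path and metadata_path")
        study = load_incidence(config.matrix_path, config.metadata_path)

    subsets = config.subsets or default_subsets(study, config.min_sites)
    rng = np.random.default_rng(config.seed)

    ems_rows: list[dict] = []
    grad_rows: list[dict] = []
    cooccur_tables: dict[str, pd.DataFrame] = {}
    cooc_rows: list[dict] = []
    warnings_log: list[str] = []

    # dataset-level gradient tests on the total ordination
    assem = study.sites["assemblage"]
    core = assem.isin(["Avalon", "White Sea", "Nama"])
    for spec in subsets:
        seed_k = int(rng.integers(0, 2**31 - 1))
        try:
            sub = (
                study.with_provenance("subset[total]")
                if spec.filters is None
                else subset_study(study, spec.filters, name=spec.name)
            )
        except IncidenceError as err:
            ems_rows.append(_insufficient_row(spec.name, 0, 0, str(err)))
            continue
        raw_sites, raw_taxa = sub.n_sites, sub.n_taxa
        if raw_sites < config.min_sites or raw_taxa < config.min_taxa:
            ems_rows.append(
                _insufficient_row(
                    spec.name, raw_sites, raw_taxa,
                    f"fewer than {config.min_sites} sites or {config.min_taxa} taxa",
                )
            )
            continue

        # --- EMS + classification
        try:
            res = analyse_metacommunity(
                sub,
                n_sims=config.n_sims,
                method=config.null_method,
                alpha=config.alpha,
                seed=seed_k,
                axis=config.axis,
            )
            ems_rows.append(_ems_row(spec.name, res))
            if res.n_sites != raw_sites:
                warnings_log.append(
                    f"{spec.name}: {raw_sites} raw sites, {res.n_sites} analysed"
                )
        except (IncidenceError, OrdinationError, ValueError) as err:
            ems_rows.append(_insufficient_row(spec.name, raw_sites, raw_taxa, str(err)))
            res = None

        # --- gradient tests on this subset's own ordination
        if res is not None:
            scores = res.ordination.site_scores
            meta = sub.sites.loc[scores.index]
            depth = meta["depth_index"].to_numpy(dtype=float)
            try:
                corr = spearman(scores.to_numpy(), depth)
                grad_rows.append(
                    {
                        "comparison": f"{spec.name} site scores x depth",
                        "R_s": corr.rho,
                        "kruskal_wallis": np.nan,
                        "df": np.nan,
                        "p_value": corr.p,
                    }
                )
            except ValueError as err:
                warnings_log.append(f"{spec.name}: depth correlation skipped ({err})")
            if spec.filters is None and core.sum() > 0:
                core_scores = scores.loc[scores.index.intersection(assem.index[core])]
                core_groups = assem.loc[core_scores.index].to_numpy()
                if len(np.unique(core_groups)) >= 2:
                    kw = kruskal_wallis(core_scores.to_numpy(), core_groups)
                    grad_rows.append(
                        {
                            "comparison": "all assemblages site scores x assemblage",
                            "R_s": np.nan,
                            "kruskal_wallis": kw.H,
                            "df": kw.df,
                            "p_value": kw.p,
                        }
                    )
                    depth_core = study.sites.loc[core, "depth_index"].to_numpy(float)
                    kw2 = kruskal_wallis(depth_core, assem[core].to_numpy())
                    grad_rows.append(
                        {
                            "comparison": "depth x assemblage",
                            "R_s": np.nan,
                            "kruskal_wallis": kw2.H,
                            "df": kw2.df,
                            "p_value": kw2.p,
                        }
                    )

        # --- co-occurrence on the singleton-filtered subset
        filtered = drop_singletons(sub)
        if filtered.n_taxa >= 2:
            pairs = analyze_pairs(
                filtered,
                alpha=config.alpha,
                expected_threshold=config.expected_threshold,
            )
            cooccur_tables[spec.name] = pairs_to_frame(pairs)
            try:
                summary = summarize(pairs)
                cooc_rows.append(
                    {
                        "group": spec.name,
                        "n_taxa": filtered.n_taxa,
                        "n_pairs_total": summary.n_pairs_total,
                        "n_pairs_analysed": summary.n_pairs_analysed,
                        "n_positive": summary.n_positive,
                        "n_negative": summary.n_negative,
                        "pct_nonrandom": summary.pct_nonrandom,
                    }
                )
            except ValueError as err:
                warnings_log.append(f"{spec.name}: co-occurrence summary ({err})")
        else:
            warnings_log.append(
                f"{spec.name}: co-occurrence skipped (<2 taxa after singleton removal)"
            )

    robustness_table = None
    if config.run_robustness:
        robustness_table = _robustness_report(study, config, rng)

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_sims": config.n_sims,
        "alpha": config.alpha,
        "null_method": config.null_method,
        "expected_threshold": config.expected_threshold,
        "warnings": warnings_log,
    }
    for key, path in (("matrix", config.matrix_path), ("metadata", config.metadata_path)):
        if path:
            log[f"{key}_sha256"] = _sha256(path)
    return ResultBundle(
        ems_table=pd.DataFrame(ems_rows),
        gradient_table=pd.DataFrame(grad_rows),
        cooccur_tables=cooccur_tables,
        cooccur_summaries=pd.DataFrame(cooc_rows),
        robustness_table=robustness_table,
        log=log,
    )


def _robustness_report(
    study: IncidenceStudy, config: AnalysisConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Subsample every large-enough assemblage down to the smallest one."""
    from .robustness import empirical_p, subsample_cooccurrence, subsample_depth_significance

    meta = study.sites
    groups = [
        a
        for a in ("Avalon", "White Sea", "Nama")
        if (meta["assemblage"] == a).sum() >= config.min_sites
    ]
    if len(groups) < 2:
        return pd.DataFrame()
    sizes = {a: int((meta["assemblage"] == a).sum()) for a in groups}
    target = min(sizes.values())
    rows = []
    dists = {}
    for a in groups:
        sub = subset_study(study, {"assemblage": a}, name=a)
        seed_k = int(rng.integers(0, 2**31 - 1))
        dist = subsample_cooccurrence(
            sub,
            size=target,
            n_reps=config.robustness_reps,
            seed=seed_k,
            alpha=config.alpha,
            expected_threshold=config.expected_threshold,
        )
        dists[a] = dist
        n_sig, _ = subsample_depth_significance(
            sub, size=target, n_reps=config.robustness_reps,
            alpha=config.alpha, seed=seed_k,
        )
        vals = dist.valid_values
        rows.append(
            {
                "assemblage": a,
                "subsample_size": target,
                "n_reps": config.robustness_reps,
                "n_missing": dist.n_missing,
                "pct_nonrandom_mean": float(np.mean(vals)) if len(vals) else np.nan,
                "pct_nonrandom_q05": float(np.quantile(vals, 0.05)) if len(vals) else np.nan,
                "pct_nonrandom_q95": float(np.quantile(vals, 0.95)) if len(vals) else np.nan,
                "n_significant_depth": n_sig,
            }
        )
    report = pd.DataFrame(rows)
    # pairwise empirical comparisons of the subsampled co-occurrence rates
    comp_rows = []
    means = {a: float(np.mean(dists[a].valid_values)) for a in groups}
    for a in groups:
        for b in groups:
            if a == b:
                continue
            tail = "ge" if means[a] <= means[b] else "le"
            comp_rows.append(
                {
                    "assemblage": f"{a} vs {b}",
                    "subsample_size": target,
                    "n_reps": config.robustness_reps,
                    "empirical_p": empirical_p(dists[a], means[b], tail),
                }
            )
    return pd.concat([report, pd.DataFrame(comp_rows)], ignore_index=True)
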