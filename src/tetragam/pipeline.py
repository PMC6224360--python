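"""End-to-end analysis driver: infer -> screen -> fit -> summarize -> report.

Mirrors the study's analysis path: diploid gametes are inferred from the
triploid progeny table, null-allele parental constitutions are evaluated for
loci with fewer than four distinct alleles, loci whose pooled allele
frequencies remain distorted (chi-square p below the configured threshold,
0.05 by default) are excluded, the segregation mixture is fitted to every
retained locus, and transmission/recombination/dissimilarity summaries are
assembled over the gamete matrix.  All stages are deterministic given the
configuration, so reruns produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .fit import FitResult, allele_distortion_test, fit_locus
from .inference import (
    GameteCall,
    LocusCounts,
    complete_signature,
    infer_gamete,
    null_allele_scenario_test,
    signature_counts,
    standard_null_candidates,
    tabulate_gametes,
)
from .io import (
    AnalysisConfig,
    read_genotype_table,
    read_parent_table,
    write_counts_table,
    write_dissimilarity,
    write_gamete_matrix,
    write_key_values,
)
from .model import NULL_ALLELE, TetraploidGenotype
from .transmission import (
    GameteMatrix,
    TransmissionSummary,
    aggregate_by_lg,
    correlate,
    detect_recombinants,
    heterozygosity_from_counts,
    simple_matching_dissimilarity,
)

__all__ = ["PipelineResult", "run_pipeline", "scenario_label"]


def scenario_label(fit: FitResult, genotype: TetraploidGenotype) -> str:
    """Human-readable pairing, e.g. ``BC/AA`` for the homologous scenario."""
    (i, j), (k, l) = fit.scenario.pairs
    copies = genotype.copies
    return (
        f"{copies[i].allele}{copies[j].allele}/"
        f"{copies[k].allele}{copies[l].allele}"
    )


@dataclass
class PipelineResult:
    counts: Dict[str, LocusCounts]
    constitutions: Dict[str, TetraploidGenotype]
    null_scenarios: pd.DataFrame
    distortion: pd.DataFrame
    excluded: List[str]
    fits: Dict[str, FitResult]
    fit_table: pd.DataFrame
    transmission: Optional[TransmissionSummary]
    lg_table: pd.DataFrame
    correlations: Dict[str, Dict[str, float]]
    dissimilarities: Dict[str, object]
    matrix: Optional[GameteMatrix]
    log: Dict


def _evaluate_constitutions(
    counts: Dict[str, LocusCounts],
    genotypes: Dict[str, TetraploidGenotype],
    grid_step: float,
    tol: float,
) -> Tuple[Dict[str, TetraploidGenotype], pd.DataFrame]:
    """Choose the best-supported parental constitution per locus.

    Loci with fewer than four distinct visible alleles admit null-allele
    variants; candidates are ranked by the fitted deviance G and the best
    one retained (the stated constitution wins ties by construction: it is
    listed first).
    """
    chosen: Dict[str, TetraploidGenotype] = {}
    rows = []
    for locus, lc in counts.items():
        genotype = genotypes[locus]
        visible = {a for a in genotype.alleles if a != NULL_ALLELE}
        observed_alleles = {
            a for cls in lc.counts for a in cls if a != NULL_ALLELE
        }
        candidates = (
            standard_null_candidates(genotype) if len(visible) < 4 else [genotype]
        )
        candidates = [
            cand
            for cand in candidates
            if observed_alleles <= {a for a in cand.alleles if a != NULL_ALLELE}
        ]
        if len(candidates) == 1:
            chosen[locus] = genotype
            continue
        ranked = null_allele_scenario_test(
            lc, candidates, grid_step=grid_step, tol=tol
        )
        for rank, (cand, g_stat, _fit) in enumerate(ranked, start=1):
            rows.append(
                {
                    "locus": locus,
                    "rank": rank,
                    "wlm": "".join(cand.alleles_of("M")),
                    "pon": "".join(cand.alleles_of("P")),
                    "G": g_stat,
                }
            )
        chosen[locus] = ranked[0][0]
    report = pd.DataFrame(rows, columns=["locus", "rank", "wlm", "pon", "G"])
    return chosen, report


def _relabel_counts(
    lc: LocusCounts, constitution: TetraploidGenotype
) -> LocusCounts:
    """Re-express counts under a different constitution via signatures."""
    sigs = signature_counts(lc)
    out: Dict = {}
    for sig, k in sigs.items():
        cls = complete_signature(sig, constitution)
        out[cls] = out.get(cls, 0) + k
    return LocusCounts(lc.locus_name, out)


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Execute the full analysis; returns the report bundle.

    Writes TSV tables, the dissimilarity matrices and a machine-readable run
    log under ``config.outdir`` when set.
    """
    genotypes, maternal, lg_map = read_parent_table(config.parents)
    allowed_nulls = {
        locus: min(2, g.alleles.count(NULL_ALLELE))
        for locus, g in genotypes.items()
    }
    calls_in = read_genotype_table(config.genotypes, allowed_nulls)
    if not calls_in:
        raise ValueError("empty progeny table: nothing to analyse")
    unknown = {c.locus_name for c in calls_in} - set(genotypes)
    if unknown:
        raise ValueError(f"genotype table references unknown loci {sorted(unknown)}")

    gamete_calls: List[GameteCall] = []
    for call in calls_in:
        gamete_calls.append(
            infer_gamete(
                call, maternal[call.locus_name], allowed_nulls[call.locus_name]
            )
        )
    dropped = [c for c in gamete_calls if c.status != "ok"]
    counts = tabulate_gametes(gamete_calls)

    chosen, null_report = _evaluate_constitutions(
        counts, genotypes, config.grid_step, config.tol
    )
    final_counts: Dict[str, LocusCounts] = {}
    for locus, lc in counts.items():
        if chosen[locus].alleles != genotypes[locus].alleles:
            final_counts[locus] = _relabel_counts(lc, chosen[locus])
        else:
            final_counts[locus] = lc

    distortion_rows = []
    excluded: List[str] = []
    for locus in sorted(final_counts):
        res = allele_distortion_test(final_counts[locus], chosen[locus])
        keep = res.p_value >= config.distortion_alpha
        if not keep:
            excluded.append(locus)
        distortion_rows.append(
            {
                "locus": locus,
                "chi2": res.chi2,
                "df": res.df,
                "p_value": res.p_value,
                "excluded": not keep,
            }
        )
    distortion = pd.DataFrame(distortion_rows).set_index("locus")

    fits: Dict[str, FitResult] = {}
    for locus in sorted(final_counts):
        if locus in excluded:
            continue
        fits[locus] = fit_locus(
            final_counts[locus],
            chosen[locus],
            grid_step=config.grid_step,
            tol=config.tol,
        )

    # gamete matrix over retained, genus-differentiating loci
    retained_calls = [
        c
        for c in gamete_calls
        if c.locus_name not in excluded
        and chosen[c.locus_name].is_fully_differentiating
    ]
    matrix: Optional[GameteMatrix] = None
    transmission: Optional[TransmissionSummary] = None
    if retained_calls:
        matrix = GameteMatrix.from_calls(
            retained_calls, {l: chosen[l] for l in chosen}, lg_map
        )
        transmission = heterozygosity_from_counts(
            {l: c for l, c in final_counts.items() if l not in excluded
             and chosen[l].is_fully_differentiating},
            {l: chosen[l].origin_map for l in chosen
             if chosen[l].is_fully_differentiating},
        )

    lg_summaries = aggregate_by_lg(
        list(fits.values()), {l: chosen[l].linkage_group for l in fits}
    )
    recomb: Dict[int, Tuple[int, float]] = {}
    if matrix is not None:
        for summary in lg_summaries:
            try:
                recomb[summary.lg] = detect_recombinants(matrix, summary.lg)
            except ValueError:
                continue
            summary.recombinant_count, summary.recombination_frequency = recomb[
                summary.lg
            ]
    lg_table = pd.DataFrame(
        [
            {
                "lg": s.lg,
                "n_markers": len(s.markers),
                "markers": ",".join(s.markers),
                "tau_mean": s.tau_mean,
                "tau_sd": s.tau_sd,
                "recombinant_count": s.recombinant_count,
                "recombination_frequency": s.recombination_frequency,
            }
            for s in lg_summaries
        ]
    )

    correlations: Dict[str, Dict[str, float]] = {}
    with_recomb = [s for s in lg_summaries if s.recombination_frequency is not None]
    if len(with_recomb) >= 3:
        try:
            cr = correlate(
                [s.tau_mean for s in with_recomb],
                [s.recombination_frequency for s in with_recomb],
            )
            correlations["tau_vs_recombination_by_lg"] = {
                "r": cr.r, "r_squared": cr.r_squared, "n": cr.n
            }
        except ValueError:
            pass
    if transmission is not None and len(fits) >= 3:
        shared = [l for l in fits if l in transmission.per_locus.index]
        if len(shared) >= 3:
            try:
                cr = correlate(
                    [fits[l].tau_hat for l in shared],
                    [
                        transmission.per_locus.loc[l, "intergeneric_het_pct"]
                        for l in shared
                    ],
                )
                correlations["tau_vs_intergeneric_het_by_locus"] = {
                    "r": cr.r, "r_squared": cr.r_squared, "n": cr.n
                }
            except ValueError:
                pass

    dissimilarities: Dict[str, object] = {}
    if matrix is not None and len(matrix.data) >= 2:
        for mode in ("all-alleles", "genus-recoded"):
            try:
                dissimilarities[mode] = simple_matching_dissimilarity(matrix, mode)
            except ValueError:
                continue

    fit_rows = []
    for locus in sorted(fits):
        f = fits[locus]
        g = chosen[locus]
        row = {
            "locus": locus,
            "lg": g.linkage_group,
            "wlm": "".join(g.alleles_of("M")),
            "pon": "".join(g.alleles_of("P")),
            "pref_pairing": scenario_label(f, g),
            "direction": f.preferential_direction,
            "beta": f.beta_hat if f.beta_identifiable else None,
            "tau": f.tau_hat,
            "lrt": f.lrt,
            "p_value": f.p_value,
            "n": f.n,
        }
        if transmission is not None and locus in transmission.per_locus.index:
            row["intrageneric_het_pct"] = transmission.per_locus.loc[
                locus, "intrageneric_het_pct"
            ]
            row["intergeneric_het_pct"] = transmission.per_locus.loc[
                locus, "intergeneric_het_pct"
            ]
        fit_rows.append(row)
    fit_table = pd.DataFrame(fit_rows)

    log = {
        "tetragam_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "scipy_version": scipy.__version__,
        "seed": config.seed,
        "n_progeny": len({c.progeny_id for c in calls_in}),
        "n_loci_input": len(genotypes),
        "n_gamete_calls": len(gamete_calls),
        "n_dropped_calls": len(dropped),
        "dropped_by_status": {
            status: sum(1 for c in dropped if c.status == status)
            for status in sorted({c.status for c in dropped})
        },
        "n_excluded_loci": len(excluded),
        "excluded_loci": excluded,
        "n_fitted_loci": len(fits),
        "distortion_alpha": config.distortion_alpha,
    }

    result = PipelineResult(
        counts=final_counts,
        constitutions=chosen,
        null_scenarios=null_report,
        distortion=distortion,
        excluded=excluded,
        fits=fits,
        fit_table=fit_table,
        transmission=transmission,
        lg_table=lg_table,
        correlations=correlations,
        dissimilarities=dissimilarities,
        matrix=matrix,
        log=log,
    )
    if config.outdir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: AnalysisConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_table(result.counts, outdir / "gamete_counts.tsv")
    result.null_scenarios.to_csv(
        outdir / "null_allele_scenarios.tsv", sep="\t", index=False
    )
    result.distortion.to_csv(outdir / "allele_distortion.tsv", sep="\t")
    result.fit_table.to_csv(outdir / "locus_fits.tsv", sep="\t", index=False)
    result.lg_table.to_csv(outdir / "linkage_group_summary.tsv", sep="\t",
                           index=False)
    if result.transmission is not None:
        result.transmission.per_locus.to_csv(
            outdir / "heterozygosity_per_locus.tsv", sep="\t"
        )
        write_key_values(
            {
                "overall_intergeneric_het_pct":
                    f"{result.transmission.overall_intergeneric_pct:.4f}",
                "overall_intrageneric_het_pct":
                    f"{result.transmission.overall_intrageneric_pct:.4f}",
                "overall_homozygous_pct":
                    f"{result.transmission.overall_homozygous_pct:.4f}",
                "n_observations": result.transmission.n_observations,
            },
            outdir / "heterozygosity_overall.txt",
        )
    if result.matrix is not None:
        write_gamete_matrix(result.matrix, outdir / "gamete_matrix.tsv")
    for mode, dm in result.dissimilarities.items():
        suffix = "all" if mode == "all-alleles" else "genus"
        write_dissimilarity(dm, outdir / f"dissimilarity_{suffix}.tsv")
    flat = {}
    for name, stats in result.correlations.items():
        for key, value in stats.items():
            flat[f"{name}.{key}"] = (
                f"{value:.6f}" if isinstance(value, float) else value
            )
    write_key_values(flat, outdir / "correlations.txt")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, sort_keys=True)
        fh.write("\n")
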