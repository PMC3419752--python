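"""End-to-end orchestration of the temporal analysis sequence.

``run_full_analysis`` runs, in order: within-sample diversity, HWE and LD
exact tests, temporal theta per river, pairwise and global theta per era,
the bootstrap test for a temporal decline in global theta, leave-one-out
self-assignment, exclusion of contemporary fish from historical baselines,
drift-null exceedance p-values, and LD-based Ne — writing one TSV per stage
plus a run log recording the seed and settings, so a run is reproducible
from (study, config, seed).
"""

from __future__ import annotations

import json
import math
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import fst as fstmod
from .assignment import exclusion_test, self_assignment
from .drift import DriftConfig, drift_pvalue
from .genepop import TemporalStudy
from .ne_ld import format_ne, ldne_estimate

__all__ = ["PipelineConfig", "run_full_analysis"]


@dataclass
class PipelineConfig:
    """Knobs for one full run; defaults follow the study-scale settings
    except the exact-test chain and counts, kept modest for desk runs."""

    seed: int = 0
    chain: tuple[int, int, int] = (1000, 100, 100)
    fst_permutations: int = 499
    bootstrap_replicates: int = 2000
    bootstrap_frac: float = 0.30
    bootstrap_markers: int = 7
    exclusion_alpha: float = 0.001
    exclusion_sims: int = 2000
    drift: DriftConfig | None = None
    drift_populations: list[str] | None = None
    ne_pcrit: float = 0.02
    rarefaction_individuals: int = 25
    loci_subset: list[str] | None = None


def run_full_analysis(
    study: TemporalStudy,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame | dict]:
    """Run the full analysis sequence; optionally write TSV reports."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    loci = config.loci_subset
    report: dict[str, pd.DataFrame | dict] = {}
    log: dict[str, object] = {
        "seed": config.seed,
        "chain": list(config.chain),
        "loci_subset": loci,
        "python": sys.version.split()[0],
    }

    pops = study.populations()
    eras_present = sorted({era for _, era in study.samples})

    # --- within-sample diversity + exact tests -------------------------------
    rows = []
    for (pop, era), s in study.samples.items():
        g = s.genotypes if loci is None else s.genotypes.restrict_loci(loci)
        s2 = type(s)(pop, era, s.years, g)
        summ = dv.diversity_summary(s2, config.rarefaction_individuals)
        hwe_sig = 0
        hwe_tested = 0
        for locus in g.locus_names:
            res = dv.hwe_exact_mc(s2, locus, config.chain, rng)
            if res.applicable:
                hwe_tested += 1
                if res.p_value < 0.05:
                    hwe_sig += 1
        ld_sig = 0
        ld_tested = 0
        names = g.locus_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                res = dv.ld_exact_mc(s2, (names[i], names[j]), config.chain, rng)
                if res.applicable:
                    ld_tested += 1
                    if res.p_value < 0.05:
                        ld_sig += 1
        rows.append(
            {
                "population": pop,
                "era": era,
                "n": s.n,
                "mean_ho": float(np.nanmean(summ.ho)),
                "mean_he": float(np.nanmean(summ.he)),
                "ar_total": summ.a_r_total,
                "hwe_sig_05": hwe_sig,
                "hwe_tested": hwe_tested,
                "ld_sig_05": ld_sig,
                "ld_tested": ld_tested,
            }
        )
    report["diversity"] = pd.DataFrame(rows)

    # --- temporal theta per river -------------------------------------------
    rows = []
    for pop in pops:
        if not (study.has(pop, "historical") and study.has(pop, "contemporary")):
            continue
        theta, p = fstmod.temporal_fst(
            study, pop, loci=loci, permutations=config.fst_permutations, seed=rng
        )
        rows.append({"population": pop, "theta": theta, "p": p})
    report["temporal_fst"] = pd.DataFrame(rows)

    # --- pairwise + global theta per era ------------------------------------
    global_rows = []
    for era in ("historical", "contemporary"):
        if era not in eras_present:
            continue
        names, theta, _ = fstmod.pairwise_fst_matrix(study, era, 0, rng, loci)
        report[f"pairwise_fst_{era}"] = pd.DataFrame(theta, index=names, columns=names)
        g = fstmod.global_theta(study.era_samples(era), loci)
        global_rows.append({"era": era, "global_theta": g})
    report["global_fst"] = pd.DataFrame(global_rows)

    # --- bootstrap decline test ---------------------------------------------
    both = [
        p for p in pops
        if study.has(p, "historical") and study.has(p, "contemporary")
    ]
    boot = fstmod.bootstrap_global_fst_difference(
        study,
        frac_individuals=config.bootstrap_frac,
        n_markers=min(config.bootstrap_markers, len(loci or study.locus_names)),
        replicates=config.bootstrap_replicates,
        seed=rng,
        populations=both,
        loci=loci,
    )
    report["bootstrap"] = {
        "theta_hist": boot.theta_hist,
        "theta_contemp": boot.theta_contemp,
        "p_one_sided": boot.p_one_sided,
        "replicates": boot.replicates,
    }

    # --- assignment and exclusion -------------------------------------------
    assign_rows = []
    for era in ("historical", "contemporary"):
        if era not in eras_present or len(study.era_samples(era)) < 2:
            continue
        overall, per_pop, _ = self_assignment(study, era, loci)
        assign_rows.append({"era": era, "pct_correct": overall, **per_pop})
    report["self_assignment"] = pd.DataFrame(assign_rows)

    excl_rows = []
    for pop in both:
        res = exclusion_test(
            study.get(pop, "contemporary"),
            study.get(pop, "historical"),
            alpha=config.exclusion_alpha,
            n_sim=max(config.exclusion_sims, 1000),
            seed=rng,
            loci=loci,
        )
        excl_rows.append({"population": pop, "pct_excluded": res.percent_excluded})
    report["exclusion"] = pd.DataFrame(excl_rows)

    # --- drift null -----------------------------------------------------------
    drift_pops = config.drift_populations
    if drift_pops is None:
        tf = report["temporal_fst"]
        drift_pops = list(tf.loc[tf["p"] < 0.05, "population"]) if len(tf) else []
    if drift_pops and config.drift is not None:
        drows = []
        for pop in drift_pops:
            res = drift_pvalue(study, pop, config.drift)
            row = {"population": pop, "observed_theta": res.observed}
            for ne in res.ne_grid:
                row[f"p_ne{ne}"] = res.p_exceed[ne]
            drows.append(row)
        report["drift"] = pd.DataFrame(drows)

    # --- LD-based Ne ----------------------------------------------------------
    ne_rows = []
    for (pop, era), s in study.samples.items():
        g = s.genotypes if loci is None else s.genotypes.restrict_loci(loci)
        s2 = type(s)(pop, era, s.years, g)
        try:
            est = ldne_estimate(s2, pcrit=config.ne_pcrit)
            ne_rows.append(
                {
                    "population": pop,
                    "era": era,
                    "ne": est.ne_point,
                    "rendered": format_ne(est),
                    "low_sample": est.low_sample_flag,
                }
            )
        except ValueError:
            ne_rows.append(
                {"population": pop, "era": era, "ne": float("nan"),
                 "rendered": "NC", "low_sample": True}
            )
    report["ne"] = pd.DataFrame(ne_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, val in report.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{key}.tsv", sep="\t", index=True)
            else:
                (out / f"{key}.json").write_text(json.dumps(val, indent=2))
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return report
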