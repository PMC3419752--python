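"""Packaged per-river summary tables and the analyses computed from them.

Three small TSVs ship with the package: per-river escapee covariates
(observation years, unweighted and weighted mean escapee percentages),
per-river temporal-stability summaries (within-sample diversity, LD-based
Ne renderings, temporal theta at 22 and 14 loci, exclusion percentages and
the temporal-change call), and the double-scoring quality-control counts.
They are analysis inputs for the covariate regressions and worked
examples — not substitutes for genotype data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .fst import ols_r2

__all__ = [
    "FixtureTables",
    "load_fixture_tables",
    "qc_error_rate",
    "fixture_regressions",
    "allelic_richness_change",
]


@dataclass
class FixtureTables:
    covariates: pd.DataFrame       # indexed by river
    stability: pd.DataFrame        # indexed by river
    qc_counts: pd.DataFrame        # indexed by era

    def __post_init__(self) -> None:
        if len(self.covariates) != len(self.stability):
            raise ValueError("covariate and stability tables disagree on rivers")
        if set(self.covariates.index) != set(self.stability.index):
            raise ValueError("river name mismatch between fixture tables")
        bad = set(self.stability["temporal_change"]) - {"Yes", "No"}
        if bad:
            raise ValueError(f"temporal_change flags must be Yes/No, got {bad}")
        if (self.qc_counts < 0).any().any():
            raise ValueError("QC counts must be non-negative")


def _read(name: str) -> pd.DataFrame:
    with resources.files("tempopg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_fixture_tables() -> FixtureTables:
    cov = _read("river_covariates.tsv").set_index("river")
    stab = _read("temporal_stability.tsv").set_index("river")
    qc = _read("qc_double_scoring.tsv").set_index("era")
    return FixtureTables(cov, stab, qc)


def qc_error_rate(counts: list[tuple[int, int]] | pd.DataFrame) -> float:
    """Pooled genotyping-discrepancy percentage from double-scored alleles.

    ``counts`` is a list of (scored_twice, discrepancies) pairs — or the
    packaged QC table.  Returns 100 * sum(discrepancies) / sum(scored),
    rounded to one decimal.
    """
    if isinstance(counts, pd.DataFrame):
        pairs = list(zip(counts["scored_twice"], counts["discrepancies"]))
    else:
        pairs = list(counts)
    scored = sum(s for s, _ in pairs)
    errs = sum(d for _, d in pairs)
    if scored <= 0:
        raise ValueError("no alleles scored twice")
    if any(d > s for s, d in pairs):
        raise ValueError("discrepancies cannot exceed alleles scored")
    return round(100.0 * errs / scored, 1)


def fixture_regressions(fixtures: FixtureTables | None = None) -> pd.DataFrame:
    """Covariate-vs-temporal-theta regressions over the 21 rivers.

    Rows: (a) unweighted escapee % vs temporal theta (22 loci);
    (b) weighted escapee % vs theta; (c) as (b) with Opo removed;
    (d) exclusion % (22 loci) vs theta.  Columns: r2, slope, p.
    """
    fx = fixtures or load_fixture_tables()
    cov = fx.covariates
    st = fx.stability.loc[cov.index]
    theta = st["fst_22"].to_numpy(dtype=float)
    rows = {}
    rows["unweighted_vs_theta"] = ols_r2(cov["unweighted_escapee_pct"].to_numpy(float), theta)
    rows["weighted_vs_theta"] = ols_r2(cov["weighted_escapee_pct"].to_numpy(float), theta)
    keep = cov.index != "Opo"
    rows["weighted_vs_theta_no_opo"] = ols_r2(
        cov.loc[keep, "weighted_escapee_pct"].to_numpy(float), theta[keep]
    )
    rows["exclusion_vs_theta"] = ols_r2(st["excl_22_pct"].to_numpy(float), theta)
    return pd.DataFrame(rows, index=["r2", "slope", "p"]).T


def allelic_richness_change(fixtures: FixtureTables | None = None) -> pd.DataFrame:
    """Per-river contemporary-minus-historical rarefied-richness change."""
    fx = fixtures or load_fixture_tables()
    st = fx.stability
    out = pd.DataFrame(
        {
            "delta_ar": pd.to_numeric(st["ar_contemp"], errors="coerce")
            - pd.to_numeric(st["ar_hist"], errors="coerce"),
            "temporal_change": st["temporal_change"],
        }
    )
    return out
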