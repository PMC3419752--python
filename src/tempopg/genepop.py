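"""GenePop-format genotype I/O and the temporal-study container.

Genotypes are multilocus codominant diploid calls.  The in-memory currency is
:class:`GenotypeTable`: an ``(n_individuals, n_loci, 2)`` integer array of
allele codes with ``MISSING`` (= -1) marking absent calls, plus individual ids
and population labels.  GenePop files use fixed-width 2- or 3-digit allele
codes where ``00``/``000`` means missing; that sentinel is converted to
``MISSING`` on read so missing data can never be confused with a real code.

Samples are organised into a :class:`TemporalStudy`: per-river
:class:`SampleSet` objects keyed by (population, era) with era one of
``historical`` / ``intermediate`` / ``contemporary``, optional per-population
covariates and an optional declared neutral-locus subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

ERAS = ("historical", "intermediate", "contemporary")


class GenepopParseError(ValueError):
    """Raised when a GenePop file is malformed (message names the line)."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    locus_names
        Ordered locus labels.
    individual_ids
        Ordered individual labels (kept verbatim from the file).
    population_labels
        One label per individual; labels partition individuals into >= 1
        non-empty groups.
    calls
        ``(n, L, 2)`` integer array of allele codes; ``MISSING`` for absent
        calls.  The pair is unordered; no code ordering is assumed.
    """

    locus_names: list[str]
    individual_ids: list[str]
    population_labels: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.population_labels) != n:
            raise ValueError("one population label required per individual")
        bad = (self.calls != MISSING) & (self.calls <= 0)
        if bad.any():
            raise ValueError("allele codes must be strictly positive")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls are not representable")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def restrict_population(self, label: str) -> "GenotypeTable":
        idx = [i for i, p in enumerate(self.population_labels) if p == label]
        if not idx:
            raise KeyError(f"no individuals labelled {label!r}")
        return GenotypeTable(
            locus_names=list(self.locus_names),
            individual_ids=[self.individual_ids[i] for i in idx],
            population_labels=[label] * len(idx),
            calls=self.calls[idx],
        )

    def restrict_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        pos = {name: j for j, name in enumerate(self.locus_names)}
        missing = [l for l in loci if l not in pos]
        if missing:
            raise KeyError(f"unknown loci: {missing}")
        cols = [pos[l] for l in loci]
        return GenotypeTable(
            locus_names=list(loci),
            individual_ids=list(self.individual_ids),
            population_labels=list(self.population_labels),
            calls=self.calls[:, cols, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.locus_names == other.locus_names
            and self.individual_ids == other.individual_ids
            and self.population_labels == other.population_labels
            and bool(
                np.array_equal(
                    np.sort(self.calls, axis=2), np.sort(other.calls, axis=2)
                )
            )
        )


@dataclass
class SampleSet:
    """One population sampled in one era.

    ``years`` is the inclusive sampling-year range; multi-year windows are
    reduced to their midpoint downstream (rounded down).
    """

    population: str
    era: str
    years: tuple[int, int]
    genotypes: GenotypeTable

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise ValueError(f"era must be one of {ERAS}, got {self.era!r}")
        y0, y1 = self.years
        if y0 > y1:
            raise ValueError("years.start must be <= years.end")
        pops = set(self.genotypes.population_labels)
        if pops != {self.population}:
            raise ValueError(
                f"genotypes carry labels {sorted(pops)}; expected only "
                f"{self.population!r}"
            )

    @property
    def n(self) -> int:
        return self.genotypes.n_individuals

    @property
    def midpoint_year(self) -> int:
        return (self.years[0] + self.years[1]) // 2


@dataclass
class TemporalStudy:
    """Per-river samples keyed by (population, era), plus covariates."""

    samples: dict[tuple[str, str], SampleSet]
    covariates: pd.DataFrame | None = None
    neutral_locus_subset: list[str] | None = None

    @property
    def locus_names(self) -> list[str]:
        first = next(iter(self.samples.values()))
        return first.genotypes.locus_names

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self.samples:
            seen.setdefault(pop)
        return list(seen)

    def era_samples(self, era: str) -> list[SampleSet]:
        return [s for (pop, e), s in self.samples.items() if e == era]

    def get(self, population: str, era: str) -> SampleSet:
        return self.samples[(population, era)]

    def has(self, population: str, era: str) -> bool:
        return (population, era) in self.samples


def build_temporal_study(
    samples: Iterable[SampleSet],
    covariates: pd.DataFrame | None = None,
    neutral_subset: Sequence[str] | None = None,
) -> TemporalStudy:
    """Assemble a TemporalStudy, checking key uniqueness and locus agreement.

    All samples must share an identical locus list and order; populations may
    lack an era (intermediate samples exist for only some rivers).
    """
    out: dict[tuple[str, str], SampleSet] = {}
    ref_loci: list[str] | None = None
    for s in samples:
        key = (s.population, s.era)
        if key in out:
            raise ValueError(f"duplicate (population, era) key {key}")
        if ref_loci is None:
            ref_loci = s.genotypes.locus_names
        elif s.genotypes.locus_names != ref_loci:
            for a, b in zip(ref_loci, s.genotypes.locus_names):
                if a != b:
                    raise ValueError(
                        f"locus list mismatch in {key}: {b!r} != {a!r}"
                    )
            raise ValueError(f"locus list length mismatch in {key}")
        out[key] = s
    if not out:
        raise ValueError("no samples supplied")
    if covariates is not None:
        pops = {pop for pop, _ in out}
        unknown = set(covariates.index) - pops
        if unknown:
            raise ValueError(f"covariate rows for unknown populations: {sorted(unknown)}")
    subset = list(neutral_subset) if neutral_subset is not None else None
    if subset is not None:
        assert ref_loci is not None
        bad = [l for l in subset if l not in ref_loci]
        if bad:
            raise ValueError(f"neutral subset names unknown loci: {bad}")
    return TemporalStudy(out, covariates, subset)


# ---------------------------------------------------------------------------
# GenePop text format


def _split_genotype_fields(line: str) -> tuple[str, list[str]]:
    if "," not in line:
        raise GenepopParseError("individual line lacks ',' separator")
    ident, rest = line.split(",", 1)
    return ident.strip(), rest.split()


def read_genepop(path: str | Path, digits: int | str = "auto") -> GenotypeTable:
    """Read a GenePop file into a :class:`GenotypeTable`.

    Layout: title line; locus names one per line or comma-separated on one
    line; ``pop`` separators; then ``id , g1 g2 ...`` rows.  Allele code 0
    (``00`` / ``000``) maps to ``MISSING``.  Populations are auto-named
    ``pop1..popN``; explicit names belong in a sidecar metadata file.

    Parameters
    ----------
    digits
        2, 3 or ``"auto"``.  Under ``auto`` the width is inferred from the
        first genotype field and must be consistent throughout.
    """
    text = Path(path).read_text().splitlines()
    if not text:
        raise GenepopParseError("empty file")
    # locus header: lines until the first 'pop'
    loci: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        line = text[i].strip()
        if line:
            if "," in line:
                loci.extend(x.strip() for x in line.split(",") if x.strip())
            else:
                loci.append(line)
        i += 1
    if i == len(text):
        raise GenepopParseError("no 'pop' separator found")
    if not loci:
        raise GenepopParseError("no locus names before first 'pop'")

    width: int | None = None if digits == "auto" else int(digits)
    if width is not None and width not in (2, 3):
        raise ValueError("digits must be 2, 3 or 'auto'")

    ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    pop_no = 0
    for lineno in range(i, len(text)):
        raw = text[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_no += 1
            continue
        ident, fields = _split_genotype_fields(line)
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: expected {len(loci)} genotype fields, "
                f"got {len(fields)}"
            )
        row = np.empty((len(loci), 2), dtype=np.int32)
        for j, f in enumerate(fields):
            if width is None:
                if len(f) % 2 or len(f) // 2 not in (2, 3):
                    raise GenepopParseError(
                        f"line {lineno + 1}: cannot infer digit width from "
                        f"field {f!r}"
                    )
                width = len(f) // 2
            if len(f) != 2 * width:
                raise GenepopParseError(
                    f"line {lineno + 1}: field {f!r} is not {2 * width} "
                    f"characters wide"
                )
            a, b = int(f[:width]), int(f[width:])
            row[j, 0] = MISSING if a == 0 else a
            row[j, 1] = MISSING if b == 0 else b
            if (row[j] == MISSING).sum() == 1:
                # a half-missing genotype cannot be represented; treat the
                # whole call as missing
                row[j] = MISSING
        ids.append(ident)
        labels.append(f"pop{pop_no}")
        rows.append(row)
    if not rows:
        raise GenepopParseError("no individuals found")
    return GenotypeTable(loci, ids, labels, np.stack(rows))


def write_genepop(table: GenotypeTable, digits: int = 3, title: str = "tempopg export") -> str:
    """Serialise a table to GenePop text (input order preserved).

    Raises if any allele code needs more than ``digits`` digits, or if the
    table has no individuals.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if table.n_individuals == 0:
        raise ValueError("cannot write a table with no individuals")
    limit = 10**digits
    present = table.calls[table.calls != MISSING]
    if present.size and present.max() >= limit:
        j = int(np.argwhere((table.calls >= limit).any(axis=(0, 2)))[0, 0])
        code = int(table.calls[:, j][table.calls[:, j] >= limit].max())
        raise ValueError(
            f"allele code {code} at locus {table.locus_names[j]!r} does not "
            f"fit in {digits} digits"
        )
    out = [title]
    out.extend(table.locus_names)
    prev: str | None = None
    for i, ident in enumerate(table.individual_ids):
        pop = table.population_labels[i]
        if pop != prev:
            out.append("pop")
            prev = pop
        fields = []
        for j in range(table.n_loci):
            a, b = table.calls[i, j]
            fa = 0 if a == MISSING else int(a)
            fb = 0 if b == MISSING else int(b)
            fields.append(f"{fa:0{digits}d}{fb:0{digits}d}")
        out.append(f"{ident} , " + " ".join(fields))
    return "\n".join(out) + "\n"


def read_metadata_sidecar(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated sidecar mapping pop blocks to river metadata.

    Columns: population, era, year_start, year_end.  Row order matches the
    order of ``pop`` blocks in the companion GenePop file.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"population", "era", "year_start", "year_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"sidecar must have columns {sorted(required)}")
    return df


def study_from_genepop(
    genepop_path: str | Path,
    sidecar_path: str | Path,
    digits: int | str = "auto",
    covariates: pd.DataFrame | None = None,
    neutral_subset: Sequence[str] | None = None,
) -> TemporalStudy:
    """Read a GenePop file plus metadata sidecar into a TemporalStudy."""
    table = read_genepop(genepop_path, digits=digits)
    meta = read_metadata_sidecar(sidecar_path)
    blocks = table.populations()
    if len(meta) != len(blocks):
        raise ValueError(
            f"sidecar has {len(meta)} rows but file has {len(blocks)} pop blocks"
        )
    samples = []
    for block, row in zip(blocks, meta.itertuples(index=False)):
        sub = table.restrict_population(block)
        sub = GenotypeTable(
            sub.locus_names,
            sub.individual_ids,
            [str(row.population)] * sub.n_individuals,
            sub.calls,
        )
        samples.append(
            SampleSet(
                population=str(row.population),
                era=str(row.era),
                years=(int(row.year_start), int(row.year_end)),
                genotypes=sub,
            )
        )
    return build_temporal_study(samples, covariates, neutral_subset)
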