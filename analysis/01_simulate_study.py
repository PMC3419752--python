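#!/usr/bin/env python
"""Generate the synthetic 21-river temporal study used by the later steps.

Six rivers receive 30%-per-generation farm introgression between the
historical (1980) and contemporary (2010) sampling years; the other fifteen
evolve by drift alone.  Writes GenePop genotypes, the metadata sidecar and
the truth record under scratch/synthetic_study/ (regenerate with this
script; the later steps read from there).
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic_study"

from tempopg.genepop import write_genepop
from tempopg.synthetic import ScenarioConfig, scenario_study

SEED = 20120815


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ScenarioConfig(seed=SEED, introgression={i: 0.3 for i in range(6)})
    study, truth = scenario_study(cfg)

    rows = []
    tables = []
    for (pop, era), s in study.samples.items():
        rows.append(f"{pop}\t{era}\t{s.years[0]}\t{s.years[1]}")
        tables.append(s.genotypes)
    # one file, one pop block per sample, sidecar rows in block order
    from tempopg.genepop import GenotypeTable
    import numpy as np

    merged = GenotypeTable(
        tables[0].locus_names,
        [i for t in tables for i in t.individual_ids],
        [f"block{k}" for k, t in enumerate(tables) for _ in t.individual_ids],
        np.concatenate([t.calls for t in tables]),
    )
    (OUT / "study.gen").write_text(write_genepop(merged, digits=2))
    (OUT / "study_meta.tsv").write_text(
        "population\tera\tyear_start\tyear_end\n" + "\n".join(rows) + "\n"
    )
    (OUT / "truth.tsv").write_text(
        "population\tintrogression_per_generation\n"
        + "\n".join(f"{p}\t{m}" for p, m in truth.introgression.items())
        + "\n"
    )
    n_tot = sum(s.n for s in study.samples.values())
    print(f"wrote {len(study.samples)} samples, {n_tot} fish, "
          f"{len(study.locus_names)} loci -> {OUT}")
    print("introgressed rivers:",
          [p for p, m in truth.introgression.items() if m > 0])


if __name__ == "__main__":
    main()
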