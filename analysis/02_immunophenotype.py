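#!/usr/bin/env python
"""Classify immune phenotypes of the simulated paired components.

Reads results/synthetic/til_fields.tsv, averages each component's five
fields, applies the 10%-density classifier and summarizes the cohort
distribution per component (no inflamed phenotype is expected under the
simulated conditions).
"""

import argparse
from collections import defaultdict
from pathlib import Path

from asc_time.io import Component, TILFieldMeasurement, read_table
from asc_time.phenotype import call_phenotype, cohort_distribution


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path,
                        default=Path("results/synthetic"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/phenotype_calls.tsv"))
    args = parser.parse_args()

    fields = read_table(args.in_dir / "til_fields.tsv", TILFieldMeasurement)
    groups = defaultdict(list)
    for f in fields:
        groups[(f.sample_id, f.component)].append(f)
    calls = [call_phenotype(fs) for fs in groups.values()]

    lines = ["sample_id\tcomponent\tmean_intratumoral\tmean_stromal\t"
             "phenotype"]
    for c in sorted(calls, key=lambda c: (c.sample_id, c.component.value)):
        lines.append(f"{c.sample_id}\t{c.component.value}\t"
                     f"{c.mean_intratumoral:.3f}\t{c.mean_stromal:.3f}\t"
                     f"{c.phenotype.value}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text("\n".join(lines) + "\n")

    for comp in (Component.ACC, Component.SCCC):
        dist = cohort_distribution(calls, component=comp)
        pretty = ", ".join(f"{ph.value} {cnt} ({100 * prop:.0f}%)"
                           for ph, (cnt, prop) in sorted(
                               dist.items(), key=lambda kv: kv[0].value))
        print(f"{comp.value}: {pretty}")
    print(f"calls -> {args.out}")


if __name__ == "__main__":
    main()
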