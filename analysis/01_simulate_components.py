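#!/usr/bin/env python
"""Simulate a paired-component cohort: every downstream stage's input.

Emulates 28 biphasic tumors, each with an adenocarcinoma (ACC) and a
squamous (SCCC) component, under the study conditions: squamous
components lean toward the immune-desert phenotype and carry higher
PD-L1/PD-1/Treg levels, more mutations (sharing a trunk with the paired
ACC) and higher TCR clonality.  Tables land under results/synthetic/.
"""

import argparse
from pathlib import Path

from asc_time.io import Component, write_table
from asc_time.synthetic import (
    ACC_PHENOTYPE_PERCENTS,
    SCCC_PHENOTYPE_PERCENTS,
    gen_mif_cells,
    gen_repertoire,
    gen_til_fields,
    gen_variants,
)

N_SAMPLES = 28
CELLS_PER_COMPONENT = 4000
CLONES_PER_REPERTOIRE = 150


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path,
                        default=Path("results/synthetic"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    import numpy as np
    rng = np.random.default_rng(args.seed)

    til, cells, acc_vars, sccc_vars = [], [], [], []
    acc_clones, sccc_clones = [], []
    for i in range(N_SAMPLES):
        sid = f"ASC-{i + 1:02d}"
        # ACC components: mostly excluded; SCCC: roughly half desert
        acc_ph = "excluded" if rng.uniform() < 0.77 else "desert"
        sccc_ph = "excluded" if rng.uniform() < 0.47 else "desert"
        til += gen_til_fields(acc_ph, 5, 2.0, seed=int(rng.integers(2**31)),
                              sample_id=sid, component=Component.ACC)
        til += gen_til_fields(sccc_ph, 5, 2.0,
                              seed=int(rng.integers(2**31)),
                              sample_id=sid, component=Component.SCCC)
        cells += gen_mif_cells(CELLS_PER_COMPONENT,
                               phenotype_props=ACC_PHENOTYPE_PERCENTS,
                               seed=int(rng.integers(2**31)),
                               sample_id=sid, component=Component.ACC)
        cells += gen_mif_cells(CELLS_PER_COMPONENT,
                               phenotype_props=SCCC_PHENOTYPE_PERCENTS,
                               seed=int(rng.integers(2**31)),
                               sample_id=sid, component=Component.SCCC)
        n_acc = int(rng.integers(2, 9))        # ~ 1.4-11.4 mut/Mb range
        n_sccc = int(rng.integers(3, 12))
        shared = min(2, n_acc, n_sccc)
        a = gen_variants(n_acc, n_pass_syn=2, n_fail_vaf=1, n_fail_reads=1,
                         seed=int(rng.integers(2**31)))
        s = gen_variants(n_sccc, n_pass_syn=1, n_fail_bias=1,
                         shared_with=a, shared_k=shared,
                         seed=int(rng.integers(2**31)))
        for v in a:
            acc_vars.append((sid, v))
        for v in s:
            sccc_vars.append((sid, v))
        c_acc = float(np.clip(rng.normal(0.272, 0.05), 0.05, 0.8))
        c_sccc = float(np.clip(c_acc + rng.normal(0.033, 0.02), 0.05, 0.8))
        acc_clones.append((sid, gen_repertoire(
            CLONES_PER_REPERTOIRE, round(c_acc, 3),
            seed=int(rng.integers(2**31)))))
        sccc_clones.append((sid, gen_repertoire(
            CLONES_PER_REPERTOIRE, round(c_sccc, 3),
            seed=int(rng.integers(2**31)))))

    write_table(til, out / "til_fields.tsv")
    write_table(cells, out / "mif_cells.tsv")
    for name, items in (("acc_variants", acc_vars),
                        ("sccc_variants", sccc_vars)):
        lines = ["sample_id\tchrom\tpos\tref\talt\tvaf\thq_support_reads\t"
                 "consequence\tpe_bias"]
        for sid, v in items:
            lines.append(f"{sid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                         f"{v.vaf!r}\t{v.hq_support_reads}\t"
                         f"{v.consequence}\t{int(v.pe_bias)}")
        (out / f"{name}.tsv").write_text("\n".join(lines) + "\n")
    for name, items in (("acc_clones", acc_clones),
                        ("sccc_clones", sccc_clones)):
        lines = ["sample_id\tcdr3\tcount\tproductive"]
        for sid, rep in items:
            for c in rep:
                lines.append(f"{sid}\t{c.cdr3}\t{c.count}\t"
                             f"{int(c.productive)}")
        (out / f"{name}.tsv").write_text("\n".join(lines) + "\n")

    print(f"simulated {N_SAMPLES} paired tumors -> {out}")
    print(f"  TIL fields: {len(til)} rows; MIF cells: {len(cells)} rows")
    print(f"  variants: {len(acc_vars)} ACC / {len(sccc_vars)} SCCC")


if __name__ == "__main__":
    main()
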