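"""Instrument selection from summary-statistics files.

Writes a simulated exposure GWAS to disk, reads it back, and walks the
selection filters one at a time: genome-wide significance, greedy LD
clumping, confounder screen, then the strength metrics (per-SNP R²,
total R², F statistic).
"""

import tempfile
from pathlib import Path

from ivmr import (SelectionConfig, build_instrument_set, read_sumstats,
                  write_sumstats)
from ivmr.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(k=15, theta=0.1, gamma_sd=0.3, maf_range=(0.2, 0.5),
                       n_null_snps=500, ld_block_spec=((3, 0.9),),
                       confounder_spec=(("rs1004", "smoking", 1e-11),),
                       seed=5)
study = simulate_study(cfg)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "exposure.tsv"
    write_sumstats(study.exposure_table, path)
    table = read_sumstats(path, trait_label="exposure")
    print(f"read {len(table)} records "
          f"({len(table.rejections)} malformed rows rejected)")

sel = SelectionConfig(p_threshold=5e-8, n_exposure=cfg.n_exp,
                      confounder_traits=("smoking",))
iv = build_instrument_set(table, study.ld, study.catalog, sel)

for step in iv.provenance:
    print(f"  {step.step:<22}{step.n_in:>5} → {step.n_out:>4} "
          f"(dropped {len(step.dropped)})")
print(f"\n{iv.k} instruments; total R² = {iv.total_r2:.4f}; "
      f"F = {iv.f_statistic:.1f} — "
      f"{'strong' if iv.is_strong else 'weak'} by the F > 10 convention")
print("the planted confounder-associated SNP (rs1004) and the two planted "
      "LD tags are removed at their own stages, as the log shows.")
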