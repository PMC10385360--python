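# camoil

Analysis toolkit for seed-oil dynamics during *Camellia* seed desiccation.

Camellia seed oil (an oleic-acid-dominated triacylglycerol) is laid down
during seed maturation and can be partially degraded again during the final
desiccation weeks, so harvest timing decides oil yield. `camoil` implements
the quantitative analyses needed to characterize that window from weekly
kernel samples of multiple germplasms:

* **FAME quantification** — GC-FID peak tables with a margaric-acid (17:0)
  internal standard are converted to per-species contents (% of kernel dry
  mass), total oil, and mole-percent composition:
  `mass_i = m_IS · (A_i / A_IS) · rf_i`, `content_i = mass_i / m_kernel`,
  with the composition ratios USFA/SFA, MUFA/PUFA and 18C/16C on a mole
  basis.
* **Enzyme-activity proxies** — the fatty-acid biosynthesis pathway maps
  each core enzyme (KASII, FatB, SAD, FAD2, FAD3, FAE) to a fixed product
  pool (e.g. KASII → {18:0, 18:1Δ9, 18:2, 18:3, 20:0}); the week-over-week
  change of a pool's summed content, Δ_E(t) = P_E(t) − P_E(t−1), is a
  relative in-planta activity proxy, and the mean pairwise Pearson r of the
  Δ series quantifies how synchronized the enzymes fluctuate.
* **Correlation networks** — Pearson correlations (two-tailed, t test with
  n−2 df) among total oil and individual fatty-acid weekly series, with
  significant-positive / significant-negative / ns edge classes and
  cross-cultivar network comparison.
* **Cross-cultivar DEG screen** — reciprocal-best-hit homolog pairing
  between two cultivars' gene sets, within-cultivar late/early fold changes
  on FPKM, the *ratio of ratios* fc_M43 / fc_HG with a ">2-fold" cutoff
  (undefined ratios printed "~" are retained), lipid-pathway KEGG
  filtering, and classification into five expression patterns
  (I up/up, II down/down, III down/up, IV down/constant, V constant/up).
  2^−ΔΔCt arithmetic for qPCR validation is included.
* **Synthetic data** — generators for every pipeline input (peak tables,
  time courses, expression tables, homolog score matrices, annotations)
  with stored ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from camoil import PeakTable, quantify, composition_ratios, load_candidate_table, screen
from collections import Counter

peaks = PeakTable(
    "M43_w52_r1", kernel_mass_mg=10.0, is_area=4.0e5,
    peaks={"16:0": 2.0e5, "18:0": 0.5e5, "18:1d9": 1.8e6, "18:2": 2.3e5, "18:3": 0.2e5},
)
profile = quantify(peaks)
print("total oil  %.2f %% dry mass" % profile.total_oil)
print("oleic acid %.1f mol%%" % profile.mol_pct["18:1d9"])
r = composition_ratios(profile)
print("USFA/SFA %.2f  MUFA/PUFA %.2f  18C/16C %.2f" % (r.usfa_sfa, r.mufa_pufa, r.c18_c16))

records, _ = load_candidate_table()
kept = screen(records, cutoff=2.0)
print(len(kept), "candidates:", dict(sorted(Counter(x.group for x in kept).items())))
```

prints

```
total oil  4.31 % dry mass
oleic acid 77.5 mol%
USFA/SFA 7.60  MUFA/PUFA 7.14  18C/16C 9.54
58 candidates: {'I': 6, 'II': 5, 'III': 6, 'IV': 15, 'V': 26}
```

The first block quantifies one GC-FID sample against 75 μg of internal
standard: every peak area is scaled by its ratio to the standard's area, so
the 1.8e6-area oleic peak is 4.5× the standard's 4.0e5 → 337.5 μg → 3.375 %
of the 10 mg kernel, and 77.5 % of total fatty-acid moles. The second block
loads the packaged 58-gene candidate table, applies the >2 ratio-of-ratios
screen, and partitions the candidates into the five expression patterns.

The same operations are available from the shell:

```sh
camoil simulate --seed 3 --outdir sim          # synthetic inputs + truth.json
camoil quantify sim/peaks.tsv --out profiles.tsv
camoil flux sim/timecourse.tsv --out-proxies proxies.tsv --out-synchrony sync.tsv
camoil correlate sim/timecourse.tsv --out edges.tsv
camoil screen --expression-hg sim/expression_hg.tsv --expression-m43 sim/expression_m43.tsv \
    --scores sim/scores.tsv --annotation sim/annotation.tsv --out candidates.tsv
```

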