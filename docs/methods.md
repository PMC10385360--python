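# Methods

## Scope and data model

The package analyzes weekly kernel samples of three *Camellia* germplasms
(two *C. meiocarpa* landraces, QG and HG, and the *C. oleifera* cultivar
M43) across the desiccation window, weeks 46–54 after anthesis, three
replicates per week, and a paired transcriptomic design (HG and M43 at an
early and a late desiccation timepoint, two replicates each). Ten
fatty-acid species are modeled, from 16:0 to 20:1Δ13; their chemical
metadata live in `species_registry` together with the pathway topology.

## Internal-standard quantification

FID response is treated as mass-proportional: with `m_IS` μg of margaric
acid (default 75 μg) spiked per sample,

    mass_i = m_IS · (A_i / A_IS) · rf_i        [μg]
    content_i = mass_i / (m_kernel · 1000) · 100   [% dry mass]

Response factors `rf_i` default to 1.0 (areas normalized directly to the
standard); a per-species table can be supplied. Contents are reported on
the as-measured FAME-equivalent scale; a single multiplicative
FAME-to-free-acid correction is exposed (`fame_correction`, default 1.0).
Mole percent divides each species' mass by its **free-fatty-acid**
molecular weight (16:0 = 256.43, 18:1 = 282.47 g/mol, …) and normalizes to
100; free-acid weights were chosen over methyl-ester weights because the
composition is reported for the acids themselves, and the registry is
configurable if an ester basis is preferred. A sample with no nonzero
peaks yields total oil 0 with an undefined (empty) composition and a
warning rather than an error. Composition ratios (USFA/SFA, MUFA/PUFA,
18C/16C) are computed on the mole basis; a zero denominator class returns
`inf` with a warning.

## Enzyme-activity proxies

Each enzyme's activity proxy is the week-over-week difference of the
summed content of its downstream product pool:

| enzyme | pool |
| --- | --- |
| KASII | 18:0, 18:1Δ9, 18:2, 18:3, 20:0 |
| FatB  | 16:0 |
| SAD   | 18:1Δ9, 18:2, 18:3 |
| FAD2  | 18:2, 18:3 |
| FAD3  | 18:3 |
| FAE   | 18:1Δ11, 20:1Δ13 |

The pools nest (FAD3 ⊂ FAD2 ⊂ SAD ⊂ KASII), which yields the useful
identity Δ(KASII) − Δ(SAD) = weekly change of the 18:0 + 20:0 sum, used as
a test invariant. 20:0 is kept in the KASII pool — its 18:0 precursor
passes through KASII even though the final elongation step is
ER-associated. The FatB proxy is Δ16:0 alone; no correction is made for
16:1 consumed by the elongase branch. Design choices:

* Proxies are computed on replicate means; units are % dry mass per week.
  They are *relative* indicators — no conversion to molar flux is
  attempted, since pool differences conflate synthesis, interconversion
  and turnover.
* Non-consecutive sampling: differences between adjacent samples are
  divided by the gap length in weeks, so a missed week does not inflate
  apparent activity. The telescoping identity (Σ deltas = last − first
  pool content) then holds exactly for weekly sampling.
* Synchrony is summarized as the mean pairwise Pearson r of the delta
  series, optionally windowed; this is a descriptive statistic defined by
  this package ("highly synchronized" has no canonical formula). Pairs
  with a zero-variance series (typically FAD3 when 18:3 is flat) are
  recorded as missing rather than NaN and excluded from the mean.

## Correlation networks

Nodes are the weekly replicate-mean series of total oil and each species
(n = number of sampled weeks, 9 in the default design). Pearson r with the
classical two-tailed test (t distribution, n−2 df, via
`scipy.stats.pearsonr`) classifies each edge as significant positive,
significant negative, or ns at α = 0.05 — the conventional default for
bivariate-correlation software, since no explicit level is attached to the
published networks. Edges are tested marginally, without multiple-testing
correction, matching the source analysis; a Benjamini–Hochberg option
(`bh_correction=True`, via statsmodels) is provided and logged when used.
Constant series give ns edges with r recorded as missing. Network
comparison lists edges whose class differs between cultivars.

## Cross-cultivar DEG screen

Homologs are paired by reciprocal best hit on a similarity score matrix;
ties for best hit are broken toward the lexicographically smallest partner
id (the choice is arbitrary but deterministic). Within each cultivar the
late/early fold change is

    fc = (mean FPKM_late + c) / (mean FPKM_early + c),  c = 0.1 FPKM

the pseudo-count stabilizing ratios at low expression. Significance is
tested on log2(FPKM + c). **With two replicates per timepoint a per-gene
test has ~1 residual df and essentially no power, so the default test is a
moderated t**: each gene's pooled variance is shrunk toward the cohort
median with 4 prior df (a fixed-prior simplification of limma's empirical
Bayes), and the statistic is referred to a t distribution with prior +
residual df. An a-priori power analysis at the design conditions (NB
dispersion 0.1, n = 2) gives ~0.98 power at |log2FC| = 2 with a calibrated
5% type-I rate, versus ≤ 0.36 for per-gene Welch at the same effect size.
Per-gene Welch's t remains available (`method="welch"`; `fold_change`
implements it) for users who prefer a test with no cross-gene sharing.

The screen itself: ratio = fc_M43 / fc_HG; records are retained when the
ratio exceeds 2 (or is the "~" sentinel: HG fold change zero or an
infinite fold change, i.e. undetected in one condition), at least one KEGG
annotation falls in the lipid-metabolism pathway set (ko00061…ko01040,
including the steroid/terpenoid branches tracked as TAG-conversion sinks),
and the pair is not constant in both cultivars. Per-cultivar status is
**up** (fc > 2 and p < α), **down** (fc < 0.5 and p < α), else
**constant** — so a >2-fold but non-significant change is constant, which
is the only reading under which the published group labels are internally
consistent (several "constant" entries have fold changes of 2.1–2.9). The
(HG, M43) status pair maps to groups I–V; other combinations are labeled
"other". Ratios are held at full precision internally and rounded to
2 d.p. only at output.

The packaged `data/candidate_table.tsv` transcribes the published 58-gene
candidate list. It prints fold changes and group labels but no p-values,
so the loader reconstructs significance flags from the labels (p = 0.01
where the label requires a significant change, p = 1.0 where it requires
constant); the classifier and screen then reproduce the printed partition
6/5/6/15/26 from those inputs. One gene id appears in two different pairs
in the printed table and is kept as printed — the table is a transcription,
whereas the package's own RBH pairing can never emit a duplicated gene.

qPCR validation arithmetic is the standard 2^−ΔΔCt fold difference.

## Synthetic-data generators

The generators define the test conditions for the whole pipeline and store
ground truth alongside every output.

**Time courses.** Piecewise-linear weekly templates (inspectable knots, no
spline fitting) with an oleic-dominant base composition (75% 18:1Δ9, 8.5%
16:0, 9.5% 18:2 by mass, total oil 26–44% dry mass — typical Camellia
kernel values):

* *QG-like*: near-linear rise to week 53, then one-week loss of a
  configurable fraction (default 25%) applied uniformly across species.
* *M43-like*: biphasic rise peaking at weeks 49 and 52, then a 30% loss by
  week 54; 20:1Δ13 is decoupled from total oil in this template only,
  planting the germplasm-specific 20:1 correlation difference the network
  comparison must detect.
* *HG-like*: fast early rise then plateau with a mild terminal increase;
  after week 50, 18:1Δ9 keeps rising at the expense of 18:2 and 16:0,
  which drives the FAD2 proxy discordant with KASII/SAD while total oil
  stays flat.

Replicate noise is multiplicative lognormal with CV 5% (mean-preserving),
three replicates. The truth record stores the noiseless trajectories, the
per-enzyme proxy sign patterns they imply, and the loss fractions. Peak
tables are back-calculated from contents (10 mg kernel, 75 μg standard) so
quantification recovers the time course exactly.

**Expression.** 400 lipid-pathway homolog pairs plus 100 off-pathway pairs
and 20 non-reciprocal decoy genes per side. Counts are negative binomial
(variance μ + αμ², dispersion α = 0.1; α = 0 returns exact means — the
zero-noise limit), scaled to FPKM via gene lengths of 1–3 kb and a
2×10⁷-read library; baselines span 3–300 FPKM. The 58 planted candidates
follow the published group sizes with log2 fold-change pairs
I (+2, +4), II (−4, −2), III (−2, +2), IV (−2.5, 0), V (0, +2.5) — every
DE side at |log2FC| ≥ 2 and every planted ratio ≥ 4, magnitudes inside the
published fold-change range; 40 non-candidate lipid pairs move equally in
both cultivars (ratio 1) and the rest are flat. All randomness flows from
one explicitly passed seeded generator; a fixed seed reproduces
byte-identical files.

**What the generators do not emulate:** chromatographic artifacts
(co-elution, drift, detection limits), length or GC bias and library-size
variation in RNA-seq, paralogy and partial assemblies in the homolog
matrix, and correlated noise across weeks. Passing tests therefore
demonstrate correctness of the computations under the stated statistical
model, not robustness to every real-data pathology.

## Numerical conventions and limitations

* Time-course TSVs are written with `%.17g` and read with round-trip float
  parsing, so write/read is exact.
* Missing species are treated as zero content with a warning; unknown
  species or enzymes raise registry errors.
* Welch p-values degenerate cleanly when both groups have zero variance
  (p = 1 for equal means, else 0); the moderated test does the same when
  the whole cohort is noiseless.
* The planted-truth recovery rate under the default noisy conditions is
  ~95% on average and hovers near the 90% bar for unlucky seeds; the
  dominant loss is the ratio gate (the ratio estimator has ≈0.63 log2
  units of standard error at n = 2, against a 1-log2 margin between the
  planted ratio of 4 and the cutoff of 2). This is a property of the
  two-replicate design, not of the implementation.
* Correlation networks use n = 9 weekly means; with so few points the
  per-edge power is modest and only edge classes, not r magnitudes, should
  be interpreted.
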