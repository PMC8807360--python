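# Methods

`fpscape` implements a sequence-stratified analysis of genome regulation:
the genome is segmented into CGI-rich **forests** (F) and CGI-poor
**prairies** (P) from inter-CGI spacing alone, and DNA methylation, Hi-C
contact structure and gene expression are then quantified relative to that
segmentation. This note records the models, the operative definitions of
every statistic, the synthetic study conditions used by the test suite and
the acceptance script, and the design choices made where more than one
reasonable convention exists.

## Segmentation

**Critical distance.** Neighbouring-CGI gap lengths are histogrammed in 50
log-spaced bins and compared with the gap-length distribution expected if
the same number of islands (with their observed lengths) were placed
uniformly on the same mappable length (20 simulated placements by default;
a closed-form exponential alternative is available). The critical distance
`d*` is the geometric midpoint of the first bin at which the
observed/expected density ratio falls below 1 and stays below for at least
3 consecutive occupied bins. Two guards keep the scan statistical rather
than cosmetic: bins with expected count < 5 are ignored (empty log bins at
the short-gap end otherwise produce spurious sub-100-bp crossings), and
the pooled deficit over the 3-bin run must exceed 3 Poisson standard
deviations (otherwise a genuinely random CGI placement yields a crossing
by noise; such inputs raise "no clustering detected"). Fewer than 50 CGIs
raises "insufficient CGIs".

**Forests and prairies.** A forest is a maximal run of **two or more**
consecutive CGIs whose internal gaps are all `< d*`, extended outward into
each flanking gap by `min(gap/2, d*/2)`, and kept only if the extended
span exceeds `d*`. Everything else, minus user-supplied excluded
intervals, is prairie. Two details of this rule were genuinely open and
are fixed as follows:

* the span test applies **after** flank extension — testing the raw CGI
  run span instead silently discards small trailing clusters at forest
  edges and recedes the recovered boundary by more than one CGI gap;
* a lone CGI can never seed a forest — it has no sub-critical neighbour
  distance, and keeping this rule is what leaves isolated prairie CGIs in
  prairies (the P-CGI class of the four-class analyses would otherwise be
  empty).

Domains tile each chromosome exactly (forest + prairie + excluded length
equals chromosome length, asserted), adjacent domains alternate labels,
and segmentation is deterministic given the inputs.

**Derived layers.** Open sea is the complement of all CGIs extended by
±4,000 bp. Bins (40 kb for Hi-C work, 1 kb for density groups) are
labelled: CGI bin if ≥ 1 bp of CGI overlaps; domain label by majority
base-pair overlap with ties resolved to P (conservative for forest-specific
claims); CpG density as dinucleotides per kb. The 1-kb CpG-density groups
I–IV use boundaries (2.0, 20.1], (1.0, 2.0], (0.5, 1.0], (0, 0.5] in
percent per 100 bp, so 2.0% at 1 kb means 20 CpGs; CGIs (minimum density
2.4%) fall in group I.

## Methylation statistics

Per-CpG methylation is `β = M/(M+U)·100%`, computed only where coverage
`M+U` strictly exceeds 3; plus/minus strand calls at one CpG dinucleotide
are summed before filtering. A domain's open-sea methylation `q` is the
**unweighted** mean β (as a fraction) over covered open-sea CpGs inside
it — coverage weighting was rejected for robustness to coverage
heterogeneity; domains with fewer than `min_cpg` contributing CpGs are
undefined. The methylation-difference index of interior domain *i* is

    MDI_i = (q_i − (q_{i−1}+q_{i+1})/2) / ((q_i + q_{i−1} + q_{i+1})/3)

which is scale invariant, bounded in [−3, 3] for positive q, and undefined
for terminal domains or undefined flanks (an all-zero trio warns). The
per-sample summary is the arithmetic mean of defined MDIs per label. Note
that averaged MDI magnitudes depend on the segmentation's granularity:
small mislabelled slivers contribute near-zero contrasts and dilute the
mean, so samples should be compared on a common domain set.

Group-wise methylation change aggregates shared covered CpGs to the
grouping's bins by mean and reports mean/median/histogram of `β_b − β_a`
(fraction scale) per group; histogram edges are fixed at [−1, 1] in steps
of 0.05 so outputs are comparable across samples. Solo-WCGW sites require
both nearest CpG neighbours > 35 bp away (the default window is exposed)
and A/T immediate flanks.

## Contact-matrix statistics

**Preprocessing.** Bins overlapping structural-variant intervals are
masked, as are bins with zero contact to more than 99% of other bins.
Iterative correction runs 50 iterations or to a relative change of 1e−5;
chromosomes with fewer than 10 usable bins are dropped. Balancing a
balanced matrix changes entries by < 1e−4 (asserted in tests).

**Compartments.** The 40-kb matrix is summed 5×5 to 200 kb and
re-balanced. Per chromosome arm (p/q split at the centromere; arms under
20 usable bins skipped): observed/expected by per-diagonal means
(pseudocount 1e−9), Pearson correlation matrix, leading eigenvector. The
sign is oriented to correlate positively with per-bin CpG density (the
open A compartment is the CGI/gene-rich one); A where the component is
positive. The compartment index uses natural log,

    CI_i = ln[ (Σ_{j≠i} C_ij δ_j / N_A') / (Σ_{j≠i} C_ij (1−δ_j) / N_B') ]

where the divisor for the bin's own class excludes the bin itself
(N' = N − 1), i.e. both terms are genuine means over actual partners; with
self-inclusive divisors a bin contacting the two classes at 3:1 would not
report ln 3. Zero contact to a class gives a missing CI.

**Distance decay and segregation.** Contacts are pooled genome-wide into
log-spaced separation bins (2 per octave, 80 kb–100 Mb) and averaged per
pair type (FF/PP/FP by the two bins' majority domain labels; diagonal
excluded; bins with < 10 pairs missing). Each bin also records the
pair-weighted mean separation, which is the abscissa used for slope fits
(the geometric bin midpoint biases coarse log bins). Decay slopes are
least-squares fits of log10 P against log10 s per window; default windows
are half-decades sliding by quarter-decades over 200 kb–20 Mb. Segregation
factors `SF_F = P_FF/P_FP` and `SF_P = P_PP/P_FP` are computed from
per-diagonal observed/expected values pooled within each bin: computing the
ratio of pooled raw means instead lets the decay law leak through uneven
pair-type composition inside a coarse bin and biases SF by several percent
even for label-independent matrices. Sample clustering uses single-linkage
("nearest point") agglomeration on Euclidean distances between slope
vectors; missing slopes are imputed by the sample's row mean with a
warning.

**Interaction strength.** For each unmasked 40-kb bin k and the four
classes {F-CGI, F-non-CGI, P-CGI, P-non-CGI}: `I(k, R) = C(k, R)/Σ C`,
self-contact excluded; rows sum to 1. A CGI bin is *aggregated* in a
cancer sample when its same-type I rises above the normal value by more
than ε (default 0; the planted-recovery experiments use ε = 0.02, about
twice the sampling noise of I at the study depth); *conservative* when
aggregated in every provided cancer sample; *less segregated* when the
same-type I falls in the queried sample.

**Contact loss.** For every unmasked bin, the mean contact with **all**
unmasked bins at separations of 600 kb–2 Mb is computed in both samples; a
bin shows contact loss when that value exceeds the per-chromosome mean
over all bins in the normal sample and falls below it in the cancer
sample. Forest bins are enriched in contacts at these TAD-scale
separations and therefore sit structurally above the all-bin average,
which is what makes the rule selective; only forest bins are reported by
default. Restricting the band mean to same-type partners was considered
and rejected: under that variant a bin whose contacts change only in the
cancer sample is above the normal-sample mean only by chance, and the rule
stops being a detector.

**Insulation.** For two adjacent regions, `IS = ln(1 + a1/b + a2/b)` with
a1/a2 the within-region means (diagonal excluded) and b the between-region
mean; natural log throughout (base only shifts the scale). The boundary
profile computes IS for sliding windows `A1 = [p−w, p)`, `A2 = [p, p+w)`
at bead positions within ±1 Mb of each forest/prairie boundary with
sufficient flank, orienting forests to the left before averaging.

## Synthetic study conditions

The generators plant every effect the pipeline is meant to recover; their
defaults are the study conditions for all tests and for
`scripts/acceptance.py`. Toy scale: one 50-Mb chromosome with a 1-Mb
centromere, 40-kb bins (1,250 bins), 2,000 genes.

* **Genome.** Alternating forest/prairie plan, forest lengths uniform in
  1.5–3.5 Mb, prairies 3–6 Mb (≈ 35% forest by length). Inter-CGI gaps are
  exponential with mean 10 kb in forests and 350 kb in prairies; CGI
  lengths uniform in 0.5–1.5 kb. CpGs are placed at mean spacings of 12 bp
  inside CGIs (density ≈ 8%, above the 2.4% CGI minimum), 100 bp in forest
  open sea and 250 bp in prairie open sea, so forests are CpG-denser at
  every scale (this is also what orients the compartment eigenvector).
  Thirty percent of genes are anchored at CGIs; gene lengths are 2–10 kb.
* **Methylome.** Open-sea means q_F = 0.85, q_P = 0.70; each cancer stage
  subtracts δ_P = 0.07 from prairies and δ_F = 0.01 from forests (the
  planted prairie-preferential hypomethylation); CGI CpGs sit at β = 0.10
  except a fixed 10% subset hypermethylated to 0.60 in cancer; per-CpG
  means jittered with sd 0.05 and sampled as Binomial(30, β*). At this
  depth the per-domain q estimates land within ±0.01 of the planted values
  for domains with ≥ 100 CpGs, and the analytic forest MDI —
  (q_F − q_P)/((q_F + 2 q_P)/3) = 0.20 in normal, 0.55 at stage 3 — is
  reproduced by the pipeline.
* **Hi-C.** Expected contacts `A[t_i, t_j]·C(s)` with affinities
  A_FF = 2.0, A_PP = 1.6, A_FP = 1.0 (forests segregate more strongly than
  prairies at short range, so SF_F > SF_P > 1) and decay C(s) ∝ s^−0.7 in
  normal; in cancer a continuous piecewise law with exponent 0.56 below
  800 kb and 1.38 above (the planted scale separation). Forest-forest
  contacts at 600 kb–2 Mb are further enriched 1.6× in both conditions — a
  TAD-scale row pattern that, unlike a marginal (row-sum) effect, survives
  iterative correction and is what places forest bins above the all-bin
  band average. Planted changes in cancer: same-four-class contacts of 50
  "conservative" CGI bins (plus 20 per-sample-specific bins) boosted
  1.5×; the band contacts of 20 forest-interior loss bins (chosen ≥ 600 kb
  apart so planted effects do not overlap) attenuated to 0.25×. Counts are
  Poisson at depth 60 (mean adjacent-bin count ≈ 100) and symmetric;
  centromere bins are empty.
* **Expression.** Negative-binomial counts (dispersion 0.2) with group
  mean TPM-scale bases F-CGI 300, F-non-CGI 150, P-CGI 180, P-non-CGI 60;
  count means scale with gene length so the planted effects live on the
  TPM scale (otherwise gene-length differences between classes confound
  the contrasts). Cancer multiplies F-CGI means by 2. Twenty samples per
  condition with ±20% library-size variation. The tissue table has 8
  tissues and 100 planted specific genes at 5× their other-tissue level
  (s = (5−1.5)/1.5 = 2.33 > 2).

All draws descend from one seed through fixed per-component substreams, so
a configuration and seed reproduce byte-identical outputs; persistent
structural state (planted bin sets, hypermethylated CGIs) is drawn once
per study and shared across conditions and samples.

**Controlled contact experiments.** The planted-recovery measurements for
contact loss and conservative CGIs use `isolated_contact_config()`: both
conditions share the normal decay exponent and sampling is deepened to
400, so the planted boosts/attenuations are the only systematic difference
between the matrices and the band-mean standard error (≈ 1%) sits well
inside the structural margins. Under the full cancer phenotype the global
decay change moves every bin's statistics — the qualitative direction
checks cover that regime instead.

## What passing tests do and do not show

The generators emulate two-regime CGI spacing, domain-level methylation
with binomial sampling noise, block-plus-decay contact structure with shot
noise, and group-structured counts. They do **not** emulate: structural
variants or karyotype changes, replication-timing or PMD fine structure,
real TAD/loop architecture (the band enrichment is a caricature),
coverage heterogeneity along the genome, multiple chromosomes, or
inter-patient variability. Recovery at the planted conditions therefore
demonstrates correctness of the statistics and their estimators, not
robustness to every artefact of real data.

Two behaviours of the real pipeline are worth knowing:

* With exponential within-forest gaps, the estimated d* lands at ≈ 1.6–2×
  the forest gap mean, so ~15% of forest gaps exceed it and threshold
  segmentation fragments forests into runs separated by thin prairie
  slivers. Planted *boundaries* are still recovered to within one CGI gap
  (0 violations over 266 boundaries × 20 seeds), but the recovered forest
  base-pair fraction underestimates the planted one and sliver-diluted
  MDI means are smaller than domain-table-based ones — compare samples on
  a common segmentation.
* The contact-loss rule thresholds at the population mean, so bins whose
  noiseless band mean sits within sampling noise of the threshold flip by
  chance; recall of the planted bins is ≈ 100% and false flags are ≤ 0.5%
  of bins, but precision against the 20-bin planted list is bounded by
  those near-threshold bins (≈ 80–100% per seed).

## Numerical conventions

Coordinates are 0-based half-open internally; BED native; CpG reports
convert from 1-based on read. Logarithms: CI and IS natural, fold change
base 2, decay slopes base 10. Ties: bin domain labels to P; zero-distance
sample pairs in clustering ordered by sample name. Pseudocounts: 1e−9 in
observed/expected; +1 in the fold-change formula (applied after averaging
TPM across samples, as defined). Promoters are TSS −1000/+500 bp,
strand-aware; a gene's domain label follows its TSS. DE tables are
consumed (gene_id, log2FC, pvalue), never fitted here; up/down means
p < 0.05 and log2FC beyond ±1; "recurrent" means strictly more than 7
cancer types.
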