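# Methods

`epicen` implements the computational side of mapping a heritable
centromeric epiallele in an Arabidopsis-like system and quantifying its
consequences: the loss of DDM1-maintained DNA methylation exposes
centromeric retrotransposons, small RNAs produced from them sustain
H3K9me2-marked heterochromatin, and when both pathways are removed the
affected centromere mis-segregates. The package provides the analyses used
to localise such an epiallele (pooled-window bulked-segregant comparison,
McrBC-style marker epigenotyping, interval logic, an EMS suppressor SNP
scan), the windowed DMR rule that identifies where epiallelic suppressors
regain methylation, transposon-anchored metaplots, and the cytology
statistics — together with a synthetic-data generator that reproduces the
statistical structure all of these assume.

## Coordinates and data containers

All coordinates are 0-based, half-open. Per-cytosine calls are pandas
DataFrames with columns `chrom, pos, strand, context, n_meth, n_total`;
1-based dialects (the Bismark-style cytosine report) are converted at the
file boundary. Cytosine context follows the standard plant trinucleotide
rule read 5'→3' on the cytosine's own strand (CG; CHG = C-H-G; CHH = C-H-H,
H ∈ {A,C,T}). A cytosine whose two downstream bases contain N or run off
the chromosome end is "undetermined" and excluded from every windowed
summary — fabricating a context for it would bias boundary windows.

## The synthetic genome and methylomes

The toy genome is 5 chromosomes × 50 kb (the default): small enough that
every analysis runs in seconds, while preserving the 5-chromosome structure
the chromosome-attribution analysis needs. Each centromere (the central
40%) is tiled by a 180 bp satellite monomer with 2% divergence between
copies; the focal chromosome (Chr5) carries three ATHILA5 and three other
ATHILA retrotransposon copies embedded in its satellites; all chromosomes
carry two centromeric ATHILA copies, one ATHILA element per arm, and three
genes per arm. One ATHILA5 copy hosts the hairpin span (relative
coordinates 0.1–0.9 of the element), the template of the artificial
small-RNA hairpin.

Methylomes are simulated per cytosine: coverage ~ Poisson(`coverage_mean`,
default 20), methylated count ~ Binomial(coverage, target level), where the
target level depends on (annotation role, context) for the genotype. The
preset levels encode the biology the analyses rely on:

| genotype | satellites | ATHILA | genes/intergenic |
|---|---|---|---|
| triple RdRP mutant (wild-type-like heterochromatin) | CG .92 / CHG .65 / CHH .12 | CG .90 / CHG .60 / CHH .15 | CG ≤.08, non-CG .02 |
| + ddm1 (quadruple) | CG .05 / CHG .05 / **CHH .15 retained** | CG .05 / CHG .05 / CHH .04 | unchanged |
| epiallelic suppressor | quadruple + hyper loci in **all three contexts** (CG .85 / CHG .60 / CHH .25) | | |
| hairpin line | quadruple + CHG .55 / CHH .30 — **CG unchanged** — at ATHILA5 hairpin-homologous spans | | |

Poisson/Binomial is the simplest pair of models with the right support;
nothing downstream depends on overdispersion. Hairpin restoration acts *in
trans*: small RNAs silence by homology, so the restored interval is the
hairpin-homologous relative span of every ATHILA5 copy (orientation-aware),
not just the source element. This is what makes the metaplot contrast —
ATHILA5 copies other than the source gain CHG/CHH but not CG — observable
after the source element is excluded from its own group.

What the generator does **not** model: read-level data (FASTQ), bisulfite
conversion error, ONT signal, overdispersed coverage, sequence-dependent
methylation variation within a role, or meiotic (as opposed to mitotic)
segregation. Passing tests therefore demonstrate that the *procedures* are
correct and well-calibrated under clean sampling noise, not that they are
robust to every artefact of real libraries.

## Epigenetic recombinant lines

A line's informative chromosome set is one meiotic product of a
heterozygote carrying a fully hypomethylated (ddm1-derived) and a fully
methylated (WT-derived) homolog. Crossover counts per chromosome are
Poisson — `crossover_rate_arm` (default 1.0) on the arms,
`crossover_rate_centromere` (default 0.1) in the centromere, placed
uniformly within each region class — reflecting only the contrast that
matters: crossovers are rare in centromeres, which is precisely why
fine-mapping stalls there. The sterile epiallele is dominant: a line is
sterile iff the causative interval (default: the hairpin-source ATHILA5
element) is entirely ddm1-derived. With a point-like locus the two gamete
classes are equally likely, so panels are ~50% sterile.

Line methylomes are composed block-by-block at the haplotype level
(ddm1-derived blocks take quadruple-mutant levels, WT-derived blocks
triple-mutant levels). Dosage dilution by the wild-type tester homolog is
deliberately not modeled; it would scale every contrast by ½ without
changing any decision boundary, at the cost of making marker thresholds
genotype-dependent.

## Windowed methylation and the suppressor DMR rule

Window levels are count-weighted: level = Σ n_meth / Σ n_total per context
per fixed-grid window. The total level is the *sum of the three context
levels* (range [0, 3]); a context with no covered cytosines is missing and
contributes 0 only if at least one context is defined, and fully missing
windows are skipped rather than imputed. (Summing pooled counts across
contexts is available as an alternative but is not the default, because the
sum-of-levels formulation weights contexts equally rather than by cytosine
abundance.)

A 300 bp window is a suppressor hyper-DMR when

* retention = quadruple / triple total level **< 0.4** (strict), and
* recovery = suppressor / triple total level **> 0.6** (strict).

Ratios are compared exactly as stated, with no epsilon. The recovery
baseline is the unsilenced (triple-mutant) parent; a rescaled variant
(suppressor − quadruple)/(triple − quadruple) is exposed via
`recovery_mode="rescaled"` for sensitivity analyses. DMRs shared by all
suppressor lines are intersected window-by-window on the common grid, and
adjacent shared windows are merged into maximal runs — which is how a
300 bp rule yields ~1 kb reported loci.

## Mapping procedures

**Pooled-window scan.** Lines are windowed individually and averaged with
equal weight per line (the group is a set of plants, not a pool of reads).
Candidate regions are maximal runs of windows with fertile − sterile total
level ≥ `delta_min` (default 0.2, about a quarter of the full
heterochromatin contrast), ranked by run length × mean delta. On the toy
genome all windowing uses 5 kb windows; the 100 kb default of
`pool_profiles` matches the scale a full-size genome calls for but would be
a single window per toy chromosome.

**Marker epigenotyping.** The in silico analogue of an McrBC
digestion/PCR readout: the methylation level in a ±1 kb window around the
marker, thresholded at < 0.2 (ddm1-derived) and > 0.5 (WT-derived), with
the gap called ambiguous. Evidence defaults to the CG context, whose
wild-type/ddm1 contrast (~0.9 vs ~0.05) the thresholds separate cleanly; an
all-context pooled level sits near 0.4 in methylated heterochromatin (CHH
sites dominate the cytosine count at low levels) and would be
systematically ambiguous. Thresholds and contexts are parameters.

**Interval logic.** For a dominant epiallele the causative interval lies in
every sterile line's ddm1-derived region and no fertile line's. Sterile
spans are bounded *generously* (extended to the nearest discordant marker
or chromosome end) and fertile spans *conservatively* (only between
ddm1-called markers), which makes the procedure sound: the planted locus is
never excluded on consistent panels, at the price of wider intervals.
Contradictions (an emptied candidate) produce an inconsistency report
naming the lines; panels without an informative sterile recombinant return
the whole region flagged "unresolved". A recessive mode is not the default
because the pooled material that defines the phenotype classes here
segregates a dominant defect.

**BSA SNP scan.** Allele-frequency difference between suppressor and
non-suppressor pools; with 15 homozygous suppressors vs 45 segregating
non-suppressors (MM:Mm = 1:2) the causal SNP is expected at ΔAF = 1 − 1/3 =
2/3. Windows (default 10 kb) slide by half a window so a linked SNP
cluster is never split across a boundary, and the reported peak is the
merged run of windows within 80% of the top window's mean ΔAF — in tight
linkage the profile is a plateau, not a spike, and reporting the plateau is
what makes "the peak contains the causal SNP" a well-posed statement. The
simulator gives each toy chromosome a genetic length of 4 crossovers (a toy
chromosome stands in for a full-length one), so linkage decays over ~10 kb.

**CAPS markers.** A SNP is classified by comparing the number of
restriction-motif occurrences (on either strand) overlapping it between the
reference and alternate sequence: more → creates a site, fewer → destroys
one, equal → uninformative.

## Metaplots and ChIP enrichment

Element bodies are rescaled to 40 bins with fixed 1 kb flanks (10 bins per
side); minus-strand elements are reversed. Bin values are ratio-of-sums
within an element, then averaged with *equal weight per element* so long
elements do not dominate — the standard metaplot convention. The
hairpin-source element is excluded from the ATHILA5 group when profiling
hairpin restoration. Elements shorter than the bin count contribute via
interpolation across their covered bins. ChIP enrichment is
log2((IP+p)/(input+p)) with each track scaled to a mean bin value of 1
(exact depth invariance); `depth_normalize=False` gives the raw closed-form
ratio. Both IP-only and input-normalised profiling are possible since
`metaprofile_track` accepts either track.

## Cytology statistics

A mis-segregating cell is an anaphase cell with ≥ 1 lagging chromosome
(multi-event cells count once). Rates carry exact Clopper–Pearson 95%
intervals; contrasts use two-sided Fisher's exact tests (both via scipy —
the tests check them against an exhaustive hypergeometric enumeration).
Chromosome attribution is scored in separate FISH experiments per probe
(records carrying a probe are excluded from rate estimation, since those
experiments pre-select abnormal cells), and per-probe proportions need not
sum to one. Cohesion is read from prophase FISH dot counts: 2 = cohered,
3–4 = reduced; 1-dot nuclei are reported separately as unclassified.
Chromocenter condensation is the fraction of nuclear signal in segmented
chromocenters; a chromocenter sum exceeding the nuclear total is rejected
as a segmentation inconsistency.

Fertility classes use the silique-length bands 3–5, 5–7, 7–9, 9–11 and
> 11 mm (→ approx. 1–5, 5–10, 10–15, 15–20 and > 20 seeds per silique).
The printed bands share endpoints, so a convention is required: bins are
half-open [lower, upper), a plant's representative length is the median
silique, lengths below 3 mm fall in the Sterile class, and a plant with
1–10 seeds is Sterile regardless of silique length.

## Problem sizes and reproducibility

Default problem sizes are chosen so the whole study runs at desk scale: a
250 kb genome (~125,000 cytosines per methylome), 20-line mapping panels,
40 EMS SNPs, 100 scored cells and 50 FISH nuclei per genotype, 30
chromocenters. Replicated checks use 100 seeded replicates (500 for
estimator calibration). One root seed drives everything through named,
independently derived RNG streams (`config.stream`), so each module is
reproducible in isolation and byte-identical under a fixed configuration.

## Known limitations

* Between-line biological variance beyond sampling noise is not modeled;
  planted-truth recovery rates are upper bounds on what noisy real panels
  would give.
* The BSA simulator models linkage to the causal SNP but not linkage
  between non-causal SNPs, and EMS density is far below real mutagenesis
  screens (scaled to the toy genome).
* The DMR rule is the thresholded sorting rule itself, not a statistical
  test; no multiple-testing control is involved, by design.
* Cytology intensity distributions (gamma) are generic; only the ratios
  and proportions built on them are analysis targets.
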