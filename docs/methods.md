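# Methods

This note documents the models and procedures implemented in `mediascape`,
the assumptions behind them, the parameters that matter, the synthetic-data
generators used by the test suite, and the numerical choices made where the
design was genuinely open.

## Interactor calling from AP-MS purification series

### Experimental design assumed

Four bait (tagged-complex) purifications — from untreated nuclear extract,
benzonase-treated extract, EtBr-treated extract, and an independent
benzonase-treated replicate — plus one mock purification per experiment. The
first experiment's control is paired with the untreated/benzonase/EtBr
purifications, the second experiment's control with the replicate. Each
protein carries per-purification Mascot identification scores and emPAI
abundance estimates; a score of 0 encodes "not detected" (blank cells in the
input TSV are read as 0).

### Rules

A protein is called an interactor iff, for each of the four bait
purifications against its paired control:

1. Mascot ≥ `mascot_min` (default 50),
2. emPAI(bait)/emPAI(control) ≥ `empai_fold_min` (default 5),
3. Mascot(bait)/Mascot(control) ≥ `mascot_fold_min` (default 3),
4. the protein is not annotated cytoskeletal/cytoplasmic,

and additionally:

5. emPAI does not drop by `treatment_drop_fold` (default 2) or more from the
   untreated purification to the benzonase purification, nor to the EtBr
   purification (chromatin independence), and
6. emPAI > 0 in all four bait purifications (presence rule).

Zero-handling conventions: a zero control with a detected bait sample counts
as infinite enrichment (rules 2–3 pass); a protein undetected in the
untreated purification cannot exhibit a treatment drop (rule 5 passes — the
presence rule still gates); a protein detected untreated but lost under a
treatment is chromatin-dependent (rule 5 fails). Ratio comparisons are done
multiplicatively (`bait ≥ fold × control`) to keep the exact-fold boundary
deterministic in floating point. These conventions make the filter total: an
absence of evidence never raises an error, and every failing protein carries
at least one named reason (`mascot_min`, `empai_fold`, `mascot_fold`,
`cyto`, `treatment_drop`, `presence`).

Mean emPAI over the four bait purifications maps to edge-weight categories
4/3/2/1 at breakpoints 1.5/0.75/0.25; the value 0.25 itself goes to the
thinnest category (the published category text leaves the boundary
unassigned; assigning boundaries to the thinner side keeps the map
monotone and total).

Cytoskeletal/cytoplasmic status and known-interactor status are input
annotation flags, not live database queries, so runs are deterministic and
offline.

## Super-enhancer identification

Constituent enhancers are Ep300 peaks with ≥ 1 bp overlap with an H3K27ac
region; the enhancer footprint is the Ep300 peak interval (the punctate
element), not the intersection segment. Constituents overlapping
`[tss − 1 kb, tss + 1 kb)` of any TSS are removed *before* stitching, so
promoter signal is never counted into a stitched region. Stitching merges
enhancers per chromosome whenever the inner gap to the running region end is
≤ 12.5 kb (the transitive closure of the pairwise gap relation). Each
stitched region is scored by the sum of Med1 coverage over its whole span
(read-bases); background subtraction is off by default and, when enabled,
floors at zero.

### The hockey-stick cutoff

Regions are sorted by ascending signal; rank is scaled as `x_i = i/(n−1)`
and signal as `y_i = (s_i − s_min)/(s_max − s_min)`. The cutoff is the
tangent point of a slope-1 line with the scaled curve, located as the index
minimizing `y_i − x_i`; ties resolve to the **last** such index (fewest
SEs). Regions with signal strictly above the cutoff signal are SEs — so ties
at the cutoff signal are typical, labels are invariant to rescaling all
signals by a positive constant, and `min(SE signal) > max(typical signal)`
always holds. For convex curves the argmin coincides with the first point
where the discrete forward slope exceeds 1 (on `y = x²` both give `x = 0.5`,
i.e. the top half of the curve), but the argmin form is robust to
adjacent-rank slope noise on real, jittered signals. If all signals are
equal the curve carries no geometry: the caller warns and labels no SEs.

A known property of any geometric cutoff of this family: on a smooth
featureless signal distribution (Gaussian- or lognormal-like), the scaled
ranked curve always has a convex tail whose slope-1 point sits around the
80th–90th percentile, so a non-trivial top fraction is labelled "SE" even
when nothing is planted. The cutoff separates regimes of a curve; it is not
a significance test, and SE calls on near-uniform signal should not be
over-interpreted.

## Colocalization and site categories

Per factor, the `top_n` (5000) most significant peaks are kept (ties broken
by ascending coordinate). The overlap percentage of A with B is the fraction
of A peaks with ≥ 1 B summit within 200 bp on the same chromosome, each A
peak counted once; the implementation is a sorted binary-search sweep,
checked in the tests against the quadratic all-pairs scan. Category
assignment uses the summit position with priority TSS > SE > typical
enhancer > other; the promoter half-width defaults to 1.5 kb and is exposed
as a flag (1 kb is a common alternative definition).

## Gene categories

- **Active gene**: mean RPKM over replicates strictly > 0.5.
- **Promoter domain width**: width of the widest H3K4me3 domain whose
  interval contains the TSS base itself; 0 if none. (A ±window variant
  would be possible; containment of the TSS base is the simplest
  deterministic reading and is what the generator plants.)
- **Broad promoter**: among genes with a nonzero domain, width ≥ the
  `ceil(top_frac · n)`-th largest width (default top 5%), ties included.
  This "k-th largest with ties" form matches a sort-and-slice oracle exactly
  and avoids the interpolation ambiguity of continuous quantile estimators.
- **SE / typical gene**: the nearest active gene to each stitched region,
  distance measured from region edges to the TSS (0 if the TSS lies inside),
  ties broken lexicographically, never across chromosomes. Typical-gene
  status excludes SE genes.
- **Partition**: SE+Broad = SE ∩ Broad; SE−Broad = SE ∖ Broad;
  Broad−SE = Broad ∖ SE; Typical = typical ∖ (SE ∪ Broad); all other active
  genes are `none`.
- **Top-100 lists**: walk SEs by descending Mediator signal, collect each
  SE's nearest gene once (first, i.e. highest, SE wins) into the SE+Broad or
  SE−Broad list by promoter breadth until each has 100; the Broad−SE list is
  the 100 widest-promoter genes of that category.

## Metaprofiles and response summaries

The TSS metaprofile averages coverage over `[pos − flank, pos + flank)`
(defaults 12 kb, 10-bp bins) across regions, reversing windows of
minus-strand genes so downstream is always to the right. Windows clipped at
a chromosome edge contribute only their covered bins, each renormalized by
covered width (clipping, not dropping). Bin values are per bp per region,
multiplied by `1e7/total_tags`; uniform coverage `c` therefore gives every
bin exactly `c·1e7/total_tags`, which the tests assert.

Pairwise group comparisons use the two-sided pooled-variance Student t-test
(Welch available via a flag); two constant identical groups (t = 0/0) are
reported as p = 1. Knockdown summaries count, per category over genes
present in the DE table: significant genes, mean and SEM of log2FC over
significant genes, and the fraction downregulated = significant AND
log2FC < 0, over measured genes. The significance flag is caller-supplied
(whatever "significant triplicates" policy produced the DE table), keeping
the summary agnostic to the upstream DE method.

## Synthetic data: what it emulates and what it does not

### AP-MS generator (defaults: 50 true / 10 chromatin-dependent / 40 contaminants / 26 core, seed 7)

True interactors and core subunits draw a lognormal base emPAI (core
subunits ~2.5× higher), present in all four bait purifications with ±5%
within-series jitter (far inside the two-fold rule) and Mascot scores well
above 50; 12% of them are faintly detected in one control at 8–20-fold
enrichment, below the cutoffs. Chromatin-dependent binders drop 3–5-fold in
every treated purification (beyond the two-fold rule) but otherwise look like
interactors, so they must fail for `treatment_drop` and nothing else.
Contaminants appear at comparable abundance in controls (a quarter of them
annotated cytoskeletal) and are sporadically absent from bait purifications.
With these separations the filter's precision and recall are exactly 1 —
the recovery tests verify the rule logic, not robustness to borderline
effect sizes, which real data will contain.

### Genome generator (defaults: 10/10/12/40 genes per category + 8 inactive, 20 SE clusters, seed 11)

One toy chromosome is laid out locus by locus in seeded-shuffled category
order: each gene gets a TSS (random strand), active genes an H3K4me3 domain
(broad 4–8 kb, typical 0.4–1.2 kb, covering the TSS) and a promoter Mediator
block; SE-category genes get a cluster of 2–4 enhancers (widths 500–800 bp,
gaps 1–3 kb) at 10× typical Med1 intensity ~3 kb from the TSS; Broad−SE and
Typical genes get one typical-intensity enhancer; ~30% of active genes also
get a TSS-proximal element that the promoter-exclusion step must remove.
Loci are spaced 13.5 kb apart — beyond the 12.5 kb stitching gap — so the
planted clusters are exactly the stitching truth and each cluster's nearest
active gene is its own locus gene. Decoy Ep300-only peaks and H3K27ac-only
regions exercise the enhancer-definition intersection. Coverage is
piecewise-constant intensity (no read-level noise); summits get N(0, 20 bp)
jitter to exercise the 200-bp colocalization window; a second factor
co-occupies each enhancer with probability 0.7 (configurable, 1.0 forces
100% overlap).

Expression draws three replicates per gene around category medians
60/15/12/4 RPKM (lognormal, σ = 0.4; inactive genes ≤ 0.5), giving the
SE+Broad > SE−Broad ≈ Broad−SE > Typical ordering. The knockdown table
plants, per category, **exactly** `⌊p·n + 0.5⌋` significantly downregulated
genes on randomly chosen members (p = 0.65/0.40/0.20/0.20), plus a 5%
significantly-upregulated sprinkle; effect sizes are lognormal/normal draws.
Planting exact counts rather than i.i.d. Bernoulli outcomes makes the
planted fraction the dataset's truth, so recovery checks measure the
pipeline, not binomial noise.

What the generator does **not** emulate: read-level sampling noise, peak
callers' false positives, overlapping/nested regulatory architecture,
enhancer–gene skipping (the nearest gene is always the regulatory target by
construction), copy-number or mappability artefacts, and borderline effect
sizes. Passing the recovery tests therefore demonstrates correctness of the
rule and geometry implementations under well-separated conditions, not
calibration on real data.

## Problem sizes and determinism

The default test suite and the acceptance script run entirely on generated
data: 126-protein AP-MS tables, ~2.4 Mb toy genomes (80 genes, 72 stitched
regions) for the SE analyses, 20 generator seeds for the recovery rates, and
a 1600-gene fixture (400 per category) for the knockdown and expression
summaries. These sizes make every stage's behaviour exactly checkable
against planted truth while keeping a full run in the order of seconds.
All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical generator output (fixed column order, `%.6g`
float formatting, sorted JSON keys), and the pipeline manifest echoes every
parameter and input checksum so reruns are bit-reproducible.

## Known limitations

- The hockey-stick cutoff labels a top tail on any smooth signal curve (see
  above); it is a regime separator, not a test.
- The interactor filter treats "present" as emPAI > 0; with real data a
  detection floor may be more appropriate (the threshold structure makes
  this a one-line config change).
- The broad-promoter rule recomputes the top-5% set from the supplied
  H3K4me3 domains; published broad-promoter lists derived from other data
  or window conventions will differ slightly in membership.
- Promoter half-width (1.5 kb vs 1 kb) and the enhancer footprint choice
  (Ep300 peak vs intersection) are exposed as flags; results are sensitive
  to both on dense genomes.
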