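# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Differential expression without replicates

The design has one sequenced sample per condition, so no within-group
variance can be estimated.  Significance for a count pair (a, b) with
library sizes (N_a, N_b) is assessed with a conditional exact test:

1. Rescale both counts to the geometric-mean library size
   L = √(N_a·N_b): a′ = round(a·L/N_a), b′ = round(b·L/N_b).
2. Condition on the total s = a′ + b′.  Under the null both halves are
   negative binomial with equal mean s/2 and fixed dispersion φ
   (variance = μ + φμ²), so the split x | s follows
   P(x) ∝ f(x)·f(s − x) — a beta-binomial-like distribution; at φ = 0
   (Poisson halves) it is exactly Binomial(s, ½).
3. The two-sided p-value is the total conditional probability of all
   splits whose probability does not exceed that of the observed split
   (the minimum-likelihood method).

Fold changes are computed on pseudocounted CPM:
CPM = (c + 0.5) / Σ(c + 0.5) × 10⁶, so each CPM column sums to exactly
10⁶ and zero counts are well-defined.  A feature is called DE when
linear |FC| > 1.5 (strict) **and** p ≤ 0.05 (inclusive).  No
multiple-testing correction is applied at this stage; the screen's
specificity comes from the intersection/subtraction algebra that follows.

**Dispersion default φ = 0.16** (biological CV 0.4), the conventional
assumption for human samples analyzed without replicates.  It is a fixed
input, not an estimate: with n = 1 per group the data cannot identify it.

**Calibration.** With all-null negative-binomial counts at φ = 0.16, the
empirical type-I error of the test at α = 0.05 over 2,000 features is
≈ 0.04–0.06 (slightly conservative through discreteness at low counts);
the acceptance suite asserts the [0.03, 0.07] band.

**Power.** The test's detectable effect has a hard floor set by the
dispersion: for large counts the log-ratio of two NB draws has standard
deviation √2·√(1/μ + φ) → √2·0.4 ≈ 0.57 (natural log).  A planted
log2FC = 2 (4-fold) is therefore a ≈ 2.4σ effect with per-contrast power
≈ 0.66 at α = 0.05, and ≈ 0.55 for the intersection of the two knockdown
contrasts.  This is a property of the single-sample design itself, not of
the implementation — which is why the default fixture's planted generic
DE features are recovered at ≈ 55–60%, while the targeted knockdown and
the planted triad effects (log2FC 3.5, ≈ 4.3σ) are recovered near-surely.

## Specificity algebra

The knockdown profile is the intersection of the S1 and S2 contrasts
**requiring direction agreement** (an up-in-one/down-in-the-other feature
is not a reproducible knockdown effect).  The control profile is the union
of S3 and S4; direction conflicts there are kept, flagged `conflict`,
because the control set's only role is removal.  Overlap removal matches
by feature id regardless of direction: a feature perturbed by nonspecific
transfection in either direction is noise.

## lncRNA–mRNA pairing

Coordinates are 0-based half-open internally (GTF I/O converts from
1-based inclusive).  For a lncRNA/mRNA pair on the same chromosome, the
classes are evaluated in priority order:

1. `antisense_natural` — opposite strand and ≥ 1 bp exon–exon overlap;
2. `antisense_intronic` — opposite strand, lncRNA span fully inside one
   intron of the mRNA;
3. `proximity` — span-to-span gap ≤ window (either strand);
4. none.

The proximity window defaults to 10 kb and is configurable; "proximity"
in the source procedure is qualitative, and 10 kb is a conventional
cis-regulation neighborhood.

## First-neighbor extension and PageRank

The LMP network adds the PPI first neighbors of the DE mRNA seeds and
keeps **every** PPI edge inside the induced subgraph on seeds ∪ neighbors
(neighbor–neighbor edges included — the reported density of real LMP
networks implies they were kept).  Protein nodes are identified with gene
ids; no isoform mapping.

PageRank is computed by power iteration with damping 0.85 (standard
default; unidentified by the procedure itself), uniform teleport, and
uniform redistribution of dangling-node mass, iterated until the L1
change falls below 1e-8 (1000-iteration cap with a diagnostic error).
Scores sum to 1 by construction; the suite asserts 1 ± 1e-9 and checks
against a dense eigenvector oracle at 1e-6.

Dominant mRNAs score at or above the mean over **all** network nodes
(ties at the mean retained).  A `mrna_nodes` scope is available because
"average" is ambiguous in the source procedure; both scopes give the same
monotone filter semantics.

Enrichment is a local hypergeometric upper-tail test per GMT term with
Benjamini–Hochberg FDR (default cut 0.05), replacing online GO/KEGG
services for offline reproducibility.  Genes in no enriched term are
dropped; the control track's dominant genes are then removed.

## Dual ceRNA screen

Seed-site classes follow the canonical definitions (target written
5′→3′; seed = miRNA nt 2–8): 6mer = reverse complement (rc) of nt 2–7;
7mer-m8 = rc of nt 2–8; 7mer-A1 = rc of nt 2–7 followed by A;
8mer = rc of nt 2–8 followed by A.  Each seed-pairing location is
reported once with its most specific class.  U/T are equivalent; context
scores, conservation and thermodynamics are out of scope.

The expression channel returns all upregulated DE miRNAs once the pattern
is satisfiable (target lncRNA down, ≥ 1 validated mRNA down); validated
mRNA directions are explicit inputs, mirroring how qPCR-validated
directions enter the real procedure.  The sequence channel is the
deduplicated union of per-gene candidate sets over all validated genes.
Final miRNAs = (expression ∩ sequence) \ control-up.  Sponge sites in the
lncRNA itself are computed and reported as evidence but not required.

## The synthetic-data generator

What it emulates:

* **Counts** — per-feature lognormal baseline means (median
  `baseline_mean` = 300, σ = 1) with NB(μ, φ = 0.16) sampling per sample;
  planted DE features shifted ×2^(±2) in S1 **and** S2; a disjoint 10% of
  features perturbed in S3–S4, deliberately overlapping 4 planted
  features so overlap removal is exercised; the targeted lncRNA down and
  triad miRNAs/mRNAs shifted at log2FC 3.5 — a strong validated-knockdown
  effect (≈ 90% knockdown), chosen so planted triads are detectable by
  design in a single-sample screen (per-molecule recovery ≈ 0.97).
* **Annotation** — one synthetic chromosome; mRNAs with two exons and one
  intron; half the lncRNAs planted as natural/intronic antisense partners
  (alternating), the rest ≥ 2 windows from any mRNA; gene blocks ≥ 3
  windows apart so no unplanned pair classifies.
* **PPI** — preferential attachment (Barabási–Albert, m = 2) over mRNA
  products plus 150 extra proteins: connected, simple, hub-containing.
* **Sequences** — uniform-random 3′UTRs (300 nt), lncRNA transcripts
  (600 nt) and 21-nt miRNAs; for each planted triad an 8mer site is
  inserted into the target UTR and the sponge lncRNA.  Chance 6mer-core
  occurrences of *any* simulated miRNA are scrubbed (site-collision
  screening, on by default), so sequence evidence equals the planted set
  exactly.
* **Gene sets** — one planted pathway collecting triad targets and
  antisense partners, plus random terms, over the mRNA + protein universe.

Default problem sizes (200 mRNAs, 24 lncRNAs, 200 miRNAs, 150 extra
proteins) are set by library-complexity realism: with too few miRNA
species, a handful of strongly released miRNAs dominates the library and
CPM normalization absorbs part of their fold change — an artifact real
miRNA libraries (hundreds of detected species) do not show at this
magnitude.  These sizes also keep a full run at a few seconds on one CPU.

What it does **not** emulate: read-level sequencing, realistic genome
coordinates, miRNA biogenesis, GC/length biases, correlated pathway
co-expression, or compositional normalization problems beyond the scale
noted above.  Passing tests therefore demonstrate the *screening logic*
(set algebra, pairing, ranking, seed matching, planted-truth recovery
under NB noise), not performance on real libraries — in particular, real
data would additionally need TMM-style normalization and annotation-grade
antisense calls.

Determinism: every stage draws from `numpy` Generators seeded by
`SeedSequence([seed, stage_index])`; identical seeds give byte-identical
TSV/FASTA/GTF outputs and reports.

## Numerical choices and degenerate inputs

* Exact-test splits are enumerated in log space and normalized; ties with
  the observed probability are included using a 1 + 1e-12 relative guard;
  p is clamped to (0, 1].  A zero total gives p = 1.
* PageRank renormalizes once after convergence to remove float drift.
* Empty DE sets, empty networks and zero planted effects are legal
  everywhere: the pipeline reports empty stages and exits successfully.
* Score-equal-to-mean mRNAs are dominant (deterministic tie handling).
* All file writes are atomic (temp + rename).

## Known limitations

* The no-replicate exact test cannot separate biological variability from
  effect: φ is assumed, and moderate effects (≤ 4-fold at CV 0.4) are
  under-powered by design; single-sample screens should be read as
  candidate generators, not inference.
* Antisense classification uses gene spans and exon blocks only — no
  transcript isoforms.
* The seed matcher implements canonical site classes without context
  scoring; per-gene candidate sets on real sequences will be noisier than
  the collision-screened synthetic ones.
* Enrichment results depend entirely on the supplied GMT; no term
  database ships with the package.
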