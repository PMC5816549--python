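# Methods

## Scope and model

`hypmine` mines a proteome for hydroxyproline-rich glycoproteins (HRGPs)
and computes the molecular-evolution and expression statistics usually run
on the resulting gene set.  HRGPs are cell-wall proteins defined not by a
conserved domain but by biased amino-acid composition and short repetitive
motifs, which is why the identification step is a rule cascade over
composition and motif grammars rather than a BLAST or HMM search:

* **AGP bias** is the PAST fraction — the proportion of Pro, Ala, Ser, Thr
  residues.  Ambiguous residues (X, B, Z, U) are retained in the length but
  never counted as P/A/S/T/K.
* **SPn motifs** (one Ser followed by exactly *n* Pro, *n* ∈ {3,4,5}) are
  the extensin repeat unit.  A serine heading a proline run longer than
  five is reported as SP5; a run of exactly four is SP4 only.  This makes
  the SP3/SP4/SP5 classes disjoint per hit, so the three extensin
  subfamilies partition the extensins.
* **PRP motifs** are PPV[X][KC] (fifth-position alphabet configurable,
  K/C by default) and the literal KKPCPP.
* **Lysine-rich regions**: the length-3 windows [X]KK, KKK and K[X]K are
  scanned with overlaps allowed; a *region* requires at least two
  non-overlapping lysine windows starting within a 30-residue span (both
  configurable).  The non-overlap reduction stops a single KKK block —
  which spawns overlapping KKK/[X]KK windows — from counting as a cluster
  on its own.
* **Fasciclin (FLA) evidence** is consumed from hmmsearch `--domtblout`
  output (default accession set {PF02469}, independent E-value ≤ 1e-5);
  profile-HMM scoring itself is out of scope, as are the signal-peptide
  and GPI predictors whose tabular outputs are only parsed.

## The rule cascade

Classification is first-match-wins over an ordered rule list (order
configurable, defaults below), with NONE a valid verdict, so the classes
always partition the proteome:

1. FLA — fasciclin hit and PAST ≥ 0.10
2. EXT-AGP — PAST ≥ 0.10 and ≥ 1 SPn hit
3. lysine-rich AGP — PAST ≥ 0.10 and a lysine-rich region
4. AG peptide — PAST ≥ 0.10 and length ≤ 90
5. classical AGP — PAST ≥ 0.30 and no swapped (non-fasciclin) domain when
   a domain table is loaded; without a table the check is skipped and the
   call carries a `domain-check-skipped` flag
6. SPn-EXT — ≥ 2 SPn hits of the same *n* (the largest *n* with enough
   hits wins; a pooled-count mode is available)
7. PRP — any PPV[X][KC] or KKPCPP hit
8. NONE

The default order is forced by the known chimeric cases: proteins carrying
both SPn motifs and a lysine region with AGP bias are EXT-AGPs, so EXT-AGP
must precede both the lysine rule and the extensin rule, and PRP is the
residual family by definition.  All thresholds are inclusive (≥) and live
in one `RuleConfig`: `past_agp=0.10`, `past_classical=0.30`,
`ag_peptide_max_len=90`, `min_ext_hits=2`, `lys_min_hits=2`,
`lys_window=30`, `fla_evalue=1e-5`.  Calls whose PAST fraction lies in
[0.08, 0.12] can additionally be flagged `borderline` (optionally with
`homology-supported` from a BLAST table against known HRGPs); flags never
change a call.  The optional repetitive-sequence collapse removes exact
amino-acid duplicates, keeping the lexicographically smallest id and
reporting every removed id.

## Ka/Ks (Nei–Gojobori 1986, Jukes–Cantor corrected)

For each codon position the synonymous-site fraction is the number of
synonymous single-base alternatives divided by the number of *non-stop*
alternatives at that position; stop codons are excluded from the site
alternatives entirely.  S is averaged over the two sequences and
N = 3·(codons) − S.  Codons differing at several positions average their
synonymous/nonsynonymous step counts over all minimal substitution
pathways, excluding pathways through a stop codon; in the degenerate case
where every pathway is blocked, all pathways are used.  ps = Sd/S and
pn = Nd/N are corrected with d = −(3/4)·ln(1 − (4/3)p).  Saturation
(p ≥ 3/4) and empty site classes are reported as `saturated` /
`undefined` statuses, and ω for Ks = 0 is reported as a status
(`undefined_omega`), never as infinity, so TSV outputs stay finite.  Gap
or ambiguous codon columns are dropped before counting.  The stop-codon
conventions above are the main source of (small) discrepancies against
other NG86 implementations; the test suite pins the implementation to an
independent exact-rational enumeration oracle at 1e-10.

Dating uses T = Ks/(2λ) with λ = 9.1e-9 synonymous substitutions per site
per year (a rate transferred from black cottonwood), and the closed
interval Ks ∈ [0.15, 0.3] flags the recent whole-genome duplication (WGD)
shared by pear and apple.  Ks histograms use half-open bins
[k·w, (k+1)·w) — edge values fall in the upper bin — and report saturated
or undefined pairs as a separate count.  The likelihood-ratio test for
nested site models is 2·|lnL_alt − lnL_null| against the χ² upper tail
(df = 2 by default for the beta vs beta+ω comparison); the site-model
likelihoods themselves are consumed as input.

## Duplicate-gene modes

Gene ranks are dense 0-based per chromosome, ordered by start with ties
broken by gene id.  Each gene gets exactly one mode, by priority: member
of a collinear pair (MCScanX `.collinearity` input) → `wgd_segmental`;
homolog at rank distance exactly 1 on the same chromosome → `tandem`;
rank distance ≤ 10 (configurable) → `proximal`; any other homolog →
`dispersed`; none → `singleton`.  WGD and segmental duplication are not
separated — collinearity evidence alone cannot distinguish them, so one
label covers both.

## Expression divergence

For a gene pair, expression conservation EC is the Pearson correlation of
the two RPKM vectors across shared samples (sample vs population
normalisation cancels in the correlation) and divergence is 1 − EC,
in [0, 2]; a zero-variance vector gives an `undefined` status rather than
a value.  The null is built from unordered, self-free random pairs drawn
uniformly without replacement among the candidate gene set, seeded;
distributions are compared with two-sided Wilcoxon rank-sum tests (the
choice of test is a package decision and is reported as such).  Heat-map
normalisation maps log2(RPKM+1) rows affinely onto [−bound, +bound]
(default bound 3.0; 4.55 reproduces the wider fruit-panel range; a
z-score-with-clipping mode is offered as an alternative), with constant
rows mapping to zero.  Relative qPCR expression is 2^−ΔΔCt.

## GC windows

Chromosomes are tiled from position 1 with non-overlapping 10 kb windows
(configurable), keeping the final partial window.  GC is computed over
unambiguous bases only: soft-masked lowercase counts normally, N and other
ambiguity codes are excluded from numerator and denominator, and an
all-ambiguous window is flagged undefined.  The base-weighted mean of
window GC therefore equals whole-chromosome GC exactly.  No "GC-rich"
significance call is made — no defensible cutoff exists — only the track
is produced.

## Synthetic data

The fixture generators are first-class, tested code and define the
conditions under which the pipeline is validated:

* **Proteomes** — one archetype per subfamily, each ≥ 1 threshold-width
  from every rule boundary (AG peptides 60–80 aa at 35–45% PAST; classical
  AGPs 200–400 aa at 35–45%; lysine-rich AGPs and EXT-AGPs at 15–25% PAST
  with planted KKK clusters / SPPP motifs; SPn-EXTs and PRPs below 8%
  PAST with three SPn / two PPVAK motifs; FLAs at 15–25% PAST with a
  synthetic PF02469 domain hit in a companion annotation table).  Backbone
  residues come from an alphabet that cannot form any motif (no P, S, K,
  V, C); PAST content is supplied by Ala/Thr filler.  Negatives are
  uniform over the 20 letters, then scrubbed of every motif occurrence
  (offending residues → Gly) and driven below 6% PAST.  This margin
  construction is what makes the 100%-recovery tests meaningful: they
  verify the rule plumbing exactly, and say nothing about borderline
  compositions, partial motifs or chimeric real proteins.
* **Expression** — per-pair log expression is bivariate normal with
  correlation ρ (log-normal marginals on the RPKM scale, matching the
  right skew of RNA-seq abundance; log-mean 2, log-sd 1).  The RPKM-scale
  Pearson correlation is mildly attenuated relative to ρ
  ((e^ρ − 1)/(e − 1) for unit log-variance), which the recovery
  tolerances account for; monotonicity in ρ is unaffected.
* **CDS pairs** — a stop-free ancestor with exactly n_syn synonymous and
  n_nonsyn nonsynonymous single-base edits in distinct codons, each edit
  chosen so no stop is created.  No transition/transversion bias or ω
  process is simulated.
* **Genomes** — i.i.d. bases at a target GC; no isochore or repeat
  structure.

## Problem sizes and numerical choices

The validation suite runs at desk scale, chosen so the whole suite stays
fast while estimates are stable: 100 proteins per archetype plus 400
negatives for recovery; 1,000 random sequences (length ≤ 200) for the
motif oracle; 200 random codon pairs (≤ 30 codons) for the Ka/Ks oracle at
1e-10; 10,000 pairs at n = 6 samples for the divergence-vs-ρ study and
1,000 pairs at n = 50 for correlation recovery within 0.05.  Headline
counts from any specific genome are not reproduced here: they require that
genome's proteome and annotation downloads and depend on collection steps
(exact repetitive-sequence handling, borderline-PAST adjudication) that
published descriptions leave under-determined.

## Known limitations

* Rule precedence between overlapping AGP subfamilies is a documented
  default, not a uniquely determined fact; the order is configurable and
  logged.
* NG86 is the simplest counting estimator; no YN00/ML model is provided.
* The duplicate-mode classifier consumes precomputed homology and
  collinearity; it does not detect collinear blocks.
* big-PI and SignalP parsing follow fixed column/keyword rules for the
  classic output layouts; genes absent from the tables are reported as
  un-annotated rather than negative.
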