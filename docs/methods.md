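# Methods

## The model in brief

Translational selection acts on synonymous codon choice through the
supply of decoding tRNAs. The package quantifies both sides of that
relationship — codon usage from CDS sets, tRNA availability from
abundance measurements — and connects them through an explicit
codon–anticodon pairing model. All genetic-code logic uses NCBI
translation table 11 (all target organisms are bacteria) over the RNA
alphabet; sequences are normalized T→U on load because anticodons are
conventionally written as RNA.

### Codon families

Synonymous families are the unit of every relative statistic. The
three 6-fold amino acids (Leu, Arg, Ser) are split by their first two
codon bases into a 2-fold and a 4-fold family, because a single
anticodon can never bridge the two halves; Met and Trp are single-codon
and carry no synonymous signal. That yields 21 families covering 59
sense codons. Wright's Nc is the exception: it uses the intact
6-fold layout (9×2-fold, Ile, 5×4-fold, 3×6-fold), which is the
layout its constants assume; a `split_sixfold` option provides the
split-layout variant (whose attainable floor is 23, not 20, because the
split layout has 23 effective families).

### Pairing rules

The rule table maps an anticodon's wobble base (position 34) to the
codon third bases it reads: C34→G (cognate only); G34→C cognate, U
wobble (s = 0.41); U34→A cognate, G wobble (s = 0.68), plus U and C
through xo⁵U-type modification (s = 0.68), restricted to 4-fold
families and the 3-fold Ile family where no cross-family misreading can
result; A34 is read as inosine: U (Watson–Crick-equivalent, s = 0), C
(s = 0.28), A (s = 0.9999). The s-values are the classic tAI
parameterization. Pairings that would cross amino-acid families are
always removed, and the whole table is editable via a YAML config
(`PairingRules.from_yaml` / `to_yaml`).

Two deliberate scope rules: availability sums (RTU, the two-step
predictor) use all pairing classes **unweighted** — what matters for
availability ranking is whether a tRNA can read the codon at all —
while the (1 − s) efficiency factors enter only the tAI weights. An
`s_weighted` flag on `codon_availability` exposes the weighted variant
for sensitivity analysis.

### tRNA quantification

tpm is computed with plain sequence length, not kallisto's effective
length: tRNAs (~76 nt) are shorter than typical sequencing fragments,
which makes effective length ill-defined for them; rankings are
unaffected, absolute values may differ from effective-length-corrected
tables. The internal read assigner (exact forward-strand substring
match, 1/k split across k multi-mapping targets, 25 nt retained-read
floor) is a deliberately simple stand-in used by the synthetic tests;
real datasets should be quantified upstream and supplied as
`abundance.tsv`.

### Expression classes

Protein-per-transcript (ppm/tpm) decouples translation efficiency from
transcription. Genes must have strictly positive ppm and tpm; set
sizes are ⌊0.30·n⌋ of the post-filter n (both counts are logged);
boundary ties break lexicographically by gene id so reruns are
deterministic. With two RNA-Seq datasets the top (bottom) sets are
intersected; genes present in only one dataset cannot enter.

### Optimal codons, prediction, and the match score

The caller demands a *strict* RSCU maximum in HEGs — exact ties yield
no call rather than an arbitrary winner, matching the practice of
leaving undecidable families blank — and confirmation against LEGs
(HEG RSCU > LEG RSCU). The availability predictor shortlists codons
sharing the maximal RTU (structural ties detected at relative tolerance
1e-9; such ties are exact when tied codons share a reader set, since
their availabilities are sums of the same terms) and picks the
shortlisted codon with the largest cognate-only abundance; residual
ties are returned as a flagged set and, under the default strict
policy, count as unmatched. The match score reports
matched/determinable over families with a called optimal codon.

### tAI and the S statistic

Gene tAI is the geometric mean of normalized weights w over the gene's
sense codons (Met and Trp included here — they contribute decoding
information even without synonymous choice; stops excluded). Codons
with no reader take the geometric mean of the nonzero weights (the
original package convention) so the product stays defined. S is the
correlation between gene tAI and f(GC3s) − Nc, Pearson by default with
Spearman behind a flag; the underlying regression method in the
literature is not uniquely specified, so results always carry a method
tag. Genes with fewer than 30 countable codons get no Nc; a missing
Ile class borrows (1/F̄2 + 1/F̄4)/2; families with n ≤ 1 are skipped in
the class averages. Note the expected-Nc curve
f(s) = 2 + s + 29/(s² + (1−s)²) is *not* symmetric about 0.5 — the
linear term gives f(s) − f(1−s) = 2s − 1 exactly — and its maximum sits
marginally above s = 0.5.

## The synthetic-data generator

The generator (`synthetic_data`) emulates the study conditions so that
each stage, and the chain of all of them, has a recoverable planted
truth.

* **tRNA pool.** One tRNA per anticodon of a 37-anticodon repertoire
  chosen so every sense codon is readable and so the predictor's
  cognate tie-break is exercised (per 4-fold family a U34+G34 pair, per
  A/G duet U34+C34, per C/U duet a single G34, G34+U34 for Ile, plus
  Met/Trp readers). Sequences are 76 nt with the anticodon at sites
  34–36 and a 3′ CCA. Abundance ~ LogNormal(μ = 9, σ = 1), normalized
  to the tpm scale — magnitudes of 10³–10⁵ like real bacterial tRNA
  tpm. Copy numbers (1–8, skewed low like bacterial gene redundancy)
  are a rank-preserving discretization of abundance blended with
  independent noise by `copy_link` (default 0.8; fast-growers couple
  copies to expression). Up to six potential methylation sites per
  tRNA are drawn from the canonical positions (18, 32, 34, 37, 46, 54);
  the >4-sites rule then classifies roughly half the pool as heavily
  methylated.
* **Genes.** 1,000 genes of 100–300 codons; each codon's family is
  uniform over the 21 families, framed by AUG…UAA. A `heg_fraction`
  (0.3) of genes is drawn under selection: codon probability
  ∝ availability^β across availability tiers and, *within* an exactly
  tied tier, ∝ (cognate + κ)^β (κ = a quarter of the tier's largest
  cognate abundance) — biologically, among equally-read codons the
  cognate-decoded one elongates fastest. β = 0 collapses to a uniform
  draw. The remaining genes follow a mutational GC3 weight
  (`gc_bias`, default 0.5 = symmetric). The planted truth per family
  is the lexicographic (availability, cognate) argmax — precisely the
  quantity the two-step predictor estimates. mRNA tpm is LogNormal;
  ppm multiplies tpm by exp(γ·(tAI_g − mean tAI)) and LogNormal noise
  (σ = 0.3), so with β, γ > 0 the selected genes have elevated ppm/tpm.
  γ = 2 produces a realistic, noisy coupling: the ppt-top-30% set is
  enriched in, not identical to, the planted selected genes.
* **Reads.** Reads (33 nt default) sample tRNAs ∝ abundance with
  uniform starts; with probability `p_stop` a read crossing an
  annotated methylation site is truncated there (reverse-transcriptase
  arrest), then dropped if under the 25 nt floor. `p_stop` defaults to
  0 — the bacterial datasets this emulates show no hard-stops.

All stages draw from substreams derived deterministically from one
seed, so identical config + seed gives byte-identical outputs and each
stage is independently reproducible.

### What the generator does not emulate

No tRNA secondary structure, ligation/priming bias, sequencing errors,
growth-phase dependence of the pool, or EM-style multi-mapping
resolution. Passing tests therefore demonstrate the *statistical
machinery* — recovery of planted signal through the full chain — not
robustness to those real-data artifacts.

## Numerical and procedural choices

* Tie detection throughout uses relative tolerance 1e-9; availability
  ties that matter are structural (shared reader sets) and survive
  estimation exactly, because estimated availabilities of tied codons
  are sums of the same per-tRNA estimates.
* Hard-stop detection: site s is flagged when the mean depth over the
  following `window` (5) sites falls to ≤ `ratio` (0.2) of the mean
  over the preceding window and the upstream mean is ≥ `min_depth`
  (10); a single cliff triggers the rule at a few adjacent sites, so
  consecutive candidates are collapsed to the site with the largest
  upstream/downstream ratio. The defaults are this package's own; no
  reference values exist. Caveats: tRNAs with depth below `min_depth`
  are undetectable by construction, and on very deep profiles the
  natural read-start coverage decay near the 3′ end (within one read
  length of the tail) can itself be flagged — inspect boundary calls.
* Methylation-site coordinates are treated as 1-based linear sequence
  positions (the samtools convention), not Sprinzl numbering; supplied
  annotations must match.
* tRNA deduplication runs before CCA appending; inputs differing only
  by the CCA suffix are collapsed after appending would have merged
  them — such cases are logged. CCA is appended iff the final three
  bases are not exactly CCA.
* Pipeline TSVs render floats at 4 decimals so reruns are
  byte-identical; the JSON manifest keeps full precision.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the study at 1,000 genes
and 50,000 reads (the chain's default conditions), parameter-recovery
checks at 150–1,000 genes, the Nc oracle comparison on 1,000 random
count tables, the predictor oracle on 500 random instances, and
hard-stop recovery over 100 seeded replicates of 3,000 reads — sizes at
which every planted signal is comfortably detectable and the whole
suite runs in well under a minute apart from the replicate loops.

## Known limitations

* The S′-vs-S contrast (tpm-weighted tAI explaining codon bias better
  than copy-number-weighted tAI) holds on average when copy numbers are
  decoupled from the true pool, but not in every replicate: the reader
  -set structure alone — how many tRNAs can read a codon — already
  explains much of the bias under *any* abundance assignment, so the
  copy-number S has a high structural floor. Real species show the
  same direction-with-exceptions pattern.
* The dual-criterion caller and the availability predictor can both be
  undecidable (ties, zero families); the pipeline reports reasons
  rather than guessing.
* Real-data runs require externally produced abundance tables; the
  built-in read assigner is exact-match only and will under-assign
  reads containing sequencing errors.
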