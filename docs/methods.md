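# Methods

`funcmark` implements the computational arc of developing and exploiting a
functional-gene qPCR marker for a microbial guild. The motivating system is
the ACC deaminase gene *acdS*: a conserved enzyme gene whose closest homolog
family (D-cysteine desulfhydrase) is so similar in sequence that a marker
database must be purged of it by catalytic-residue evidence before primers
can be designed. Every stage below is a library function; the `funcmark`
CLI wraps them without adding logic.

## Reference-database curation (`seqdb`)

A `ResiduePolicy` anchors required catalytic residues as 1-based positions
in the **ungapped** reference protein (default policy used throughout the
fixtures: Lys51, Ser78, Tyr295, Glu296, Leu322, the residues required for
ACC deaminase activity, with the reference in the role of *P. kilonensis*
F113). Positions are mapped through the alignment by counting the
reference's non-gap symbols, then every row is kept iff it shows the
expected amino acid at every mapped column.

Decisions where the procedure was genuinely open:

* **Gap at a required column ⇒ discard.** A deleted catalytic residue
  cannot support activity; a partial sequence not covering the position
  cannot be certified. Both are discarded, but the report distinguishes
  them (`discarded_mismatch` vs `discarded_partial`, observed symbol `-`),
  so partial-length entries are auditable rather than silently conflated
  with true paralogs.
* **Dereplication** collapses only groups that are both 100% identical in
  nucleotide sequence *and* share the species label; the lexicographically
  smallest accession is retained (deterministic, reproducible).
* **CDS translation** assumes frame 0 (curated database entries are
  in-frame CDS); trailing partial codons are dropped, stops render `*`,
  N-containing codons `X`.
* **Amplicon coordinates** are 0-based half-open on the plus strand and
  primer-inclusive, so a 25 + 83 + 25 construct is a 133-nt core — the
  product-size convention of the qPCR assay. Templates with zero or
  multiple products are excluded from the core database and logged.

## Oligo thermodynamics (`thermo`)

Melting temperature uses the two-state nearest-neighbor model with the
unified duplex parameter set (SantaLucia 1998): initiation terms per
terminal base pair plus one stacking term per dinucleotide step, entropy
corrected by 0.368·(N−1)·ln[Na⁺], and

Tm(K) = 1000·ΔH / (ΔS + R·ln(C_T/x)), R = 1.9872 cal·mol⁻¹·K⁻¹,

with x = 4 for non-self-complementary duplexes. Defaults are 1 μM primer
and 50 mM monovalent salt, matching a standard qPCR mix. The parameter set
is a deliberate choice: "the nearest-neighbor method" does not pin a table,
and the unified set is the de-facto standard; absolute agreement with any
particular desktop tool is not attempted.

Hairpin and dimer prediction is **run-based**, not free-energy folding: a
hairpin is two reverse-complementary runs of ≥ 4 bases separated by ≥ 3
unpaired bases; a primer dimer is an antiparallel complementary run of ≥ 8
bases anywhere, or ≥ 4 bases anchored at either primer's 3′ end (what the
polymerase would extend). Run-based rules are deterministic and are checked
against exhaustive O(n⁴) scans in the tests; they approximate, and do not
reproduce, thermodynamic folding predictions.

## Primer screening (`primer_screen`)

Candidate enumeration replaces "visually selected in conserved regions"
with explicit thresholds: every 25-30-column window whose columns all have
majority-base fraction ≥ 0.80 and gap fraction ≤ 0.10 yields one forward
and one reverse consensus candidate (ties in the majority base break
A < C < G < T). Candidates are non-degenerate consensus oligos; the
≤ 3-mismatch tolerance of criterion (v) stands in for degeneracy.

A pair is judged on six criteria, each reported with its measured value:
(i) Tm of each primer in [60, 67] °C; (ii) no hairpin/self-dimer/
cross-dimer; (iii) |ΔTm| ≤ 1 °C; (iv) product ≤ 300 bp; (v) every database
sequence matched with ≤ 3 mismatches per primer; (vi) no in-silico product
from any non-target homolog. The verdict is the conjunction.

In-silico PCR scans both template orientations with a vectorized Hamming
profile; a primer binds when it has ≤ `max_mm` mismatches **and** its
3′-terminal trinucleotide matches exactly (configurable anchor length, 0
disables). The 3′-anchor rule is an explicit modelling choice — polymerase
extension requires a matched 3′ end — in a step the wet-lab protocol
resolves empirically. `N` in a template never matches.

## qPCR quantification (`qpcr`)

Standard curves are ordinary least squares of mean Ct (per concentration,
over replicates — the instrument convention; a flag fits per-replicate
instead) on log₁₀ concentration. Efficiency is E = 10^(−1/slope) − 1,
reported as a percent; the "error of the method" is the residual mean
square about the line with divisor n − 2. Copies follow
mass·N_A/(bp·660 g·mol⁻¹). Unknowns are inverted through the curve;
a Ct beyond the most dilute standard sets `below_limit` rather than
reporting zero ("not quantifiable"). Scaling to copies per gram of soil
divides by the fraction of the extract loaded and the grams extracted.

## Amplicon communities (`community`)

Reads are kept when 120-160 nt with no non-ACGT symbol, then dereplicated;
`drop_singletons` removes unique sequences seen once (the usual precaution
before rarefaction/diversity). Denoising beyond dereplication is out of
scope: amplicon libraries of this kind are commonly processed by
proprietary sequencing-service pipelines whose denoising and
chimera-removal algorithms are unpublished, so absolute OTU and read
counts are pipeline-dependent and not comparable across implementations.
A pass-through hook marks where chimera removal would sit.

OTUs form by greedy centroid clustering in decreasing-abundance order
(ties by representative read id) at identity ≥ 0.97. Pairwise identity is a
global alignment with free end gaps under match +1 / mismatch 0 / gap −1;
end gaps cost nothing but **count as columns**, and among co-optimal
alignments the one with most matches, then fewest columns, is taken.
Counting end-gap columns matters: without it a one-base shift of two
near-identical reads could report identity 1.0. The deterministic
tie-break makes clustering and best-hit classification exactly
reproducible; classification is best-hit by identity (ties to the
lexicographically smaller accession), genus = first token of the hit's
taxon label — deliberately single-best-hit, not LCA.

Alpha diversity: Shannon H = −Σ pᵢ ln pᵢ (nats); Simpson reported as
dominance λ = Σ pᵢ² by default (higher = less diverse; a `gini` form 1−λ is
available); Chao1 = S_obs + n₁²/(2n₂), switching to the bias-corrected
S_obs + n₁(n₁−1)/(2(n₂+1)) when doubletons are absent. Subsampling and
rarefaction draw without replacement (multivariate hypergeometric) under an
explicit seed; samples shallower than the depth are excluded with a
warning. Bray-Curtis is Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ); a zero-total sample is an error.

## Host-phylogeny correlation (`evocorr`)

K2P distance: K = −½ ln(1−2P−Q) − ¼ ln(1−2Q) over sites where neither
sequence has a gap/N; saturation (non-positive log argument) raises rather
than returning a capped value. Community-side distances are |xᵢ−xⱼ| on raw
or log₁₀ quantities.

Two correlation modes are provided. The default applies plain Spearman to
the matched off-diagonal distances with the asymptotic two-sided p —
the classical treatment, reproduced as-is even though the n(n−1)/2
pairwise distances are not independent observations. A `mantel_spearman`
mode permutes one matrix's labels, p = (count+1)/(permutations+1), under an
explicit seed, and is the statistically defensible alternative; the two can
disagree, and the default exists to reproduce the classical analysis, not
to endorse it.

## Synthetic data (`fixtures`)

`gen_family` builds a gapless 330-codon family: a random stop-free
reference with the policy residues forced, 30 targets at 2% per-site
divergence (policy codons and two primer-site windows protected;
substitutions creating in-frame stops are reverted), and 8 paralogs at 30%
divergence carrying prescribed key-residue violations. The 30% figure
models a paralogous outgroup — at the ~12% divergence of a sister clade the
"non-targets" would often amplify within the 3-mismatch tolerance,
contradicting their own truth label. The two conserved windows carry fixed
canonical sequences whose derived 25-mer pair (product 133 nt) satisfies
all six screening criteria for every seed; this is what makes the
"generate → curate → design yields a passing pair" guarantee a property of
the generator rather than luck of the seed. Being gapless, the family's
alignment is the identity alignment — indel evolution and alignment error
are explicitly not modelled, so passing tests say nothing about
misalignment robustness.

`gen_reads` draws reads multinomially over core-region sequences with
uniform per-base substitution errors (default 0.5%, a post-QC short-read
magnitude) and optional end-trimming/extension jitter; quality scores,
indels and chimeras are not modelled. `gen_standards`/`gen_ct` place a
dilution series (default 5×10⁻⁹…5×10⁻¹⁵ g/μL, triplicate — the range of a
genomic-DNA standard curve) on a chosen slope/intercept (default: perfect
doubling, −3.3219) with Gaussian Ct noise. All generators take explicit
seeds; there is no hidden global random state.

## Numerical and testing notes

* Problem sizes in the test batteries (≤ 50-60-nt sequences for the
  clustering/classification oracles, 250-500-nt templates for in-silico
  PCR, 100 instances per battery, 200 simulated qPCR runs) were chosen so
  exhaustive oracles stay exact while the default suite completes in well
  under a minute per module.
* The alignment DP encodes (score, matches, −columns) in one integer key
  and vectorizes rows via a running-maximum identity, so clustering
  133-nt amplicons is exact, not banded or heuristic.
* Ties everywhere (dereplication, classification, conservation majority,
  clustering order) break lexicographically; no operation depends on dict
  or input ordering.
* Known limitations: no divalent-cation or dangling-end Tm corrections; no
  degenerate-base primer enumeration; hairpin/dimer rules are heuristics;
  classification is nucleotide-identity best-hit, which cannot resolve taxa
  beyond what a 133-nt fragment supports.
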