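# Methods

## Feature partition

Every base of the genome receives exactly one of nine labels, resolved by a
fixed priority: stop codon > start codon > 5′ splice site > 3′ splice site >
3′ UTR > 5′ UTR > exon > intron > intergenic. The rule operates on the union
of all protein-coding transcripts' features, so a base that is exonic in one
isoform and intronic in another is exonic. Splice sites are defined as
exactly the two intronic bases at each intron end in transcript orientation
(the GT/AG dinucleotides); no wider window is part of the feature itself —
wider context is analysed through positional profiles instead. Bases inside
a lncRNA gene that overlap none of the eight genic features are excluded
from the intergenic denominator rather than forming a tenth reported class.
Internal coordinates are 1-based inclusive throughout (GTF/VCF convention);
conversion to 0-based half-open happens only at the BED boundary.

## Variability statistics

The elementary statistic is `100·m/n` variants per 100 bp, with m counting
variable *sites*: a multiallelic VCF record is one site, because the
genome-wide site-spacing arithmetic treats the catalogue total as a site
count. Substitution (Ti/Tv) spectra are the deliberate exception: there
every ALT allele is one event, since substitution types are allele-level.
Minor allele frequencies are folded to [0, 0.5], taken from INFO/AF (the
most frequent ALT at multiallelic sites) or from genotypes when AF is
absent.

Positional profiles measure `100·m/n` at oriented offsets around anchors.
At the 5′ splice site, offset 0 is the first intronic base and negative
offsets are exonic; at the 3′ site, offset 0 is the last intronic base and
positive offsets are exonic. An anchor drops out of an offset's denominator
when that offset leaves its parent feature (short intron or short flanking
exon), so n varies by offset. Around branch points, offsets are relative to
the branch point (heptamer positions 1–7 at offsets −5…+1) and both sides
are bounded by the intron.

Codon positions derive from each CDS interval's frame in transcript
orientation; when isoforms disagree, a base contributes once per distinct
claimed position (union semantics), with a "first transcript wins" mode
available.

Pairwise contrasts use a two-sided Fisher's exact test. Tables with grand
total ≤ 10⁶ use the exact conditional hypergeometric test; larger tables
fall back to a chi-square approximation with continuity correction, flagged
`exact=False` in the result, with the p-value floored at the smallest
positive float rather than underflowing to 0.

## Branch point prediction

Distances are counted from the intron's 3′ end with the last base (second
base of the acceptor AG) at distance 1. Candidates are enumerated at every
distance d in [9, 250] whose heptamer (branch point at position 6) and
covering octamer (heptamer + 1 downstream base) fit inside the intron;
introns shorter than 20 bp yield no prediction, and windows containing N
are skipped. The score is the sum of the heptamer PWM log₂-odds against a
background composition and the octamer's log₂-odds weight. Ties break
toward the smallest d, on the rationale that scanning recognition and
first-AG selection favor proximal elements. The minimum distance of 9
leaves room for the downstream octamer base clear of the acceptor
dinucleotide and is deliberately more permissive than the empirically
observed 14-bp minimum.

Octamer weights are trained from introns longer than 300 bp by sliding all
7 octamers of the 14-mer at distances 3–16 (polypyrimidine-tract region)
and at 187–200 (background), with a pseudocount (default 1.0) spread over
all 65,536 octamers — with ~10⁵ training windows, most octamers are
otherwise unobserved. The placement of the octamer one base downstream of
the heptamer is this package's reconstruction of the mixture; no numeric
compatibility with other tools' score scales is claimed, and comparisons
across prediction sets are made on branch-point coordinates, not scores.

The PWM can be loaded from a 7×4 tab-separated probability file, estimated
from aligned heptamers (0.5 pseudocount per cell), or taken from the
built-in degenerate `nnyTrAy`-style default.

## AG exclusion zone

The AGEZ of an intron runs from the base immediately 3′ of the branch point
to the base immediately 5′ of the acceptor AG (a flag moves the start to
the heptamer end instead). An AG-creating opportunity is a (position,
alternate base) pair whose substitution *strictly increases* the number of
AG dinucleotides; this is computed as a local delta over the two dinucleotide
pairs touching the mutated base, which is exactly equivalent to global
mutate-and-count. The naive "non-A before G / non-G after A" rule
over-counts cases such as AGG→AAG where an AG is destroyed as another is
created, so the strict-increase definition is used. The depletion test
pools opportunities over the AGEZ versus the remainder of the same introns
(terminal splice-site dinucleotides excluded, introns without a prediction
or without an AG acceptor excluded entirely), counts an opportunity as
observed when a variant carries the required oriented ALT, and compares
rates per opportunity site with the Fisher engine — per opportunity rather
than per base, because the event is only possible at opportunity positions.

## Synthetic data

The generator emits FASTA + GTF + VCF plus truth tables. Defaults: 2
chromosomes × 400 kb, 60 protein-coding genes (3–7 exons of 60–240 bp,
introns 200–1500 bp, UTRs 20–60 bp) and 4 lncRNA genes; background base
composition (A,C,G,T) = (0.30, 0.20, 0.20, 0.30). Every intron gets a
GTAAG donor start, an AG acceptor, a 10-base polypyrimidine tract (85%
pyrimidine) at distances 3–12, and one heptamer sampled from the planted
PWM at a distance drawn from a truncated normal (mean 29, sd 11, bounds
14–145) — the empirically reported placement law. Variants are drawn per
feature class: site counts are binomial in the class size (a fixed-count
mode supports exact-count tests), the planted per-feature densities default
to intergenic 1.5, intron 1.1, UTR3 1.0, UTR5 0.9, exon 0.8, splice sites
0.18/0.13 and codons 0.5 per 100 bp, per-feature Ti/Tv defaults span
1.5–2.5 with introns at 2.1, and folded MAFs follow 0.5·Beta(0.5, 3). An
optional suppression factor drops AG-creating variants inside the truth
AGEZ to plant a depletion signal. The same seed yields byte-identical
files.

What the generator does *not* emulate: linkage disequilibrium and
recombination, diploid genotypes, sequencing error, overlapping genes,
alternative isoforms per gene, introns shorter than the branch-point
distance bound (real genomes have introns down to ~22 bp), and
non-canonical splice sites. Passing recovery tests therefore demonstrates
the correctness of the counting and search machinery under the assumed
generative structure, not predictive accuracy on real genomes, where the
true placement signal is far weaker than a sharp planted PWM.

## Problem sizes and numerical choices

Recovery tests run on the default 0.8-Mb simulation (~220 introns, ~11,000
variant sites); the planted AGEZ-depletion experiment uses 2 × 1.2 Mb and
180 genes so the expected opportunity-hit counts support a stable Fisher
test. The ≥95% branch-point recovery property is evaluated with a sharp
planted PWM (probability 0.97 on a consensus base per position) on uniform
background and scored with the planted PWM alone — under the degenerate
default PWM the argmax is intentionally noisy and no recovery bar would be
meaningful. Binomial and delta-method standard errors back the ±3 SE
recovery assertions. Headline percentages are rounded half-up to two
decimals. PWM validation requires rows to sum to 1 within 1e-9 and all
entries positive; consensus-matrix information content is
`2 + Σ p·log₂ p` bits with 0·log 0 = 0, clipped to [0, 2].

## Known limitations

Only the single best branch point per intron is reported, though multiple
branch points per intron are common in mammals. The octamer-window
placement within the mixture score is a reconstruction. The large-table
Fisher fallback is approximate by design and labelled as such. Transcripts
lacking CDS are kept for intron extraction but excluded from codon-position
analysis; single-exon transcripts contribute no introns.
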