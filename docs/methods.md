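# Methods

## Scope and model

`champterm` models one-step terminal-peptide isolation as a deterministic
rule system on digest products, not as a chromatographic continuum. Three
stages are chained:

1. **Digestion.** Cleavage boundaries are between-residue indices
   (boundary *i* lies between residues *i* and *i+1*, 1-based).
   LysargiNase cleaves N-terminal to Lys/Arg, trypsin C-terminal to
   Lys/Arg, V8 C-terminal to Asp/Glu. A digest at `max_missed = m`
   returns every peptide bounded by protein termini or boundaries that
   spans at most *m* internal boundaries; the 0-missed peptides tile the
   protein. The semi-specific "N-terminal free" digest fixes the
   C-terminus on a boundary (or the protein C-terminus) and frees the
   N-terminus, which is how neo-N-termini become searchable.
2. **Isolation.** The charge number at acidic pH is
   `Z = [free α-amine] + #K + #R + #H`, with charge positions recorded as
   0 for the α-amine and the 1-based peptide index for side chains.
   Acetylation removes exactly one charge (the α-amine). CHAMP-N keeps
   `Z ≤ 1` and `Z = 2` with distant charges; CHAMP-NC keeps `Z ≤ 1`;
   CHAMP-C keeps peptides whose C-terminal residue is not D/E. These are
   binary verdicts: no retention-strength continuum, elution volumes or
   fractionation profiles are modeled.
3. **Annotation and metrics.** Neo classification, acetylation classes,
   exact presequence-end matching (`neo = end + 1`), near-cognate start
   codon checks, ladder detection, and intensity-based summary
   statistics.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `max_missed` | 2 | missed-cleavage ceiling of the simulated search |
| `min_len`, `max_len` | 6, 45 residues | MS-detectable peptide length window; typical search-engine bounds. Terminal peptides outside it count as undetectable ("too long or too short") |
| proximity threshold | 2 positions | two charges ≤ 2 positions apart are "proximal" and strongly retained. The dichotomy is qualitative in the underlying retention model; 2 is the smallest value that both rejects internal LysargiNase peptides (α-amine at 0, K/R at 1) and keeps N-terminal peptides with a deeper His. Exposed, not fitted |
| `distant_his_only` | off | restrict Z = 2 distant-charge selection to His-bearing peptides; the permissive default accepts any distant basic residue |
| iMet-removal set | `{A,C,G,P,S,T,V}` | initiator Met is excised when residue 2 has a small side chain; configurable because the rule is a heuristic for methionine-aminopeptidase specificity |
| `ragged_window` | ±3 residues | a neo call this close to (but not at) an annotated presequence end+1 is flagged `near_annotated` for review, never counted as a match. The near flag is suppressed whenever any exact match exists |
| near-cognate codon set | 9 single-mismatch ATG variants | `CTG GTG TTG ATA ATC ATT ACG AAG AGG`; configurable |
| ladder `min_run` | 3 | runs of ≥ 3 consecutive neo positions; 2 would be indistinguishable from a single ragged cleavage |

## Category labeling

A peptide is `protein_nt` when it starts at a native start (residue 1,
or residue 2 after iMet removal), `protein_ct` when it ends at the
protein C-terminus (N-terminal labeling takes precedence for a
whole-protein peptide), `neo_nt` for any non-native, non-enzyme-specific
start, and `internal` otherwise. A start at residue 3 is always labeled
`neo_nt`, even when residue 3 happens to be K/R and so coincides with a
LysargiNase boundary: residue-3 starts are over-cleavage products of
methionine aminopeptidase, the dominant neo mechanism close to the
native start, and treating them as internal would hide them.

## The synthetic study

The generator's defaults define the simulated study: 600 proteins of
80–400 residues drawn from average human amino-acid frequencies, all
starting with Met; mutually exclusive presequences (P(signal) = 0.15,
P(transit) = 0.10, lengths 10–50 residues); iMet removal by the rule
above; Nt-acetylation probability conditioned on the second residue
(0.7 small, 0.5 acidic/amide, 0.15 otherwise); one neo mechanism per
protein — presequence cleavage (released at end+1 with probability 0.9),
exopeptidase ladders (5% of non-presequence proteins, runs of 3–7
starting at residues 4–30), residue-3 over-cleavage (10%, acetylated with
probability 0.17), near-cognate starts (1%, a planted internal Met whose
codon is CTG); missed cleavages sampled 0.6/0.3/0.1 for 0/1/2; log-normal
intensities (ln-scale location 14, scale 1); triplicates that share the
peptide set and jitter intensities with ~10% CV; and a contamination
sample of rejected internal peptides scaled to a 5% intensity share
(intensity share, not count share, is controlled because selectivity is
intensity-based).

Evidence emission applies the real selection rules: a planted neo site is
emitted only if some semi-specific end variant (tried in increasing
missed-cleavage order) passes both selection and the length window.
Because Z is monotone in the variant's end position, sites whose shortest
admissible peptide already carries Z ≥ 3 are genuinely lost — roughly a
third of planted sites at default composition, which is the model's
honest account of why presequence catalogs recovered this way are
incomplete. Ground truth records which events were emitted, so recovery
is always assessed conditional on detectability.

The CDS back-translation uses the most-frequent human codon per residue,
so coding sequences are deterministic. At a planted near-cognate start
the protein carries Met (initiator-tRNA decoding) while the codon is the
configured near-cognate; CDS validation accepts Met at a codon from the
near-cognate set for exactly this reason.

What the generator does **not** emulate: missing values and interference
noise, retention-time structure, decoy/FDR behavior, peptides shared
between proteins (accessions are unique by construction), protein-group
inference (overlap statistics use accessions), and neo-C-termini. Passing
tests therefore demonstrate correctness of the rules and estimators, not
robustness to those real-data complications.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; spans parse from
  "start–end" (hyphen or en-dash) or a bare end integer.
* Missing intensities stay `None` and are excluded from both numerator
  and denominator of selectivity; they are never imputed as zero.
* Replicate RSD is `100 · sd/mean` with the sample (ddof = 1) standard
  deviation over per-replicate intensity sums; peptides seen in fewer
  than two replicates are excluded. Raw (not log) intensities are used.
* `detect_ladders` flushes runs with a sentinel, so single positions and
  pairs never form ladders at the default `min_run = 3`.
* Empty inputs return empty results (empty feature file, empty evidence
  table, empty call list for histograms) rather than raising.
* Evidence rows identifying the same peptide within a replicate are
  summed before RSD; charge states and injections are not modeled
  separately.
* Peptides mapping to multiple proteins are out of scope: each evidence
  row names one accession and is validated as an exact subsequence.

## Problem sizes

The default study (600 proteins, three methods, triplicates) produces
roughly 1.6k/0.7k/1.2k evidence rows for CHAMP-N/-NC/-C and runs the
whole acceptance computation in about a second; the digestion
brute-force cross-check uses 500 random proteins of ≤ 50 residues. These
sizes give stable (±0.2 point) selectivity estimates while keeping the
suite quick.

## Known limitations

* The proximity threshold is a surrogate for a continuous retention
  model; peptides with exactly two moderately spaced charges are the
  regime where the binary rule is least trustworthy.
* CHAMP-C is modeled with a single-residue rule; in reality acidic
  residues *near* (not at) the C-terminus also strengthen retention.
* Coverage calculations use the mature database start only; proteins
  whose physiological N-terminus is a presequence cleavage site are
  counted by their database start.
* The acetylation-probability table and neo-mechanism rates are
  field-plausible settings, not fitted to any dataset.
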