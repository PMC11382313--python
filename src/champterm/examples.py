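"""Curated worked-example dataset: predicted vs observed presequence
cleavage sites.

Two small published example sets from HEK293T N-terminomics: proteins
whose observed neo-N-terminal position agrees with a modern predictor's
presequence end (SignalP-6.0-style for signal peptides, TargetP-2.0-style
for transit peptides) while often disagreeing with the database
annotation.  Each row carries the predictor presequence end, the observed
neo-N-terminal position, and the database (UniProt) presequence end when
one is annotated and parseable.

These rows are inputs for worked examples and cross-checks of
:func:`champterm.annotation.match_cleavage`; they are not synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CleavageExample:
    accession: str
    gene: str
    predicted_end: int
    neo_position: int
    uniprot_end: int | None  # None: not annotated or span end unknown


#: Signal-peptide cleavage sites consistent with the predictor.
SIGNAL_CLEAVAGE_EXAMPLES = (
    CleavageExample("O00115", "DNASE2", 16, 17, 18),
    CleavageExample("P13667", "PDIA4", 24, 25, 20),
    CleavageExample("P04843", "RPN1", 24, 25, 23),
    CleavageExample("Q14257", "RCN2", 25, 26, 22),
    CleavageExample("Q9Y3Q3", "TMED3", 27, 28, 23),
    CleavageExample("O95302", "FKBP9", 29, 30, 24),
    CleavageExample("P11047", "LAMC1", 35, 36, 33),
)

#: Transit-peptide cleavage sites consistent with the predictor.
TRANSIT_CLEAVAGE_EXAMPLES = (
    CleavageExample("P82673", "MRPS35", 22, 23, None),
    CleavageExample("Q8TD30", "GPT2", 24, 25, None),
    CleavageExample("Q9Y2Q9", "MRPS28", 28, 29, 71),
    CleavageExample("P49419", "ALDH7A1", 29, 30, 26),
    CleavageExample("Q9BX68", "HINT2", 30, 31, 17),
    CleavageExample("P49590", "HARS2", 34, 35, 33),
    CleavageExample("P54886", "ALDH18A1", 43, 44, None),
    CleavageExample("Q7Z6M4", "MTERF4", 43, 44, 42),
    CleavageExample("P06576", "ATP5F1B", 46, 47, 47),
    CleavageExample("P82650", "MRPS22", 53, 54, None),
    CleavageExample("Q9H2K0", "MTIF3", 55, 56, 31),
)
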