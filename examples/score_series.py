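"""Turn a nucleotide sequence into its word-identity score series.

The sequence below is eleven tandem copies of the motif AT.  Every
position starts a 6-bp word that is compared, gaplessly, against all
6-bp words in the 24-bp windows flanking it; the score is the best
per-position match count, so positions inside the repeat saturate at 6.
"""

from ssrscan import ScoringParams, SequenceRecord, score_sequence

record = SequenceRecord("at-repeat", "AT" * 11)
series = score_sequence(record, ScoringParams(word_length=6, half_window=24))

print(f"sequence ({len(record)} bp): {record.seq}")
print(f"scores:              {' '.join(str(s) for s in series.scores)}")
print(f"score at position 8 (start of the middle ATATAT word): {series.scores[8]}")
print()
print("Every position whose 6-bp word fits inside the repeat scores the")
print("maximum, 6: an exact copy of the word sits in a flanking window.")
print("The last 5 positions have no complete 6-bp word, so they score 0.")
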