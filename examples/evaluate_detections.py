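"""Compute the four evaluation measures on a small worked interval case.

Sensitivity, false-positive rate, modified precision and percentage
predicted are all base-pair measures over merged interval sets, so they do
not depend on how a tool happens to split or order its calls.
"""

from ssrscan import Interval, evaluate

detections = [Interval("chr", 0, 10), Interval("chr", 30, 45), Interval("chr", 50, 60)]
reference = [Interval("chr", 5, 12), Interval("chr", 35, 40), Interval("chr", 58, 70)]
shuffled_detections = [Interval("chr", 100, 103)]

result = evaluate(detections, reference, shuffled_detections, sequence_length=1000)

print("detections:          [0,10) [30,45) [50,60)   -> 35 bp")
print("reference:           [5,12) [35,40) [58,70)   -> 24 bp")
print("shuffled detections: [100,103)               -> 3 bp")
print()
print(f"overlap with reference: {result.overlap_bp} bp (5 + 5 + 2)")
print(f"sensitivity:            {result.sensitivity:.1f}%   (100 * 12 / 24)")
print(f"FPR:                    {result.fpr:.0f} bp/Mbp (1e6 * 3 / 1000)")
print(f"precision:              {result.precision:.1f}%   (100 * 12 / (12 + 3))")
print(f"percentage predicted:   {result.pp:.1f}%    (100 * 35 / 1000)")
print()
print("Precision is 'modified': false positives are taken from the shuffled")
print("sequence, because unannotated real-sequence detections may be true")
print("repeats the reference annotation simply missed.")
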