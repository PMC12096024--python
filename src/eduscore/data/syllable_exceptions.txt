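# Syllable exception table: words the vowel-group heuristic miscounts.
# One entry per line: word <space> syllable-count. Lines starting with "#"
# are comments. Editable; unknown words fall back to the heuristic.
osteoarthritis 6
osteoporosis 6
physiotherapy 6
cardiovascular 6
idea 3
area 3
being 2
science 2
quiet 2
diet 2
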