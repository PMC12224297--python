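# Regulation-focused keywords used to select Pfam families by description.
# This shipped list carries only the commonly cited example keywords and is
# deliberately incomplete: replace it with a full curated list (one keyword
# per line) for real-genome mining.
helix–turn–helix (HTH)
helix–loop–helix (HLH)
repressor
activator
DNA binding
transcriptional regulator
sigma factor
response regulator
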