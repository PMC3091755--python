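# Curated sex-linked genes with documented sex-biased expression in mouse:
# Xist and regulators of X-pairing/X-inactivation, coding X-inactivation
# escapees, and their Y-linked paralogues. Edit freely; one symbol per line.
Xist
Jpx
2010000I03Rik  # Jpx alias
Kdm5c
Eif2s3x
Kdm6a
Ddx3x
Kdm5d
Eif2s3y
Uty
Ddx3y
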