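name	node
Met	methionine
Tyr	tyrosine
Gly	glycine
Ser	serine
lysoPC a C17:0	lysophosphatidylcholine
PC aa C32:1	phosphatidylcholine
PC ae C38:4	phosphatidylcholine
C3-OH	hydroxypropionylcarnitine
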