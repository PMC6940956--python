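MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF ABRE_like bZIP
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
0.90 0.03 0.04 0.03
0.02 0.90 0.04 0.04
0.03 0.03 0.90 0.04
0.04 0.03 0.03 0.90
0.05 0.05 0.85 0.05
0.05 0.05 0.85 0.05
0.05 0.80 0.10 0.05

MOTIF Gbox_like bZIP
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.10 0.70 0.10 0.10
0.05 0.85 0.05 0.05
0.88 0.04 0.04 0.04
0.04 0.88 0.04 0.04
0.04 0.04 0.88 0.04
0.04 0.04 0.04 0.88
0.05 0.05 0.85 0.05
0.10 0.10 0.70 0.10

MOTIF Wbox_like WRKY
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.20 0.10 0.10 0.60
0.05 0.05 0.05 0.85
0.05 0.05 0.05 0.85
0.05 0.05 0.85 0.05
0.88 0.04 0.04 0.04
0.04 0.88 0.04 0.04
0.10 0.60 0.10 0.20
0.20 0.30 0.20 0.30

MOTIF MYBR_like MYB_related
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.60 0.10 0.20 0.10
0.88 0.04 0.04 0.04
0.04 0.88 0.04 0.04
0.04 0.88 0.04 0.04
0.20 0.10 0.10 0.60
0.88 0.04 0.04 0.04
0.88 0.04 0.04 0.04
0.10 0.70 0.10 0.10

MOTIF GATA_like GATA
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
0.10 0.10 0.10 0.70
0.05 0.05 0.05 0.85
0.88 0.04 0.04 0.04
0.04 0.04 0.04 0.88
0.88 0.04 0.04 0.04
0.04 0.88 0.04 0.04
0.60 0.10 0.20 0.10

MOTIF Kbox_like G2-like
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.05 0.05 0.85 0.05
0.88 0.04 0.04 0.04
0.04 0.04 0.04 0.88
0.04 0.04 0.04 0.88
0.05 0.85 0.05 0.05
0.10 0.60 0.20 0.10
0.88 0.04 0.04 0.04
0.10 0.10 0.70 0.10
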