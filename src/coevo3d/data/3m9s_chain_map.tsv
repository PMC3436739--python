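# Example chain -> unit mapping for PDB 3M9S (T. thermophilus complex I),
# pairing bacterial Nqo subunits with their human orthologs:
#   Nqo1=NDUFV1  Nqo2=NDUFV2  Nqo3=NDUFS1  Nqo4=NDUFS2  Nqo5=NDUFS3
#   Nqo6=NDUFS7  Nqo9=NDUFS8  Nqo8=NADH1   Nqo14=NADH2  Nqo13=NADH4
#   Nqo12=NADH5  Nqo7+Nqo10+Nqo11=NADH34L6 (merged: the three subunits are
#   direct neighbors and are treated as a single pooled unit).
# Chain IDs below follow the deposition convention chain "1".."9" for
# Nqo1..Nqo9 and "A".."F" for Nqo10..Nqo15.  Verify them against your
# local copy of the structure before use; the mapping is configuration,
# not code.
1	NDUFV1
2	NDUFV2
3	NDUFS1
4	NDUFS2
5	NDUFS3
6	NDUFS7
9	NDUFS8
8	NADH1
E	NADH2
D	NADH4
C	NADH5
7	NADH34L6
A	NADH34L6
B	NADH34L6
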