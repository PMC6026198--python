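# BLOSUM62 joint (target) frequencies q_ij, lower triangle.
# Row/column order: A R N D C Q E G H I L K M F P S T W Y V
# Entries sum to 1 over the lower triangle (diagonal counted once).
# The symmetric pair distribution is p(x,y) = q_xy / 2 for x != y, q_xx on
# the diagonal, so that the full 20x20 matrix sums to 1.
A 0.0215
R 0.0023 0.0178
N 0.0019 0.0020 0.0141
D 0.0022 0.0016 0.0037 0.0213
C 0.0016 0.0004 0.0004 0.0004 0.0119
Q 0.0019 0.0025 0.0015 0.0016 0.0003 0.0073
E 0.0030 0.0027 0.0022 0.0049 0.0004 0.0035 0.0161
G 0.0058 0.0017 0.0029 0.0025 0.0008 0.0014 0.0019 0.0378
H 0.0011 0.0012 0.0014 0.0010 0.0002 0.0010 0.0014 0.0010 0.0093
I 0.0032 0.0012 0.0010 0.0012 0.0011 0.0009 0.0012 0.0014 0.0006 0.0184
L 0.0044 0.0024 0.0014 0.0015 0.0016 0.0016 0.0020 0.0021 0.0010 0.0114 0.0371
K 0.0033 0.0062 0.0024 0.0024 0.0005 0.0031 0.0041 0.0025 0.0012 0.0016 0.0025 0.0161
M 0.0013 0.0008 0.0005 0.0005 0.0004 0.0007 0.0007 0.0007 0.0004 0.0025 0.0049 0.0009 0.0040
F 0.0016 0.0009 0.0008 0.0008 0.0005 0.0005 0.0009 0.0012 0.0008 0.0030 0.0054 0.0009 0.0012 0.0183
P 0.0022 0.0010 0.0009 0.0012 0.0004 0.0008 0.0014 0.0014 0.0005 0.0010 0.0014 0.0016 0.0004 0.0005 0.0191
S 0.0063 0.0023 0.0031 0.0028 0.0010 0.0019 0.0030 0.0038 0.0011 0.0017 0.0024 0.0031 0.0009 0.0012 0.0017 0.0126
T 0.0037 0.0018 0.0022 0.0019 0.0009 0.0014 0.0020 0.0022 0.0007 0.0027 0.0033 0.0023 0.0010 0.0012 0.0014 0.0047 0.0125
W 0.0004 0.0003 0.0002 0.0002 0.0001 0.0002 0.0003 0.0004 0.0002 0.0004 0.0007 0.0003 0.0002 0.0008 0.0001 0.0003 0.0003 0.0065
Y 0.0013 0.0009 0.0007 0.0006 0.0003 0.0007 0.0009 0.0008 0.0015 0.0014 0.0022 0.0010 0.0006 0.0042 0.0005 0.0010 0.0009 0.0009 0.0102
V 0.0051 0.0016 0.0012 0.0013 0.0014 0.0012 0.0017 0.0018 0.0006 0.0120 0.0095 0.0019 0.0023 0.0026 0.0012 0.0024 0.0036 0.0004 0.0015 0.0196
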