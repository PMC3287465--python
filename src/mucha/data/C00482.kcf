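# Sinapic acid (3,5-dimethoxy-4-hydroxycinnamic acid), hand-encoded.
# Numbering: benzene ring atoms 1-6 with the side-chain-bearing carbon as
# atom 1 and ring labels C8y-C8x-C8y-C8y-C8y along atoms 1-5 (atom 6 C8x);
# substituents breadth-first: 7 C2b (vinyl, on 1), 8 O2a (3-OMe oxygen),
# 9 O1a (4-OH), 10 O2a (5-OMe oxygen), 11 C2b (vinyl), 12/13 C1a (methyls),
# 14 C6a (carboxyl carbon), 15/16 O6a (carboxylate oxygens).
# Label conventions: C8y/C8x aromatic C with/without heteroatom substituent,
# C2b vinylic CH, C6a carboxyl C, O6a carboxyl O, O1a hydroxyl, O2a ether,
# C1a methyl.
ENTRY       C00482    Compound
ATOM        16
            1   C8y  C    0.0000    0.0000
            2   C8x  C    1.0000    0.0000
            3   C8y  C    2.0000    0.0000
            4   C8y  C    3.0000    0.0000
            5   C8y  C    2.0000    1.0000
            6   C8x  C    1.0000    1.0000
            7   C2b  C   -1.0000    0.0000
            8   O2a  O    2.0000   -1.0000
            9   O1a  O    4.0000    0.0000
            10  O2a  O    2.0000    2.0000
            11  C2b  C   -2.0000    0.0000
            12  C1a  C    3.0000   -1.0000
            13  C1a  C    3.0000    2.0000
            14  C6a  C   -3.0000    0.0000
            15  O6a  O   -4.0000    0.0000
            16  O6a  O   -3.0000    1.0000
BOND        16
            1     1   2 2
            2     2   3 1
            3     3   4 2
            4     4   5 1
            5     5   6 2
            6     6   1 1
            7     1   7 1
            8     3   8 1
            9     4   9 1
            10    5  10 1
            11    7  11 2
            12    8  12 1
            13   10  13 1
            14   11  14 1
            15   14  15 2
            16   14  16 1
///
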