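# p-Coumaryl alcohol 4-O-glucoside, hand-encoded.
# Numbering: benzene ring atoms 1-6 with the side-chain-bearing carbon as
# atom 1 and ring labels C8y-C8x-C8x-C8y-C8x along atoms 1-5 (atom 6 C8x);
# substituents breadth-first: 7 C2b (vinyl, on 1), 8 O2a (glycosidic O on 4),
# 9 C2b (vinyl), 10 C1y (anomeric glucose C), 11 C1b (allylic CH2),
# 12 O2x (pyranose ring O), 13 C1y (glucose C2'), 14 O1a (allylic OH),
# 15 C1y (glucose C5'), 16 C1y (glucose C3'), 17 O1a (2'-OH),
# 18 C1b (glucose C6'), 19 C1y (glucose C4'), 20 O1a (3'-OH),
# 21 O1a (6'-OH), 22 O1a (4'-OH).
# Sugar labels follow common KEGG conventions: ring CH carbons C1y,
# exocyclic CH2 C1b, ring oxygen O2x, hydroxyls O1a, glycosidic ether O2a.
ENTRY       C05855    Compound
ATOM        22
            1   C8y  C    0.0000    0.0000
            2   C8x  C    1.0000    0.0000
            3   C8x  C    2.0000    0.0000
            4   C8y  C    3.0000    0.0000
            5   C8x  C    2.0000    1.0000
            6   C8x  C    1.0000    1.0000
            7   C2b  C   -1.0000    0.0000
            8   O2a  O    4.0000    0.0000
            9   C2b  C   -2.0000    0.0000
            10  C1y  C    5.0000    0.0000
            11  C1b  C   -3.0000    0.0000
            12  O2x  O    6.0000    0.0000
            13  C1y  C    5.0000   -1.0000
            14  O1a  O   -4.0000    0.0000
            15  C1y  C    7.0000    0.0000
            16  C1y  C    6.0000   -1.0000
            17  O1a  O    5.0000   -2.0000
            18  C1b  C    8.0000    0.0000
            19  C1y  C    7.0000   -1.0000
            20  O1a  O    6.0000   -2.0000
            21  O1a  O    9.0000    0.0000
            22  O1a  O    7.0000   -2.0000
BOND        23
            1     1   2 2
            2     2   3 1
            3     3   4 2
            4     4   5 1
            5     5   6 2
            6     6   1 1
            7     1   7 1
            8     4   8 1
            9     7   9 2
            10    8  10 1
            11    9  11 1
            12   10  12 1
            13   10  13 1
            14   11  14 1
            15   12  15 1
            16   13  16 1
            17   13  17 1
            18   15  18 1
            19   15  19 1
            20   16  19 1
            21   16  20 1
            22   18  21 1
            23   19  22 1
///
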