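# Monolignol panel: p-coumaryl, coniferyl and sinapyl alcohols, hand-encoded
# with consistent numbering. Ring atoms 1-6 (chain-bearing carbon = atom 1,
# 4-OH para), chain C2b(7)=C2b-C1b-O1a, methoxy groups O2a+C1a on ring
# positions 3 (coniferyl, sinapyl) and 5 (sinapyl). Methoxy counts across
# the panel: 0 / 1 / 2.
ENTRY       C02646    Compound
ATOM        11
            1   C8y  C    0.0000    0.0000
            2   C8x  C    1.0000    0.0000
            3   C8x  C    2.0000    0.0000
            4   C8y  C    3.0000    0.0000
            5   C8x  C    2.0000    1.0000
            6   C8x  C    1.0000    1.0000
            7   C2b  C   -1.0000    0.0000
            8   O1a  O    4.0000    0.0000
            9   C2b  C   -2.0000    0.0000
            10  C1b  C   -3.0000    0.0000
            11  O1a  O   -4.0000    0.0000
BOND        11
            1     1   2 2
            2     2   3 1
            3     3   4 2
            4     4   5 1
            5     5   6 2
            6     6   1 1
            7     1   7 1
            8     4   8 1
            9     7   9 2
            10    9  10 1
            11   10  11 1
///
ENTRY       C00590    Compound
ATOM        13
            1   C8y  C    0.0000    0.0000
            2   C8x  C    1.0000    0.0000
            3   C8y  C    2.0000    0.0000
            4   C8y  C    3.0000    0.0000
            5   C8x  C    2.0000    1.0000
            6   C8x  C    1.0000    1.0000
            7   C2b  C   -1.0000    0.0000
            8   O2a  O    2.0000   -1.0000
            9   O1a  O    4.0000    0.0000
            10  C2b  C   -2.0000    0.0000
            11  C1a  C    3.0000   -1.0000
            12  C1b  C   -3.0000    0.0000
            13  O1a  O   -4.0000    0.0000
BOND        13
            1     1   2 2
            2     2   3 1
            3     3   4 2
            4     4   5 1
            5     5   6 2
            6     6   1 1
            7     1   7 1
            8     3   8 1
            9     4   9 1
            10    7  10 2
            11    8  11 1
            12   10  12 1
            13   12  13 1
///
ENTRY       C02325    Compound
ATOM        15
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
            14  C1b  C   -3.0000    0.0000
            15  O1a  O   -4.0000    0.0000
BOND        15
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
            15   14  15 1
///
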