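# Reconstructed 5x5 binary digit font (synthetic).
# Designed to satisfy the structural constraints of the receptive-field
# classifiers: every digit carries a run of >= 3 pixels in some row or
# column, and digits 2 and 5 are mirror twins carrying the asymmetric
# marker patterns 10111 / 11101.

digit 0
01100
10001
10001
10001
01010

digit 1
00100
01000
00100
00100
01110

digit 2
01110
01010
01110
01101
00110

digit 3
11110
01001
01100
00001
10110

digit 4
10010
10010
11101
00010
00010

digit 5
01110
01010
01110
10110
01100

digit 6
00110
10000
11110
10001
01010

digit 7
11101
00001
00010
00100
00100

digit 8
01010
10001
00110
10001
01110

digit 9
11110
10000
01101
00001
01110
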