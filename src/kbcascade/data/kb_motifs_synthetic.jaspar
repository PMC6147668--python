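>KB1 synthetic-RELA-like
A  [  3  2  1 60 20  4  3  2  2  1 ]
C  [  2  2  2  3 25  8 10  6 95 96 ]
G  [ 93 94 96 35 30  3  2  2  2  2 ]
T  [  2  2  1  2 25 85 85 90  1  1 ]
>KB2 synthetic-NFKB1-like
A  [  2  1  1  2 55  5 15  3  2  2 ]
C  [  3  2  2  2  5  8 10 90 95 94 ]
G  [ 92 95 95 94 25  2  5  4  2  2 ]
T  [  3  2  2  2 15 85 70  3  1  2 ]
>KB3 synthetic-REL-like
A  [  4  2  2 55 50  5  4  2  2  2 ]
C  [  3  2  2  3  5 10  8  8 94 94 ]
G  [ 91 94 94 40 30  3  3  2  2  2 ]
T  [  2  2  2  2 15 82 85 88  2  2 ]
>KB4 synthetic-NFKB2-like
A  [  3  2  1  3 45 10  5  3  2  2 ]
C  [  2  2  2  2 10  5 12 88 94 95 ]
G  [ 93 94 95 92 25  5  3  4  2  1 ]
T  [  2  2  2  3 20 80 80  5  2  2 ]
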