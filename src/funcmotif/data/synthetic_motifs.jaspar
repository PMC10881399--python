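>SYN0522.1	TCF3_Ebox_synthetic
A  [  21 473 459   3 458  20  15  23  19  12   9  16 ]
C  [ 434  10  16 484  18  15 455  18  27  10   6  24 ]
G  [  26   6  14   6  13 450  11  17 439   6  13 440 ]
T  [  19  11  11   7  11  15  19 442  15 472 472  20 ]
>SYN0028.2	ELK1_ETS_synthetic
A  [ 481 471   6  17   8  14 454 475   3  21  18   6 ]
C  [  10   9 474 440   6  19  14   9  12  21  19   8 ]
G  [   4  10  10  23 482 454  14   6 476  17 445 473 ]
T  [   5  10  10  20   4  13  18  10   9 441  18  13 ]
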