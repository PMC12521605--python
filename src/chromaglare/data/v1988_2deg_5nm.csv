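wavelength_nm,value
380,0.0002
385,0.0004
390,0.0008
395,0.0015
400,0.0028
405,0.0046
410,0.0074
415,0.0114
420,0.0175
425,0.0219
430,0.0273
435,0.0322
440,0.0379
445,0.0421
450,0.0468
455,0.0530
460,0.0600
465,0.0739
470,0.0910
475,0.1126
480,0.1390
485,0.1693
490,0.2080
495,0.2586
500,0.3230
505,0.4073
510,0.5030
515,0.6082
520,0.7100
525,0.7932
530,0.8620
535,0.9149
540,0.9540
545,0.9803
550,0.9950
555,1.0000
560,0.9950
565,0.9786
570,0.9520
575,0.9154
580,0.8700
585,0.8163
590,0.7570
595,0.6949
600,0.6310
605,0.5668
610,0.5030
615,0.4412
620,0.3810
625,0.3210
630,0.2650
635,0.2170
640,0.1750
645,0.1382
650,0.1070
655,0.0816
660,0.0610
665,0.0446
670,0.0320
675,0.0232
680,0.0170
685,0.0119
690,0.0082
695,0.0057
700,0.0041
705,0.0029
710,0.0021
715,0.0015
720,0.0010
725,0.0007
730,0.0005
735,0.0004
740,0.0002
745,0.0002
750,0.0001
755,0.0001
760,0.0001
765,0.0000
770,0.0000
775,0.0000
780,0.0000
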