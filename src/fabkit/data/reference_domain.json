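{
 "version": "toy-reference-1",
 "seed": 712,
 "positions": [
  [
   1,
   ""
  ],
  [
   2,
   ""
  ],
  [
   3,
   ""
  ],
  [
   4,
   ""
  ],
  [
   5,
   ""
  ],
  [
   6,
   ""
  ],
  [
   7,
   ""
  ],
  [
   8,
   ""
  ],
  [
   9,
   ""
  ],
  [
   10,
   ""
  ],
  [
   11,
   ""
  ],
  [
   12,
   ""
  ],
  [
   13,
   ""
  ],
  [
   14,
   ""
  ],
  [
   15,
   ""
  ],
  [
   16,
   ""
  ],
  [
   17,
   ""
  ],
  [
   18,
   ""
  ],
  [
   19,
   ""
  ],
  [
   20,
   ""
  ],
  [
   21,
   ""
  ],
  [
   22,
   ""
  ],
  [
   23,
   ""
  ],
  [
   24,
   ""
  ],
  [
   25,
   ""
  ],
  [
   26,
   ""
  ],
  [
   27,
   ""
  ],
  [
   28,
   ""
  ],
  [
   29,
   ""
  ],
  [
   30,
   ""
  ],
  [
   31,
   ""
  ],
  [
   32,
   ""
  ],
  [
   33,
   ""
  ],
  [
   34,
   ""
  ],
  [
   35,
   ""
  ],
  [
   36,
   ""
  ],
  [
   37,
   ""
  ],
  [
   38,
   ""
  ],
  [
   39,
   ""
  ],
  [
   40,
   ""
  ],
  [
   41,
   ""
  ],
  [
   42,
   ""
  ],
  [
   43,
   ""
  ],
  [
   44,
   ""
  ],
  [
   45,
   ""
  ],
  [
   46,
   ""
  ],
  [
   47,
   ""
  ],
  [
   48,
   ""
  ],
  [
   49,
   ""
  ],
  [
   50,
   ""
  ],
  [
   51,
   ""
  ],
  [
   52,
   ""
  ],
  [
   53,
   ""
  ],
  [
   54,
   ""
  ],
  [
   55,
   ""
  ],
  [
   56,
   ""
  ],
  [
   57,
   ""
  ],
  [
   58,
   ""
  ],
  [
   59,
   ""
  ],
  [
   60,
   ""
  ]
 ],
 "coreset": [
  [
   13,
   ""
  ],
  [
   14,
   ""
  ],
  [
   15,
   ""
  ],
  [
   16,
   ""
  ],
  [
   17,
   ""
  ],
  [
   18,
   ""
  ],
  [
   19,
   ""
  ],
  [
   20,
   ""
  ],
  [
   21,
   ""
  ],
  [
   22,
   ""
  ],
  [
   23,
   ""
  ],
  [
   24,
   ""
  ],
  [
   25,
   ""
  ],
  [
   26,
   ""
  ],
  [
   27,
   ""
  ],
  [
   28,
   ""
  ],
  [
   29,
   ""
  ],
  [
   30,
   ""
  ],
  [
   31,
   ""
  ],
  [
   32,
   ""
  ],
  [
   33,
   ""
  ],
  [
   34,
   ""
  ],
  [
   35,
   ""
  ],
  [
   36,
   ""
  ],
  [
   37,
   ""
  ],
  [
   38,
   ""
  ],
  [
   39,
   ""
  ],
  [
   40,
   ""
  ],
  [
   41,
   ""
  ],
  [
   42,
   ""
  ],
  [
   43,
   ""
  ],
  [
   44,
   ""
  ],
  [
   45,
   ""
  ],
  [
   46,
   ""
  ],
  [
   47,
   ""
  ],
  [
   48,
   ""
  ]
 ],
 "origin": [
  0.0,
  0.0,
  0.0
 ],
 "v1": [
  0.4082482904638631,
  0.4082482904638631,
  0.8164965809277261
 ],
 "v2": [
  0.5773502691896258,
  0.5773502691896258,
  -0.5773502691896258
 ],
 "coords": [
  [
   -17.675270922293564,
   -4.976569268895986,
   -4.779360914977108
  ],
  [
   -13.233872579634909,
   -4.473200506687137,
   -5.078102566570805
  ],
  [
   -9.426550329850881,
   -4.828727429491473,
   -4.776568944992618
  ],
  [
   -5.828077121564355,
   -4.203208082038098,
   -5.120544420323058
  ],
  [
   -2.213975446218488,
   -4.997319140289878,
   -5.425157737806915
  ],
  [
   1.113144110173191,
   -4.855137258545568,
   -3.9597664764721494
  ],
  [
   6.140283303395303,
   -4.94281866565615,
   -4.834250637967203
  ],
  [
   9.577227032466674,
   -5.056904812812171,
   -4.6033958734359794
  ],
  [
   12.962494716078323,
   -4.8444928875533675,
   -4.677578440416185
  ],
  [
   17.040553885623268,
   -4.870778687098183,
   -5.255696645430284
  ],
  [
   -17.351165647228125,
   -4.893727776652345,
   0.1600455590294022
  ],
  [
   -13.203895065206536,
   -4.377030986709773,
   -0.34386400965467395
  ],
  [
   -9.634877651915396,
   -5.242763659362604,
   0.23141593030419133
  ],
  [
   -5.694921138674371,
   -4.918682687690068,
   -0.18079627123748634
  ],
  [
   -1.9723528214301145,
   -4.893960874133201,
   0.08451183257319098
  ],
  [
   1.652932658963805,
   -5.174916532821649,
   -0.3167929742336341
  ],
  [
   5.435921705589825,
   -4.6036835407379595,
   -0.14583902206873742
  ],
  [
   9.84444007456501,
   -4.6027686266848455,
   0.2442659683434483
  ],
  [
   13.12519090294017,
   -5.032810822434923,
   -0.7020748590441802
  ],
  [
   16.78911016431783,
   -4.9186878005778745,
   -0.31292698581019707
  ],
  [
   -17.024728164308407,
   -5.263342553387444,
   4.818748971200276
  ],
  [
   -13.540679088116333,
   -5.274247503113541,
   4.65640568847514
  ],
  [
   -9.109990909672112,
   -4.487683702902237,
   5.0825584696508095
  ],
  [
   -5.51829091597984,
   -4.861960054894156,
   4.61676504350626
  ],
  [
   -0.9838733950395062,
   -5.306589893834631,
   5.151583519576639
  ],
  [
   1.9380641909227025,
   -4.9216397672878625,
   4.770940290067459
  ],
  [
   5.799047222640869,
   -5.109215302863016,
   5.039438341691894
  ],
  [
   9.808719877706539,
   -5.269186350084064,
   4.482571882107044
  ],
  [
   13.361328594812882,
   -5.29530612641702,
   4.49963732226681
  ],
  [
   17.10576277420145,
   -4.790957572580279,
   5.351507411577617
  ],
  [
   -16.947627211131465,
   5.325896736410951,
   -4.654927606171561
  ],
  [
   -13.246262494608008,
   4.716184124338592,
   -4.243976938328766
  ],
  [
   -9.937337179596769,
   4.849136908142569,
   -4.730049082078914
  ],
  [
   -5.452488985201426,
   4.873060103420492,
   -4.723479089609658
  ],
  [
   -2.370411809229447,
   4.478696995547591,
   -4.949893556324176
  ],
  [
   1.723420388688323,
   4.864260964502432,
   -4.612608218155017
  ],
  [
   5.967613494402834,
   5.091711309644129,
   -4.85766525343164
  ],
  [
   9.309653895535444,
   4.8787632525745686,
   -5.110636982320792
  ],
  [
   13.083622499933474,
   4.737423467054277,
   -4.400816671453759
  ],
  [
   16.97031281532942,
   5.407205790079449,
   -5.45497926654537
  ],
  [
   -17.14038316952775,
   4.91853973491791,
   0.34749337825653237
  ],
  [
   -13.041458089583589,
   5.412824782456622,
   0.26132463751080887
  ],
  [
   -9.33265079140952,
   5.109609914395797,
   0.1929920301724047
  ],
  [
   -5.757913186121419,
   5.3323071462393345,
   -0.18474489784174403
  ],
  [
   -1.8748865745493772,
   5.14415335119086,
   -0.2774794768210629
  ],
  [
   1.4387619895886445,
   4.573743712810704,
   0.011655808190419037
  ],
  [
   5.580283224894634,
   4.711660547596281,
   -0.24438661524964442
  ],
  [
   9.646947101060992,
   5.543224530484816,
   0.26025724125540767
  ],
  [
   12.700881898666093,
   4.820948057302218,
   -0.43915907182085595
  ],
  [
   17.299712326251537,
   5.202205748798031,
   -0.005826883662524687
  ],
  [
   -17.34098620221448,
   5.313671967046075,
   4.844696608745032
  ],
  [
   -13.325280850996084,
   4.947050979420163,
   4.871483091759485
  ],
  [
   -10.159601563361196,
   4.855674730054942,
   4.382681110326402
  ],
  [
   -5.61543303722352,
   5.35900602907682,
   5.005617911969346
  ],
  [
   -2.0507087912884834,
   4.897526741442708,
   4.212198530899339
  ],
  [
   1.7283305448230928,
   5.008144935871608,
   4.548148660912092
  ],
  [
   5.071328138632285,
   5.333963271071841,
   5.003544464014409
  ],
  [
   9.819434095860437,
   4.956405512168232,
   4.438597627395304
  ],
  [
   12.58644915045382,
   5.256057775842992,
   5.108545544056434
  ],
  [
   17.09043527282498,
   5.324576680173633,
   4.7887671969673296
  ]
 ]
}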