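{
 "schema_version": 99,
 "specimen_id": "MAL",
 "side": "R",
 "sex": "unknown",
 "age": null,
 "landmarks": {
  "head_surface": [
   [
    47.177154622579984,
    20.676838520886633,
    21.241967991662985
   ],
   [
    31.061444258724755,
    28.86108015270146,
    18.941967991662988
   ],
   [
    41.325420597718164,
    5.522018705763632,
    16.641967991662987
   ],
   [
    50.62999751041425,
    34.54777875824334,
    14.341967991662989
   ],
   [
    21.080255277997832,
    17.331014527789588,
    12.041967991662988
   ],
   [
    57.32585107302668,
    9.652628544108817,
    9.741967991662987
   ],
   [
    34.40216906694718,
    41.48340455831128,
    7.441967991662986
   ],
   [
    29.73116684694871,
    0.9136688451490222,
    5.1419679916629875
   ],
   [
    61.35536460143784,
    28.47746080606904,
    2.841967991662988
   ],
   [
    18.76205069811965,
    29.44165930439127,
    0.5419679916629885
   ],
   [
    49.73167161264854,
    -0.12899359226831209,
    -1.7580320083370136
   ],
   [
    46.80105553791866,
    42.37431871904809,
    -4.05803200833701
   ],
   [
    20.727452438045987,
    9.510665053178483,
    -6.3580320083370125
   ],
   [
    61.038123891724794,
    16.050656225085973,
    -8.658032008337015
   ],
   [
    28.18244585477734,
    37.47956004946836,
    -10.958032008337012
   ],
   [
    37.526872450197715,
    1.627328355279566,
    -13.258032008337013
   ],
   [
    53.36031428024553,
    31.940796589445362,
    -15.55803200833701
   ],
   [
    24.795328025996838,
    21.30540950467089,
    -17.858032008337013
   ],
   [
    48.58358539520073,
    12.130453872741574,
    -20.158032008337013
   ],
   [
    39.66367161386502,
    27.85092046101875,
    -22.45803200833701
   ]
  ],
  "neck_station_centroids": [
   [
    -14.249016475665748,
    0.4732263585567864,
    -41.89442910939427
   ],
   [
    -0.6879106256438554,
    5.524129399139248,
    -31.572829834129955
   ],
   [
    12.873195224378037,
    10.57503243972171,
    -21.25123055886564
   ],
   [
    26.434301074399933,
    15.625935480304172,
    -10.929631283601324
   ],
   [
    39.99540692442182,
    20.676838520886633,
    -0.6080320083370125
   ]
  ],
  "canal_centroids": [
   [
    0.0,
    0.0,
    -0.0
   ],
   [
    0.0,
    -0.04166642554059763,
    -9.999884259661137
   ],
   [
    0.0,
    -0.1666628086777564,
    -19.999074086934073
   ],
   [
    0.0,
    -0.3749804691567533,
    -29.996875097654797
   ],
   [
    0.0,
    -0.6666049405578178,
    -39.99259300410434
   ],
   [
    0.0,
    -1.0415159712981676,
    -49.9855336632229
   ],
   [
    0.0,
    -1.4996875260403613,
    -59.975003124813995
   ],
   [
    0.0,
    -2.0410877874996913,
    -69.96030767973508
   ],
   [
    0.0,
    -2.66567915865312,
    -79.9407539080716
   ],
   [
    0.0,
    -3.3734182653508924,
    -89.91564872729082
   ],
   [
    0.0,
    -4.164255959328557,
    -99.8842994403723
   ],
   [
    0.0,
    -5.038137321619615,
    -109.8460137839116
   ],
   [
    0.0,
    -5.995001666369035,
    -119.80009997619379
   ],
   [
    0.0,
    -7.034782545049211,
    -129.74586676523361
   ],
   [
    0.0,
    -8.157407751072014,
    -139.68262347677876
   ],
   [
    0.0,
    -9.36279932480511,
    -149.60968006227324
   ],
   [
    0.0,
    -10.650873558984813,
    -159.52634714677689
   ],
   [
    0.0,
    -12.021541004528899,
    -169.4319360768386
   ],
   [
    0.0,
    -13.474706476749361,
    -179.32575896831906
   ],
   [
    0.0,
    -15.010269061960798,
    -189.20712875416024
   ],
   [
    0.0,
    -16.62812212448989,
    -199.07535923209804
   ],
   [
    0.0,
    -18.328153314079827,
    -208.92976511231512
   ],
   [
    0.0,
    -20.11024457369217,
    -218.76966206503008
   ],
   [
    0.0,
    -21.974272147705733,
    -228.59436676802005
   ],
   [
    0.0,
    -23.92010659051016,
    -238.40319695407345
   ],
   [
    0.0,
    -25.9476127754956,
    -248.19547145836924
   ],
   [
    0.0,
    -28.0566499044362,
    -257.97051026578
   ],
   [
    0.0,
    -30.24707151726807,
    -267.72763455809456
   ],
   [
    0.0,
    -32.51872550225926,
    -277.46616676115826
   ],
   [
    0.0,
    -34.871454106573765,
    -287.1854305919263
   ],
   [
    0.0,
    -37.305093947226396,
    -296.88475110542754
   ],
   [
    0.0,
    -39.819476022428034,
    -306.56345474163516
   ],
   [
    0.0,
    -42.41442572332335,
    -316.2208693722421
   ],
   [
    0.0,
    -45.089762846114354,
    -325.85632434733543
   ],
   [
    0.0,
    -47.84530160457666,
    -335.46915054196984
   ],
   [
    0.0,
    -50.68085064295883,
    -345.0586804026338
   ],
   [
    0.0,
    -53.59621304927282,
    -354.62424799360747
   ],
   [
    0.0,
    -56.59118636896778,
    -364.165189043208
   ],
   [
    0.0,
    -59.66556261898904,
    -373.6808409899188
   ],
   [
    0.0,
    -62.81912830222109,
    -383.17054302840114
   ],
   [
    0.0,
    -66.05166442231484,
    -392.63363615538265
   ]
  ],
  "gt_tip": [
   [
    -10.0,
    0.0,
    8.0
   ]
  ],
  "neck_lateral_entry": [
   [
    -14.249016475665748,
    0.4732263585567864,
    -41.89442910939427
   ]
  ],
  "dicn": [
   [
    0.0,
    -66.05166442231484,
    -392.63363615538265
   ]
  ],
  "condyle_post_medial": [
   [
    22.0,
    -81.05166442231484,
    -392.63363615538265
   ]
  ],
  "condyle_post_lateral": [
   [
    -22.0,
    -81.05166442231484,
    -392.63363615538265
   ]
  ]
 }
}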